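"""A small atom-selection language.

Grammar (case-insensitive keywords)::

    expr     := and_expr ('or' and_expr)*
    and_expr := unary ('and' unary)*
    unary    := 'not' unary | '(' expr ')' | primary
    primary  := 'element' SYM+ | 'name' NAME+ | 'resname' NAME+
              | 'resnum' ITEM+ | 'chain' ID+ | 'water' | 'protein'
              | 'backbone' | 'hydrogen' | 'heavy' | 'all'

``resnum`` items are integers or inclusive ranges ``a-b``.  Examples:
``"name CA"``, ``"resnum 29-49"``, ``"chain A and not water"``.
"""

from __future__ import annotations

import re

import numpy as np

from .structures import MolecularStructure, STANDARD_AMINO_ACIDS, WATER_RESNAMES

__all__ = ["select", "SelectionSyntaxError"]

_KEYWORDS = {
    "element", "name", "resname", "resnum", "chain",
    "water", "protein", "backbone", "hydrogen", "heavy", "all",
    "and", "or", "not", "(", ")",
}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionSyntaxError(ValueError):
    """Selection expression could not be parsed; names the bad token."""


class _Parser:
    def __init__(self, expression: str, structure: MolecularStructure):
        self.tokens = _TOKEN_RE.findall(expression)
        self.pos = 0
        self.s = structure
        self.n = structure.n_atoms

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression")
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of selection expression")
        if tok.lower() == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.peek() != ")":
                raise SelectionSyntaxError("missing closing parenthesis")
            self.next()
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in _KEYWORDS:
                break
            vals.append(self.next())
        if not vals:
            raise SelectionSyntaxError(f"keyword needs at least one value near token {self.pos}")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.next().lower()
        atoms = self.s.atoms
        if tok == "all":
            return np.ones(self.n, dtype=bool)
        if tok == "water":
            return np.array([a.residue_name.upper() in WATER_RESNAMES for a in atoms])
        if tok == "protein":
            return np.array([a.residue_name.upper() in STANDARD_AMINO_ACIDS for a in atoms])
        if tok == "backbone":
            bb = {"N", "CA", "C", "O"}
            return np.array(
                [a.residue_name.upper() in STANDARD_AMINO_ACIDS and a.name.upper() in bb for a in atoms]
            )
        if tok == "hydrogen":
            return np.array([a.element.upper() == "H" for a in atoms])
        if tok == "heavy":
            return np.array([a.element.upper() != "H" for a in atoms])
        if tok == "element":
            wanted = {v.upper() for v in self._values()}
            return np.array([a.element.upper() in wanted for a in atoms])
        if tok == "name":
            wanted = {v.upper() for v in self._values()}
            return np.array([a.name.upper() in wanted for a in atoms])
        if tok == "resname":
            wanted = {v.upper() for v in self._values()}
            return np.array([a.residue_name.upper() in wanted for a in atoms])
        if tok == "chain":
            wanted = {v for v in self._values()}
            return np.array([a.chain_id in wanted for a in atoms])
        if tok == "resnum":
            mask = np.zeros(self.n, dtype=bool)
            for item in self._values():
                m = re.fullmatch(r"(-?\d+)-(-?\d+)", item)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                elif re.fullmatch(r"-?\d+", item):
                    lo = hi = int(item)
                else:
                    raise SelectionSyntaxError(f"bad resnum item {item!r}")
                mask |= np.array([lo <= a.residue_number <= hi for a in atoms])
            return mask
        raise SelectionSyntaxError(f"unknown selection token {tok!r}")


def select(structure: MolecularStructure, expression: str) -> np.ndarray:
    """Evaluate a selection expression; returns sorted atom indices."""
    mask = _Parser(expression, structure).parse()
    return np.flatnonzero(mask)
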