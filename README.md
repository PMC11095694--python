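# lcpscan

Geometric and energetic analysis tools for enzymes with **buried active
sites acting on polymeric substrates** — written around the latex clearing
protein LcpK30, a heme *b* enzyme that oxidatively cleaves the C=C bonds of
cis-1,4-polyisoprene (natural rubber) into oligoisoprenoids. Because the
heme cofactor sits deep inside the protein, understanding catalysis means
answering geometric questions: which tunnels connect the surface to the
active site, which cavities can hold a hydrophobic polymer chain, which
double bond of the bound chain sits close enough to the heme-bound O₂ to
react, and what interactions hold the complex together.

`lcpscan` implements that tool chain as a reusable library + CLI:

- **Tunnel detection** — a free-radius field on a regular grid, Dijkstra
  minimum-cost paths (cost `ds/r²`) from a buried start point to bulk
  solvent, CAVER-style parameters (minimum probe radius 0.9 Å, shell
  radius 3 Å, shell depth 4 Å), and average-linkage clustering of
  centerlines (threshold 3.5) with per-cluster bottleneck / length /
  curvature / throughput / priority statistics.
- **Pocket detection** — alpha spheres (Voronoi-vertex tangent spheres,
  radii 3.4–6.2 Å measured to atom centers), single-linkage clustering
  with a ≥ 15-sphere rule, Monte-Carlo pocket volumes with binomial
  standard errors, and an apolar-lining hydrophobicity fraction.
- **Trajectory metrics** — Kabsch superposition, RMSD/RMSF profiles,
  cartesian backbone PCA (N, Cα, C, O) with porcupine-mode export
  (motions ≥ 2 Å), radial distribution functions, and moving-average
  trajectory smoothing (window 5).
- **Polymer builder** — idealized cis-1,4-polyisoprene n-mers
  (C₅ₙH₈ₙ₊₂; n = 10 gives the C₅₀H₈₂ substrate model), with double bonds
  numbered from the dimethyl terminus, chain-width estimation, and the
  cleavage-product rule: cleaving bond *k* of an *n*-mer leaves oligomers
  with *k−1* and *n−k* intact C=C bonds.
- **Binding analysis** — per-residue contact fractions (5 Å cutoff,
  4.5 % report threshold), extended / folded / extended-like pose
  classification, near-attack-conformation (NAC) profiling of
  C=C-to-distal-O₂ distances (< 4 Å) with the implied fragment-size
  spectrum, and a linear interaction energy (LIE) decomposition into
  van der Waals and electrostatic terms.
- **Synthetic fixtures** — wall-atom channels with analytic clearance,
  hollow shells with analytic void volume, trajectories with planted
  contact schedules, NAC dip schedules, two-state displacements and
  uniform-gas frames, each with a JSON manifest of the planted truth.

## Worked example

Build the substrate model, find the tunnel of a synthetic channel with a
known 1.5 Å clearance, and recover a planted cleavage profile:

```bash
$ lcpscan build-polymer --units 10 --out substrate.pdb
built 10-mer: C50H82, 10 C=C bonds, width 4.19 Å

$ lcpscan simulate channel --seed 7 --out ch/
$ lcpscan tunnels --pdb ch/channel.pdb --start "0,0,3.7" --out tunnels.tsv
$ cat tunnels.tsv
id  bottleneck  length     curvature  throughput  cost
1   1.089566    11.200000  1.000000   0.430697    9.434322

$ lcpscan simulate binding --seed 7 --n-frames 1000 --out bind/
$ lcpscan cleavage --traj bind/binding.pdb --out cleavage.tsv
$ cat cleavage.tsv
bond  nac_count  fraction
...
5     100        0.100000
...
```

The builder prints the substrate formula (C50H82 at n = 10) and its
extended-chain width. The tunnel table reports one tunnel whose
bottleneck (1.09 Å) matches the fixture's planted clearance to within the
grid discretization: the structure was written with its wall atoms'
planted radii replaced by the default united-atom table on re-reading, so
the effective clearance shrinks slightly below 1.5 Å. The cleavage
profile recovers the planted near-attack schedule exactly — 100 of 1000
frames on bond 5 — and the derived fragment spectrum puts equal weight on
4- and 5-unit oligomers, the products of cleaving the central bond of a
10-mer.

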