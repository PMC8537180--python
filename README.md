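# specmap

Mapping the specificity landscape of an enzyme family from sequence
alone: correlated mutations analysis (CMA) of a family multiple
sequence alignment, rule-based selection of specificity-determining
positions, per-clade fingerprint motifs, motif-based specificity and
mechanism prediction, colored-ring phylogeny annotation, and
Michaelis–Menten characterization of candidate enzymes.

The package is written for protein-family curators and enzyme hunters.
The motivating use case is Glycoside Hydrolase Family 65 (GH65), a
family of inverting α-glucoside phosphorylases and hydrolases with 10
characterized specificities (maltose/trehalose/kojibiose/nigerose
phosphorylases, trehalases, and relatives), where a handful of
co-evolving alignment positions act as a specificity fingerprint and
led to the discovery of a dedicated kojibiose hydrolase. Everything is
testable offline: a synthetic-family generator plants a known
co-evolution network over subfamily structure, so each pipeline stage
can be validated against ground truth without any database downloads.

## The model

**Specificity-determining positions** are alignment columns conserved
within each substrate specificity but divergent between specificities.
Because a function-switching substitution typically requires
compensatory changes, such columns co-evolve, and the pairwise signal
is measurable. For columns *i*, *j* the package scores

> NMI(i, j) = MI(i, j) / min(H(i), H(j)) ∈ [0, 1]

— weighted mutual information in bits over the joint residue
distribution (Henikoff position-based sequence weights,
pairwise-complete deletion of gaps and X), normalized by the smaller
column entropy. A co-evolution network is built from pairs with
NMI ≥ 0.8, and positions with at least one score > 0.9 *and* at least
two partners at ≥ 0.8 are selected as the family's fingerprint.

Per subgroup (clade) of the family tree, the residues at the selected
positions are summarized as a consensus motif (e.g. `KV[MF]NES` for
maltose phosphorylases, `EEAPxx` for kojibiose phosphorylases);
classification of a query motif maximizes the fraction of matched
informative positions. Kinetic confirmation uses nonlinear
least-squares Michaelis–Menten fitting, v = V·S/(K<sub>M</sub>+S),
with k<sub>cat</sub> = V·MW/60 converting specific activity (U/mg,
U = µmol/min) to turnover per second.

## Worked example

`examples/01_simulate_and_discover.py` generates the shipped benchmark
family — 22 subfamilies × 50 sequences plus a reference row, 600
columns, 24 planted co-evolving columns, 2% per-site noise — and
rediscovers the planted network:

```
family: 1101 sequences x 600 columns, 22 subgroups
positions with a correlation score >= 0.8: 24
hub position 392 has 20 correlation partners
selected specificity-determining positions: [64, 392, 394, 402, 416, 585]
```

24 positions carry at least one strong pairwise signal; position 392
is the network hub with 20 partners; the two-stage rule narrows the
fingerprint to six positions (numbered in the reference sequence's
residue numbering). `examples/02_fingerprints_and_classification.py`
then classifies four query motifs read off real candidate sequences:

```
query TRIGPP -> TP (match 1.00)        # trehalose phosphorylase
query FAITQA -> oligoNP (match 1.00)   # α-1,3-oligoglucan phosphorylase
query EEAPWS -> KP (match 1.00)        # kojibiose phosphorylase
query DQGQDE -> T6PP (match 1.00)      # trehalose-6-phosphate phosphorylase
```

and `examples/04_kinetics.py` fits simulated triplicate initial rates
(nine concentrations, 0.25–10 mM, 3% noise):

```
K_M   = 0.765 +- 0.026 mM
k_cat = 9.76 +- 0.10 1/s
k_cat/K_M = 12.76 1/(mM s)  (2 s.f.: 13)
```

recovering the generating parameters (K<sub>M</sub> 0.77 mM,
k<sub>cat</sub> 9.9 s⁻¹) within the noise.

## Command line

A thin CLI wraps the library: `specmap preprocess` (redundancy filter
at 90% identity, catalytic-residue filter, ≥95% gap-column trim),
`specmap cma`, `specmap select`, `specmap motifs`, `specmap classify`,
`specmap annotate` (iTOL COLORSTRIP rings, RasMol colors),
`specmap simulate family|mm`, `specmap fitmm`, and `specmap run` for
the whole pipeline from a YAML config with a reproducible manifest.

## Layout

- `src/specmap/` — library (`family_io`, `preprocess`, `cma`,
  `fingerprints`, `tree_annotation`, `kinetics`, `simulate`,
  `pipeline`, `cli`)
- `src/specmap/data/` — packaged specificity vocabulary, fingerprint
  motifs, and the benchmark family config
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, parameter choices, and limitations
- `tests/` — pytest suite with independent oracles
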