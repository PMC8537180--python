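# Methods

## The correlation statistic

The pairwise column score is weighted normalized mutual information,

    score(i, j) = MI(i, j) / min(H(i), H(j)),

computed in bits. Residue counts are weighted by Henikoff
position-based sequence weights (a sequence carrying residue *a* among
*n_a* alike out of *k* distinct residues at a column contributes
1/(k·n_a); per-sequence sums are normalized to total the number of
sequences; rows consisting entirely of gaps/X receive the mean weight
so the positivity invariant holds). Gap handling is pairwise-complete:
rows with `-` or `X` at either column are dropped from that pair's
counts. The min-entropy normalization bounds the score in [0, 1], is
symmetric, equals 1 exactly when either column is a deterministic
function of the other on the retained rows, and tends to 0 for
independent columns as the number of sequences grows.

Dedicated coevolution servers do not publish their statistic; the
package therefore fixes a fully specified, reproducible one and
exposes it as a pluggable kernel (`cma_matrix(statistic=...)`) so that
variants (e.g. with average-product correction) can be swapped in. APC
is deliberately **off** by default: it changes the meaning of absolute
thresholds like 0.8, and the selection semantics here are defined on
the plain normalized MI.

Masking: a pair is undefined (NaN) when fewer than `min_pairs = 20`
rows survive pairwise-complete deletion or when either column's
weighted entropy is below `h_min = 0.1` bits. Normalized MI is
unstable at low counts and meaningless at zero entropy; both cutoffs
are configuration-exposed.

Finite-sample behavior matters for interpretation: with ~10³
sequences and 20-letter columns, the empirical NMI of independent
columns is biased upward by roughly (q−1)²/(2·N·ln2·H) ≈ 0.05–0.08,
not 0. The thresholds (edge 0.8, strong 0.9) therefore act on scores
that include this estimator bias, which is the same regime in which
such thresholds are used in practice. Independence tests assert
< 0.05 only at N = 2000 where the bias for the 2-column case is small.

## Position selection

Two-stage rule: build the network from pairs with score ≥ `edge
threshold` (default 0.8); select positions with (a) maximum pair score
strictly above `strong threshold` (default 0.9) and (b) at least
`min_partners` (default 2) network partners. Output is sorted by
reference residue number; all user-facing positions are 1-based and
translated through the reference-sequence numbering map (k-th non-gap
residue of the reference row ↔ its alignment column).

## Curation rules

Order is fixed: redundancy → catalytic filter → gap-column trim.

* **Redundancy**: exact greedy longest-first clustering (ties by id);
  a sequence joins the first representative with identity strictly
  above the threshold (default 0.90). Identity is matches in a global
  alignment (match 1 / mismatch 0 / linear gap −1) divided by the
  shorter sequence's length — the short-sequence convention of common
  clustering tools, with scoring pinned so results are bit-stable. No
  k-mer prefilter: desk-scale families (≤ a few thousand members) do
  not need heuristics, and exactness permits an all-pairs oracle test.
  A keep-list re-adds annotated representatives even when redundant.
* **Catalytic filter**: rows whose residue at a user-supplied column
  is outside the allowed set (default {D, E}, the catalytic acid)
  are removed. The column must be supplied: the package does not guess
  active-site positions. "Lacking" can mean gap-only or any non-D/E,
  controlled through `allowed_residues`.
* **Trim**: columns with gap fraction ≥ 0.95 are removed (`-` only;
  `X` is an unknown residue, not a gap). Idempotent by construction.
  Correlation analysis always runs on the trimmed alignment.

## Fingerprint motifs and classification

Per subgroup and selected position, sequence-weighted residue
frequencies exclude gaps from the normalization; information content
is log2(20) − H (Schneider–Stephens, no small-sample correction).
Consensus tokens: a single residue if its frequency ≥ 0.5 and leads
the runner-up by ≥ 0.2; a bracketed pair `[AB]` if the top two each
reach 0.2 and jointly 0.7; otherwise `x`. Logo-style renderings do not
print their consensus rules; these defaults reproduce the reference
motif strings on fixture data and are configuration-exposed. Tie
ranking falls back to descending alphabetical order, matching the
conventional `[MF]` rendering.

Classification scores each reference motif by matched informative
positions over informative positions (`x` excluded from the
denominator, so `EEAPxx` is a four-position constraint; `[MF]`
accepts M or F). Ties and scores below the acceptance threshold
(default 0.8) return `unknown`. The packaged fingerprint table
contains only motifs documented as text for GH65 (MP `KV[MF]NES`, KP
`EEAPxx`, TP `TRIGPP`, oligoNP `FAITQA`, T6PP `DQGQDE`, plus the
singleton subgroup-7 motif `SVSWRQ`); figure-only logos are not
transcribed.

Mechanism calls (phosphorylase vs hydrolase) require the caller to
configure phosphate-binding positions and their phosphorylase residue
sets — these are structural knowledge the sequence pipeline cannot
derive. All configured positions matching → phosphorylase; any
deviation → hydrolase; any gap → undetermined.

## Tree annotation

The automated subgroup heuristic is a reconstruction aid, not a
substitute for expert curation; user-supplied partitions always take
precedence. Top-down traversal assigns the first (largest) clade on
each root-to-leaf path with ≥ `min_clade_size` (default 5) leaves and
homogeneity ≥ 0.9 at the selected positions. Homogeneity is the mean,
over selected positions, of the modal-residue frequency among the
clade's leaves. The per-position definition is deliberate: exact
residue-string agreement decays geometrically with the number of
positions (at 5% per-site noise and six positions only ~74% of
members match the modal string exactly), whereas per-position modal
frequency stays near 1 − ε and degrades gracefully. Stricter
homogeneity always yields a refinement of the looser partition.

Ring export writes one iTOL COLORSTRIP dataset per selected position,
ordered inner→outer by ascending reference number, with the classic
RasMol amino color classes (D/E share one color, K/R another, gap =
neutral white). Files are byte-stable given identical inputs.

## Kinetics

Unweighted nonlinear least squares of v = V·S/(K_M+S) (the common
default of commercial fitting software; weighting is configurable),
started from a Hanes–Woolf linearization, parameters bounded positive.
Units: S in mM, v in U/mg with U = µmol/min, k_cat = V·MW/60 per
second with MW in kDa (1 kDa = 1 mg/µmol). Identifiability is checked
explicitly — K_M estimated far outside the measured concentration
range (×100 beyond either end) or with an unbounded standard error
raises an error instead of returning a spurious number. Catalytic
efficiency k_cat/K_M is reported both raw and rounded to two
significant figures (0.77 mM and 9.9 s⁻¹ give 12.86, which prints
as 13).

## The synthetic-family generator

Each sequence takes its subgroup's residue at every planted column,
flipped to a uniformly random other residue with probability ε, and
draws the remaining columns i.i.d. from a typical database amino-acid
composition, independent of subgroup; gaps are sprinkled uniformly at
`gap_rate`. A star-of-ladders tree (one clade per subgroup) and a
ground-truth record accompany every dataset; output is byte-identical
for equal seeds. An optional `background_drift` mode adds
subgroup-level profile drift to background columns, to stress-test the
statistic's known confounding of phylogeny and function.

The shipped benchmark (`gh65_analog_spec`) fixes 22 subgroups × 50
sequences, 600 columns, ε = 0.02, gap rate 0.01, seed 20210. Its 24
planted columns are block partitions of the 22 subgroups constructed
so the measured network reproduces the benchmark geometry at n ≈ 1100:

* six *strong* columns (reference positions 64, 392, 394, 402, 416,
  585) share one 16-block partition (six merged subgroup-pairs + ten
  singletons) — mutual scores ≈ 0.94, so each clears the 0.9 rule;
* fifteen *weak* columns realize the fifteen 4-subsets of the six
  merged pairs, splitting those pairs and merging singleton pairs via
  a second latent label — scores with the strong columns land
  ≈ 0.85 ∈ [0.8, 0.9), giving every strong column exactly 20 partners
  (5 strong + 15 weak) without qualifying for selection themselves;
* three *loop* columns carry near-orthogonal 7-block partitions:
  ≈ 0.85 with each other, ≈ 0.73 with everything else.

Expected scores were derived analytically from the block structure
under the ε-noise model and confirmed by simulation; design margins
exceed three standard deviations of sampling noise, so the counts
(24 positions ≥ 0.8, hub degree 20, six selected) are stable across
seeds. With only 20 residues available for 22 subgroups, and a
min-entropy normalization that sends any near-injective column to
score ≈ 1 against every other subgroup-determined column, sub-unity
score bands *require* non-injective crossed partitions; a side effect
is that subgroup pairs share their residues at the strong columns, so
fingerprints at those positions identify 11 subgroup pairs rather than
all 22 subgroups. Classifier self-consistency tests therefore use
smaller families with injective assignments.

What the generator does **not** emulate: phylogenetic autocorrelation
of background columns (unless `background_drift` is enabled), indel
structure beyond uniform gaps, rate variation across sites, and
compositional biases of real families. Passing the planted-recovery
tests shows the statistic and selection rule behave as specified under
the planted model; it does not certify performance on real alignments,
where phylogenetic confounding can create correlated columns unrelated
to specificity.

## Problem sizes and numerical choices

The benchmark analyses run on 1101 × 600 alignments (the CMA stage,
~180k column pairs, completes in seconds); kinetics fits use the
nine-point 0.25–10 mM design in triplicate, and the noise-recovery
suite uses 200 seeded replicates at 3% noise. Scores are clipped to
[0, 1] against floating-point round-off; selection ties are broken by
ascending reference number; all randomness flows from explicit
`numpy.random.default_rng` seeds.
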