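# Methods

`hgtscan` packages the computational evidence chain behind a horizontal gene
transfer (HGT) claim as independent, testable stages. This note documents
the models, the defaults and why they were chosen, the numerical choices,
and what the synthetic-data generators do and do not emulate.

## Bit-score density and the AGD statistic

For a query protein `q` and target `t`, the bit-score density is

    D(q, t) = bits(q, t) / bits(q, q),

the bit score of the optimal local alignment of `q` against `t` normalized
by the query's self-alignment bit score. Self-similarity is exactly 1, and
under a diagonally dominant substitution matrix the density lies in [0, 1],
giving a length-free similarity scale.

Scores come from Smith–Waterman local alignment with affine gaps
(BLOSUM62, gap open 11 / extend 1) converted to bits with the
Karlin–Altschul transform `bits = (λ·S − ln K) / ln 2` using the standard
gapped-BLOSUM62 parameters λ = 0.267, K = 0.041. A deliberate design
choice: deterministic pairwise alignment makes the statistic self-contained
and exactly reproducible, where profile-search scores depend on a database
snapshot and search heuristics. The divergence layer also accepts
externally computed bit scores from TSV (`agd_from_bits`) for users who
have them. Two conventions that differ between tools are fixed and
documented here: a gap of length L costs `open + L·extend`, and the
ambiguity character X scores 0 against everything. Only optimal scores are
used, never tracebacks, so DP tie-breaking is irrelevant.

The accumulated genetic divergence of a protein over a homolog triple
(reference, bridge, distal — e.g. a human protein, its amphioxus homolog,
and its cyanobacterial homolog) is

    AGD = D(ref, bridge) − D(ref, distal),

with the reference as the query in both comparisons so the two densities
share a denominator. AGD measures the extra divergence accumulated on the
deep comparison: large for vertically inherited conserved proteins, near
zero for a gene that entered the reference's lineage from near the distal
lineage after the bridge split. The subtraction is oriented so that AGD is
a positive divergence measure for vertical descent, matching the way panel
values are reported.

Control panels (26 universally conserved ribosomal proteins for vertical
descent, 19 mitochondrially located endosymbiotic-transfer candidates, 10
mitochondrially encoded proteins; membership ships as a TSV fixture) give a
null distribution. Panels are summarized by mean and sample (n−1) SD,
checked for normality with the Shapiro–Wilk test (normality retained when
p > 0.05), and a candidate AGD is tested as a z-score outlier. The default
test is one-tailed lower — the HGT hypothesis predicts anomalously *small*
AGD — so `z = −2.439` gives `p = Φ(z) ≈ 0.0074`; a two-tailed version would
double it. Φ is computed through the complementary error function and is
accurate to better than 1e−7 over |z| ≤ 8.

## K-mer composition scan

The k-mer spectrum of a DNA sequence is the vector of counts of the 4^k
words indexed lexicographically, normalized by the total number of words
counted (L1; an L2 option exists). Words containing N are not counted.
K-mers are counted on the given strand only; canonical (strand-collapsed)
counting is a documented switch away but not the default, since the scan
compares like with like.

The scan slides a window (default 1 kb, step 500 bp, k = 4) across the
genome and scores each window by the L1 distance between its spectrum and
the whole-genome spectrum, `Σ |f_w − f_g| ∈ [0, 2]`. Windows are emitted
only where a full window fits (`floor((L − window)/step) + 1` windows);
windows more than half N are reported missing rather than scored. The
genome average includes all positions — excluding the window under test
changes nothing asymptotically and complicates the rolling update, which
is maintained exactly (the tests hold it to a naive recount).

Because the underlying analysis is visual — deviation plotted along the
genome — the numeric flagging step is an explicit extension: windows whose
score exceeds the median by more than 5 normalized MADs (robust z) are
flagged and merged into intervals; if the MAD degenerates to zero the
flagger falls back to a quantile rule with a warning. Coordinates are
0-based half-open throughout; anomalies export as BED.

## Synapomorphy typing

PADI-like sequences fall into a three-domain type shared by animals and
late-diverging cyanobacteria ("Ai") and a two-domain actinobacterial/fungal
type ("Bi"). Diagnostic sites, in 1-based ungapped human-PADI2 numbering,
are mapped through alignment columns via a `ColumnMap` built from a
designated reference row.

The shipped rule TSV encodes: the catalytic/substrate residues
(D351, H471, D473, C647) as critical *conserved* rules that any confident
call must satisfy; calcium-site-6 residues 125/131 with the
binding-preserving substitutions D125N and E131D tolerated; the calcium
switch D389 (aspartate = Ai, glycine = metal-coordination-incompetent = Bi)
and the 300–302 triple-histidine connector motif as critical *diagnostic*
rules; and region-level rules (155–180, 292–302, calcium sites 2/4) as
advisory — reported, never decisive — because their residue composition is
not enumerated site-by-site in the source material. A sequence is Ai_like
when every critical rule with Ai states matches and no Bi marker fires,
Bi_like in the mirror case, and ambiguous otherwise (including gaps at any
critical position). Rule-level Ai/Bi state disjointness is enforced at
construction, so no sequence can satisfy both calls.

Per-group conservation is summarized as: single shared residue; `"X/Y"`
when exactly two residues occur (gapped members excluded as unevaluable);
else `"nc"` (not conserved) — the "one or two amino acids" consensus
convention read as exact set cardinality ≤ 2.

The shipped alignment fixture is synthetic (random sequences with the rule
sites set), generated deterministically in code; it exercises the
machinery and the numbering round-trip, not real PADI biology.

## Strict-clock root-age estimation

Given a rooted tree with branch lengths in expected substitutions/site and
normal fossil calibrations (mean, σ in Ma) on monophyletic clades, the
fitter minimizes

    Σ_branches (b_i − r·τ_i)² / max(b_i, ε)  +  Σ_cal ((t_c − μ_c)/σ_c)²

over the shared rate r and internal node ages t, with tips fixed at 0,
parent ≥ child ordering, and ε = 1e−6 substitutions/site. The weight
treats branch-length variance as proportional to branch length
(Poisson-like). This penalized weighted least squares is a deliberate,
documented stand-in for Bayesian MCMC dating: it tests the *logic* — can a
single rate plus fossil calibrations date the root? — with a deterministic,
seconds-fast estimator, and makes no claim to posterior inference;
relaxed-clock models are out of scope.

Numerics: the rate enters quadratically and is profiled out in closed form;
ages are then optimized with SLSQP under the linear ordering constraints
using an exact analytic gradient (the envelope theorem kills the ∂r term at
the profiled rate). Initialization is deterministic — substitution depths
scaled through the calibrations — and convergence is to `ftol` 1e−14, with
a single longer retry before a hard error. On noise-free clock-like input
the fit recovers ages to machine precision, and scaling all branch lengths
by c scales the rate by c leaving ages unchanged.

Uncertainty: a nonparametric residual bootstrap — resample branch residuals
about the fitted clock with replacement, truncate rebuilt branch lengths at
zero, refit, take the 2.5/97.5 percentiles of the root age (default 200
replicates, minimum 40, seeded).

Calibration placement matters for identifiability. With a single
calibration on a shallow cherry, a bootstrap replicate that shrinks the
cherry's two branches toward zero leaves the root age almost flat (inflate
all other ages, deflate the rate, and only the cherry's residuals object).
The recovery experiments therefore place their single calibration on the
deepest proper clade; with several nested calibrations, as in the shipped
fossil set, the issue does not arise.

The six shipped calibrations are the fossil-record normal priors used for
the metazoan side of the dating analysis, deepest (797.0 ± 72.5 Ma) to
shallowest (89.5 ± 3.0 Ma), as a TSV fixture keyed by taxon set.

## Synthetic-data generators

`simulate_family` evolves fixed-length protein families along an
ultrametric species tree under a 20-state Poisson (equal-exchangeability)
model: a site with at least one event (event rate (20/19)·d for a branch of
d expected substitutions/site) resamples uniformly over the 20 amino acids,
which is the exact per-branch transition distribution. The closed form
p-distance `(19/20)(1 − e^{−(20/19)d})` is what the calibration tests hold
the generator to. HGT/EGT scenarios replace the recipient lineage's
sequence at the transfer time with the donor lineage's sequence at that
moment (EGT differs only in label and in placing the transfer at the
recipient clade's stem). The empirical-matrix upgrade (WAG etc.) is a
deliberate non-feature: equal exchangeabilities keep every expectation
closed-form and testable.

Default study conditions for the AGD recovery experiments: species tree
`((ref:600, bridge:600):1900, distal:2500)` Ma with a global rate of
3e−4 substitutions/site/My and 300-aa families. These place the
bridge–reference comparison at d ≈ 0.36 (≈70% identity — a conserved
protein over ~1.2 Gy of separation) and the distal comparison at d ≈ 1.5,
a realistic deep-homology contrast; the HGT scenario transfers from the
distal lineage into the (ref, bridge) stem at 650 Ma, shortly after its
origin. Limitations to keep in mind: no indels (families are trivially
aligned, so alignment error is not modeled), no rate heterogeneity across
sites, no selection, and i.i.d. genome composition (no repeats, no local GC
structure), which makes island detection easier than in real genomes.
Passing recovery tests demonstrate the statistics behave as designed under
their own model, not that real data are this clean.

`simulate_genome_with_island` draws an i.i.d. host genome and inserts an
island drawn from different base frequencies at a known position (truth
coordinates 0-based half-open; defaults in the tests: 100 kb host at
uniform composition, 5 kb island at 80% GC). `simulate_clocklike_tree`
draws a coalescent-style topology (exponential waiting times rescaled so
the root sits exactly at the requested age) and renders branches as
`rate · duration · (1 + N(0, noise_sd))` truncated at zero.

All generators are deterministic per seed; re-running writes byte-identical
FASTA/Newick.

## Survey filters and rounding

The homolog screen keeps hits with E-value strictly below 1e−3 and drops
fragments shorter than 450 aa (both boundaries tested). Species are
deduplicated by exact name within each group; percentages are
`100 · n_hit / n_total` rounded half-up, default 2 dp with per-row
precision available (the shipped published table uses 3 dp for the virus
row, which would otherwise print as 0.00).

## Problem sizes used by the acceptance script

`scripts/acceptance.py` regenerates everything from the `--seed`: 200
random pairs against the alignment oracle; 50 genomes of 3–20 kb against
the recount oracle; 50 AGD replicates (12-family vertical panel + 1 HGT
family each, 300 aa); 25 island genomes of 105 kb; one noise-free and 100
noisy (10%) 8-taxon clock trees with 100 bootstrap replicates each; one
10,000-site p-distance calibration; and the four informative rows of the
synthetic typing fixture. These sizes keep the full run within a few
minutes on one CPU while leaving the binomial/bootstrap margins
comfortable.
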