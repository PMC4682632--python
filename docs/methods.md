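# Methods

## The kinetic model

Internal asparagine residues deamidate spontaneously near neutral pH
through a succinimide intermediate: the backbone amide nitrogen of the
residue C-terminal to the Asn (the *N+1* residue) attacks the side-chain
carbonyl carbon. In unstructured peptides the rate is governed almost
entirely by the N+1 side chain — Asn-Gly deamidates in about a day,
bulky β-branched residues take a year or more — while in folded proteins
local structure slows the reaction by restricting that nucleophilic
attack.

The package models the observed half-time of an internal Asn as

    t50 = t50(sequence) · exp(wH·H + wO·(1 − D))

where

* `t50(sequence)` — the half-time of the Asn-(N+1) dipeptide in
  unstructured model peptides, looked up in a packaged table
  (`data/halftimes.tsv`, days);
* `H ∈ {0, 1}` — whether the Asn lies in a predicted α-helix;
* `D ∈ [0, 1]` — an intrinsic-disorder score (1 = fully disordered),
  used as a proxy for the absence of protecting hydrogen bonds;
* `wH, wO ≥ 0` — dimensionless empirical weights, defaults 0.571 and
  2.989 (averages from repeated-split training; see below).

The exponential is the **protection factor** `P = t50/t50(sequence) ≥ 1`.
A fully disordered coil (H=0, D=1) is unprotected (P=1); a fully ordered
helix is maximally protected (P = e^(wH+wO) ≈ 35 at the default
weights). Strand (E) states were considered as a protecting feature but
carry no weight; profiles map E and C both to H=0.

Modelling assumptions worth keeping in mind:

* first-order kinetics per site, sites independent;
* only *internal* Asn (positions 2..L−1): terminal deamidation follows
  different mechanisms;
* no quaternary structure, disulfides, ligand or membrane effects;
* enzymatic deamidation, glutamine deamidation and low-pH chemistry are
  out of scope.

Derived quantities:

* **percent deamidated** after a horizon `t` (default 2 days):
  `100·(1 − 2^(−t/t50))` — the base-2 form is the direct translation of
  "half-time" into an exponential decay law;
* **whole-protein half-time**: independent first-order clocks add rates,
  so `t50(protein) = 1/Σᵢ 1/t50ᵢ` — the half-time of the *first*
  deamidation event anywhere in the chain. This composition is
  unit-tested against a direct simulation of competing exponential
  clocks (10⁵ draws);
* **classification**: positive iff `t50 ≤ θ`. Tie goes to positive — a
  degradation screen should err toward flagging. When a labelled dataset
  is available, `threshold_at_fpr` derives θ at a target false-positive
  rate (conservatively: the realised FPR never exceeds the target,
  default 5%). Without one, the CLI default is θ = 100 days, the same
  cutoff that separates positive from negative sites in the evidence
  labelling rules;
* **N-glycosylation sequons** (N[^P][ST]) are flagged, never suppressed:
  a glycan-occupied Asn cannot deamidate, but occupancy is unknowable
  from sequence alone, so the flag is a warning column.

### The dipeptide half-time table

The packaged table is a representative model-peptide calibration
(pH 7.4, 37 °C): Gly fastest at 1 day, His/Ser around 10 days, and the
β-branched aliphatics slowest (~1–1.5 years). The table is an editable
3-column TSV and every computation takes it as an explicit argument, so
an alternative calibration is a drop-in replacement. Proline is
deliberately absent: its backbone nitrogen is a tertiary amide and the
succinimide route differs; a site with N+1 = Pro is reported with a
missing half-time rather than an invented value. Non-standard N+1 codes
(X, B, Z, U, O) are treated the same way.

## Structure tracks

Two provenance-tagged routes produce the per-residue (H, D) profile:

* **File ingestion** (`parsed-external`) — horizontal H/E/C strings
  (wrapped lines allowed, `-` read as coil), the `key:H,H,C,…` dialect
  of common secondary-structure predictors, and 3-column
  `index residue score` disorder tables (contiguous indices from 1,
  scores validated against [0, 1], residues validated against the
  sequence when given). This is the fidelity path: reproducing published
  per-protein values requires the original predictor outputs.
* **Bundled fallbacks** (`fallback`) — deterministic, dependency-free
  stand-ins: a Chou–Fasman-style helix caller (per-residue α-propensity
  averaged over a 7-residue window, helix where the mean exceeds 1.10)
  and a FoldIndex-style disorder score
  (`u = 2.785·⟨hydrophobicity⟩ − |⟨net charge⟩| − 1.151` over a
  21-residue window — disorder predictors integrate a context of about
  that size — squashed to [0, 1] by a logistic with slope 6 so that
  u = 0 maps to 0.5). Windows shrink symmetrically at the termini rather
  than padding. These are coarse screening tools; every output row
  carries the provenance tag so they cannot be confused with
  predictor-backed runs.

## Training and evaluation

Evidence curation admits records at pH 6.5–8.5 ("neutral or slightly
basic", config-overridable), temperature ≤ 313 K, and known sample age.
A site is **positive** when deamidation was unequivocal and, where
quantified, conversion ≥ 50% with half-time < 100 days; **negative**
when tested-and-absent or slower than 100 days. Records meeting both
criteria are flagged for manual review and excluded; every record
receives exactly one disposition (positive / negative / dropped-with-
reason), so the log partitions the input.

ROC analysis uses the smaller-is-positive orientation throughout (a site
is called positive at threshold θ when t50 ≤ θ); the AUC equals the
Mann–Whitney probability that a random positive scores below a random
negative, which the tests verify by exhaustive pair counting. Paired
AUCs are compared with the DeLong variance estimate (two-sided normal
test), cross-checked against a label-permutation oracle at small n.

Weight fitting mirrors the original protocol: the labelled dataset is
split in half 100 times (stratified within one site per class;
`round(n_class · fraction)` sites per class to the test side), the
training-set AUROC of `log t50 = log t50(sequence) + wH·H + wO·(1−D)` is
maximised by exhaustive grid search (default grid [0, 6] step 0.01 per
axis, config-exposed; ties resolve to the lexicographically smallest
pair), the selected weights are averaged over splits, and the test-set
AUROC is tallied against sequence-only scoring (wH = wO = 0).

## The synthetic fixture generator

The generator emulates the study design of a curated deamidation
dataset: sequences carrying internal Asn-X sites planted inside regions
of controlled structural context, with matched helix/disorder tracks and
binary labels produced by the model itself (t50 ≤ cutoff) plus
independent label noise (default 5%). Contexts:

| context          | H | D            |
|------------------|---|--------------|
| disordered-coil  | 0 | U(0.7, 1)    |
| ordered-helix    | 1 | U(0, 0.3)    |
| ordered-coil     | 0 | U(0, 0.3)    |

Defaults: length 120, 4 sites per sequence (planted ≥ 6 residues apart
so context windows never overlap), context mix 0.35/0.40/0.25 —
helix-enriched because helix sites are the only carriers of information
about wH. Everything derives from one integer seed and regeneration is
bit-identical; emitted labels are recomputable from the emitted tracks
(noise flips are recorded), which the tests assert.

**Identifiability drives the label-cutoff and N+1 design.** The weights
enter the labels only through the score
`log t50(sequence) + wH·H + wO·(1−D)`, and AUROC-based training sees
only ranks, so a weight is pinned down exactly when context × N+1 cells
*straddle* the cutoff — contain both classes, with the decision boundary
inside the cell's (1−D) band. Cells that never change class contribute
no boundary information. With the default table, planted weights (1, 3)
and cutoff 245 days (log 245 ≈ 5.5), the default context-conditional N+1
pools put most sites into straddling cells: disordered-coil draws from
{F, N, Q, M, Y, W} (six interleaved boundaries pinning wO) plus G/A
anchors; ordered-helix from {H, S} (pinning wH) plus G; ordered-coil
from {A} plus G/W. With an early draft design (cutoff 10 days, N+1 from
{G, S, A, D} independent of context) only ~11% of sites were positive,
the AUROC surface was a wide plateau, and the grid argmax wandered along
a wH/wO trade-off ridge — a useful reminder that rank-based calibration
data must populate the decision boundary in every feature direction.

What the fixture does *not* emulate: real secondary-structure and
disorder predictors (tracks are planted, not predicted), homologous
sequence families, correlated labelling errors between sites of the same
protein, and the pH/temperature heterogeneity of literature evidence.
Passing the recovery harness therefore shows that the *training
machinery* is correct and well-conditioned, not that the published
weight values are optimal for real proteins.

The turnover fixture is a bivariate log-normal sample: log10 half-life
(minutes, mean 1.7, sd 0.6 — centred near ~50 min, typical of
exponential growth) against log10 predicted t50 (days, mean 2.0,
sd 0.5), correlated at a planted Pearson r on the log scale. At
n = 3750 the sampling error of r is ≈ 0.016, so a planted r = 0.2 is
recovered well within ±0.05.

## Problem sizes and numerical choices

* The weight-recovery harness (tests and `scripts/acceptance.py`) uses
  500 sequences × 4 sites = 2000 labelled sites, 20 splits, grid
  [0, 2] × [0, 6] at step 0.1, 10 generator seeds. Measured recovery
  rate at this size is 10/10 within one grid step; at ~280 sites
  (the scale of the real curated dataset) it drops to ~0.8 because the
  argmax plateau widens — the scaling is documented here so users can
  trade size against precision.
* AUC/pair-count agreement is checked on 200 random fixtures of ≤ 12
  sites with deliberately tied scores; agreement is exact to 1e-12.
* The protein half-time simulation uses 10⁵ draws; the Monte-Carlo error
  of the median is ~0.6%, asserted at 2%.
* Grid ties, ROC threshold grouping and the classification tie are all
  deterministic (first-max lexicographic, grouped thresholds, tie →
  positive). Disorder track scores are rounded to 1e-6 when written so
  that written fixtures re-read bit-consistently.
* Report tables print half-times to 3 significant figures and keep full
  precision in companion `*_exact` columns; data tables contain no
  timestamps, so identical inputs give byte-identical outputs.

## Known limitations

* The packaged half-time table is a representative calibration, not a
  re-measurement; absolute t50 values inherit its uncertainty. Rankings
  within a protein are far more robust than absolute values.
* The fallback structure predictors are single-sequence heuristics;
  alignment-based predictors used through the file interface will give
  different (better) per-protein numbers.
* The FPR-anchored classification threshold depends on the labelled
  dataset used to derive it; the shipped default (100 days) is a
  labelling-rule constant, not an ROC-derived value.
* Whole-protein half-times assume site independence; cooperative
  unfolding or a deamidation-triggered structural change violates this.
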