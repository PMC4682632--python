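# ngome — sequence-based prediction of spontaneous asparagine deamidation

Asparagine residues in proteins deamidate spontaneously to aspartate /
iso-aspartate through a succinimide intermediate, on timescales from
days to years. The reaction acts as a molecular clock for protein
function and turnover, matters for the shelf life of therapeutic
proteins, and is modulated both by the residue C-terminal to the Asn
(the **N+1** residue) and by local structure. This package predicts
deamidation half-times of internal Asn residues **from sequence alone**,
for protein scientists, formulation developers and anyone doing
proteome-scale turnover analyses.

The model: the observed half-time is the intrinsic dipeptide half-time
times an exponential protection factor,

```
t50 = t50(sequence) · exp(wH·H + wO·(1 − D))
```

with `t50(sequence)` the Asn-(N+1) half-time in unstructured model
peptides (packaged table; Asn-Gly ≈ 1 day), `H ∈ {0,1}` a predicted
helix indicator, `D ∈ [0,1]` an intrinsic-disorder score (1 = fully
disordered), and non-negative weights `wH = 0.571`, `wO = 2.989` by
default. `P = exp(wH·H + wO·(1−D)) ≥ 1` is the protection factor; a
fully disordered coil is unprotected. The package also reports percent
deamidation after a user horizon (default 2 days), a whole-protein
half-time under independent site kinetics (`1/Σ 1/t50ᵢ`), a
positive/negative call at a configurable threshold, and an
N-glycosylation sequon (N[^P][ST]) warning flag. Beyond prediction it
contains the full training stack (evidence curation, ROC/AUC, DeLong
paired-AUC test, stratified repeated splits, exhaustive grid search for
the weights), proteome batch analysis with turnover correlation, and a
synthetic fixture generator. See `docs/methods.md` for the science and
the numerical choices.

## Worked example

Helix and disorder tracks come either from external predictor output
files (`--ss-file`, `--disorder-file` — the fidelity path) or from
bundled approximate fallback predictors:

```
$ ngome predict demo.fasta --fallback-predictors --out-dir demo_out
demo    sites=2 t50_protein_days=0.907
```

with `demo.fasta` containing
`>demo` / `MKTANGSAYIAKQRNGSFVKSHFSRQLEERLGLIEVQ`. The per-site report
(`demo_out/demo_table1_asn_by_position.tsv`, first columns):

```
protein_id  position  n_plus_1  sequon  t50_sequence  t50_ngome  protection  pct_at_horizon  label
demo        5         G         yes     1             1.72       1.72        55.4            positive
demo        15        G         yes     1             1.92       1.92        51.4            positive
```

Reading: both internal asparagines are Asn-Gly sites (intrinsic
half-time 1 day). The fallback predictors place them in largely
disordered surroundings, so protection is weak (factors 1.72 and 1.92)
and the predicted half-times stay under 2 days; after the default 2-day
horizon 55% and 51% of each site has deamidated. Both sites sit in
N-G-S sequons, so they *may* be glycosylated in a eukaryote — in which
case they would not deamidate at all; the flag is a warning, not a
filter. The whole-protein half-time (first deamidation event anywhere)
is 0.907 days, faster than either site alone because the two
independent clocks add rates. A second table sorts the same rows by
`t50_ngome`, tables 3–4 repeat the layout for a hypothetical scan that
asks "what if this position held an Asn?" at every internal position,
and two track files carry per-position log10 half-times and protection
factors for plotting.

The same computation in Python:

```python
from ngome import HalfLifeTable, fallback_profile, predict_protein

seq = "MKTANGSAYIAKQRNGSFVKSHFSRQLEERLGLIEVQ"
profile = fallback_profile(seq, "demo")          # or build_profile(...) from files
pred = predict_protein(seq, "demo", profile, table=HalfLifeTable.default())
print(pred.t50_protein)                           # 0.907...
```

Other subcommands: `ngome scan` (the hypothetical per-position report),
`ngome train` (repeated-split grid search on a labelled feature table),
`ngome proteome` (batch prediction + log–log turnover correlation),
`ngome fixture` (deterministic synthetic data). All data tables are TSV
and byte-identical across reruns on the same inputs.

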