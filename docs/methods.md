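# Methods

This note defines the feature set, the cascade training protocol, the
evaluation conventions, and the synthetic-data generator in enough detail
to reproduce every number the package emits.

## 1. Input model

The unit of analysis is a **gene** with one or more CDS–protein pairs
(alternative transcripts). Inputs are a CDS FASTA, a protein FASTA, and a
pairing table `gene_id, cds_id, protein_id, chromosome`. Exact duplicate
records are dropped; an id present in the pairing table but missing from a
FASTA is a hard error. Each pair is checked by translating the CDS with the
standard genetic code (trailing stop removed); mismatches are flagged in a
`translation_mismatch` column but not rejected.

Labels are `positive`, `negative`, or `unlabeled`. When a training run has
no explicit negatives, they are sampled from the unlabeled genes **in
proportion to the chromosome distribution of the unlabeled pool**, using
largest-remainder apportionment for the per-chromosome quotas; if a
chromosome cannot fill its quota the deficit is redistributed
proportionally over the others (with a warning). Splits are stratified
6:2:2 train/validation/test per class with largest-remainder rounding, and
the training partition is down-sampled to a 1:1 class ratio.

## 2. Features (79 slots)

All features are computed per CDS–protein pair.

**Inherent (2).** CDS length in codons; protein length.

**Codon usage (13).** Codon counting uses frame 0, drops a trailing partial
codon, and skips codons containing ambiguity characters.

- `RSCU`-based synonymous composition feeds the indices below.
- `CAI`: geometric mean of relatedness values w over codons, excluding Met,
  Trp and stops; w from a human codon-usage table shipped with the package
  (per-family maximum normalised, floored at 0.01).
- `CBI = (N_opt − N_rand) / (N_tot − N_rand)` and `Fop = N_opt / N_tot`
  over the human-optimal codon set (most-used codon per family).
- `Nc` (effective number of codons): `2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6`
  with `F̂ = (nΣp² − 1)/(n − 1)` averaged within each synonymous-family
  size class; families with n < 2 are excluded, a missing 3-fold class
  falls back to the mean of the 2- and 4-fold classes, and the value is
  clipped to [20, 61] (61 under uniform synonymous usage, 20 under extreme
  bias). Reported missing if the 2-, 4- or 6-fold class is empty.
- `GC`, `GC3s`, and the four silent third-position frequencies
  `T3s/C3s/A3s/G3s` (each base's count at synonymous third positions over
  the positions where that base would be silent), plus the number of
  synonymous third positions.

**Amino-acid usage (22).** The 20 residue frequencies (unknown `X`
excluded from the denominator); the rare-residue fraction (default set
{W, C, H, M}); and the close-to-stop fraction: the share of sense codons
whose prefix is TA or TG, i.e. one third-position substitution away from a
stop codon.

**Physicochemical (12).** Pepstats-style block: molecular weight, average
residue weight, isoelectric point (net-charge bisection on [0, 14] to 1e-6
using EMBOSS pKa values: N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1,
H 6.5, K 10.8, R 12.5, Y 10.1), charge at pH 7, and the Tiny / Small /
Aliphatic / Aromatic / Non-polar / Polar / Charged / Basic / Acidic class
fractions (with B and Z counted in the appropriate classes), plus GRAVY
(mean Kyte–Doolittle hydropathy) and aromaticity.

**Transmembrane (3).** `ExpAA`, `First60`, `PredHel`. By default a
Kyte–Doolittle heuristic (window 19, threshold 1.6) supplies them; if a
TMHMM short-format file is given via `--tm-override`, its values replace
the heuristic for the listed proteins and the source is recorded
out-of-band per row.

**Hurst exponent (1).** The CDS is digitised A,G,C,T → 0,1,2,3 and a
rescaled-range (R/S) estimate is fitted by least squares over ~12
log-spaced window sizes from 8 to len/2 (non-overlapping blocks), clipped
to [0, 1]; missing for sequences shorter than 32 bases or constant.

**Information theory (26).** Using log base 2 throughout and overlapping
k-mers: Shannon entropies H1, H2, H3; the 16 adjacent-base mutual
information terms (marginals taken from whole-sequence base frequencies, in
A/G/C/T order) and their exact sum `mi_total`; KL divergence and
cross-entropy against a background distribution for k = 1, 2, 3 (the
background is the dataset-pooled distribution unless one is supplied;
background probabilities are smoothed with an ε = 1e-6 pseudocount, so
`CE = H + KL` holds exactly).

An optional 80th slot reports the total mutual information in nats
(`--include-mi-nats`); it is off by default because it is a rescaling of
`mi_total`.

Feature matrices are TSV with a `schema_version` column; floats are
written with `%.17g` so write→read round trips are exact.

## 3. Preprocessing

Imputation and scaling are fitted **on the training partition only**:
missing values take the training mean (a slot missing everywhere in
training is an error), then min–max scaling to [0, 1] with out-of-range
held-out values clipped; a degenerate (constant) slot maps to 0. The fitted
parameters are stored in the model bundle (`normalization.json`) and reused
verbatim at prediction time.

## 4. Cascade

Three levels, each a committee of `n_cycles` (default 50) scikit-learn
`MLPClassifier` networks (`solver='sgd'`, constant learning rate). Default
per-level settings:

| level | hidden | activation | learning rate | momentum | max_iter |
|------:|-------:|------------|--------------:|---------:|---------:|
| 1 | 21 | relu | 0.048 | 0.8 | 5000 |
| 2 | 20 | tanh | 0.048 | 0.8 | 5000 |
| 3 | 37 | logistic | 0.098 | 0.9 | 5000 |

Cycle *c* of a level draws its negatives without replacement from the
negative pool with `numpy.random.default_rng(seed + c)` (one negative per
positive by default) and fits one network; per-cycle validation metrics are
recorded. At prediction time each network votes (P ≥ 0.5, cutoff
inclusive); a sample **survives** the level only if its votes reach the
pass threshold, which defaults to all `n_cycles` (unanimity). Only
survivors are scored by later levels.

Per gene: `score` = summed votes over all its samples across the levels
they reached; `candidate` = at least one sample survived every level.
Ranking sorts by score (desc), then mean probability, then gene id, with a
stable sort. An optional grid search picks hidden-unit count, learning
rate, and activation by validation AUC (ties: fewer hidden units, then
lower learning rate).

Model bundles contain `config.yaml`, `normalization.json`, and one joblib
file per level; a saved and reloaded model reproduces its vote trace
bit-for-bit.

## 5. Evaluation

Binary metrics (accuracy, precision, recall, F1, G-mean = √(sensitivity ×
specificity)) are computed from the confusion matrix with NaN for undefined
ratios. ROC/AUC and PR/AUPR come from scikit-learn; vote counts are valid
scores. Held-out reporting pools the validation and test partitions (when
no hyperparameter search is run, validation is unused for training, and
pooling halves the variance of the held-out AUC); the binary call is
"survived all levels" and the score is the total vote count.
`replicate_summary` reports per-metric means with the count of non-missing
replicates, matching the per-cycle validation table layout.

## 6. Synthetic generator

Sequences are emitted codon-by-codon from a first-order base chain
`M(b'|b) = (1 − α)π(b') + α·1[b'=b]` restricted to the 61 sense codons,
with an exponential tilt toward human-optimal codons. The positive class
differs from the null class by four switchable effects (defaults in
parentheses): a GC-content shift (+0.15 centred on 0.50), optimal-codon
bias (1.0), Markov self-transition α (0.2), and a probability of inserting
a hydrophobic transmembrane segment (0.3). Each CDS starts with ATG and
ends with a stop codon; the protein is the exact translation, so the
feature extractor sees internally consistent pairs.

Two numerical choices matter for calibration:

- Restricting the chain to sense codons biases GC downward relative to the
  unconstrained chain, so the GC weight is solved exactly (Brent's method)
  such that the stationary expected GC of the sense-codon-restricted
  kernel equals the target. Residual bias from the fixed start/stop codons
  and TM inserts is ≈ 0.005, inside the ±0.01 test tolerance.
- The stationary adjacent-base mutual information of the chain has a
  closed form, which the tests compare against the empirical `mi_total` of
  long generated sequences.

Genes are assigned to chromosomes round-robin; missingness is applied only
to the four features that are legitimately unavailable in practice (`Nc`
on short sequences, and the three TM summaries). A 12-gene worked fixture
(sequences, features, vote trace) is frozen under `src/genesieve/fixtures/`
and regenerated byte-for-byte by the test suite; the trace regression
asserts integer vote counts and survival flags rather than float
probabilities to stay robust to BLAS threading differences.

**Scope and limits.** The generator produces i.i.d. genes with
transcript-level duplication but no homology structure, no intron/isoform
complexity, no GC isochores, and class effects that are far cleaner than
real disease-gene signal; it validates the machinery (feature correctness,
cascade mechanics, end-to-end recovery, null behaviour), not biological
effect sizes. The perfect AUC under default effects reflects the
deliberately separable design, and the null condition confirms the
pipeline does not manufacture signal.

## 7. Determinism

Every stochastic step takes an explicit seed: generation, negative
sampling, splitting, per-cycle draws, and network initialisation (cycle
seeds are `seed + cycle`; level seeds are offset by 1000 per level).
Re-running any stage with the same seed is bit-identical.
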