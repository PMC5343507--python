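# Methods

## Fitness estimation

A bulk competition is modeled at the library level: each 10-position
saturation library is an independent experiment in which all single-codon
variants plus the WT gene grow together. Raw fitness *w* of a variant is
the unweighted OLS slope of log₂(N_mut(t)/N_WT(t)) against time in WT
doublings; the WT denominator of every position in a library is the count
of reads matching the WT reference exactly at the nucleotide level.
Synonymous-WT codon variants form their own outcome class (the WT amino
acid) and are *not* pooled into the denominator by default; a
`pool_synonymous_wt` switch provides the alternative, since published
analyses are ambiguous on this point.

Time points with a zero count in either series carry no defined log-ratio
and are dropped (a `pseudocount` option offers the alternative); fewer
than two usable points flags the cell `low_coverage`. Selection
coefficients are s = −w / w̄_STOP with w̄_STOP the mean raw fitness of the
library's stop-codon outcomes — the unique linear map sending WT-like
growth to 0 and the average stop allele to −1. If w̄_STOP is not negative
the selection evidently failed and the library is flagged unnormalizable
rather than silently rescaled. The normalization contract (mean stop s =
−1 within each library, to 1e−9) is asserted in the test suite and
recomputed end-to-end by `scripts/acceptance.py`.

Exclusions follow two rules: cells whose *every* encoding codon creates an
MmeI site in its sequence context are unobservable (the enzyme destroys
their reads during barcode ligation) and are excluded with reason `mmei`;
cells below a configurable initial-count threshold (default 10 reads at
t₀ — no published value exists, so this is a package default) are excluded
as `low_coverage`. A cell hit by both rules is counted once, as `mmei`.
Exclusions change membership only, never surviving values. The design
accounting over the canonical three-orthologue layout (3 × 8 × 10 × 21 =
5,040 cells) uses the seven named poor-coverage mutations shipped as data
and a deterministic synthetic stand-in set of 79 MmeI-forced cells (the
historical cells are not enumerated anywhere public), leaving 4,954
analysable cells.

## Read processing

Reads are barcode + library window, 36 nt in the canonical geometry (6-nt
barcode, 30-nt window). Four criteria are evaluated in a fixed order —
quality (every base ≥ Q20; the threshold is the Phred score whose error
probability is 0.01), barcode, reference (exactly one library matches as
WT or a single-codon variant; anything else is ambiguous), MmeI (TCCRAC
on either strand of the post-barcode payload) — and the first failure is
the recorded rejection reason, making reports reproducible. Mapping is by
exact anchoring to the window; there is no aligner, no support for
indels, paired ends, or error-prone-PCR libraries. The module is fully
deterministic and conserves reads: passed + Σ rejected = total, always.

## Synthetic data

The generator inverts the estimator's model: expected relative abundance
of variant *i* at time *t* is proportional to its initial abundance times
2^(w_i·t), with w_i = s_i·stop_scale and WT at w = 0, so the expected
log₂ ratio is linear in *t* with slope w_i. Defaults are: 8 time points
evenly spanning 4 doublings; multinomial sampling of a fixed read total
per time point (Poisson and noise-free modes available); depth 10⁵
reads/time point; WT initially at 10 copies per variant copy (cassette
ligation leaves WT over-represented); stop_scale = 1 (stops fully lethal,
so w and s coincide numerically). No published depth or count-variance
model exists for this assay; these defaults are the package's own choices
and are not claims about any original experiment.

True selection coefficients default to a bimodal distribution of fitness
effects: stop outcomes at −1, synonymous-WT at 0, and substitutions drawn
from a deleterious mode at −0.93 ± 0.06 versus a near-neutral mode at
0 ± 0.10 with a mildly beneficial tail. Each position's deleterious
probability is Beta-distributed around the global 55% (spread parameter
0.5): mutational tolerance varies between buried and surface positions,
which is what gives real scans their strong position-mean factor (and
makes column-centered PC1 track average fitness). The generator records
truth tables so recovery is measurable; at depth 10⁵ the estimator
achieves Pearson ≈ 0.998 against truth, and RMSE decreases monotonically
over depths 10³/10⁴/10⁵.

Read emission writes one read per counted molecule and corrupts a
configurable fraction through three independent Bernoulli channels (one
base dropped to Q2; an unknown barcode; two extra codon changes). Real
sequencing noise is not base-resolved: there is no PCR/jackpot model, no
substitution-error model beyond the quality channel, and no growth-lag
model. Randomly drawn WT contexts can contain cells where every codon of
some outcome creates an MmeI site; such cells are physically unobservable
and the round-trip contract is exact reconstruction of all other cells
plus rejection of exactly those reads.

Landscape trios mix a shared standard-normal 20-vector per position with
independent ones, value = √ρ·shared + √(1−ρ)·independent, so the expected
cross-orthologue profile correlation equals ρ; values are then placed on
an s-like scale (−0.4 ± 0.35), which leaves every correlation unchanged.
MSA simulation draws sequences independently per column from given
profiles. What passing tests show is therefore internal consistency and
statistical calibration of the machinery — not that real landscapes have
any particular ρ, nor that real alignment columns are independent.

## Comparative statistics

Profile correlations default to excluding amino acids that are WT at
either position of a pair (18–19 shared substitutions; `include_all_20`
available) and excluding stop outcomes, which measure expression shutdown
rather than substitution response. Pairs with fewer than 3 shared finite
values or zero variance are skipped and counted, never imputed. The
four-fold position set pairs positions occupying the same (quadrant,
offset) cell, where quadrant = ⌈library/2⌉ and the offset runs 1–10
through the odd library and 11–20 through the even one — a bijection of
the 80 slots onto 4 × 20 cells.

The beneficial-fraction permutation test reassigns whole per-position
substitution profiles to random positions (equivalently, redraws the
subset), and reports p as the add-one-corrected fraction of null values
at least as extreme as the observed one; two-sided extremeness is
absolute deviation from the null mean. The doubled-min-tail alternative
was rejected deliberately: with a discrete statistic its tie mass makes
the test markedly conservative (empirical type-I ≈ 0.02 at α = 0.05),
whereas the centered definition calibrates to ≈ 0.05 while remaining
exact. Calibration is verified over 240-position landscapes with
60-position subsets; much smaller landscapes leave too much tie mass in
the discrete statistic for any exact permutation p to look uniform.
Distribution contrasts use scipy's two-sample KS test; note that KS
p-values are themselves discrete when both samples are small and equal in
size.

## PCA

Matrices are decomposed by SVD after one of two normalizations:
`per_position_z` (every position the same mean and s.d.) or
`per_column_center` (outcome columns centered, position means retained).
The default is `per_column_center` because only it can reproduce the
collinearity of the first component with average position fitness; every
result records its normalization. Component signs are fixed by requiring
each loading vector to have a non-negative sum. Excluded landscape cells
are imputed by row mean before PCA (and the imputation is the caller's
explicit step, `impute_row_mean`). Alignment frequency matrices are
per-column amino-acid frequencies (gaps excluded) with pseudocount
1/(n_sequences + 20) by default, log-transformed. The hydrophobicity
scale is Kyte–Doolittle and the max-ASA scale for RSA is the theoretical
tripeptide table shipped as package data; both are configurable, and
neither is asserted to be what any particular historical analysis used.

## Numerical choices and limitations

- OLS slopes and Pearson correlations are computed in closed form;
  agreement with independent oracles (scipy, brute-force
  covariance/eigen-decomposition, IUPAC motif scans, group-by means) is
  asserted to 1e−9–1e−12 in the test suite.
- All randomness flows through `numpy.random.default_rng` seeds; identical
  configurations and seeds produce identical outputs, byte-for-byte for
  emitted files.
- Problem sizes in the test and acceptance runs — one library for
  recovery, 80-position trios with 200 seeds for KS calibration, 500
  permutation-calibration trials at n_perm = 2,000 — were chosen as the
  smallest sizes at which the stochastic contracts are sharp.
- Out of scope by design: structural superposition, secondary-structure
  assignment and ASA computation (consumed as input tables), statistical
  coupling analysis, epistasis model fitting, and any wet-lab protocol
  modeling.
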