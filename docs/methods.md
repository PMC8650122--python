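# Methods

## Scope and model

`msisig` evaluates three published RNA-seq signatures of tumor
microsatellite instability (MSI) as binary classifiers against the
PCR marker-panel gold standard. The positive class is MSI-high;
MSI-low and microsatellite-stable samples are pooled into a single
negative class, because only MSI-high status carries therapeutic
consequence. The unit of analysis is a cohort: a dense, non-negative
gene × sample expression matrix with unique HGNC gene symbols and an
explicit normalization state, plus a per-sample MSI label.

## Signature definitions

- **Li** (15 genes): plus = {LYG1, MSH4, RPL22L1}; minus = {DDX27,
  EPM2AIP1, HENMT1, MLH1, NHLRC1, NOL4L, RNLS, RTFDC1, SHROOM4, SMAP1,
  TTC30A, ZSWIM3}. Score = signed sum of log₁₀(x + pseudocount).
- **Pacinkova–Popovici** (25 genes): plus = {AGR2, TNNT1, VNN2, TNFSF9,
  TRIM7, RPL22L1}; minus = {ACSL6, ARID3A, ASCL2, AXIN2, EPDR1, GGT7,
  GNG4, KHDRBS3, KRT23, MLH1, NKD1, PLAGL2, PRR15, RUBCNL, SHROOM2,
  SHROOM4, TFCP2L1, TNNC2, VAV3}. Same additive form.
- **Danaher** (14 genes): MLS genes MLH1, MSH2, MSH6, PMS2; HPS genes
  EPM2AIP1, TTC30A, SMAP1, RNLS, WNT11, SFXN1, SREBF1, TYMS, EIF5AL1,
  WDR76. MLS = (Z_min + 1.03)/0.69, where Z_min is the per-sample
  minimum of the four cohort Z-scores of log₂ expression and
  1.03/0.69 are the magnitude of the expectation and the standard
  deviation of the minimum of four independent standard normals (the
  Monte Carlo check in `scripts/acceptance.py` reproduces 1.03). HPS is
  the cohort Z-score of Σ coeff·log₂(x + pseudocount). The combined
  predictor is √(min(MLS,0)² + max(HPS,0)²): non-negative, raised by
  MMR loss (negative MLS) or hypermutation (positive HPS), zero iff
  MLS ≥ 0 and HPS ≤ 0. The rendered combination formula in the source
  literature is ambiguous about the root; we take the square root,
  which leaves the ranking — and therefore every AUC — unchanged
  either way, since the clamped sum of squares is non-negative and the
  root is monotone.

The three gene sets share exactly one gene, MLH1; Li additionally
shares EPM2AIP1, RNLS, SMAP1 and TTC30A with Danaher and RPL22L1 and
SHROOM4 with Pacinkova–Popovici; Pacinkova–Popovici and Danaher share
nothing else. The union is 46 unique symbols. `signature_overlap()`
computes this structure from the definitions.

### Danaher HPS coefficients

The original coefficient table is not redistributed here. The packaged
file `data/danaher_hps_coefficients_synthetic.yaml` is a synthetic
stand-in: unit magnitudes, with −1 for the four HPS genes that the Li
signature lists as minus-genes (down in MSI-high) and +1 for the rest.
Because the HPS is cohort Z-scored, only relative weights matter for
ranking; correctly signed unit weights preserve orientation, but users
wanting faithful absolute scores should supply the published table via
`load_hps_coefficients(path)`. All tests parameterize the coefficients
so no correctness claim rests on this transcription.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| pseudocount | 1.0 | expression units | added before every log transform; the scoring rules do not define log(0), and 1.0 on a normalized-count scale perturbs expressed genes negligibly |
| normalize | on | — | quantile normalization before scoring; exposed because public expression matrices may arrive pre-normalized |
| alpha | 0.05 | — | 1 − confidence level of the DeLong interval |
| missing_policy | error | — | missing signature genes abort by default; `"skip"` drops their terms with a warning, changing the score scale |

## Numerical choices

- **Quantile normalization** follows the classic recipe: the reference
  distribution is the across-sample mean of each order statistic;
  values are assigned by within-sample rank; ties within a sample
  receive the mean of the reference values of their tied ranks (the
  "average" dialect). With tie-free columns the normalized columns
  share their sorted values exactly and the operation is idempotent;
  tied values break exact column identity — continuous expression data
  make ties rare, and the property tests use tie-free draws.
- **Z-scores** (per-MMR-gene for MLS, the final HPS) use the scored
  cohort itself as the reference population with the n−1 standard
  deviation; Danaher scores are therefore cohort-relative and need at
  least two samples. A zero-variance gene (or zero-variance raw HPS)
  yields Z = 0 with a warning rather than an error, so constant
  fixtures remain scorable.
- **AUC** uses the Mann–Whitney kernel with ties counting ½. The
  DeLong variance is S10/m + S01/n over the structural components
  V10 and V01 (n−1 sample variances); the normal-approximation CI is
  clipped to [0, 1], which matters near perfect separation. The
  orientation is fixed (higher score ⇒ MSI-high); there is no
  pROC-style automatic direction selection, a deliberate choice so an
  inverted signature is visible as AUC < 0.5 instead of silently
  flipped. During development the implementation was checked against
  an independently coded naive DeLong restatement (in the test suite)
  to 1e-10 and agreed with R pROC's DeLong CI to machine precision on
  random fixtures.
- **PCR rule**: with zero unstable main markers the additional markers
  are ignored, reading the stepwise protocol literally (reflex testing
  is triggered only by exactly one unstable main marker). `missing` is
  a first-class call state; a missing main call, or missing additional
  calls when reflex testing is required, fails loudly.
- **Identifier mapping**: unmapped genes are dropped (and counted in
  the log) rather than zero-filled, since zero-filling would corrupt
  log-transformed scores; collisions of several source IDs onto one
  symbol are resolved by an explicit policy (error / sum / first).

## Synthetic cohorts

`simulate_expression_cohort` emulates the class structure of an
MSI-annotated tumor cohort: labels are Bernoulli(msi_high_fraction =
0.3, a colorectal-like minority), per-gene log₂ baselines are
Normal(8, 2) — several hundred normalized counts with realistic
between-gene spread — and each observation adds Normal(0, 1) log₂
noise before exponentiation to the linear scale, so the pipeline's own
log transforms and pseudocounts are exercised. MSI-high samples
receive −2 log₂ units on every minus-set/MMR gene and +2 on every
plus-set gene (fourfold shifts, the magnitude of MLH1 silencing-class
effects); gene roles are derived from the signature definitions, one
shift per gene even when several signatures use it, and a gene claimed
by both directions is shifted down because MMR loss is the primary
biology. HPS genes are up-shifted only when their configured
coefficient is positive, keeping the simulator honest about the
stand-in weights. Default cohort size is n = 200 with 200 unshifted
background genes — large enough for stable AUC bands, small enough
that the full suite runs in seconds.

What the simulator does **not** model: negative-binomial count noise,
library-size and batch effects, FFPE degradation, or correlation
between signature genes beyond the shared class shift. Passing the
recovery tests therefore shows the pipeline's arithmetic and plumbing
are sound under the assumed effect structure, not that the signatures
reach any particular accuracy on real tumors.

`simulate_marker_profiles` draws each of the seven locus calls
independently with class-conditional instability probabilities; with
p(unstable|MSI-high) = 1 and p(unstable|low) = 0 the PCR rule recovers
truth exactly, and with equal probabilities classification accuracy
matches the closed-form binomial chance level.

## Pipeline and reproducibility

`run_pipeline` (CLI `msisig run --config config.yaml`) chains
load → map → normalize → score → evaluate and writes scores, the
report table, histogram data, the resolved config and a run log.
Labels come either from a labels TSV or from marker calls pushed
through the PCR rule; both routes give identical reports. All
randomness flows through a single integer seed, and identical
config + seed reproduces byte-identical outputs.

## Known limitations

- Danaher absolute score values depend on the stand-in HPS weights
  (ranking and AUC behavior do not, under sign-consistent weights).
- Cohort-relative Z-scoring means a sample's Danaher score changes
  with the cohort it is scored in; single-sample calibrated scoring is
  out of scope.
- No operating threshold is chosen: the package reports discrimination
  (AUC), not clinical calls from RNA-seq scores.
- Correlated-AUC comparison between signatures (paired DeLong test)
  is not implemented.
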