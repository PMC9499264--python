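# Methods

## The evaluation matrix

The integrative score is a rank aggregation. For parameter *j*
measured on a set T_j of treatments, values are sorted ascending and
assigned positions 1…|T_j|; each treatment's score is the position of
its value, with **ties resolved to the maximum of the tied positions**
— not the average (the common "competition rank" variants would be
minimum or mean). The max-tie rule is the one consistent with the
published reference matrix the package ships: e.g. eight wheat root
dry weights tied at 0.1 g all score 8 of 12, and four maize root dry
weights tied at 0.2 g all score 4 of 8. `rank_scores` delegates to
`scipy.stats.rankdata(method="max")`; an independent brute-force
oracle (max over enumerated tied sort positions) guards it in the
tests.

Every parameter is treated as higher-is-better. This was checked
column by column against the reference matrix (all 13 columns rank
ascending-good); `TreatmentRanker(directions=...)` exists for reuse
with lower-is-better parameters but defaults to ascending-good.

Totals sum a treatment's available scores. Means divide by the number
of available parameters and are rounded **half-up** to one decimal
(79/9 → 8.8, 61/13 → 4.7); the division is done in exact decimal
arithmetic so 0.05-boundary ratios never fall to binary-float
banker's rounding. Parameters not tested for a treatment (n.t.) are
excluded from both numerator and denominator — this is what makes a
9-parameter row comparable to a 13-parameter row. A parameter with
fewer than two measured treatments is an error at matrix level; a
parameter measured for no treatment (a skipped pipeline stage)
propagates as an all-n.t. column.

Ranking operates on the values it is given. The packaged reference
tables carry means at printed precision, so the golden reproduction
uses them as-is; for full-precision data (e.g. simulated studies) an
optional `precision` parameter rounds before ranking to emulate
published tables.

### Known inconsistency in the reference matrix

One published score cell cannot be reproduced from the published trait
means: wheat MC-C_AMF shoot length (31.6 cm) is the 4th-smallest of
the twelve published means, but the published matrix prints 5,
propagating to that row's total (81 printed, 80 recomputed; the mean
is 6.2 either way). The pipeline recomputes, does not guess intent,
and flags the cell in the run log. The remaining 179 of 180
physiological cells, and all totals/means of internally consistent
rows, reproduce exactly.

### Metagenomic and expression columns of the reference study

The per-treatment Shannon indices and fold-change values behind the
reference matrix's last four columns were not published in recomputable
form, so those columns are shipped as published inputs
(`datasets.aux_scores`). Because max-tie rank scores are a fixed point
of re-ranking, passing them through `TreatmentRanker` alongside the
trait means returns them unchanged — the totals test covers this.

## Group comparisons

The reference workflow pairs a nonparametric omnibus with Dunn's post
hoc (the default pairing in the Past statistics package). We
implement Kruskal–Wallis (tie-corrected) plus Dunn's z-tests on
pooled midranks,

z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)],

and report classical one-way ANOVA alongside for transparency. Dunn
p-values are unadjusted by default (Past's default; whether the
reference analysis adjusted is unknown), with Holm and Bonferroni
selectable. All-identical data short-circuit to omnibus p = 1 and one
shared letter.

Letters come from the insert-and-absorb algorithm: start with one set
holding all treatments; each significant pair (p < α) splits every
set containing both members; subset sets are absorbed. This
guarantees the display invariant *two treatments share a letter iff
their pairwise p ≥ α*. Note Dunn's test is conservative at small n:
three adjacent groups of 5 with disjoint supports give z ≈ 1.77
(p ≈ 0.077) for neighbouring pairs, so fully distinct letters require
roughly n ≥ 10 per group. Because replicate-level data behind the
reference tables were never published, letter displays are
property-tested (consistency, null calibration), not golden-tested.

## Diversity

Shannon H′ uses natural log by default. The reference study's remark
that its low-diversity fungal communities sit below 3 is consistent
with nats; `base=2` is available. Chao-1 defaults to the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), defined even when
F2 = 0; the classic F1²/(2F2) form is selectable and errors on F2 = 0.
Both are authored in-package (they are part of the specified surface)
and cross-checked against scikit-bio in the tests. No rarefaction by
default — the reference workflow does not mention it — but
`diversity.rarefy` provides seeded subsampling for sensitivity checks.

## Expression (2^−ΔΔCt)

Technical replicates collapse by arithmetic mean over *determined*
wells; a cell with zero determined wells is undetermined, and partial
cells are flagged. Raw Ct strictly above 36 cycles is undetermined at
read time (36.0 is a valid measurement). ΔCt = Ct_target − Ct_HK is
formed per biological replicate with matched housekeeping wells;
biological replicates are averaged **on the ΔCt/ΔΔCt (log) scale**,
so the reported fold change 2^−ΔΔCt is the geometric mean across
replicates — the standard choice for this method, symmetric under
multiplicative noise. Arithmetic-mean FC is selectable
(`fc_averaging="arithmetic"`) since the reference description is
silent. The calibrator's own ΔΔCt is 0 by construction and its FC is
pinned to exactly 1 under log-scale averaging. Classification uses
inclusive thresholds: up iff FC ≥ 2, down iff FC ≤ 0.5; undetermined
genes are excluded from up-gene counts. Heatmap export emits the mean
ΔCt matrix and the log2-FC matrix side by side. Amplification-efficiency
correction (Pfaffl) and multi-gene normalization are out of scope.

## Ordination

Correlation-matrix PCA is the default because trait matrices mix cm,
g, % and SPAD units (the reference analyses do not state their
scaling); covariance-matrix PCA via `standardize=False`. The SVD is
taken on the centered/scaled matrix; explained variance fractions are
σ_k²/Σσ². Signs follow a deterministic convention (largest-magnitude
loading per component positive). Zero-variance columns error under
standardization and are named. Reproducing the reference figures'
printed variance percentages is explicitly not a goal: the
replicate-level matrices behind them were not published.

## Synthetic data

The generator emulates the reference study's stated world, not a
tunable benchmark:

* **Design** — 12 wheat / 8 maize treatments, 6 pots per treatment,
  duplicate soil samples per treatment, 14 target genes, 2 timepoints
  (21/60 DAS).
* **Traits** — Normal(mean, sd) with the published per-treatment
  means/SDs, truncated at 0 by resampling (clipping would pile mass
  at 0). Dry weight is fresh weight × a Beta-distributed dry
  fraction with mean dw_mean/fw_mean and SD dw_sd/fw_mean, so
  DW ≤ FW holds by construction and zero-SD configs reproduce the
  configured means exactly; dry-biomass % is derived, never drawn.
* **Communities** — per sample, taxon proportions ~
  Dirichlet(c · profile), counts ~ Multinomial(library, proportions).
  The bacterial profile fixes Proteobacteria at 56%, Bacteroidetes
  11%, five minor phyla at 3–8%; the fungal profile puts four phyla
  above 90% together. Each phylum splits over 5 genus-level OTUs with
  harmonic weights (a deterministic rank-abundance shape; genus-level
  structure was unconstrained). Defaults chosen once where unstated:
  library 50,000 reads, concentration c = 200 (amplicon-typical
  overdispersion).
* **Ct tables** — housekeeping 18S at Ct 15.0 ± 0.3 (an abundant
  rRNA target), target genes offset 6–12 cycles, technical noise
  0.15 cycles; planted fold changes enter as −log2(FC) cycles, so the
  ΔΔCt stage inverts them exactly at zero noise. The default plants
  FC 4 for nine genes in Char_MC-C_AMF at 21 DAS. Values above 36
  cycles are emitted as-is; the reader marks them.
* **Seeding** — one `numpy` Generator per output table, seeded from
  (master seed, CRC32 of the table name): identical seeds give
  byte-identical studies, and adding a new table type never perturbs
  existing ones.

What the generator does **not** emulate: read-level sequence error,
chimeras, contamination, compositional correlations between taxa
beyond the Dirichlet, spatial/greenhouse block effects, or
amplification-efficiency differences between genes. A green test on
synthetic data therefore establishes algorithmic correctness
(parameter recovery, invariants, calibration), not robustness to
those real-data artifacts.

## Numerical choices

* Half-up rounding of means via exact `decimal` division of integer
  total by integer count.
* Rank ties: `rankdata(method="max")`; oracle-tested.
* Shannon terms with zero counts contribute exactly 0 (no 0·log 0).
* Truncation-by-resampling caps at 1000 rounds then clips (reachable
  only for configs with mean far below 0).
* PCA uses the full SVD solver; tolerances 1e-9 against the
  eigendecomposition oracle.

## Limitations

* Replicate-level reference data are unpublished, so trait fixtures
  are single pseudo-replicates and letter displays cannot be
  golden-tested.
* The rank aggregation is unweighted and treats all parameters as
  exchangeable evidence; no significance is attached to rank totals.
* Dunn's test at n ≤ 6 per group has limited power; interpret letter
  displays at reference-study sample sizes accordingly.
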