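# Methods

## Scope and model

`pandmr` implements a pan-cancer differential DNA-methylation workflow
over 450K-style beta matrices. The unit of observation is a CpG probe's
beta value β ∈ [0, 1] (methylated fraction); the unit of inference is a
probe (DMS) and then a region (DMR) shared across cancer-type cohorts.
Each cohort contributes paired normal/tumor matrices over one shared
probe manifest; collections of cohorts (e.g. a discovery and a
validation collection) are analyzed independently and intersected at the
region level.

All coordinates are 1-based inclusive, as on array manifests; BED export
converts to 0-based half-open at the boundary (bed_start = start − 1,
bed_end = end), and both directions are covered by tests.

## Normalization

The default scheme (`rank-mean`) builds its reference as the *sorted
vector of per-probe means across all enrolled samples* and assigns the
k-th smallest reference value to each sample's rank-k probe. This
differs from classic quantile normalization (reference = mean of
per-sample sorted columns), which is available as `qn_mode="classic"`.
Both guarantee that every sample column carries one shared multiset of
values and that within-sample rank order is preserved.

Numerical choices:

* **Ties** within a sample all receive the mean of the reference values
  over the tied rank span — deterministic and invariant to row order.
* **Idempotence** holds exactly for the classic mode. The rank-mean mode
  is *not* exactly idempotent: after one pass the per-probe means are
  rank-mixed across samples, so the recomputed reference differs
  (two probes × two samples with opposite ranks is a counterexample).
  Re-application still preserves ranks and the shared-multiset contract;
  tests assert exactly that.
* **Missing values** are not permitted inside the normalizer; the
  explicit policy (`drop_missing_probes`) removes a probe across all
  samples and logs the count.
* **Scope**: default is joint normalization of all samples in a
  collection; per-cohort scope is a config switch.

Cohorts with fewer than 30 samples in either group are excluded before
testing (boundary inclusive: exactly 30 passes); excluding every cohort
is an error, not an empty success.

## Site statistics

* **Test**: two-sided Welch t-test on beta values (no equal-variance
  assumption), optionally on logit-transformed values (M-value-like
  scale). Degenerate probes with zero variance in both groups get p = 1
  when the means agree (logged) and p = 0 otherwise.
* **FDR**: Benjamini–Hochberg step-up within each cohort across all
  probes (statsmodels); tests cross-check a hand-coded step-up rule on
  every permutation of four p-values.
* **AUROC**: tumor is the positive class and β the score;
  AUC = P(β_t > β_n) + ½·P(tie), computed exactly from midranks
  (the normalized Mann–Whitney U). Tests cross-check exhaustive pair
  counting and the antisymmetry auroc(A,B) = 1 − auroc(B,A).
* **Pan-cancer aggregation**: probe passes when q < 0.01 (strict) in at
  least `min_significant_fraction` of cohorts (default 1.0 — every
  cohort) and mean AUROC across cohorts ≥ 0.75 (inclusive). The default
  `hyper` direction mode uses the raw tumor-positive mean AUC;
  `symmetric` mode gates on max(AUC, 1 − AUC) so hypomethylated probes
  can qualify. Whether the per-cohort FDR gate must hold in *all*
  cohorts is genuinely underdetermined for this style of analysis; it is
  exposed as `min_significant_fraction` rather than hard-coded.

## Region calling

A candidate run is a maximal set of consecutive manifest probes on one
chromosome, all flagged as DMS; any intervening non-DMS probe breaks the
run, and no maximum genomic gap is imposed within a run (the density
gate handles sparse runs). A run becomes a DMR iff it has at least 10
sites (inclusive — the reference catalogue contains 10-site regions) and
n_DMS / (end − start) ≥ 3/1000 per bp. Length is end − start;
density is stored per bp and printed rounded half-even (5 decimals by
default) — the per-bp convention reproduces the reference table's
printed densities, whose column header is nominally per kb.

Merging combines same-chromosome records whose gap (next.start −
prev.end) is at most `max_gap_bp` (default 1000, chosen to capture the
observed 45 bp case with wide margin; config-exposed). Intersection of
two collections keeps regions of A overlapping any region of B by at
least `min_overlap_bp` on the half-open reading of the spans.

## Co-expression disruption

The cluster heatmap observation — genes modular in normal tissue,
decorrelated in tumor — is formalized as the **block contrast**: mean
off-diagonal Pearson r within blocks minus mean r across blocks. The
default cluster is HOXA1–HOXA13 (the eleven genes with expression
entries) split block1 = HOXA1–HOXA6, block2 = HOXA7–HOXA13. An optional
one-sided permutation p shuffles gene→block labels. Zero-variance genes
are excluded from the correlation matrix and reported as explicit error
records, never as silent NaNs. Distal-gene association (motivated by
TAX1BP1, ~700 kb downstream of the HOXA locus) reports Pearson r per
cluster gene with the two-sided t-transform p (df = n − 2) at α = 0.05.

## Synthetic cohorts

The generators emulate the study conditions the pipeline is meant for:

* **Manifest**: probes split across chromosomes with geometric
  inter-probe gaps (mean 500 bp default — a CpG-dense, island-like
  spacing). `build_manifest_with_runs` embeds each planted run as
  consecutive probes with exact endpoints and surrounds it with ±10 kb
  of flanking background probes, as on a real array; without flankers,
  two distant runs on one chromosome would sit adjacent in manifest
  order and fuse into one low-density run.
* **Beta values**: each probe draws one baseline mean from
  Beta(0.8, 0.8) — bimodal, as array-wide beta distributions are —
  shared across cohorts (methylation maintained from the tissue of
  origin). Planted probes draw from Beta(2, 8) (low-methylation mode),
  modeling CpG-island probes that gain methylation in tumors, so a
  planted Δβ = +0.3 stays representable; hypomethylated runs mirror to
  Beta(8, 2). Per-cohort baseline offsets (sd 0.02) emulate batch and
  tissue heterogeneity. Per-sample noise (sd 0.4) is added on the logit
  scale and back-transformed, keeping values in (0, 1) without mass at
  the clip bounds [1e-6, 1 − 1e-6]; the slight mean bias of the
  logit-normal (≲ 0.02 at these settings) is well inside the ±0.03
  recovery tolerance asserted at n = 40/40.
* **Default conditions** for planted-recovery runs: Δβ = 0.3, three
  cohorts, 40 normal + 40 tumor samples per cohort — sizes at which the
  FDR and AUROC gates recover a planted run site-for-site.
* **Expression**: multivariate normal on the log scale with unit
  variances and target correlation r_within (group-dependent: 0.8
  normal, 0.2 tumor) inside blocks and r_between = 0.1 across; the
  distal gene is independent of the cluster in normal samples and
  correlated at 0.3 with every cluster gene in tumor. Targets are
  validated for positive semi-definiteness (a distal coupling of 0.5 to
  all eleven genes alongside the tumor block structure is *not* a valid
  correlation matrix — the validator names the offending entries);
  sampling uses the eigendecomposition so exactly singular targets
  (r = 0.99 pairs) remain usable.
* **Seeding**: one master seed; sub-streams per cohort/matrix via
  `SeedSequence.spawn`, so generators are reproducible and adding a
  cohort never perturbs another's draws.

What the generator does **not** emulate: Infinium I/II probe chemistry,
detection p-values, cross-reactive probes, purity/cell-composition
effects, and realistic genome-scale probe counts. Passing tests
therefore demonstrate the pipeline's logic and calibration under clean
planted truth, not robustness to those artifacts.

## Problem sizes

Simulated checks run at deliberately desk-scale sizes chosen as the
smallest at which the asserted effects are comfortably identifiable:
~2 000–2 800 probes, 3 cohorts × 80 samples for planted-recovery runs;
200–300 probes for 20-replicate null calibrations; n = 200 per group for
co-expression parameter recovery (sampling sd of r ≈ 0.07 at r = 0).

## Known limitations

* The rank-mean normalizer loads all samples of a collection at once;
  it is meant for matrices that fit in memory.
* DMR calling treats the manifest as ground truth; unannotated or
  filtered probes silently change contiguity, as they would on a real
  array after probe QC.
* The block contrast is an unweighted mean over gene pairs; very uneven
  block sizes weight the within-mean toward the larger block.
* No covariate adjustment, survival analysis, genome-build liftover, or
  chromatin-interaction (Hi-C/TAD) computation.
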