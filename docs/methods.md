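# Methods

`tomarker` implements the data-processing and statistics layer of an
untargeted LC-MS food-profiling study of tomatoes: four product groups —
organic datterini (DO), conventional datterini (D), fresh plump (PF) and
processed sauce (PS), six food replicates each — are compared pairwise to
find compounds whose abundance discriminates organic production, variety,
or processing. Because the raw instrument data are not part of the
package, every stage is exercised end to end on synthetic data with known
ground truth, and the published 70-compound marker table ships as a
packaged fixture for the set-level bookkeeping.

## Preprocessing model

**Drift correction.** Instrumental drift is modeled per feature as linear
in injection order on the log10 scale. For feature *f* with anchor
injections *A* (pooled QCs by default):

    log10 I[f,i] = a_f + b_f * order(i) + e,     fitted by OLS over A
    corrected[f,i] = log10 I[f,i] - b_f * (order(i) - mean_A(order))

Recentring at the mean anchor order removes the trend without rescaling
the feature's level. QC anchoring is the default because QCs are pooled
aliquots with no biological signal, so their trend is pure drift; an
`all_samples` fallback exists for runs without QCs. Features with fewer
than two present anchor values are flagged and passed through. The
correction is idempotent: re-fitted anchor slopes after one pass are zero
to machine precision, because OLS residuals are orthogonal to the
regressor.

**Imputation.** Missing values are treated as left-censored
(below-detection), not missing-at-random. Each missing cell of a feature
is replaced by an independent uniform draw on `(0, m/10]`, where *m* is
the feature's minimum observed intensity over all injections. The
interval is open at zero so downstream log10 is always finite; the draw
is implemented as `(1 - U) * m/10` with `U ~ [0, 1)`. A feature with no
observed value has no minimum and raises; the pipeline drops such
never-detected rows up front (a peak-picked table cannot contain them).

**Filtering.** Three reason-coded filters, applied to the
drift-corrected, pre-imputation table (detection rates are only
meaningful against the true missing mask):

| filter | keep when | default |
|---|---|---|
| `blank_ratio` | mean(samples)/mean(blanks) ≥ threshold, or never seen in blanks | 3 |
| `qc_rsd` | RSD over present QC intensities ≤ threshold (< 2 QC values fails) | 30% |
| `detection_rate` | fraction present ≥ threshold in ≥ 1 sample group | 0.5 |

The thresholds are community-standard values, configurable everywhere and
recorded in the per-feature report. Each filter is monotone: tightening a
threshold can only shrink the kept set.

**PCA diagnostics.** PCA of feature-wise mean-centered log10 data
(no variance scaling — the least-assumption default; scaling is an
option) via SVD, used to confirm that blanks separate from samples, QCs
cluster tightly, and the dominant biological contrast (processing)
appears on the leading component.

## Discriminant classifier

Statistics run per feature on log10, drift-corrected, imputed
intensities. For contrast (a, b) with fixed pairs Organic = (DO, D),
Variety = (D, PF), Process = (PS, PF):

    d = (mean_a - mean_b) / s_pooled,
    s_pooled^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)

with a two-sided pooled-variance Student t-test, and the three-state
label

    "+"  iff  d > 1     and p < 0.05      (strict inequalities)
    "-"  iff  d < -1    and p < 0.05
    "="  otherwise.

Design choices: classic pooled-SD Cohen's d without the Hedges
small-sample correction (available by flag), Student rather than Welch
(consistent with the pooled-SD effect size; Welch by flag), no
multiple-testing correction in compatibility mode (a Benjamini–Hochberg
column is emitted for transparency but never alters labels). Degenerate
zero-variance input maps to d = 0, p = 1 for equal means and signed
infinity, p = 0 otherwise. At n = 6 + 6 the p < 0.05 condition already
implies |d| > 1.286, so the effect-size threshold only binds at larger
sample sizes — and the false-label rate of the rule on true nulls is by
construction close to the nominal 5%.

The marker matrix (features × 3 contrasts) is decomposed by set algebra
into the 7 regions of the three-set Venn diagram plus the non-discriminant
remainder, and rendered as a red/green/grey tile heatmap grouped by
compound class.

## Suspect-screening annotation

Evidence layers: precursor (theoretical adduct m/z, `[M+H]+` = M +
1.007276, `[M-H]-` = M − 1.007276, within a ppm tolerance of the observed
m/z, polarity-gated, error reported relative to the theoretical mass);
retention time against an authentic standard; MS/MS via greedy one-to-one
fragment pairing (closest pairs first, each peak used once) scored by
cosine similarity of square-root-weighted intensities over the full peak
lists. Confidence levels:

* **L1** — authentic standard: precursor + |RT error| ≤ tolerance + MS/MS
  agreement;
* **L2** — library MS/MS agreement (no RT requirement);
* **L3** — precursor match with interpretable experimental MS/MS but no
  spectral match, flagged for manual review (structural plausibility is a
  human judgement, modeled as a flag, not automated);
* *derivative rule* — MS/MS matches a standard but RT does not: L3,
  renamed "derivative of <standard>".

Defaults (stated nowhere upstream, conventional for QToF data, all
configurable and recorded in outputs): 5 ppm precursor, 0.2 min RT,
0.01 Da fragments, cosine ≥ 0.6 with ≥ 2 shared fragments. A 1e-12 guard
on the cosine threshold keeps exact-boundary scores (e.g. 3/5 shared
equal-intensity peaks) from being lost to floating-point rounding. Among
multiple hits for one feature/suspect pair the best is chosen by level,
then |ppm|, then |RT error|. Same-suspect annotations on distinct
features with the same adduct and MS/MS kind, chained within an RT
window, receive (I), (II), … suffixes in ascending RT.

## Targeted quantification

Unweighted OLS external calibration (1/x weighting by flag), LOQ = lowest
calibration level, censoring sentinel `BELOW_LOQ` that propagates through
every conversion. Dry-to-fresh weight: fw (mg/kg) = dw (µg/g) × (1 − w)
with w the measured water fraction (0.92 default); µg/g and mg/kg are
numerically identical so the dry-matter factor is the whole conversion.
Note a documented inconsistency in the source material: the printed LOQ
pair (1.56 µg/g dw ↔ 0.078 mg/kg fw) implies a factor 0.05 rather than
the 0.08 that follows from 92% water; the module follows the formula and
does not reproduce that pair. Serving math: mg per serving = conc (mg/kg)
× serving (g) × part mass fraction / 1000.

## Synthetic data: what it emulates, and what not

Per feature and injection: log10 intensity = baseline + group effect +
slope × order + noise; raw intensity = 10^log10; cells below a log10
threshold become MISSING (left-censoring). Defaults and their grounds:

| parameter | default | basis |
|---|---|---|
| groups / replicates | DO, D, PF, PS × 6 | emulated design |
| QC interval | every 10 samples, plus opening and closing QC | emulated design |
| baseline | N(5.0, 0.8) log10 | typical peak-area magnitudes |
| replicate sd | 0.15 log10 (≈ 36% CV) | biological + method variability |
| QC/blank sd | 0.05 log10 (≈ 12% CV) | instrumental-only repeatability (<15%); a pooled QC has no biological variance |
| drift slope sd | 0.004 log10/injection | ~0.1–0.3 log10 over a 31-injection run; magnitudes are not reported upstream, an engineering choice |
| marker effect | 0.5 log10 | ≈ 3.2-fold, a clearly detectable but not trivial effect at n = 6 |
| marker fraction | 0.10 per contrast | sparse markers, as observed |
| censor threshold | 3.0 log10 | ≈ 1–6% missing cells at the default baseline |
| blanks | 3, at baseline − 2 log10 | procedural blanks near noise |

Markers are injected so each contrast is independently perturbed: an
Organic marker shifts DO only, a Variety marker shifts both datterini
groups, a Process marker shifts PS only; true labels are derived from the
realized group-effect differences, never assumed. QCs follow the pooled
mean of the group profiles.

Not simulated: chromatographic peak shapes, isotope patterns, nonlinear
or multi-batch drift, missing-at-random dropouts, correlated features. A
green recovery test therefore establishes that the pipeline inverts
exactly the generative model it assumes (linear log-scale drift,
left-censoring, independent log-normal noise) — not that it is robust to
model misspecification.

## Packaged reference table

The 70-compound marker table is stored verbatim as TSV with a SHA-256
guard, including its printed oddities: the two Aspartame isomer rows
whose masses (295.1154 / 295.1297) are too far apart for one precursor,
the Leucine-leucine (I)/(II) pair labelled against ascending RT, and the
Guanine / acetaminophen-derivative rows sharing m/z 152.0709 at RT 1.58.
Adduct typography is normalized to ASCII (`[M+H]+`, `[M-H]-`). Row-level
tallies reproduce every published set-level count (8/26/42 discriminants,
2/8/22 exclusives, 62/8 neuroactivity, class sizes) except one: the
narrated confidence-level totals (30, 33, 7) disagree with the table as
printed, which tallies to (30, 32, 8). The package reports what the rows
say; the one failing acceptance check records the narrated claim.

## Known limitations

* Drift is strictly linear per feature; LOESS/spline models and
  between-batch alignment are out of scope.
* The isomer suffix convention is ascending RT; the published table
  contains one pair labelled the other way, which the fixture preserves.
* `n_per_group < 2` is rejected rather than degraded, since the
  classifier needs within-group variance.
* All randomness flows from explicit integer seeds (stage seeds derived
  by hashing the stage name into [0, 2^31)); reruns are bit-identical.
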