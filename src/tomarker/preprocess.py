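"""Feature-table preprocessing: drift correction, imputation, filtering, PCA QC.

The processing chain mirrors standard untargeted LC-MS practice:

1. :func:`correct_drift` — per-feature ordinary least squares of log10
   intensity on injection order over anchor injections (pooled QCs by
   default), subtracting the fitted slope while preserving the feature's
   overall level.
2. :func:`impute_missing` — left-censored floor imputation: each missing
   cell gets an independent uniform draw on (0, m/10], m the feature's
   minimum observed intensity.
3. :func:`filter_features` — blank ratio, QC relative standard deviation
   and group-wise detection-rate filters, with per-feature reason codes.
4. :func:`pca_qc` — PCA of feature-centered log10 data as a run-quality
   diagnostic (blanks apart, QCs tight, sample structure visible).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import FeatureTable, FeatureTableError, to_log10

logger = logging.getLogger(__name__)

REASON_BLANK = "blank_ratio"
REASON_QC_RSD = "qc_rsd"
REASON_DETECTION = "detection_rate"


class PreprocessingError(ValueError):
    pass


def drop_undetected(table: FeatureTable) -> FeatureTable:
    """Remove features with no present value in any injection.

    A peak-picked feature table never contains such rows, but a simulated
    table with heavy left-censoring can; they carry no information and
    have no minimum for floor imputation.
    """
    detected = ~table.missing.all(axis=1)
    if detected.all():
        return table
    kept = table.features.index[detected]
    logger.info("dropping %d never-detected feature(s)", int((~detected).sum()))
    return FeatureTable(
        features=table.features.loc[kept].copy(),
        injections=table.injections.copy(),
        values=table.values.loc[kept].copy(),
        missing=table.missing.loc[kept].copy(),
        scale=table.scale,
    )


def correct_drift(table: FeatureTable, anchor: str = "qc") -> tuple[FeatureTable, pd.DataFrame]:
    """Remove per-feature linear drift in log10 intensity vs injection order.

    For each feature the slope is fitted by OLS over the anchor injections
    (``anchor="qc"``: pooled QCs; ``anchor="all_samples"``: biological
    samples).  The correction subtracts ``slope * (order - mean anchor
    order)`` from every log10 intensity, i.e. the drift component is
    removed and the level at the anchor midpoint is preserved.  The output
    is returned on the raw scale; missing cells are untouched.

    Features with fewer than two present anchor values (or no spread in
    anchor order) cannot be fitted; they are flagged ``corrected=False``
    and passed through unchanged.

    Returns the corrected table and a per-feature drift model table with
    columns ``intercept``, ``slope``, ``n_anchor``, ``corrected``.
    """
    if table.scale != "raw":
        raise PreprocessingError("correct_drift expects a raw-scale table")
    if anchor == "qc":
        anchor_ids = table.injection_ids(sample_type="qc")
        if len(anchor_ids) == 0:
            raise PreprocessingError(
                "no QC injections in table; use anchor='all_samples'"
            )
    elif anchor == "all_samples":
        anchor_ids = table.injection_ids(sample_type="sample")
    else:
        raise PreprocessingError(f"unknown anchor {anchor!r}")

    order = table.injections["injection_order"].astype(float)
    anchor_order = order.loc[anchor_ids].to_numpy()

    vals = table.masked_values().to_numpy()
    log10 = np.where(np.isnan(vals), np.nan, np.log10(np.where(np.isnan(vals), 1.0, vals)))
    anchor_cols = table.values.columns.get_indexer(anchor_ids)

    model = pd.DataFrame(
        index=table.features.index,
        columns=["intercept", "slope", "n_anchor", "corrected"],
    )
    corrected = log10.copy()
    all_order = order.to_numpy()
    for i in range(table.n_features):
        y = log10[i, anchor_cols]
        ok = ~np.isnan(y)
        x = anchor_order[ok]
        n = int(ok.sum())
        if n < 2 or np.ptp(x) == 0:
            model.iloc[i] = [np.nan, np.nan, n, False]
            continue
        slope, intercept = np.polyfit(x, y[ok], 1)
        corrected[i] -= slope * (all_order - x.mean())
        model.iloc[i] = [intercept, slope, n, True]

    out = table.copy()
    raw = np.where(np.isnan(corrected), np.nan, 10.0 ** corrected)
    out.values = pd.DataFrame(raw, index=out.values.index, columns=out.values.columns)
    out.values = out.values.where(~out.missing)
    model = model.astype({"n_anchor": int, "corrected": bool})
    return out, model


def impute_missing(table: FeatureTable, seed: int) -> FeatureTable:
    """Replace missing cells with uniform draws on (0, m/10].

    m is the feature's minimum present intensity across all injections.
    Present cells are never altered; the result is reproducible from
    *seed*.  A feature with no present value has no minimum and raises.
    """
    if table.scale != "raw":
        raise PreprocessingError("impute_missing expects a raw-scale table")
    rng = np.random.default_rng(seed)
    vals = table.values.to_numpy(copy=True)
    mask = table.missing.to_numpy()

    all_missing = mask.all(axis=1)
    if all_missing.any():
        bad = table.features.index[all_missing].tolist()
        raise PreprocessingError(
            f"cannot impute features with no observed value (no minimum): {bad}"
        )

    for i in range(vals.shape[0]):
        miss = mask[i]
        if not miss.any():
            continue
        m = np.nanmin(np.where(miss, np.nan, vals[i]))
        # uniform on (0, m/10]: 1 - U with U ~ [0, 1) is in (0, 1]
        vals[i, miss] = (1.0 - rng.random(miss.sum())) * (m / 10.0)

    out = table.copy()
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.missing = pd.DataFrame(
        False, index=out.missing.index, columns=out.missing.columns
    )
    return out


def filter_features(
    table: FeatureTable,
    blank_ratio_min: float = 3.0,
    qc_rsd_max: float = 30.0,
    detection_rate_min: float = 0.5,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop noisy and non-relevant features; report every removal reason.

    A feature is kept iff all of:

    * blank ratio: mean over sample injections / mean over blank
      injections >= ``blank_ratio_min`` (a feature never detected in any
      blank passes; with no blank injections the filter is skipped with a
      logged notice);
    * QC repeatability: RSD (sd/mean, percent) over present QC
      intensities <= ``qc_rsd_max`` (skipped if the table has no QCs; a
      feature with < 2 present QC values fails, being unassessable);
    * detection: fraction of present values >= ``detection_rate_min``
      within at least one sample group.

    Detection rate is evaluated on the missing mask, so this filter is
    meaningful only before imputation.
    """
    vals = table.masked_values()
    present = ~table.missing

    blank_ids = table.injection_ids(sample_type="blank")
    qc_ids = table.injection_ids(sample_type="qc")
    sample_ids = table.injection_ids(sample_type="sample")

    report = pd.DataFrame(index=table.features.index)
    report["kept"] = True
    report["reasons"] = ""

    def flag(mask: pd.Series, code: str) -> None:
        report.loc[mask, "kept"] = False
        sep = report.loc[mask, "reasons"].where(report.loc[mask, "reasons"] == "", other=report.loc[mask, "reasons"] + ",")
        report.loc[mask, "reasons"] = sep + code

    if len(blank_ids) == 0:
        logger.info("no blank injections: blank-ratio filter skipped")
    else:
        blank_mean = vals[blank_ids].mean(axis=1)
        sample_mean = vals[sample_ids].mean(axis=1)
        in_blank = present[blank_ids].any(axis=1)
        ratio = sample_mean / blank_mean
        fail = in_blank & ~(ratio >= blank_ratio_min)
        flag(fail, REASON_BLANK)

    if len(qc_ids) == 0:
        logger.info("no QC injections: QC-RSD filter skipped")
    else:
        qc_vals = vals[qc_ids]
        n_qc = present[qc_ids].sum(axis=1)
        rsd = qc_vals.std(axis=1, ddof=1) / qc_vals.mean(axis=1) * 100.0
        fail = (n_qc < 2) | ~(rsd <= qc_rsd_max)
        flag(fail, REASON_QC_RSD)

    groups = table.sample_groups()
    if groups:
        rates = pd.concat(
            {g: present[table.injection_ids(group=g)].mean(axis=1) for g in groups},
            axis=1,
        )
        fail = ~(rates.max(axis=1) >= detection_rate_min)
        flag(fail, REASON_DETECTION)

    kept_ids = report.index[report["kept"]]
    out = FeatureTable(
        features=table.features.loc[kept_ids].copy(),
        injections=table.injections.copy(),
        values=table.values.loc[kept_ids].copy(),
        missing=table.missing.loc[kept_ids].copy(),
        scale=table.scale,
    )
    for fid, row in report[~report["kept"]].iterrows():
        logger.debug("removed feature %s: %s", fid, row["reasons"])
    return out, report


@dataclasses.dataclass
class PCAResult:
    scores: pd.DataFrame        # injections x components
    loadings: pd.DataFrame      # features x components
    explained_variance_ratio: np.ndarray


def pca_qc(table: FeatureTable, n_components: int | None = None) -> PCAResult:
    """PCA of log10, feature-centered data (no variance scaling).

    Requires an imputed table (no missing cells) with >= 3 injections.
    Scores are reproducible up to per-component sign.
    """
    if table.missing.to_numpy().any():
        raise PreprocessingError("table contains missing values; impute before PCA")
    if table.n_injections < 3:
        raise PreprocessingError("PCA needs at least 3 injections")
    work = to_log10(table) if table.scale == "raw" else table
    X = work.values.to_numpy().T  # injections x features
    X = X - X.mean(axis=0, keepdims=True)
    k = min(X.shape) if n_components is None else n_components
    k = min(k, min(X.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=work.injections.index, columns=cols),
        loadings=pd.DataFrame(pca.components_.T, index=work.features.index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
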