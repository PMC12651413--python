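"""Synthetic untargeted LC-MS data with known ground truth.

Emulates the structure of a four-group tomato feeding-quality study:
organic datterini (DO), conventional datterini (D), fresh plump (PF) and
processed/sauce (PS), six biological replicates each, a pooled QC injected
every ``qc_interval`` samples, procedural blanks, randomized injection
order, per-feature linear drift on log10 intensities, multiplicative group
effects on designated marker features, and left-censored (below-detection)
missingness.

The generative model, per feature f and injection i:

    log10 I[f, i] = baseline[f] + effect[f, group(i)]
                    + slope[f] * order(i) + eps,   eps ~ N(0, replicate_sd)

QC injections use the pooled profile (arithmetic mean of the group
effects, matching a QC pooled from every sample) and carry only
instrumental noise (``qc_log10_sd``), since a pooled QC has no biological
variability; blanks sit at a low baseline.  Raw intensity is 10**log10; any cell whose log10 value falls
below ``censor_log10_threshold`` is recorded as MISSING.

Marker features are injected per contrast so that each contrast is
perturbed independently: an Organic marker shifts DO only, a Variety
marker shifts both datterini groups (DO and D) so the organic contrast is
untouched, and a Process marker shifts PS only.  True labels are derived
from the realized effect differences, never assumed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import FeatureTable, Spectrum

CONTRAST_GROUPS = {"Organic": ("DO", "D"), "Variety": ("D", "PF"), "Process": ("PS", "PF")}
# groups whose effect a marker for the given contrast perturbs
_MARKER_TARGETS = {"Organic": ("DO",), "Variety": ("DO", "D"), "Process": ("PS",)}

PROTON_MASS = 1.007276  # Da, charge-adjusted


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_features: int = 200
    n_per_group: int = 6
    groups: tuple[str, ...] = ("DO", "D", "PF", "PS")
    qc_interval: int = 10
    n_blanks: int = 3
    baseline_log10_mean: float = 5.0
    baseline_log10_sd: float = 0.8
    replicate_log10_sd: float = 0.15
    qc_log10_sd: float = 0.05  # instrumental-only noise on QC/blank injections
    drift_slope_log10_sd: float = 0.004  # per injection
    marker_effect_log10: float = 0.5
    marker_fraction_per_contrast: float = 0.10
    censor_log10_threshold: float = 3.0
    blank_log10_offset: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (downstream tests need replicates)")
        if self.qc_interval < 1:
            raise ValueError("qc_interval must be >= 1")
        for name in ("baseline_log10_sd", "replicate_log10_sd", "qc_log10_sd",
                     "drift_slope_log10_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.marker_fraction_per_contrast <= 1:
            raise ValueError("marker_fraction_per_contrast must be in [0, 1]")
        if self.n_blanks < 0:
            raise ValueError("n_blanks must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually injected, for recovery testing."""

    labels: pd.DataFrame          # feature x contrast, in {+, -, =}
    drift_slope: pd.Series        # log10 units per injection, per feature
    group_effect: pd.DataFrame    # feature x group, log10 units
    censor_log10_threshold: float


def _injection_layout(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Blanks first, then QC-bracketed batches of randomized samples.

    A QC opens the sample sequence, recurs after every ``qc_interval``
    samples, and closes the run.
    """
    sample_ids, sample_groups = [], []
    for g in cfg.groups:
        for r in range(cfg.n_per_group):
            sample_ids.append(f"{g}_{r + 1}")
            sample_groups.append(g)
    perm = rng.permutation(len(sample_ids))

    rows: list[tuple[str, str, str | None]] = []
    rows += [(f"blank_{b + 1}", "blank", None) for b in range(cfg.n_blanks)]
    qc_n = 1
    rows.append((f"QC_{qc_n}", "qc", None))
    for k, j in enumerate(perm, start=1):
        rows.append((sample_ids[j], "sample", sample_groups[j]))
        if k % cfg.qc_interval == 0 and k < len(perm):
            qc_n += 1
            rows.append((f"QC_{qc_n}", "qc", None))
    rows.append((f"QC_{qc_n + 1}", "qc", None))

    df = pd.DataFrame(rows, columns=["id", "sample_type", "group"]).set_index("id")
    df["injection_order"] = np.arange(1, len(df) + 1)
    return df


def simulate_feature_table(cfg: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one synthetic study; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    contrasts = {
        name: pair for name, pair in CONTRAST_GROUPS.items()
        if pair[0] in cfg.groups and pair[1] in cfg.groups
    }

    feat_ids = [f"F{i + 1:04d}" for i in range(cfg.n_features)]
    baselines = rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd, cfg.n_features)
    slopes = rng.normal(0.0, cfg.drift_slope_log10_sd, cfg.n_features)

    effect = pd.DataFrame(0.0, index=feat_ids, columns=list(cfg.groups))
    n_markers = int(round(cfg.marker_fraction_per_contrast * cfg.n_features))
    for name in contrasts:
        chosen = rng.choice(cfg.n_features, size=n_markers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_markers)
        for j, s in zip(chosen, signs):
            for g in _MARKER_TARGETS[name]:
                if g in effect.columns:
                    effect.iloc[j, effect.columns.get_loc(g)] += s * cfg.marker_effect_log10

    labels = pd.DataFrame("=", index=feat_ids, columns=list(contrasts))
    for name, (ga, gb) in contrasts.items():
        diff = effect[ga] - effect[gb]
        labels.loc[diff > 0, name] = "+"
        labels.loc[diff < 0, name] = "-"

    injections = _injection_layout(cfg, rng)
    order = injections["injection_order"].to_numpy()
    pooled_effect = effect[list(cfg.groups)].mean(axis=1).to_numpy()

    log10 = np.empty((cfg.n_features, len(injections)))
    for col, (inj_id, row) in enumerate(injections.iterrows()):
        if row["sample_type"] == "sample":
            mu = baselines + effect[row["group"]].to_numpy()
        elif row["sample_type"] == "qc":
            mu = baselines + pooled_effect
        else:
            mu = baselines + cfg.blank_log10_offset
        log10[:, col] = mu + slopes * order[col]
    # biological-replicate noise on samples; instrumental-only noise on
    # QC and blank injections (a pooled QC has no biological variability)
    col_sd = np.where(
        (injections["sample_type"] == "sample").to_numpy(),
        cfg.replicate_log10_sd,
        cfg.qc_log10_sd,
    )
    log10 = log10 + rng.standard_normal(log10.shape) * col_sd[np.newaxis, :]

    raw = 10.0 ** log10
    missing = log10 < cfg.censor_log10_threshold
    values = pd.DataFrame(raw, index=feat_ids, columns=injections.index)
    values = values.where(~missing)

    features = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(60.0, 1100.0, cfg.n_features), 4),
            "rt": np.round(rng.uniform(0.5, 17.0, cfg.n_features), 2),
            "ion_mode": rng.choice(["pos", "neg"], size=cfg.n_features),
        },
        index=pd.Index(feat_ids, name="feature_id"),
    )

    table = FeatureTable(
        features=features,
        injections=injections,
        values=values,
        missing=pd.DataFrame(missing, index=feat_ids, columns=injections.index),
        scale="raw",
    )
    truth = GroundTruth(
        labels=labels,
        drift_slope=pd.Series(slopes, index=feat_ids, name="slope"),
        group_effect=effect,
        censor_log10_threshold=cfg.censor_log10_threshold,
    )
    return table, truth


# -- suspect database / spectra ---------------------------------------


def _random_spectrum(precursor_mz: float, n_fragments: int, rng: np.random.Generator) -> Spectrum:
    frag_mz = np.sort(rng.uniform(50.0, max(60.0, precursor_mz - 1.0), n_fragments))
    inten = rng.uniform(10.0, 100.0, n_fragments)
    return Spectrum(precursor_mz=precursor_mz, peaks=np.column_stack([frag_mz, inten]))


def simulate_suspect_db(
    table: FeatureTable,
    n_true: int,
    n_decoy: int,
    mz_jitter_ppm: float = 2.0,
    fragment_overlap: float = 1.0,
    n_fragments: int = 5,
    rt_known_fraction: float = 1.0,
    seed: int = 0,
):
    """Build a suspect list + spectra wired to designated features of *table*.

    The first ``n_true`` features (by table order) become annotatable: each
    gets a suspect whose theoretical adduct m/z sits within
    ``mz_jitter_ppm`` of the feature m/z, a synthetic experimental MS/MS
    spectrum, and a library spectrum sharing ``fragment_overlap`` of its
    fragments.  Decoy suspects are offset by >= 40 ppm from every feature
    and match nothing at conventional tolerances.

    Returns
    -------
    suspects : list of :class:`tomarker.annotate.SuspectEntry`
    feature_spectra : dict feature_id -> Spectrum (experimental MS/MS)
    expected : dict suspect name -> feature id (the recovery oracle)
    """
    from .annotate import SuspectEntry  # local import to avoid a cycle

    if n_true < 0 or n_decoy < 0:
        raise ValueError("counts must be >= 0")
    if n_true > table.n_features:
        raise ValueError("n_true exceeds the number of features in the table")
    rng = np.random.default_rng(seed)

    suspects: list[SuspectEntry] = []
    feature_spectra: dict[str, Spectrum] = {}
    expected: dict[str, str] = {}

    for k in range(n_true):
        fid = table.features.index[k]
        fmz = float(table.features.loc[fid, "mz"])
        frt = float(table.features.loc[fid, "rt"])
        mode = table.features.loc[fid, "ion_mode"]
        adduct = "[M+H]+" if mode == "pos" else "[M-H]-"
        # theoretical adduct m/z within the jitter window of the observed m/z;
        # |offset| is drawn in (jitter/2, jitter] so the realized error scales
        # with the configured jitter rather than collapsing toward zero
        offset = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0) * mz_jitter_ppm
        theo = fmz * (1.0 + offset * 1e-6)
        neutral = theo - PROTON_MASS if adduct == "[M+H]+" else theo + PROTON_MASS

        exp_spec = _random_spectrum(fmz, n_fragments, rng)
        n_shared = int(round(fragment_overlap * n_fragments))
        lib_peaks = exp_spec.peaks.copy()
        for j in range(n_fragments - n_shared):  # displace the non-shared tail
            lib_peaks[n_fragments - 1 - j, 0] += rng.uniform(1.0, 5.0)
        lib_spec = Spectrum(precursor_mz=theo, peaks=lib_peaks) if n_shared > 0 or n_fragments else None

        has_std = bool(rng.random() < rt_known_fraction)
        name = f"true_suspect_{k + 1}"
        suspects.append(
            SuspectEntry(
                name=name,
                neuroactivity="protective",
                chem_class="synthetic",
                neutral_mass=neutral,
                allowed_adducts=(adduct,),
                standard_rt=frt if has_std else None,
                has_authentic_standard=has_std,
                library_spectrum=lib_spec,
            )
        )
        feature_spectra[fid] = exp_spec
        expected[name] = fid

    all_mz = table.features["mz"].to_numpy(dtype=float)
    for k in range(n_decoy):
        adduct = "[M+H]+" if rng.random() < 0.5 else "[M-H]-"
        for _ in range(1000):
            theo = float(rng.uniform(60.0, 1100.0))
            ppm_dist = np.abs(all_mz - theo) / theo * 1e6
            if np.all(ppm_dist > 40.0):
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not place a decoy away from all features")
        neutral = theo - PROTON_MASS if adduct == "[M+H]+" else theo + PROTON_MASS
        suspects.append(
            SuspectEntry(
                name=f"decoy_{k + 1}",
                neuroactivity="disrupting",
                chem_class="synthetic_decoy",
                neutral_mass=neutral,
                allowed_adducts=(adduct,),
                library_spectrum=_random_spectrum(theo, n_fragments, rng),
            )
        )
    return suspects, feature_spectra, expected
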