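"""End-to-end pipeline: read/simulate -> correct -> impute -> filter -> PCA ->
classify -> marker matrix -> Venn -> annotate -> heatmap, with a run manifest.

A single config seed fans out to per-stage seeds derived by hashing the
stage name, so each stochastic stage is independently reproducible and no
two stages share a stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import pandas as pd

from . import __version__
from .io import FeatureTable, read_feature_table, to_log10, write_feature_table
from .preprocess import correct_drift, drop_undetected, filter_features, impute_missing, pca_qc
from .simulate import SimulationConfig, simulate_feature_table
from .stats import CONTRASTS, build_marker_matrix, classify_contrast, render_heatmap, venn_partition

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Stage-specific seed: stable hash of (seed, stage name), < 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs; serialized into the manifest."""

    seed: int = 0
    # input: either three file paths or a simulation config
    matrix_path: str | None = None
    injection_metadata_path: str | None = None
    feature_metadata_path: str | None = None
    simulation: SimulationConfig | None = None
    # thresholds
    drift_anchor: str = "qc"
    blank_ratio_min: float = 3.0
    qc_rsd_max: float = 30.0
    detection_rate_min: float = 0.5
    d_threshold: float = 1.0
    alpha: float = 0.05
    paper_compat: bool = True   # raw per-feature p-values decide labels


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    suspects=None,
    spectra=None,
) -> dict:
    """Execute the full workflow and write all artifacts under *outdir*.

    Returns a report dict with the key in-memory objects (tables, marker
    matrix, Venn partition, PCA result, classification results, ground
    truth when simulated).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    if config.simulation is not None:
        sim_cfg = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        table, truth = simulate_feature_table(sim_cfg)
        report["ground_truth"] = truth
        truth.labels.to_csv(outdir / "ground_truth_labels.tsv", sep="\t")
    elif config.matrix_path:
        table = read_feature_table(
            config.matrix_path,
            config.injection_metadata_path,
            config.feature_metadata_path,
        )
    else:
        raise ValueError("config provides neither input paths nor a simulation")

    corrected, drift_model = correct_drift(drop_undetected(table), anchor=config.drift_anchor)
    drift_model.to_csv(outdir / "drift_model.tsv", sep="\t")

    imputed = impute_missing(corrected, seed=stage_seed(config.seed, "impute"))
    # the detection-rate filter needs the pre-imputation missing mask
    filtered, filter_report = filter_features(
        corrected,
        blank_ratio_min=config.blank_ratio_min,
        qc_rsd_max=config.qc_rsd_max,
        detection_rate_min=config.detection_rate_min,
    )
    filter_report.to_csv(outdir / "filter_report.tsv", sep="\t")
    # carry the imputed values for the surviving features
    kept = filtered.features.index
    final = FeatureTable(
        features=imputed.features.loc[kept].copy(),
        injections=imputed.injections.copy(),
        values=imputed.values.loc[kept].copy(),
        missing=imputed.missing.loc[kept].copy(),
        scale=imputed.scale,
    )
    write_feature_table(
        final,
        outdir / "intensities_processed.csv",
        outdir / "injections.csv",
        outdir / "features.csv",
    )

    pca = pca_qc(final)
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pd.Series(pca.explained_variance_ratio, name="explained_variance_ratio").to_csv(
        outdir / "pca_explained_variance.tsv", sep="\t"
    )
    report["pca"] = pca

    log_table = to_log10(final)
    results = {}
    for contrast in CONTRASTS:
        res = classify_contrast(
            log_table, contrast, d_threshold=config.d_threshold, alpha=config.alpha
        )
        res.to_csv(outdir / f"comparison_{contrast.lower()}.tsv", sep="\t")
        results[contrast] = res
    matrix = build_marker_matrix(results)
    matrix.to_csv(outdir / "marker_matrix.tsv", sep="\t")
    part = venn_partition(matrix)
    with open(outdir / "venn_partition.json", "w") as fh:
        json.dump(
            {
                "sizes": part.sizes(),
                "regions": {
                    ("none" if not k else "&".join(sorted(k))): sorted(v)
                    for k, v in part.regions.items()
                },
            },
            fh,
            indent=2,
        )
    fig, _ = render_heatmap(matrix, path=str(outdir / "marker_heatmap.png"))
    import matplotlib.pyplot as plt

    plt.close(fig)

    report.update(
        {
            "table": final,
            "results": results,
            "marker_matrix": matrix,
            "venn": part,
            "filter_report": filter_report,
            "drift_model": drift_model,
        }
    )

    if suspects:
        from .annotate import annotate_features, annotations_to_frame

        anns = annotate_features(final, suspects, spectra=spectra)
        annotations_to_frame(anns).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        report["annotations"] = anns

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "impute")},
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "n_features_in": table.n_features,
        "n_features_kept": final.n_features,
        "n_injections": final.n_injections,
        "discriminant_sizes": {k: len(v) for k, v in part.discriminant.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(
            f"tomarker run (seed {config.seed})\n"
            f"features in/kept: {table.n_features}/{final.n_features}\n"
            f"injections: {final.n_injections}\n"
            f"PC1/PC2 explained variance: "
            f"{pca.explained_variance_ratio[0]:.3f}/{pca.explained_variance_ratio[1]:.3f}\n"
            + "".join(
                f"{name}: {len(part.discriminant[name])} discriminant\n"
                for name in part.discriminant
            )
        )
    report["manifest"] = manifest
    return report
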