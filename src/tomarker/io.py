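"""Core data model and text-format I/O for untargeted LC-MS feature tables.

The central object is :class:`FeatureTable`: an intensity matrix
(features x injections) with sidecar feature and injection metadata and a
first-class missing-value mask.  Missing ("not detected") is distinct from
any numeric value: the left-censored imputation rule downstream depends on
that distinction, so it is never encoded as 0.

File formats are plain delimited text: a wide matrix (features as rows,
injections as columns) plus two metadata tables, matching how vendor
exports of peak-picked data are usually shaped.  MS/MS spectra are read
and written as MGF or MSP, both simple line-oriented text formats.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("sample", "qc", "blank")
GROUPS = ("DO", "D", "PF", "PS")
MZ_MIN, MZ_MAX = 50.0, 1500.0  # acquisition window, Da


class FeatureTableError(ValueError):
    """Structural or validation problem in a feature table."""


@dataclasses.dataclass
class Spectrum:
    """A centroided MS/MS spectrum: precursor m/z plus (mz, intensity) peaks.

    Peaks are stored sorted by m/z; at least one peak with nonzero
    intensity is required.
    """

    precursor_mz: float
    peaks: np.ndarray  # shape (n, 2): mz, intensity

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.peaks.shape[0] < 1:
            raise FeatureTableError("spectrum must contain at least one peak")
        if np.any(self.peaks[:, 1] < 0):
            raise FeatureTableError("peak intensities must be non-negative")
        if not np.any(self.peaks[:, 1] > 0):
            raise FeatureTableError("peak intensities must not all be zero")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclasses.dataclass
class FeatureTable:
    """Feature x injection intensity matrix with metadata and missing mask.

    Parameters
    ----------
    features
        DataFrame indexed by feature id with columns ``mz`` (Da), ``rt``
        (minutes) and ``ion_mode`` (``pos``/``neg``).
    injections
        DataFrame indexed by injection id with columns ``sample_type``
        (``sample``/``qc``/``blank``), ``group`` (one of DO, D, PF, PS for
        samples, empty/None otherwise) and ``injection_order`` (unique
        positive integers).
    values
        Float matrix aligned to ``features.index`` x ``injections.index``.
        Cells flagged in ``missing`` carry no information (stored as NaN).
    missing
        Boolean mask, same shape as ``values``; True marks "not detected".
    scale
        ``"raw"`` (peak areas, present values > 0) or ``"log10"``.
    """

    features: pd.DataFrame
    injections: pd.DataFrame
    values: pd.DataFrame
    missing: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        f_idx, i_idx = self.features.index, self.injections.index
        if not f_idx.is_unique:
            raise FeatureTableError("duplicate feature ids")
        if not i_idx.is_unique:
            raise FeatureTableError("duplicate injection ids")
        if list(self.values.index) != list(f_idx):
            raise FeatureTableError(
                "intensity matrix rows do not match feature metadata (feature axis)"
            )
        if list(self.values.columns) != list(i_idx):
            raise FeatureTableError(
                "intensity matrix columns do not match injection metadata (injection axis)"
            )
        if self.missing.shape != self.values.shape:
            raise FeatureTableError("missing mask shape differs from value matrix")
        if self.scale not in ("raw", "log10"):
            raise FeatureTableError(f"unknown scale {self.scale!r}")
        order = self.injections["injection_order"]
        if order.duplicated().any():
            dupes = order[order.duplicated()].tolist()
            raise FeatureTableError(f"duplicate injection_order values: {dupes}")
        if (order < 1).any():
            raise FeatureTableError("injection_order must be positive")
        bad_type = set(self.injections["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise FeatureTableError(f"unknown sample_type values: {sorted(bad_type)}")
        is_sample = self.injections["sample_type"] == "sample"
        grp = self.injections["group"]
        if grp[is_sample].isna().any():
            raise FeatureTableError("sample injections must carry a group label")
        if grp[~is_sample].notna().any():
            raise FeatureTableError("QC/blank injections must not carry a group label")
        if self.scale == "raw":
            present = self.values.to_numpy()[~self.missing.to_numpy()]
            if present.size and np.any(present <= 0):
                raise FeatureTableError("raw-scale present intensities must be > 0")
        if "mz" in self.features:
            mz = self.features["mz"].astype(float)
            if ((mz < MZ_MIN) | (mz > MZ_MAX)).any():
                bad = self.features.index[(mz < MZ_MIN) | (mz > MZ_MAX)].tolist()
                raise FeatureTableError(
                    f"feature m/z outside the {MZ_MIN}-{MZ_MAX} Da acquisition window: {bad}"
                )
        if "rt" in self.features and (self.features["rt"].astype(float) < 0).any():
            raise FeatureTableError("feature retention times must be >= 0")
        bad_mode = set(self.features.get("ion_mode", [])) - {"pos", "neg"}
        if bad_mode:
            raise FeatureTableError(f"unknown ion_mode values: {sorted(bad_mode)}")

    # -- convenience ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    def injection_ids(self, sample_type: str | None = None, group: str | None = None):
        """Injection ids filtered by sample_type and/or group."""
        sel = pd.Series(True, index=self.injections.index)
        if sample_type is not None:
            sel &= self.injections["sample_type"] == sample_type
        if group is not None:
            sel &= self.injections["group"] == group
        return self.injections.index[sel]

    def sample_groups(self) -> list[str]:
        g = self.injections.loc[
            self.injections["sample_type"] == "sample", "group"
        ].unique()
        return [x for x in GROUPS if x in g] + sorted(set(g) - set(GROUPS))

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            features=self.features.copy(),
            injections=self.injections.copy(),
            values=self.values.copy(),
            missing=self.missing.copy(),
            scale=self.scale,
        )

    def masked_values(self) -> pd.DataFrame:
        """Values with missing cells as NaN (a safe read-only view for numerics)."""
        return self.values.where(~self.missing)


def to_log10(table: FeatureTable) -> FeatureTable:
    """Return a copy of *table* with present intensities log10-transformed.

    Missing cells are preserved.  Refuses to transform twice.
    """
    if table.scale == "log10":
        raise FeatureTableError("table is already on the log10 scale")
    out = table.copy()
    vals = out.values.to_numpy(copy=True)
    mask = out.missing.to_numpy()
    vals[~mask] = np.log10(vals[~mask])
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.scale = "log10"
    return out


def from_log10(table: FeatureTable) -> FeatureTable:
    """Inverse of :func:`to_log10`."""
    if table.scale == "raw":
        raise FeatureTableError("table is already on the raw scale")
    out = table.copy()
    vals = out.values.to_numpy(copy=True)
    mask = out.missing.to_numpy()
    vals[~mask] = 10.0 ** vals[~mask]
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.scale = "raw"
    return out


# -- feature-table file set -------------------------------------------

_MISSING_TOKENS = ("", "NA", "NaN", "nan")


def read_feature_table(
    matrix_path: str | Path,
    injection_metadata_path: str | Path,
    feature_metadata_path: str | Path,
    sep: str = ",",
) -> FeatureTable:
    """Read a raw-scale feature table from its three-file delimited set.

    Empty cells, ``NA`` and literal ``0`` in the matrix denote MISSING.
    The matrix is wide: one row per feature, one column per injection,
    first column the feature id.
    """
    matrix = pd.read_csv(
        matrix_path, sep=sep, index_col=0, na_values=list(_MISSING_TOKENS),
        keep_default_na=False, float_precision="round_trip",
    )
    feats = pd.read_csv(
        feature_metadata_path, sep=sep, index_col=0, keep_default_na=False,
        na_values=list(_MISSING_TOKENS),
    )
    injs = pd.read_csv(
        injection_metadata_path, sep=sep, index_col=0, keep_default_na=False,
        na_values=list(_MISSING_TOKENS),
    )
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    feats.index = feats.index.astype(str)
    injs.index = injs.index.astype(str)

    missing_feat = set(feats.index) - set(matrix.index)
    extra_feat = set(matrix.index) - set(feats.index)
    if missing_feat or extra_feat:
        raise FeatureTableError(
            "feature axis mismatch between matrix and feature metadata: "
            f"absent from matrix {sorted(missing_feat)}, absent from metadata {sorted(extra_feat)}"
        )
    missing_inj = set(injs.index) - set(matrix.columns)
    extra_inj = set(matrix.columns) - set(injs.index)
    if missing_inj or extra_inj:
        raise FeatureTableError(
            "injection axis mismatch between matrix and injection metadata: "
            f"absent from matrix {sorted(missing_inj)}, absent from metadata {sorted(extra_inj)}"
        )

    matrix = matrix.loc[feats.index, injs.index].astype(float)
    values = matrix.where(matrix != 0)  # 0 denotes not-detected
    missing = values.isna()
    injs["injection_order"] = injs["injection_order"].astype(int)
    if "group" in injs:
        injs["group"] = injs["group"].where(injs["group"].notna() & (injs["group"] != ""))
    return FeatureTable(
        features=feats, injections=injs, values=values, missing=missing, scale="raw"
    )


def write_feature_table(
    table: FeatureTable, matrix_path, injection_metadata_path, feature_metadata_path,
    sep: str = ",",
) -> None:
    """Write the three-file delimited set read by :func:`read_feature_table`.

    Missing cells are written as empty fields; values use repr-precision so
    a round trip preserves them bit-exactly.
    """
    out = table.values.where(~table.missing)
    out.to_csv(matrix_path, sep=sep, index_label="feature_id",
               float_format=lambda x: np.format_float_positional(x, unique=True))
    table.injections.to_csv(injection_metadata_path, sep=sep, index_label="injection_id")
    table.features.to_csv(feature_metadata_path, sep=sep, index_label="feature_id")


# -- MGF / MSP spectra ------------------------------------------------


def read_mgf(path: str | Path) -> dict[str, Spectrum]:
    """Read an MGF file into a dict keyed by TITLE."""
    spectra: dict[str, Spectrum] = {}
    title, pepmass, peaks = None, None, []
    in_block = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "BEGIN IONS":
            in_block, title, pepmass, peaks = True, None, None, []
        elif line == "END IONS":
            if title is None:
                title = f"spectrum_{len(spectra)}"
            spectra[title] = Spectrum(precursor_mz=float(pepmass), peaks=np.array(peaks))
            in_block = False
        elif in_block:
            if "=" in line:
                key, _, val = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = val.strip()
                elif key == "PEPMASS":
                    pepmass = float(val.split()[0])
            else:
                mz, inten = line.split()[:2]
                peaks.append((float(mz), float(inten)))
    return spectra


def write_mgf(spectra: dict[str, Spectrum], path: str | Path) -> None:
    lines: list[str] = []
    for title, sp in spectra.items():
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={title}")
        lines.append(f"PEPMASS={np.format_float_positional(sp.precursor_mz, unique=True)}")
        for mz, inten in sp.peaks:
            lines.append(
                f"{np.format_float_positional(mz, unique=True)} "
                f"{np.format_float_positional(inten, unique=True)}"
            )
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_msp(path: str | Path) -> dict[str, Spectrum]:
    """Read an MSP library file into a dict keyed by Name."""
    spectra: dict[str, Spectrum] = {}
    name, precursor, peaks, n_expected = None, None, [], None

    def flush():
        if name is not None and peaks:
            spectra[name] = Spectrum(precursor_mz=float(precursor), peaks=np.array(peaks))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            flush()
            name, precursor, peaks, n_expected = None, None, [], None
            continue
        low = line.lower()
        if low.startswith("name:"):
            flush()
            name, precursor, peaks, n_expected = line[5:].strip(), None, [], None
        elif low.startswith(("precursormz:", "precursor_mz:")):
            precursor = float(line.split(":", 1)[1])
        elif low.startswith("num peaks:"):
            n_expected = int(line.split(":", 1)[1])
        elif ":" not in line:
            parts = line.replace(";", " ").split()
            if len(parts) >= 2:
                peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return spectra
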