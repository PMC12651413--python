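"""Packaged reference marker matrix for tomato neuroactive compounds.

The package ships a curated table of 70 neuroactive compounds annotated
in tomato products (organic/conventional datterini, fresh plump,
processed), each with its neuroactivity class, chemical class, measured
precursor m/z, retention time, ion adduct, annotation confidence level
and three-state discriminant labels for the Organic, Variety and Process
contrasts.  The table is stored verbatim — including a handful of printed
oddities (two "Aspartame" isomer rows whose masses differ beyond any
single precursor, an (I)/(II) pair ordered against ascending RT, and two
rows sharing m/z and RT) — and guarded by a checksum so silent edits fail
loudly.

:func:`tally` provides the bookkeeping counts over the table; set-level
counts delegate to :mod:`tomarker.stats`.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from . import stats as _stats

_DATA_FILE = "tomato_neuroactive_markers.tsv"

# checksum of the shipped fixture; recorded at packaging time
_FIXTURE_SHA256 = "13661dc32e3cfdb3be70772ce18ad775f547e222322241082ee9db48205a2378"

LABEL_COLUMNS = ("organic", "variety", "process")
CONTRAST_OF_COLUMN = {"organic": "Organic", "variety": "Variety", "process": "Process"}


class ReferenceDataError(RuntimeError):
    pass


def _fixture_bytes() -> bytes:
    return (resources.files("tomarker") / "data" / _DATA_FILE).read_bytes()


def load_marker_reference(verify_checksum: bool = True) -> pd.DataFrame:
    """Load the packaged 70-compound marker table.

    Returns a DataFrame with columns neuroactivity, chem_class, compound,
    mz, rt, adduct, level, organic, variety, process.  Validates the
    record count, label alphabet and file checksum.
    """
    raw = _fixture_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ReferenceDataError(
                f"packaged marker table checksum mismatch: {digest} != {_FIXTURE_SHA256}"
            )
    import io as _io

    df = pd.read_csv(_io.BytesIO(raw), sep="\t")
    if len(df) != 70:
        raise ReferenceDataError(f"expected 70 records, found {len(df)}")
    for col in LABEL_COLUMNS:
        bad = set(df[col]) - {"+", "-", "="}
        if bad:
            raise ReferenceDataError(f"invalid labels in {col}: {bad}")
    if not df["compound"].is_unique:
        raise ReferenceDataError("compound names must be unique")
    return df


def marker_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Compound x contrast label matrix from the reference records."""
    matrix = records.set_index("compound")[list(LABEL_COLUMNS)].copy()
    matrix.columns = [CONTRAST_OF_COLUMN[c] for c in LABEL_COLUMNS]
    return matrix


def tally(records: pd.DataFrame, by: str) -> pd.Series | dict:
    """Deterministic counts over the reference records.

    ``by`` is one of:

    * ``level`` — annotation confidence levels;
    * ``neuroactivity`` — protective vs disrupting;
    * ``chem_class`` — chemical classes (optionally filter the records
      first, e.g. to protective compounds);
    * ``contrast_discriminant`` — discriminant-set size per contrast;
    * ``venn_region`` — the 7 Venn regions plus the non-discriminant
      remainder (both delegate to the set algebra in tomarker.stats).
    """
    if by == "level":
        return records["level"].value_counts().sort_index()
    if by == "neuroactivity":
        return records["neuroactivity"].value_counts().sort_index()
    if by == "chem_class":
        return records["chem_class"].value_counts().sort_index()
    if by in ("contrast_discriminant", "venn_region"):
        part = _stats.venn_partition(marker_matrix(records))
        if by == "contrast_discriminant":
            return pd.Series({k: len(v) for k, v in part.discriminant.items()})
        return {
            ("none" if not k else "&".join(sorted(k))): len(v)
            for k, v in part.regions.items()
        }
    raise KeyError(f"unknown tally key {by!r}")


def reference_summary() -> dict:
    """Every headline count of the reference table, as one dict."""
    rec = load_marker_reference()
    part = _stats.venn_partition(marker_matrix(rec))
    protective = rec[rec["neuroactivity"] == "protective"]
    return {
        "n_compounds": len(rec),
        "levels": tally(rec, "level").to_dict(),
        "neuroactivity": tally(rec, "neuroactivity").to_dict(),
        "protective_classes": tally(protective, "chem_class").to_dict(),
        "discriminant_sizes": {k: len(v) for k, v in part.discriminant.items()},
        "exclusive_sizes": {
            name: len(part.region(name)) for name in part.discriminant
        },
        "venn_regions": tally(rec, "venn_region"),
    }
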