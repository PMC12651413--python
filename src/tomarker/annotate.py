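"""Suspect-screening annotation with MSI-style confidence levels.

Features are matched against a curated suspect list in three layers of
evidence:

* precursor: theoretical adduct m/z ([M+H]+ or [M-H]-) within a ppm
  tolerance of the observed feature m/z;
* retention time: against the RT of an authentic standard, when one exists;
* MS/MS: greedy one-to-one fragment pairing within a Da tolerance, scored
  by cosine similarity on square-root-weighted intensities.

Confidence levels follow the Metabolomics Standards Initiative scheme:
L1 (confirmed: standard-backed m/z + RT + MS/MS), L2 (putatively
annotated: library MS/MS match), L3 (putatively characterized:
interpretable experimental MS/MS without a library match, flagged for
manual review).  A special case covers derivatives: when the MS/MS
pattern matches an authentic standard but the RT does not, the feature
is annotated "derivative of <standard>" at L3.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import FeatureTable, Spectrum

PROTON_MASS = 1.007276  # Da, proton mass adjusted for electron/charge

ADDUCTS = {"[M+H]+": ("pos", +PROTON_MASS), "[M-H]-": ("neg", -PROTON_MASS)}

LEVEL_ORDER = {"L1": 3, "L2": 2, "L3": 1, "none": 0}


class AnnotationError(ValueError):
    pass


@dataclasses.dataclass
class SuspectEntry:
    """One candidate compound in the suspect database."""

    name: str
    neuroactivity: str              # protective | disrupting
    chem_class: str
    neutral_mass: float | None = None   # monoisotopic, Da
    adduct_mzs: dict[str, float] | None = None  # explicit adduct m/z, overrides
    allowed_adducts: tuple[str, ...] = ("[M+H]+", "[M-H]-")
    standard_rt: float | None = None    # minutes, only with an authentic standard
    has_authentic_standard: bool = False
    library_spectrum: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass is None and not self.adduct_mzs:
            raise AnnotationError(f"suspect {self.name}: no neutral mass and no adduct m/z")
        if self.standard_rt is not None and not self.has_authentic_standard:
            raise AnnotationError(
                f"suspect {self.name}: standard_rt given without an authentic standard"
            )

    def theoretical_mz(self, adduct: str) -> float:
        if self.adduct_mzs and adduct in self.adduct_mzs:
            return self.adduct_mzs[adduct]
        return adduct_mz(self.neutral_mass, adduct)


@dataclasses.dataclass
class AnnotationResult:
    feature_id: str
    feature_rt: float
    suspect: str
    annotated_name: str             # suspect name, possibly "derivative of X" or "(I)" tagged
    adduct: str
    mass_error_ppm: float
    rt_error_min: float | None
    ms2_score: float | None
    n_shared_fragments: int
    level: str                      # L1 | L2 | L3 | none
    isomer_tag: str | None = None
    review_flag: bool = False       # L3 plausibility is a manual call


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical adduct m/z from a monoisotopic neutral mass."""
    if adduct not in ADDUCTS:
        raise AnnotationError(f"unsupported adduct {adduct!r}")
    if neutral_mass is None or neutral_mass <= 0:
        raise AnnotationError("neutral mass must be positive")
    mz = neutral_mass + ADDUCTS[adduct][1]
    if mz <= 0:
        raise AnnotationError(
            f"non-physical adduct m/z {mz} for neutral mass {neutral_mass}"
        )
    return mz


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in ppm, relative to the theoretical mass."""
    return (observed - theoretical) / theoretical * 1e6


def match_precursor(
    observed_mz: float,
    ion_mode: str,
    suspect: SuspectEntry,
    tol_ppm: float = 5.0,
):
    """Best adduct-level precursor match, or None.

    Only adducts of the feature's polarity are considered.  Returns
    ``(adduct, signed ppm error)`` for the smallest |error| within
    tolerance.
    """
    if tol_ppm <= 0:
        raise AnnotationError("tol_ppm must be positive")
    best = None
    for adduct in suspect.allowed_adducts:
        if ADDUCTS[adduct][0] != ion_mode:
            continue
        err = ppm_error(observed_mz, suspect.theoretical_mz(adduct))
        if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best[1])):
            best = (adduct, err)
    return best


def match_ms2(
    query: Spectrum,
    reference: Spectrum,
    frag_tol_da: float = 0.01,
    min_shared: int = 2,
    min_score: float = 0.6,
) -> tuple[float, int, bool]:
    """Greedy one-to-one fragment pairing and cosine score.

    Peak pairs within ``frag_tol_da`` are matched greedily by smallest m/z
    difference, each peak used at most once.  The score is the cosine
    similarity of square-root-weighted intensities over the full peak
    lists (unmatched peaks contribute only to the norms).  Agreement
    requires ``score >= min_score`` and ``n_shared >= min_shared``.

    Returns (score, n_shared, agreement).
    """
    qi = np.sqrt(query.intensity)
    ri = np.sqrt(reference.intensity)
    # candidate pairs within tolerance, closest-first
    pairs = [
        (abs(qmz - rmz), iq, ir)
        for iq, qmz in enumerate(query.mz)
        for ir, rmz in enumerate(reference.mz)
        if abs(qmz - rmz) <= frag_tol_da
    ]
    pairs.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    dot = 0.0
    for _, iq, ir in pairs:
        if iq in used_q or ir in used_r:
            continue
        used_q.add(iq)
        used_r.add(ir)
        dot += qi[iq] * ri[ir]
    norm = float(np.linalg.norm(qi) * np.linalg.norm(ri))
    score = dot / norm if norm > 0 else 0.0
    n_shared = len(used_q)
    # 1e-12 guard so an exact-boundary score (e.g. 3/5 vs 0.6) is not lost
    # to floating-point rounding
    agree = (score >= min_score - 1e-12) and n_shared >= min_shared
    return score, n_shared, agree


def assign_level(
    feature_id: str,
    feature_rt: float,
    suspect: SuspectEntry,
    adduct: str,
    mass_error: float,
    query_spectrum: Spectrum | None,
    rt_tol_min: float = 0.2,
    frag_tol_da: float = 0.01,
    min_shared: int = 2,
    min_score: float = 0.6,
) -> AnnotationResult:
    """Confidence level from the available evidence for one precursor match.

    * L1: authentic standard, |RT error| <= rt_tol_min, MS/MS agreement.
    * derivative special case: standard MS/MS agreement but RT outside
      tolerance -> L3, renamed "derivative of <suspect>".
    * L2: MS/MS agreement against a library spectrum (no RT required).
    * L3: experimental MS/MS present, precursor match, no spectral match
      (manual-plausibility review flag set).
    * none: precursor match only, no interpretable MS/MS.
    """
    rt_error = (
        feature_rt - suspect.standard_rt if suspect.standard_rt is not None else None
    )
    score: float | None = None
    n_shared = 0
    agree = False
    if query_spectrum is not None and suspect.library_spectrum is not None:
        score, n_shared, agree = match_ms2(
            query_spectrum, suspect.library_spectrum,
            frag_tol_da=frag_tol_da, min_shared=min_shared, min_score=min_score,
        )

    name = suspect.name
    review = False
    if suspect.has_authentic_standard and agree:
        if rt_error is not None and abs(rt_error) <= rt_tol_min:
            level = "L1"
        else:
            level = "L3"  # same fragmentation, shifted RT: a structural derivative
            name = f"derivative of {suspect.name}"
            review = True
    elif agree:
        level = "L2"
    elif query_spectrum is not None:
        level = "L3"
        review = True
    else:
        level = "none"

    return AnnotationResult(
        feature_id=feature_id,
        feature_rt=feature_rt,
        suspect=suspect.name,
        annotated_name=name,
        adduct=adduct,
        mass_error_ppm=mass_error,
        rt_error_min=rt_error,
        ms2_score=score,
        n_shared_fragments=n_shared,
        level=level,
        review_flag=review,
    )


def annotate_features(
    table: FeatureTable,
    suspects: list[SuspectEntry],
    spectra: dict[str, Spectrum] | None = None,
    tol_ppm: float = 5.0,
    rt_tol_min: float = 0.2,
    frag_tol_da: float = 0.01,
    min_shared: int = 2,
    min_score: float = 0.6,
    rt_isomer_window_min: float = 0.5,
) -> list[AnnotationResult]:
    """Screen every feature against every suspect; keep the best per pair.

    "Best" means highest confidence level, then smallest |ppm error|, then
    smallest |RT error| — a deterministic ordering.  Results at level
    ``none`` (precursor-only hits without MS/MS) are retained so the
    caller can inspect them, and isomer tags are assigned afterwards.
    """
    spectra = spectra or {}
    results: list[AnnotationResult] = []
    for fid in table.features.index:
        fmz = float(table.features.loc[fid, "mz"])
        frt = float(table.features.loc[fid, "rt"])
        mode = table.features.loc[fid, "ion_mode"]
        query = spectra.get(fid)
        for suspect in suspects:
            hit = match_precursor(fmz, mode, suspect, tol_ppm=tol_ppm)
            if hit is None:
                continue
            adduct, err = hit
            results.append(
                assign_level(
                    fid, frt, suspect, adduct, err, query,
                    rt_tol_min=rt_tol_min, frag_tol_da=frag_tol_da,
                    min_shared=min_shared, min_score=min_score,
                )
            )
    results = enumerate_isomers(results, rt_window_min=rt_isomer_window_min)
    return results


def enumerate_isomers(
    annotations: list[AnnotationResult], rt_window_min: float = 0.5
) -> list[AnnotationResult]:
    """Tag same-suspect annotations at distinct nearby-RT features (I), (II), ...

    Two annotations are isomer candidates when they name the same suspect
    via the same adduct (hence compatible precursor), both carry MS/MS
    evidence of the same kind, sit on different features, and their RTs
    chain within ``rt_window_min`` of a neighbour.  Suffixes are assigned
    in ascending retention time.
    """
    by_key: dict[tuple, list[AnnotationResult]] = {}
    for ann in annotations:
        by_key.setdefault((ann.suspect, ann.adduct, ann.annotated_name), []).append(ann)

    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    for group in by_key.values():
        with_ms2 = [a for a in group if a.level in ("L1", "L2", "L3")]
        if len(with_ms2) < 2 or len({a.feature_id for a in with_ms2}) < 2:
            continue
        with_ms2.sort(key=lambda a: a.feature_rt)
        # require each member to be within the window of its predecessor
        chain = [with_ms2[0]]
        for a in with_ms2[1:]:
            if a.feature_rt - chain[-1].feature_rt <= rt_window_min:
                chain.append(a)
        if len(chain) < 2:
            continue
        for k, ann in enumerate(chain):
            ann.isomer_tag = roman[k] if k < len(roman) else str(k + 1)
            ann.annotated_name = f"{ann.annotated_name} ({ann.isomer_tag})"
    return annotations


def annotations_to_frame(annotations: list[AnnotationResult]) -> pd.DataFrame:
    """Flatten results to a DataFrame for delimited-text output."""
    return pd.DataFrame([dataclasses.asdict(a) for a in annotations])


def best_per_feature(annotations: list[AnnotationResult]) -> list[AnnotationResult]:
    """Deterministic best annotation per (feature, suspect) pair."""
    best: dict[tuple[str, str], AnnotationResult] = {}
    for ann in annotations:
        key = (ann.feature_id, ann.suspect)
        cur = best.get(key)
        rank = (
            LEVEL_ORDER[ann.level],
            -abs(ann.mass_error_ppm),
            -abs(ann.rt_error_min) if ann.rt_error_min is not None else 0.0,
        )
        cur_rank = None if cur is None else (
            LEVEL_ORDER[cur.level],
            -abs(cur.mass_error_ppm),
            -abs(cur.rt_error_min) if cur.rt_error_min is not None else 0.0,
        )
        if cur is None or rank > cur_rank:
            best[key] = ann
    return list(best.values())
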