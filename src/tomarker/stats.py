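"""Discriminant-compound classification and marker-set combinatorics.

A compound discriminates two tomato groups when the standardized mean
difference is large AND statistically significant on log10 intensities:

    |Cohen's d| > 1   and   p < 0.05  (two-sided Student t-test)

with d = (mean_a - mean_b) / s_pooled and the pooled SD using n-1
variances.  Direction is encoded three-state: "+" (higher in the first
group of the contrast), "-" (lower), "=" (non-discriminant).

The three fixed contrasts are Organic = DO vs D, Variety = D vs PF,
Process = PS vs PF; "+" therefore means higher in organic datterini,
in datterini, or in processed tomatoes respectively.

The marker matrix (compounds x contrasts) feeds a three-set Venn
partition and a three-color tile heatmap.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable

logger = logging.getLogger(__name__)

#: contrast name -> (group_a, group_b); d > 0 / "+" means higher in group_a
CONTRASTS: dict[str, tuple[str, str]] = {
    "Organic": ("DO", "D"),
    "Variety": ("D", "PF"),
    "Process": ("PS", "PF"),
}

LABELS = ("+", "-", "=")


class StatsError(ValueError):
    pass


def _check_groups(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    return a, b


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    return math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )


def cohens_d(a, b, hedges: bool = False) -> float:
    """Standardized mean difference (a minus b), pooled-SD convention.

    Zero pooled SD: returns 0 for equal means, signed infinity otherwise.
    ``hedges=True`` applies the small-sample correction factor
    1 - 3/(4(n_a+n_b)-9) (off by default; the classic pooled-SD d is the
    reported statistic).
    """
    a, b = _check_groups(a, b)
    diff = a.mean() - b.mean()
    s = pooled_sd(a, b)
    if s == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    d = diff / s
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (a.size + b.size) - 9.0)
    return d


def independent_t_test(a, b, welch: bool = False) -> float:
    """Two-sided independent t-test p-value (pooled-variance Student by default).

    Implemented from the closed form (t statistic and the t survival
    function) so library routines can serve as an independent cross-check.
    Degenerate zero-variance input: p = 1 for equal means, p = 0 otherwise.
    """
    a, b = _check_groups(a, b)
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            return 1.0 if diff == 0.0 else 0.0
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = diff / math.sqrt(se2)
    else:
        s = pooled_sd(a, b)
        if s == 0.0:
            return 1.0 if diff == 0.0 else 0.0
        df = na + nb - 2
        t = diff / (s * math.sqrt(1.0 / na + 1.0 / nb))
    return 2.0 * sps.t.sf(abs(t), df)


def label_from(d: float, p: float, d_threshold: float = 1.0, alpha: float = 0.05) -> str:
    """Three-state label from effect size and p-value (strict inequalities)."""
    if p < alpha and d > d_threshold:
        return "+"
    if p < alpha and d < -d_threshold:
        return "-"
    return "="


def classify_contrast(
    table: FeatureTable,
    contrast: str,
    d_threshold: float = 1.0,
    alpha: float = 0.05,
    hedges: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-feature effect size, p-value and three-state label for one contrast.

    The table must be preprocessed (imputed; no missing cells) and on the
    log10 scale.  Returns a DataFrame indexed by feature id with columns
    ``d``, ``p``, ``p_bh`` (Benjamini-Hochberg adjusted, informational
    only — it never alters labels), ``label``, ``n_a``, ``n_b``.
    """
    if contrast not in CONTRASTS:
        raise StatsError(f"unknown contrast {contrast!r}; expected one of {list(CONTRASTS)}")
    if table.scale != "log10":
        raise StatsError("statistics are computed on the log10 scale; call to_log10 first")
    if table.missing.to_numpy().any():
        raise StatsError("table contains missing values; impute before classification")

    ga, gb = CONTRASTS[contrast]
    ids_a = table.injection_ids(sample_type="sample", group=ga)
    ids_b = table.injection_ids(sample_type="sample", group=gb)
    if len(ids_a) == 0 or len(ids_b) == 0:
        missing = [g for g, ids in ((ga, ids_a), (gb, ids_b)) if len(ids) == 0]
        raise StatsError(f"contrast {contrast}: group(s) {missing} absent from table")

    A = table.values[ids_a].to_numpy()
    B = table.values[ids_b].to_numpy()
    rows = []
    for i, fid in enumerate(table.features.index):
        d = cohens_d(A[i], B[i], hedges=hedges)
        p = independent_t_test(A[i], B[i], welch=welch)
        rows.append((fid, d, p, label_from(d, p, d_threshold, alpha), A.shape[1], B.shape[1]))
    res = pd.DataFrame(rows, columns=["feature", "d", "p", "label", "n_a", "n_b"])
    res = res.set_index("feature")
    res.insert(2, "p_bh", multipletests(res["p"].to_numpy(), method="fdr_bh")[1])
    return res


def build_marker_matrix(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble per-contrast classification results into a label matrix.

    *results* maps contrast name -> classify_contrast output; all three
    contrasts must cover the same feature set.
    """
    names = list(results)
    base = results[names[0]].index
    for name in names[1:]:
        if set(results[name].index) != set(base):
            extra = set(results[name].index) ^ set(base)
            raise StatsError(
                f"contrast {name} covers a different feature set; symmetric difference: {sorted(extra)}"
            )
    matrix = pd.DataFrame(index=base)
    for name in names:
        matrix[name] = results[name]["label"].reindex(base)
    return matrix


@dataclasses.dataclass
class VennPartition:
    """Disjoint decomposition of the three discriminant sets.

    ``discriminant`` maps contrast -> set of row ids with label != "=".
    ``regions`` maps a frozenset of contrast names (the exact membership
    combination) -> set of row ids; the empty frozenset holds the
    non-discriminant remainder.
    """

    discriminant: dict[str, set]
    regions: dict[frozenset, set]

    def region(self, *names: str) -> set:
        return self.regions[frozenset(names)]

    def sizes(self) -> dict[str, int]:
        out = {f"{name}_total": len(s) for name, s in self.discriminant.items()}
        for combo, members in self.regions.items():
            key = "none" if not combo else "&".join(sorted(combo))
            out[key] = len(members)
        return out


def venn_partition(matrix: pd.DataFrame) -> VennPartition:
    """Set algebra over the marker matrix: 7 Venn regions + remainder."""
    contrasts = list(matrix.columns)
    disc = {c: set(matrix.index[matrix[c] != "="]) for c in contrasts}
    universe = set(matrix.index)
    regions: dict[frozenset, set] = {}
    for r in range(len(contrasts) + 1):
        for combo in itertools.combinations(contrasts, r):
            inside = set.intersection(*(disc[c] for c in combo)) if combo else universe
            outside = set.union(*(disc[c] for c in set(contrasts) - set(combo)), set())
            regions[frozenset(combo)] = inside - outside
    return VennPartition(discriminant=disc, regions=regions)


_TILE_COLORS = {"+": "#c0392b", "-": "#27ae60", "=": "#bdbdbd"}  # red / green / grey


def render_heatmap(
    matrix: pd.DataFrame,
    class_grouping: dict[str, str] | None = None,
    path: str | None = None,
):
    """Three-color tile plot of the marker matrix, rows grouped by class.

    "+" is a red tile (higher abundance in the contrast's first group),
    "-" green (lower), "=" grey (non-discriminant).  Compounds absent from
    *class_grouping* go to an "unclassified" block with a logged notice.

    Returns ``(figure, encoded)`` where *encoded* is the row-ordered label
    table actually drawn (also written next to *path* as ``.tsv`` when a
    path is given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    if class_grouping is None:
        class_grouping = {}
    order_key = {}
    for rid in matrix.index:
        cls = class_grouping.get(rid)
        if cls is None:
            if class_grouping:
                logger.info("compound %s missing from class map; placed in 'unclassified'", rid)
            cls = "unclassified"
        order_key[rid] = cls
    encoded = matrix.copy()
    encoded.insert(0, "class", [order_key[r] for r in matrix.index])
    encoded = encoded.sort_values("class", kind="stable")

    n_rows, n_cols = len(encoded), len(matrix.columns)
    fig, ax = plt.subplots(figsize=(4 + 0.5 * n_cols, max(2.0, 0.22 * n_rows)))
    for y, (rid, row) in enumerate(encoded.iterrows()):
        for x, col in enumerate(matrix.columns):
            ax.add_patch(plt.Rectangle((x, n_rows - 1 - y), 1, 1,
                                       facecolor=_TILE_COLORS[row[col]],
                                       edgecolor="white"))
    ax.set_xlim(0, n_cols)
    ax.set_ylim(0, n_rows)
    ax.set_xticks(np.arange(n_cols) + 0.5, matrix.columns)
    ax.set_yticks(np.arange(n_rows) + 0.5, list(encoded.index[::-1]), fontsize=6)
    ax.legend(handles=[Patch(color=c, label=s) for s, c in _TILE_COLORS.items()],
              loc="upper left", bbox_to_anchor=(1.01, 1.0))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        encoded.to_csv(str(path).rsplit(".", 1)[0] + ".tsv", sep="\t")
    return fig, encoded
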