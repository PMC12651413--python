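import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tomarker.io import to_log10
from tomarker.reference import load_marker_reference, marker_matrix
from tomarker.stats import (
    CONTRASTS,
    StatsError,
    build_marker_matrix,
    classify_contrast,
    cohens_d,
    independent_t_test,
    label_from,
    render_heatmap,
    venn_partition,
)

from conftest import make_table


def brute_force_d(a, b):
    """Textbook pooled-SD formula, written independently of the library."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (ma - mb) / sp


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed(self):
        """Means 2 and 5 with pooled SD 1 give d = -3."""
        assert cohens_d([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.0, abs=1e-12)

    def test_zero_variance_equal_means(self):
        assert cohens_d([5, 5, 5], [5, 5, 5]) == 0.0

    def test_zero_variance_unequal_means_is_signed_infinity(self):
        assert cohens_d([1, 1], [0, 0]) == math.inf
        assert cohens_d([0, 0], [1, 1]) == -math.inf

    def test_too_small_group_rejected(self):
        with pytest.raises(StatsError):
            cohens_d([1.0], [1.0, 2.0])

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            na, nb = rng.integers(2, 9, size=2)
            a = rng.normal(0, 1 + rng.random(), na).tolist()
            b = rng.normal(rng.normal(), 1, nb).tolist()
            assert cohens_d(a, b) == pytest.approx(brute_force_d(a, b), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=10),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=10),
    )
    def test_antisymmetry(self, a, b):
        """Swapping the groups negates d and preserves the p-value."""
        d_ab, d_ba = cohens_d(a, b), cohens_d(b, a)
        assert d_ab == -d_ba or (math.isinf(d_ab) and math.isinf(d_ba))
        assert independent_t_test(a, b) == pytest.approx(
            independent_t_test(b, a), abs=1e-14
        )


class TestTTest:
    def test_frozen_example(self):
        """[1,2,3] vs [4,5,6]: t = -3.6742, df = 4, p = 0.0213116."""
        p = independent_t_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.021311641128756713, abs=1e-12)

    def test_identical_groups_p_one(self):
        assert independent_t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_zero_variance(self):
        assert independent_t_test([0, 0, 0, 0], [1, 1, 1, 1]) == 0.0
        assert independent_t_test([1, 1], [1, 1]) == 1.0

    def test_matches_scipy_on_random_inputs(self):
        """Dual route: closed-form implementation vs scipy.stats.ttest_ind."""
        rng = np.random.default_rng(1)
        for _ in range(500):
            na, nb = rng.integers(2, 9, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(0.5, 2, nb)
            assert independent_t_test(a, b) == pytest.approx(
                sps.ttest_ind(a, b, equal_var=True).pvalue, abs=1e-10
            )
            assert independent_t_test(a, b, welch=True) == pytest.approx(
                sps.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-10
            )


class TestLabelRule:
    @pytest.mark.parametrize(
        "d,p,expected",
        [
            (2.3, 0.01, "+"),
            (1.8, 0.07, "="),   # significant effect size but p fails
            (-1.5, 0.04, "-"),
            (1.0, 0.01, "="),   # strict inequality at d = 1
            (2.0, 0.05, "="),   # strict inequality at alpha
            (0.5, 0.001, "="),
        ],
    )
    def test_three_state_rule(self, d, p, expected):
        assert label_from(d, p) == expected

    def test_classify_contrast_end_to_end(self, four_group_table):
        log = to_log10(four_group_table)
        res = classify_contrast(log, "Organic")
        assert res.loc["F0", "label"] == "+"   # DO tenfold above D
        assert res.loc["F1", "label"] == "="
        assert res.loc["F0", "n_a"] == 3 and res.loc["F0", "n_b"] == 3

    def test_requires_log_scale_and_groups(self, four_group_table):
        with pytest.raises(StatsError, match="log10"):
            classify_contrast(four_group_table, "Organic")
        log = to_log10(four_group_table)
        with pytest.raises(StatsError, match="unknown contrast"):
            classify_contrast(log, "Ripeness")
        do_only = make_table([[1.0, 2.0]], groups=["DO", "DO"])
        with pytest.raises(StatsError, match="absent"):
            classify_contrast(to_log10(do_only), "Process")

    def test_monotone_in_thresholds(self, small_sim):
        """Raising the d threshold or lowering alpha never grows the
        discriminant set."""
        from tomarker.preprocess import drop_undetected, impute_missing

        _, table, _ = small_sim
        log = to_log10(impute_missing(drop_undetected(table), seed=0))
        base = classify_contrast(log, "Process")
        n_base = (base["label"] != "=").sum()
        for d_thr, alpha in [(1.5, 0.05), (1.0, 0.01), (2.0, 0.001)]:
            res = classify_contrast(log, "Process", d_threshold=d_thr, alpha=alpha)
            assert (res["label"] != "=").sum() <= n_base


class TestMarkerMatrix:
    def test_reference_rows(self):
        """The packaged matrix reproduces the published per-compound labels."""
        matrix = marker_matrix(load_marker_reference())
        assert tuple(matrix.loc["Serotonin"]) == ("=", "+", "-")
        assert tuple(matrix.loc["Pantothenic Acid"]) == ("+", "=", "=")

    def test_all_equal_inputs(self):
        frames = {
            c: pd.DataFrame({"label": ["="] * 3}, index=["a", "b", "c"])
            for c in CONTRASTS
        }
        matrix = build_marker_matrix(frames)
        assert (matrix.to_numpy() == "=").all()

    def test_inconsistent_feature_sets_rejected(self):
        frames = {
            "Organic": pd.DataFrame({"label": ["+"]}, index=["a"]),
            "Variety": pd.DataFrame({"label": ["-"]}, index=["b"]),
            "Process": pd.DataFrame({"label": ["="]}, index=["a"]),
        }
        with pytest.raises(StatsError, match="different feature set"):
            build_marker_matrix(frames)


class TestVennPartition:
    def test_empty_matrix(self):
        matrix = pd.DataFrame(columns=list(CONTRASTS))
        part = venn_partition(matrix)
        assert all(len(v) == 0 for v in part.regions.values())

    def test_regions_are_disjoint_and_cover(self, small_sim):
        from tomarker.preprocess import drop_undetected, impute_missing

        _, table, _ = small_sim
        log = to_log10(impute_missing(drop_undetected(table), seed=0))
        matrix = build_marker_matrix(
            {c: classify_contrast(log, c) for c in CONTRASTS}
        )
        part = venn_partition(matrix)
        regions = list(part.regions.values())
        assert sum(len(r) for r in regions) == len(matrix)
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1:]:
                assert not (r1 & r2)
        for name, disc in part.discriminant.items():
            covering = set().union(
                *(r for k, r in part.regions.items() if name in k)
            )
            assert covering == disc


class TestHeatmap:
    def test_encoded_counts_match_matrix(self, tmp_path):
        matrix = marker_matrix(load_marker_reference())
        classes = dict(
            zip(load_marker_reference()["compound"], load_marker_reference()["chem_class"])
        )
        fig, encoded = render_heatmap(
            matrix, class_grouping=classes, path=str(tmp_path / "h.png")
        )
        assert encoded.shape == (70, 4)  # class column + 3 contrasts
        for symbol in ("+", "-", "="):
            assert (
                (encoded[list(CONTRASTS)] == symbol).sum().sum()
                == (matrix == symbol).sum().sum()
            )
        assert (tmp_path / "h.png").exists() and (tmp_path / "h.tsv").exists()
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_single_row(self):
        matrix = pd.DataFrame(
            [["+", "-", "="]], columns=list(CONTRASTS), index=["only"]
        )
        fig, encoded = render_heatmap(matrix)
        assert len(encoded) == 1
        import matplotlib.pyplot as plt

        plt.close(fig)
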