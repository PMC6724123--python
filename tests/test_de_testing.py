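import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldcascade.io_formats import (
    NINE_CONTRASTS,
    AnnotationBundle,
    CountMatrix,
    SampleDesign,
)
from coldcascade.synthetic_data import SimulationConfig, simulate_counts
from coldcascade.de_testing import testable_flags as compute_testable_flags
from coldcascade.de_testing import (
    NormalizedMatrix,
    annotation_filter,
    bh_adjust,
    deg_selection,
    estimate_dispersions,
    filter_report,
    low_count_filter,
    nb_contrast_test,
    normalize,
    size_factors,
)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH computed literally from its definition (the oracle)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(1.0, p[idx] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, design):
        frame = pd.DataFrame(
            np.tile([[10], [20], [30]], (1, 24)),
            index=["a", "b", "c"],
            columns=design.sample_ids,
        )
        factors = size_factors(CountMatrix(frame))
        np.testing.assert_allclose(factors.to_numpy(), 1.0)

    def test_hand_computed_two_by_two(self):
        """[[10, 20], [30, 60]]: geometric means (sqrt200, sqrt1800); the
        per-sample ratio medians are 1/sqrt2 and sqrt2."""
        frame = pd.DataFrame([[10, 20], [30, 60]], index=["a", "b"], columns=["s1", "s2"])
        factors = size_factors(CountMatrix(frame))
        np.testing.assert_allclose(
            factors.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_scaled_columns_recover_scaling(self, design):
        """Columns = scaled copies of one column recover the constants up to
        a common multiplier."""
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=50) + 1
        scale = rng.uniform(0.5, 2.0, size=24)
        frame = pd.DataFrame(
            np.rint(np.outer(base, scale)).astype(int),
            index=[f"g{i}" for i in range(50)],
            columns=design.sample_ids,
        )
        factors = size_factors(CountMatrix(frame)).to_numpy()
        ratio = factors / scale
        assert ratio.std() / ratio.mean() < 0.02

    def test_all_zero_genes_error(self):
        frame = pd.DataFrame(
            [[0, 5], [3, 0]], index=["a", "b"], columns=["s1", "s2"]
        )
        with pytest.raises(ValueError, match="median-of-ratios"):
            size_factors(frame_matrix(frame), zero_tolerant_fraction=0.0)


def frame_matrix(frame: pd.DataFrame) -> CountMatrix:
    return CountMatrix(frame)


class TestFlags:
    def test_testability_boundaries(self, design):
        frame = pd.DataFrame(
            0, index=["zero", "one", "two"], columns=design.sample_ids
        )
        frame.iloc[1, 0] = 5
        frame.iloc[2, [0, 5]] = 5
        flags = compute_testable_flags(CountMatrix(frame))
        assert not flags["zero"]
        assert not flags["one"]
        assert flags["two"]

    def test_low_count_filter_boundary(self, design):
        sf = pd.Series(1.0, index=design.sample_ids)
        frame = pd.DataFrame(
            [[2.0] * 24, [2.0] * 24, [0.0] * 24],
            index=["at48", "above", "zero"],
            columns=design.sample_ids,
        )
        frame.loc["above"] += 0.5 / 24
        norm = NormalizedMatrix(frame, sf)
        flags = low_count_filter(norm, threshold=48)
        assert not flags["at48"]  # total exactly 48 is discarded
        assert flags["above"]  # 48.5 is kept
        assert not flags["zero"]


class TestNbContrastTest:
    def test_exact_null_gives_p_one(self, design):
        frame = pd.DataFrame(10, index=["g"], columns=design.sample_ids)
        counts = CountMatrix(frame)
        norm = NormalizedMatrix(
            frame.astype(float), pd.Series(1.0, index=design.sample_ids)
        )
        disp = pd.Series([0.05], index=["g"])
        res = nb_contrast_test(counts, design, ("ChNT0", "TeNT0"), norm, disp)
        assert res.loc["g", "p_raw"] == 1.0
        assert res.loc["g", "log2_fold_change"] == 0.0

    def test_zero_in_both_groups_untestable(self, design):
        frame = pd.DataFrame(10, index=["g"], columns=design.sample_ids)
        cond = design.condition_labels()
        for c in ("ChNT0", "TeNT0"):
            frame.loc["g", cond.index[cond == c]] = 0
        counts = CountMatrix(frame)
        norm = NormalizedMatrix(
            frame.astype(float), pd.Series(1.0, index=design.sample_ids)
        )
        disp = pd.Series([0.05], index=["g"])
        res = nb_contrast_test(counts, design, ("ChNT0", "TeNT0"), norm, disp)
        assert res.loc["g", "p_raw"] == 1.0
        assert res.loc["g", "log2_fold_change"] == 0.0

    def test_type_i_calibration_on_null_genes(self, design):
        """Raw p <= 0.05 fraction within [0.03, 0.07] under the null."""
        cfg = SimulationConfig(n_genes_per_archetype={"NULL": 5000}, seed=21)
        counts, _ = simulate_counts(cfg, design)
        norm = normalize(counts)
        disp = estimate_dispersions(norm, design)
        res = nb_contrast_test(counts, design, ("ChLT0", "ChLT2"), norm, disp)
        frac = (res["p_raw"] <= 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_eight_fold_difference(self, design):
        """An 8-fold mean shift at dispersion 0.01 is detected (p <= 0.02)
        in >= 90% of genes even with 2 vs 2 samples."""
        rng = np.random.default_rng(22)
        n_genes = 500
        cond = design.condition_labels()
        mu = pd.DataFrame(100.0, index=range(n_genes), columns=design.sample_ids)
        mu.loc[:, cond.index[cond == "ChLT2"]] = 800.0
        n_param = 1 / 0.01
        frame = pd.DataFrame(
            rng.negative_binomial(n_param, n_param / (n_param + mu.to_numpy())),
            index=[f"g{i}" for i in range(n_genes)],
            columns=design.sample_ids,
        )
        counts = CountMatrix(frame)
        norm = NormalizedMatrix(
            frame.astype(float), pd.Series(1.0, index=design.sample_ids)
        )
        disp = pd.Series(0.01, index=frame.index)
        res = nb_contrast_test(counts, design, ("ChLT0", "ChLT2"), norm, disp)
        assert (res["p_raw"] <= 0.02).mean() >= 0.90

    def test_null_p_values_uniform_on_permutation_free_null(self, design):
        """Kolmogorov-Smirnov check of p-value uniformity at 2000 genes."""
        from scipy import stats

        cfg = SimulationConfig(n_genes_per_archetype={"NULL": 2000}, seed=23)
        counts, _ = simulate_counts(cfg, design)
        norm = normalize(counts)
        disp = estimate_dispersions(norm, design)
        res = nb_contrast_test(counts, design, ("TeNT0", "TeNT2"), norm, disp)
        assert stats.kstest(res["p_raw"], "uniform").pvalue > 0.001


class TestBhAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_four_rank_example(self):
        result = bh_adjust(np.array([0.01, 0.04, 0.03, 0.02]))
        np.testing.assert_allclose(result, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(30)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_adjusted_at_least_raw(self, values):
        p = np.array(values)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestSelectionFilters:
    def _contrast_frame(self, p_by_gene):
        rows = []
        for gene, ps in p_by_gene.items():
            for i, p in enumerate(ps):
                rows.append(
                    {"gene_id": gene, "contrast": f"c{i}", "p_adj": p,
                     "p_raw": p, "log2_fold_change": 0.0}
                )
        return pd.DataFrame(rows)

    def test_deg_selection_boundaries(self):
        table = self._contrast_frame(
            {
                "at_alpha": [0.02] + [1.0] * 8,
                "below": [0.019] + [1.0] * 8,
                "none": [1.0] * 9,
            }
        )
        flags = deg_selection(table, alpha=0.02)
        assert flags["at_alpha"]  # adjusted p = 0.02 exactly is retained
        assert flags["below"]
        assert not flags["none"]

    def test_deg_selection_monotone_in_alpha(self):
        rng = np.random.default_rng(31)
        table = self._contrast_frame(
            {f"g{i}": rng.uniform(size=9) for i in range(50)}
        )
        low = deg_selection(table, alpha=0.01)
        high = deg_selection(table, alpha=0.10)
        assert (high | ~low).all()  # raising alpha can only add genes

    def test_annotation_filter_boundaries(self):
        bundle = AnnotationBundle(
            best_hit={
                "at": ("s", 9e-4),
                "above": ("s", 1e-3),
            }
        )
        flags = annotation_filter(["at", "above", "nohit"], bundle)
        assert flags["at"]  # E = 9e-4 exactly passes
        assert not flags["above"]
        assert not flags["nohit"]


class TestFilterReport:
    def test_flag_implications_hold(self, design):
        cfg = SimulationConfig(
            n_genes_per_archetype={"NULL": 150, "TCR_UP": 50}, seed=33
        )
        counts, truth = simulate_counts(cfg, design)
        # plant some unfilterable genes
        frame = counts.values.copy()
        frame.iloc[0] = 0
        frame.iloc[1] = 0
        frame.iloc[1, 0] = 1
        report, contrasts, _ = filter_report(CountMatrix(frame), design)
        assert not report["testable"].iloc[0]
        assert not report["testable"].iloc[1]
        # passed_deg_filter implies passed_count_filter implies testable
        assert (~report["passed_deg_filter"] | report["passed_count_filter"]).all()
        assert (~report["passed_count_filter"] | report["testable"]).all()
        assert set(contrasts["contrast"].unique()) == {
            f"{a}:{b}" for a, b in NINE_CONTRASTS
        }
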