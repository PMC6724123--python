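import numpy as np
import pandas as pd
import pytest

from coldcascade.io_formats import CONDITION_ORDER, SampleDesign
from coldcascade.de_testing import NormalizedMatrix
from coldcascade.pattern_clustering import (
    PatternTieError,
    assign_subsets,
    condition_means,
    hcl_average_pearson,
    pattern_label,
    pearson_distance_matrix,
    standardize,
)


def brute_force_upgma(dist: np.ndarray) -> np.ndarray:
    """Exhaustive average-linkage agglomeration recomputing every
    cross-pair mean distance at each step (the oracle)."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [dist[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(
        [[a, b, d, size] for a, b, d, size in merges], dtype=float
    )


def make_norm(frame: pd.DataFrame, design: SampleDesign) -> NormalizedMatrix:
    return NormalizedMatrix(frame, pd.Series(1.0, index=design.sample_ids))


class TestConditionMeans:
    def test_replicate_means_and_column_order(self, design):
        cond = design.condition_labels()
        frame = pd.DataFrame(
            np.zeros((1, 24)), index=["g"], columns=design.sample_ids
        )
        samples = cond.index[cond == "ChLT1"]
        frame.loc["g", samples[0]] = 3.0  # log2(3+1)=2
        frame.loc["g", samples[1]] = 15.0  # log2(15+1)=4
        means = condition_means(make_norm(frame, design), design)
        assert list(means.columns) == list(CONDITION_ORDER)
        assert means.loc["g", "ChLT1"] == pytest.approx(3.0)  # mean of 2 and 4
        assert means.loc["g", "ChNT0"] == 0.0

    def test_identical_replicates_pass_through(self, design):
        rng = np.random.default_rng(50)
        cond = design.condition_labels()
        frame = pd.DataFrame(
            np.zeros((5, 24)), index=[f"g{i}" for i in range(5)],
            columns=design.sample_ids,
        )
        per_cond = rng.uniform(1, 100, size=(5, 12))
        for j, c in enumerate(CONDITION_ORDER):
            frame.loc[:, cond.index[cond == c]] = per_cond[:, [j, j]]
        means = condition_means(make_norm(frame, design), design)
        np.testing.assert_allclose(means.to_numpy(), np.log2(per_cond + 1))


class TestStandardize:
    def test_zero_mean_unit_variance(self):
        profiles = pd.DataFrame([np.arange(12.0)], index=["g"])
        out, constant = standardize(profiles)
        assert out.loc["g"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.loc["g"].std(ddof=0) == pytest.approx(1.0)
        assert not constant["g"]

    def test_constant_profile_flagged(self):
        profiles = pd.DataFrame([[2.0] * 12], index=["g"])
        out, constant = standardize(profiles)
        assert constant["g"]
        assert (out.loc["g"] == 0.0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(51)
        profiles = pd.DataFrame(rng.normal(size=(4, 12)))
        once, _ = standardize(profiles)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


class TestHclAveragePearson:
    def test_two_blocks_of_identical_profiles_recovered(self):
        up = np.linspace(-1, 1, 12)
        down = -up
        profiles = pd.DataFrame(
            [up] * 5 + [down] * 5, index=[f"g{i}" for i in range(10)]
        )
        ids, _ = hcl_average_pearson(profiles, k=2)
        assert set(ids.iloc[:5]) == {1}
        assert set(ids.iloc[5:]) == {2}

    def test_matches_brute_force_oracle_on_five_gene_toys(self):
        """Merge heights and memberships equal the exhaustive UPGMA oracle
        on a fixture set of random 5-gene profile sets."""
        rng = np.random.default_rng(52)
        for _ in range(20):
            profiles = pd.DataFrame(
                rng.normal(size=(5, 12)), index=[f"g{i}" for i in range(5)]
            )
            condensed = pearson_distance_matrix(profiles)
            square = np.zeros((5, 5))
            square[np.triu_indices(5, 1)] = condensed
            square += square.T
            oracle = brute_force_upgma(square)
            _, tree = hcl_average_pearson(profiles, k=2)
            np.testing.assert_allclose(tree[:, 2], oracle[:, 2], atol=1e-10)
            np.testing.assert_array_equal(tree[:, 3], oracle[:, 3])

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(53)
        profiles = pd.DataFrame(rng.normal(size=(30, 12)))
        _, tree = hcl_average_pearson(profiles, k=3)
        assert (np.diff(tree[:, 2]) >= -1e-12).all()

    def test_affine_invariance(self):
        """Replacing a profile x by a*x + b (a > 0) leaves the tree unchanged."""
        rng = np.random.default_rng(54)
        profiles = pd.DataFrame(rng.normal(size=(8, 12)))
        scaled = profiles.copy()
        scaled.iloc[3] = 2.5 * scaled.iloc[3] + 7.0
        ids1, tree1 = hcl_average_pearson(profiles, k=3)
        ids2, tree2 = hcl_average_pearson(scaled, k=3)
        pd.testing.assert_series_equal(ids1, ids2)
        np.testing.assert_allclose(tree1[:, 2], tree2[:, 2], atol=1e-10)

    def test_permutation_invariance_of_memberships(self):
        rng = np.random.default_rng(55)
        profiles = pd.DataFrame(
            rng.normal(size=(12, 12)), index=[f"g{i}" for i in range(12)]
        )
        perm = rng.permutation(12)
        shuffled = profiles.iloc[perm]
        ids1, _ = hcl_average_pearson(profiles, k=3)
        ids2, _ = hcl_average_pearson(shuffled, k=3)
        # memberships agree as partitions (numbering may differ)
        for g in profiles.index:
            for h in profiles.index:
                same1 = ids1[g] == ids1[h]
                same2 = ids2[g] == ids2[h]
                assert same1 == same2

    def test_invalid_k_rejected(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 12)))
        with pytest.raises(ValueError):
            hcl_average_pearson(profiles, k=0)
        with pytest.raises(ValueError):
            hcl_average_pearson(profiles, k=5)


class TestPatternLabel:
    def _profile(self, ch_level, te_level, lt_trend):
        """A 12-condition profile with given line levels and LT trend."""
        values = {}
        for c in CONDITION_ORDER:
            base = ch_level if c.startswith("Ch") else te_level
            if c[2] == "L":  # LT condition
                step = int(c[-1])
                base = base + lt_trend * step
            values[c] = base
        return pd.Series(values)

    def test_lr_subsets(self):
        assert pattern_label(self._profile(1, -1, 0), "LR") == "LRa"
        assert pattern_label(self._profile(-1, 1, 0), "LR") == "LRb"

    def test_tcr_subsets(self):
        assert pattern_label(self._profile(0, 0, -1), "TCR") == "TCRa"
        assert pattern_label(self._profile(0, 0, +1), "TCR") == "TCRb"

    def test_tlsr_quadrants(self):
        assert pattern_label(self._profile(1, -1, -1), "TLSR") == "TLSRa"
        assert pattern_label(self._profile(1, -1, +1), "TLSR") == "TLSRb"
        assert pattern_label(self._profile(-1, 1, -1), "TLSR") == "TLSRc"
        assert pattern_label(self._profile(-1, 1, +1), "TLSR") == "TLSRd"

    def test_exact_tie_raises(self):
        with pytest.raises(PatternTieError):
            pattern_label(self._profile(0, 0, 0), "LR")

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            pattern_label(self._profile(1, -1, 0), "NS")


class TestAssignSubsets:
    def test_subset_labels_respect_set_membership(self, design):
        """LR genes only get LRa/LRb, TCR only TCRa/b, TLSR only TLSRa-d."""
        from coldcascade.synthetic_data import SimulationConfig, simulate_counts
        from coldcascade.de_testing import normalize

        cfg = SimulationConfig(
            n_genes_per_archetype={
                "LR_CH_UP": 20, "LR_TE_UP": 20, "TCR_DOWN": 20, "TCR_UP": 20,
                "TLSR_A": 20, "TLSR_B": 20, "TLSR_C": 20, "TLSR_D": 20,
            },
            seed=56,
        )
        counts, truth = simulate_counts(cfg, design)
        norm = normalize(counts)
        classification = pd.DataFrame(
            {"set_label": truth["archetype"].map(lambda a: a.split("_")[0])},
            index=truth.index,
        )
        subsets, trees = assign_subsets(norm, design, classification)
        allowed = {
            "LR": {"LRa", "LRb"},
            "TCR": {"TCRa", "TCRb"},
            "TLSR": {"TLSRa", "TLSRb", "TLSRc", "TLSRd"},
        }
        for set_label, ok in allowed.items():
            got = set(
                subsets.loc[subsets["set_label"] == set_label, "subset_label"]
            )
            assert got <= ok
        assert set(trees) == {"LR", "TCR", "TLSR"}
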