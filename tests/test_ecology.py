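import itertools
import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from nanofish.ecology import (
    DistanceMatrix,
    accumulation_curve,
    alpha_diversity,
    beta_dispersion,
    diel_ratios,
    fit_log_accumulation,
    jaccard_matrix,
    kruskal_dunn,
    mann_whitney,
    pcoa,
    permanova,
)


class TestAlphaDiversity:
    def test_uniform_shannon(self, count_table_factory):
        table = count_table_factory(
            {f"sp{i}": {"S1": 10} for i in range(4)}
        )
        res = alpha_diversity(table)
        assert res.at["S1", "shannon"] == pytest.approx(math.log(4))
        assert res.at["S1", "simpson"] == pytest.approx(0.75)

    def test_single_species(self, count_table_factory):
        table = count_table_factory({"sp": {"S1": 99}})
        res = alpha_diversity(table)
        assert res.at["S1", "shannon"] == 0.0
        assert res.at["S1", "simpson"] == 0.0

    def test_chao1_bias_corrected(self, count_table_factory):
        counts = {"a": 4, "b": 3, "c": 2, "d": 1, "e": 1}
        table = count_table_factory({k: {"S1": v} for k, v in counts.items()})
        res = alpha_diversity(table)
        assert res.at["S1", "singletons"] == 2
        assert res.at["S1", "doubletons"] == 1
        assert res.at["S1", "chao1"] == pytest.approx(5.5)
        assert res.at["S1", "chao1"] >= res.at["S1", "richness"]


class TestJaccard:
    def test_forced_values(self, count_table_factory):
        table = count_table_factory(
            {
                "a": {"S1": 1, "S2": 0, "S3": 1},
                "b": {"S1": 1, "S2": 1, "S3": 1},
                "c": {"S1": 1, "S2": 1, "S3": 1},
                "d": {"S1": 0, "S2": 1, "S3": 0},
            }
        )
        d = jaccard_matrix(table)
        i, j = d.labels.index("S1"), d.labels.index("S2")
        assert d.values[i, j] == pytest.approx(0.5)  # {a,b,c} vs {b,c,d}
        k = d.labels.index("S3")
        assert d.values[i, k] == 0.0  # identical presence sets

    def test_disjoint_sets(self, count_table_factory):
        table = count_table_factory(
            {"a": {"S1": 5, "S2": 0}, "b": {"S1": 0, "S2": 3}}
        )
        d = jaccard_matrix(table)
        assert d.values[0, 1] == 1.0


class TestPcoa:
    def test_two_points(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        res = pcoa(d)
        coords = res.coordinates.iloc[:, 0].to_numpy()
        assert sorted(coords) == pytest.approx([-1.0, 1.0])

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(7, 2))
        dmat = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
        res = pcoa(DistanceMatrix([f"S{i}" for i in range(7)], dmat))
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        assert np.abs(recon - dmat).max() < 1e-8

    def test_three_equidistant_points(self):
        d = DistanceMatrix(["A", "B", "C"], np.ones((3, 3)) - np.eye(3))
        res = pcoa(d)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        points = rng.normal(size=(6, 3))
        dmat = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
        ours = pcoa(DistanceMatrix([f"S{i}" for i in range(6)], dmat))
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dmat, [f"S{i}" for i in range(6)])
        )
        np.testing.assert_allclose(
            ours.eigenvalues,
            theirs.eigvals.to_numpy()[: len(ours.eigenvalues)],
            atol=1e-8,
        )


def _two_group_distance(between=4.0, within=0.5, n_per=3, seed=0):
    rng = np.random.default_rng(seed)
    centers = {"g1": np.zeros(4), "g2": np.full(4, between)}
    labels, points = [], []
    for g, c in centers.items():
        for i in range(n_per):
            labels.append(f"{g}_{i}")
            points.append(c + rng.normal(scale=within, size=4))
    points = np.array(points)
    dmat = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    groups = pd.Series([l.split("_")[0] for l in labels], index=labels, name="group")
    return DistanceMatrix(labels, dmat), groups


def anderson_f_oracle(d: DistanceMatrix, groups: pd.Series) -> float:
    """Single-factor PERMANOVA pseudo-F from the direct distance identity:
    SS_total = sum of squared distances / n; SS_within analogous per group."""
    n = len(d.labels)
    d2 = d.values**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    lab = groups.loc[d.labels].to_numpy()
    for g in np.unique(lab):
        idx = np.where(lab == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(np.unique(lab))
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_r2_partition_sums_to_one(self):
        d, groups = _two_group_distance(seed=5)
        meta = pd.DataFrame({"group": groups})
        res = permanova(d, meta, "group", n_perm=99, seed=0)
        assert res.table["r2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_f_matches_direct_withinbetween_identity(self):
        d, groups = _two_group_distance(seed=8)
        meta = pd.DataFrame({"group": groups})
        res = permanova(d, meta, "group", n_perm=0, seed=0)
        assert res["group"]["pseudo_f"] == pytest.approx(
            anderson_f_oracle(d, groups), rel=1e-9
        )

    def test_exhaustive_permutation_p_at_n6(self):
        """Two clearly separated groups of three: the permutation p equals
        the exhaustively enumerated exceedance probability."""
        d, groups = _two_group_distance(between=10.0, within=0.1, seed=2)
        meta = pd.DataFrame({"group": groups})
        f_obs = anderson_f_oracle(d, groups)
        lab = groups.to_numpy()
        exceed = total = 0
        for perm in itertools.permutations(range(6)):
            permuted = pd.Series(lab[list(perm)], index=groups.index, name="group")
            if anderson_f_oracle(d, permuted) >= f_obs - 1e-12:
                exceed += 1
            total += 1
        exact_p = exceed / total
        res = permanova(d, meta, "group", n_perm=4999, seed=3)
        assert res["group"]["p_value"] == pytest.approx(exact_p, abs=0.01)
        # with full separation only the 2 relabellings reproducing the split
        # reach f_obs: p = 2/720 = 1/C(6,3)/... check magnitude
        assert exact_p == pytest.approx(
            (math.factorial(3) ** 2 * 2) / math.factorial(6)
        )

    def test_two_factor_sequential_matches_vegan_adonis2(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(17)
        n = 12
        habitat = ["barrier"] * 4 + ["fringing"] * 4 + ["outer"] * 4
        season = (["March", "September"] * 6)[:n]
        points = rng.normal(size=(n, 5))
        points[:4] += 2.0
        dmat = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
        labels = [f"S{i}" for i in range(n)]
        meta = pd.DataFrame(
            {"habitat": habitat, "season": season}, index=labels
        )
        res = permanova(
            DistanceMatrix(labels, dmat), meta, "habitat * season",
            n_perm=99, seed=0,
        )
        pd.DataFrame(dmat, index=labels, columns=labels).to_csv(tmp_path / "d.csv")
        meta.to_csv(tmp_path / "m.csv")
        rcode = f"""
        suppressMessages(library(vegan))
        d <- as.dist(as.matrix(read.csv("{tmp_path}/d.csv", row.names=1)))
        m <- read.csv("{tmp_path}/m.csv", row.names=1)
        fit <- adonis2(d ~ habitat * season, data=m, permutations=99, by="terms")
        cat(paste(fit$Df, fit$SumOfSqs, fit$R2, sep=","), sep="\n")
        """
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        lines = [l for l in proc.stdout.strip().splitlines() if l]
        vegan = [tuple(float(x) for x in l.split(",")) for l in lines[:4]]
        ours = res.table.loc[["habitat", "season", "habitat:season", "residual"]]
        for (v_df, v_ss, v_r2), (_, row) in zip(vegan, ours.iterrows()):
            assert row["df"] == int(v_df)
            assert row["sum_sq"] == pytest.approx(v_ss, rel=1e-6)
            assert row["r2"] == pytest.approx(v_r2, rel=1e-6)

    def test_constant_factor_errors(self):
        d, groups = _two_group_distance()
        meta = pd.DataFrame({"group": ["x"] * 6}, index=d.labels)
        with pytest.raises(ValueError):
            permanova(d, meta, "group", n_perm=9, seed=0)


class TestBetaDispersion:
    def test_identical_samples_zero_dispersion(self):
        dmat = np.zeros((6, 6))
        dmat[:3, 3:] = 5.0
        dmat[3:, :3] = 5.0
        labels = [f"S{i}" for i in range(6)]
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=labels)
        res = beta_dispersion(DistanceMatrix(labels, dmat), groups, n_perm=99, seed=0)
        assert np.allclose(res.distances.to_numpy(), 0.0)

    def test_mirror_symmetric_groups(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 3))
        points = np.vstack([pts, pts + 10.0])
        dmat = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
        labels = [f"S{i}" for i in range(8)]
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=labels)
        res = beta_dispersion(DistanceMatrix(labels, dmat), groups, n_perm=199, seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_hand_computed_four_points(self):
        # two groups on a line: a={0, 2}, b={10, 16}
        coords = np.array([0.0, 2.0, 10.0, 16.0])
        dmat = np.abs(coords[:, None] - coords[None, :])
        labels = ["a1", "a2", "b1", "b2"]
        groups = pd.Series(["a", "a", "b", "b"], index=labels)
        res = beta_dispersion(DistanceMatrix(labels, dmat), groups, n_perm=0, seed=0)
        assert res.distances["a1"] == pytest.approx(1.0, abs=1e-9)
        assert res.distances["b1"] == pytest.approx(3.0, abs=1e-9)
        assert res.group_means["a"] == pytest.approx(1.0, abs=1e-9)
        assert res.group_means["b"] == pytest.approx(3.0, abs=1e-9)


class TestAccumulation:
    def test_identical_samples_flat(self, count_table_factory):
        table = count_table_factory(
            {f"sp{i}": {"S1": 3, "S2": 5, "S3": 1} for i in range(6)}
        )
        curve = accumulation_curve(table)
        assert list(curve["mean_richness"]) == [6.0, 6.0, 6.0]
        assert list(curve["sd_richness"]) == [0.0, 0.0, 0.0]

    def test_disjoint_samples_linear(self, count_table_factory):
        counts = {}
        for j in range(4):
            for i in range(3):
                counts[f"sp{j}_{i}"] = {f"S{k}": (5 if k == j else 0) for k in range(4)}
        table = count_table_factory(counts)
        curve = accumulation_curve(table)
        assert list(curve["mean_richness"]) == [3.0, 6.0, 9.0, 12.0]
        assert max(curve["sd_richness"]) == 0.0

    def test_exact_enumeration_matches_bruteforce_orderings(self, count_table_factory):
        rng = np.random.default_rng(4)
        counts = {
            f"sp{i}": {f"S{j}": int(rng.integers(0, 2)) for j in range(4)}
            for i in range(9)
        }
        table = count_table_factory(counts)
        curve = accumulation_curve(table)
        presence = [
            {r for r in table.counts.index if table.counts.at[r, c] > 0}
            for c in table.counts.columns
        ]
        for k in range(1, 5):
            vals = []
            for order in itertools.permutations(range(4)):
                seen = set()
                for idx in order[:k]:
                    seen |= presence[idx]
                vals.append(len(seen))
            assert curve["mean_richness"][k - 1] == pytest.approx(np.mean(vals))
            assert curve["sd_richness"][k - 1] == pytest.approx(np.std(vals))

    def test_final_point_is_total_richness(self, count_table_factory):
        rng = np.random.default_rng(9)
        counts = {
            f"sp{i}": {f"S{j}": int(rng.integers(0, 3)) for j in range(10)}
            for i in range(15)
        }
        table = count_table_factory(counts)
        curve = accumulation_curve(table, n_perm=50, seed=1)
        total = int((table.counts.sum(axis=1) > 0).sum())
        assert curve["mean_richness"].iloc[-1] == pytest.approx(total)
        assert curve["sd_richness"].iloc[-1] == pytest.approx(0.0)


class TestLogFit:
    def test_exact_recovery_and_threshold(self):
        n = np.arange(1, 9)
        curve = pd.DataFrame(
            {"n_samples": n, "mean_richness": 10 + 20 * np.log(n)}
        )
        fit = fit_log_accumulation(curve)
        assert fit.a == pytest.approx(10.0, abs=1e-9)
        assert fit.b == pytest.approx(20.0, abs=1e-9)
        assert fit.threshold_n == 20
        # bracketing: at 20 the marginal gain drops below one species
        assert 20 * math.log(21 / 20) < 1 < 20 * math.log(20 / 19)

    def test_immediate_saturation(self):
        n = np.arange(1, 6)
        curve = pd.DataFrame({"n_samples": n, "mean_richness": 3 + 0.5 * np.log(n)})
        assert fit_log_accumulation(curve).threshold_n == 1

    def test_flat_curve(self):
        curve = pd.DataFrame({"n_samples": [1, 2, 3], "mean_richness": [5.0, 5.0, 5.0]})
        fit = fit_log_accumulation(curve)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.threshold_n == 1


class TestRankTests:
    def test_mann_whitney_exact_extreme(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(1 / math.comb(6, 3))

    def test_identical_groups(self):
        res = kruskal_dunn({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_kruskal_matches_permutation_oracle(self):
        from scipy import stats

        groups = {"a": [1.0, 5.0, 2.0], "b": [8.0, 9.0, 4.0], "c": [3.0, 7.0, 6.0]}
        res = kruskal_dunn(groups)
        pooled = np.array(sum((list(v) for v in groups.values()), []))
        sizes = [3, 3, 3]
        rng = np.random.default_rng(0)
        exceed = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h = stats.kruskal(perm[:3], perm[3:6], perm[6:]).statistic
            if h >= res.h_statistic - 1e-12:
                exceed += 1
        p_perm = exceed / n_perm
        assert abs(res.p_value - p_perm) < 0.05

    def test_dunn_holm_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        groups = {
            "g1": list(rng.normal(0, 1, 8)),
            "g2": list(rng.normal(0, 1, 8)),
            "g3": list(rng.normal(3, 1, 8)),
        }
        res = kruskal_dunn(groups)
        assert (res.dunn["p_adjusted"] >= res.dunn["p_raw"] - 1e-12).all()
        worst = res.dunn.sort_values("p_raw").iloc[-1]
        assert worst["p_adjusted"] <= 1.0


class TestDielRatios:
    def test_read_ratio(self, count_table_factory):
        table = count_table_factory(
            {"Nocto fish": {"S1": 30}, "Day fish": {"S1": 70}}
        )
        traits = {"Nocto fish": "nocturnal", "Day fish": "diurnal"}
        res = diel_ratios(table, traits)
        assert res.at["S1", "nocturnal_read_ratio"] == pytest.approx(0.30)
        assert res.at["S1", "nocturnal_species_ratio"] == pytest.approx(0.5)

    def test_all_nocturnal(self, count_table_factory):
        table = count_table_factory({"A fish": {"S1": 10}, "B fish": {"S1": 5}})
        res = diel_ratios(table, {"A fish": "nocturnal", "B fish": "nocturnal"})
        assert res.at["S1", "nocturnal_read_ratio"] == 1.0
        assert res.at["S1", "nocturnal_species_ratio"] == 1.0

    def test_both_counts_only_in_denominator(self, count_table_factory):
        table = count_table_factory(
            {"N": {"S1": 20}, "B": {"S1": 30}, "U": {"S1": 50}}
        )
        res = diel_ratios(table, {"N": "nocturnal", "B": "both"})
        assert res.at["S1", "nocturnal_read_ratio"] == pytest.approx(20 / 50)
        assert res.at["S1", "nocturnal_species_ratio"] == pytest.approx(0.5)

    def test_unknown_only_flagged(self, count_table_factory):
        table = count_table_factory({"Mystery": {"S1": 5}})
        res = diel_ratios(table, {})
        assert not res.at["S1", "defined"]
        assert np.isnan(res.at["S1", "nocturnal_read_ratio"])
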