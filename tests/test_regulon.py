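"""Normalization, activity inference, coactivation and module partitioning."""

import numpy as np
import pandas as pd
import pytest

from colonyevo.regulon import (
    ActivityMatrix,
    CoactivationMatrix,
    Regulon,
    RegulonSet,
    activity_fits,
    coactivation,
    normalize_log,
    partition_modules,
    regulator_activity,
    size_factors,
)


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self):
        # sample2 = 2 x sample1: median ratios are (1/sqrt(2), sqrt(2))
        # after rescaling to geometric mean 1 (hand computation)
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                              index=["g1", "g2", "g3"])
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert f["s2"] == pytest.approx(np.sqrt(2), rel=1e-12)
        assert f["s2"] / f["s1"] == pytest.approx(2.0, rel=1e-12)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 7, 9], "s2": [5, 7, 9], "s3": [5, 7, 9]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_no_allpositive_gene_advises_pseudocount(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [4, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)
        # pseudocount mode succeeds
        assert len(size_factors(counts, pseudocount=0.5)) == 2


class TestNormalizeLog:
    def test_anchor_values(self):
        counts = pd.DataFrame({"s1": [0, 15]})
        f = pd.Series({"s1": 1.0})
        norm = normalize_log(counts, f)
        assert norm.iloc[0, 0] == 0.0
        assert norm.iloc[1, 0] == pytest.approx(4.0)

    def test_joint_rescaling_invariance(self):
        counts = pd.DataFrame({"s1": [3, 8], "s2": [5, 2]}, dtype=float)
        f = pd.Series({"s1": 1.3, "s2": 0.7})
        a = normalize_log(counts, f)
        b = normalize_log(2 * counts, 2 * f)
        pd.testing.assert_frame_equal(a, b)


def _single_target_setup(mode):
    # one gene with z-scores (+1, -1) over two of three samples is impossible;
    # use 4 samples where the target's z-pattern is explicit
    norm = pd.DataFrame(
        {"s1": [1.0], "s2": [3.0], "s3": [1.0], "s4": [3.0]}, index=["t1"]
    )
    regs = RegulonSet([Regulon("R", mode, ("t1",))])
    return norm, regs


class TestRegulatorActivity:
    def test_single_target_activator_equals_z(self):
        norm, regs = _single_target_setup("activator")
        act = regulator_activity(norm, regs)
        z = (norm.loc["t1"] - norm.loc["t1"].mean()) / norm.loc["t1"].std(ddof=0)
        np.testing.assert_allclose(act.activities.loc["R"], z)

    def test_single_target_repressor_is_negated(self):
        norm, regs_a = _single_target_setup("activator")
        _, regs_r = _single_target_setup("repressor")
        a = regulator_activity(norm, regs_a).activities.loc["R"]
        r = regulator_activity(norm, regs_r).activities.loc["R"]
        np.testing.assert_allclose(r, -a)

    def test_multi_target_mean(self):
        # two targets whose z-rows are (+1,-1) and (+1,-1) scaled: mean of z
        norm = pd.DataFrame(
            {"s1": [2.0, 6.0, 5.0], "s2": [0.0, 0.0, 5.0], "s3": [1.0, 3.0, 5.0]},
            index=["t1", "t2", "flat"],
        )
        regs = RegulonSet([Regulon("R", "activator", ("t1", "t2"))])
        act = regulator_activity(norm, regs).activities.loc["R"]
        z = norm.loc[["t1", "t2"]].apply(
            lambda row: (row - row.mean()) / row.std(ddof=0), axis=1
        )
        np.testing.assert_allclose(act, z.mean(axis=0))

    def test_row_means_are_zero(self):
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(
            rng.poisson(50, size=(20, 6)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        regs = RegulonSet(
            [Regulon("R1", "activator", ("g0", "g1", "g2")),
             Regulon("R2", "repressor", ("g3", "g4"))]
        )
        act = regulator_activity(norm, regs).activities
        assert np.allclose(act.mean(axis=1), 0.0, atol=1e-9)

    def test_global_count_rescaling_leaves_activity_unchanged(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(100, size=(30, 8)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(8)],
        )
        regs = RegulonSet([Regulon("R", "activator", ("g0", "g5", "g7"))])
        a = regulator_activity(normalize_log(counts, size_factors(counts)), regs)
        b = regulator_activity(
            normalize_log(3 * counts, size_factors(3 * counts)), regs
        )
        # size factors absorb the common factor; activities match closely
        # (not exactly: log2(x/f+1) is not scale-equivariant at small counts)
        np.testing.assert_allclose(
            a.activities.to_numpy(), b.activities.to_numpy(), atol=5e-2
        )

    def test_regulon_without_usable_targets_is_flagged(self):
        norm = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["g"])
        regs = RegulonSet([Regulon("R", "activator", ("missing",))])
        act = regulator_activity(norm, regs)
        assert act.undefined == ["R"]
        assert "R" not in act.activities.index

    def test_too_few_samples_rejected(self):
        norm = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            regulator_activity(norm, RegulonSet([Regulon("R", "activator", ("g",))]))


class TestCoactivation:
    def _activity(self, data):
        return ActivityMatrix(activities=pd.DataFrame(data))

    def test_affine_dependence_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=10)
        act = self._activity({f"s{i}": [a[i], 2 * a[i] + 1, -a[i]] for i in range(10)})
        act.activities.index = ["A", "B", "C"]
        co = coactivation(act)
        assert co.corr.loc["A", "B"] == pytest.approx(1.0, abs=1e-12)
        assert co.corr.loc["A", "C"] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diag(co.corr), 1.0)
        assert np.allclose(co.corr, co.corr.T, atol=1e-12)

    def test_independent_activities_weakly_correlated(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 200))
        act = self._activity(
            pd.DataFrame(data, index=list("ABCDE"),
                         columns=[f"s{i}" for i in range(200)])
        )
        co = coactivation(act)
        off = co.corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(4)
        act = self._activity(
            pd.DataFrame(rng.normal(size=(8, 30)),
                         index=[f"R{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(30)])
        )
        eig = np.linalg.eigvalsh(coactivation(act).corr.to_numpy())
        assert eig.min() > -1e-8

    def test_zero_variance_regulator_masked(self):
        act = self._activity(
            pd.DataFrame({"s1": [1.0, 0.0], "s2": [2.0, 0.0], "s3": [3.0, 0.0]},
                         index=["A", "flat"])
        )
        co = coactivation(act)
        assert co.masked == ["flat"]
        assert "flat" not in co.corr.index


def _block_coactivation(within=0.9, between=-0.8, sizes=(4, 4)):
    n = sum(sizes)
    corr = np.full((n, n), between)
    start = 0
    for s in sizes:
        corr[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(corr, 1.0)
    names = [f"R{i}" for i in range(n)]
    return CoactivationMatrix(
        corr=pd.DataFrame(corr, index=names, columns=names), n_samples=20
    )


class TestPartitionModules:
    def test_planted_two_blocks_recovered(self):
        co = _block_coactivation()
        part = partition_modules(co)
        assert part.k == 2
        assert not part.degenerate
        labels = part.labels
        block1 = {labels[f"R{i}"] for i in range(4)}
        block2 = {labels[f"R{i}"] for i in range(4, 8)}
        assert len(block1) == 1 and len(block2) == 1 and block1 != block2

    def test_uniform_correlation_flagged_degenerate(self):
        co = _block_coactivation(within=0.95, between=0.95)
        part = partition_modules(co)
        assert part.degenerate

    def test_forced_k3_nests_the_two_blocks(self):
        # tiny symmetric jitter breaks merge-height ties so a 3-way cut exists
        co = _block_coactivation()
        rng = np.random.default_rng(7)
        eps = rng.uniform(0, 5e-3, size=co.corr.shape)
        eps = (eps + eps.T) / 2
        np.fill_diagonal(eps, 0.0)
        co.corr -= eps
        part = partition_modules(co, k=3)
        assert part.k == 3
        # each of the two planted blocks maps into labels that never mix blocks
        labs1 = {part.labels[f"R{i}"] for i in range(4)}
        labs2 = {part.labels[f"R{i}"] for i in range(4, 8)}
        assert labs1.isdisjoint(labs2)

    def test_silhouette_matches_direct_formula_on_planted_blocks(self):
        # independent silhouette computation from its definition
        co = _block_coactivation()
        part = partition_modules(co)
        d = 1 - co.corr.to_numpy()
        labels = np.array([part.labels[r] for r in co.corr.index])
        sils = []
        for i in range(len(labels)):
            same = (labels == labels[i]) & (np.arange(len(labels)) != i)
            a = d[i, same].mean()
            b = min(
                d[i, labels == l].mean() for l in set(labels) if l != labels[i]
            )
            sils.append((b - a) / max(a, b))
        assert part.silhouette_by_k[2] == pytest.approx(np.mean(sils), abs=1e-9)

    def test_masked_rows_rejected(self):
        co = _block_coactivation()
        co.masked = ["R0"]
        with pytest.raises(ValueError):
            partition_modules(co)


class TestActivityFits:
    def _activity(self, arr, samples):
        return ActivityMatrix(
            activities=pd.DataFrame(arr, index=["R"], columns=samples)
        )

    def test_perfect_linear_relation(self):
        x = pd.Series(np.linspace(0, 1, 10), index=[f"s{i}" for i in range(10)])
        act = self._activity([3 * x.to_numpy() - 1], x.index)
        fits = activity_fits(act, x)
        assert fits.loc["R", "r2"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_covariate_low_r2(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(100)]
        act = self._activity([rng.normal(size=100)], samples)
        x = pd.Series(rng.normal(size=100), index=samples)
        fits = activity_fits(act, x)
        assert fits.loc["R", "r2"] < 0.1

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(30)]
        y = rng.normal(size=30)
        x = pd.Series(rng.normal(size=30), index=samples)
        act = self._activity([y], samples)
        fits = activity_fits(act, x)
        r = np.corrcoef(x, y)[0, 1]
        assert fits.loc["R", "r2"] == pytest.approx(r**2, abs=1e-10)

    def test_constant_covariate_flagged(self):
        samples = [f"s{i}" for i in range(5)]
        act = self._activity([np.arange(5.0)], samples)
        fits = activity_fits(act, pd.Series(1.0, index=samples))
        assert bool(fits.loc["R", "undefined"])
        assert np.isnan(fits.loc["R", "r2"])


class TestSyntheticRecovery:
    def test_inferred_activity_tracks_truth(self, default_synthetic, normalized_synthetic):
        _, ann, _, truth = default_synthetic
        act = regulator_activity(normalized_synthetic, ann.regulons)
        for reg in act.activities.index:
            r = np.corrcoef(
                act.activities.loc[reg], truth.activity.activities.loc[reg]
            )[0, 1]
            assert r >= 0.9, f"{reg}: correlation {r:.3f}"

    def test_planted_modules_recovered_exactly(self, default_synthetic, normalized_synthetic):
        _, ann, _, truth = default_synthetic
        act = regulator_activity(normalized_synthetic, ann.regulons)
        part = partition_modules(coactivation(act))
        assert part.k == 2
        by_label = {}
        for reg, lab in part.labels.items():
            by_label.setdefault(lab, set()).add(truth.modules[reg])
        assert all(len(mods) == 1 for mods in by_label.values())
        assert {m for mods in by_label.values() for m in mods} == {
            "vegetative", "dormancy"
        }
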