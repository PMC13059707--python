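import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest

import guildflow as gf
from guildflow.ordination import _ss_decomposition, _pseudo_f


def _euclid_df(points, ids=None):
    ids = ids or [f"S{i}" for i in range(len(points))]
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(d, index=ids, columns=ids)


class TestBrayCurtis:
    def test_hand_computed_value(self):
        abund = pd.DataFrame([[2.0, 2.0], [1.0, 3.0]], index=["S1", "S2"], columns=["a", "b"])
        d = gf.bray_curtis(abund)
        assert d.loc["S1", "S2"] == pytest.approx(0.25)  # (1+1)/(3+5)

    def test_identical_and_disjoint(self):
        abund = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]], index=["S1", "S2", "S3"], columns=["a", "b"]
        )
        d = gf.bray_curtis(abund)
        assert d.loc["S1", "S2"] == 0.0
        assert d.loc["S1", "S3"] == 1.0

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            gf.bray_curtis(pd.DataFrame([[1.0, -0.1], [0.2, 0.3]]))

    def test_all_zero_pair_convention(self):
        abund = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]], columns=["a", "b"])
        d = gf.bray_curtis(abund)
        assert d.iloc[0, 1] == 0.0


class TestPcoa:
    def test_collinear_points_give_one_axis(self):
        d = _euclid_df([[0.0], [1.0], [3.0]])
        res = gf.pcoa(d)
        assert len(res.eigenvalues) == 1
        rec = np.abs(np.diff(np.sort(res.coordinates[:, 0])))
        assert np.allclose(sorted(rec), [1.0, 2.0])

    def test_duplicated_sample_identical_coordinates(self):
        d = _euclid_df([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        res = gf.pcoa(d)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(12, 3))
        d = _euclid_df(pts)
        res = gf.pcoa(d)
        rec = squareform(pdist(res.coordinates))
        assert np.abs(rec - d.to_numpy()).max() < 1e-8

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = np.abs(rng.normal(size=(10, 5)))
        abund = pd.DataFrame(pts, index=[f"S{i}" for i in range(10)])
        d = gf.bray_curtis(abund)
        ours = gf.pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        k = min(3, ours.coordinates.shape[1])
        assert np.allclose(
            ours.eigenvalues[:k], ref.eigvals.to_numpy()[:k], atol=1e-8
        )
        for axis in range(k):
            a, b = ours.coordinates[:, axis], ref.samples.to_numpy()[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            gf.pcoa(_euclid_df([[0.0], [1.0]]))


class TestApcoa:
    def test_single_level_covariate_equals_pcoa(self, rng):
        pts = rng.normal(size=(8, 2))
        d = _euclid_df(pts)
        meta = pd.DataFrame({"donor": ["D1"] * 8}, index=d.index)
        plain, adj = gf.pcoa(d), gf.apcoa(d, meta, "donor")
        assert np.allclose(np.abs(plain.coordinates), np.abs(adj.coordinates), atol=1e-9)

    def test_removes_planted_donor_shift(self, rng):
        # donors displaced by large offsets; treatment balanced within donor
        n_per, donors = 12, ["D1", "D2", "D3"]
        pts, meta_rows = [], []
        offsets = {"D1": [0, 0], "D2": [40, 0], "D3": [0, 40]}
        for d_ in donors:
            for i in range(n_per):
                trt = "Oxygen" if i % 2 else "Control"
                shift = [0, 3] if trt == "Oxygen" else [0, 0]
                pts.append(rng.normal(size=2) + offsets[d_] + shift)
                meta_rows.append((d_, trt))
        ids = [f"S{i}" for i in range(len(pts))]
        meta = pd.DataFrame(meta_rows, columns=["donor", "treatment"], index=ids)
        d = _euclid_df(pts, ids)
        adj = gf.apcoa(d, meta, "donor")
        coords2 = adj.coordinates[:, :2]
        d_adj = _euclid_df(coords2, ids)
        donor_r2 = gf.permanova(d_adj, meta["donor"], n_perm=19, seed=0).r2
        assert donor_r2 < 0.01
        # treatment separation survives adjustment
        unadj = gf.pcoa(d)
        r2_before = gf.permanova(
            _euclid_df(unadj.coordinates[:, :2], ids), meta["treatment"], n_perm=19, seed=0
        ).r2
        r2_after = gf.permanova(d_adj, meta["treatment"], n_perm=19, seed=0).r2
        assert r2_after > 0.5 * r2_before

    def test_adjusted_donor_r2_never_larger(self, default_dataset):
        _, counts, meta, _, _ = default_dataset
        rel = gf.to_relative(counts).iloc[::4]  # spread across donors/arms
        meta = meta.iloc[::4]
        d = gf.bray_curtis(rel)
        before = gf.permanova(d, meta["donor"], n_perm=19, seed=0).r2
        adj = gf.apcoa(d, meta, "donor")
        d_adj = _euclid_df(adj.coordinates, list(rel.index))
        after = gf.permanova(d_adj, meta["donor"], n_perm=19, seed=0).r2
        assert after <= before + 1e-9

    def test_one_sample_per_level_is_an_error(self):
        d = _euclid_df([[0.0], [1.0], [2.0]])
        meta = pd.DataFrame({"donor": ["a", "b", "c"]}, index=d.index)
        with pytest.raises(ValueError):
            gf.apcoa(d, meta, "donor")


def brute_force_permanova_p(d: np.ndarray, groups: np.ndarray) -> float:
    """Exhaustive enumeration oracle over all distinct label assignments."""
    d2 = d**2
    n = len(groups)
    idx_a = [c for c in itertools.combinations(range(n), int((groups == groups[0]).sum()))]

    def f_for(assignment_a):
        lab = np.ones(n, dtype=int)
        lab[list(assignment_a)] = 0
        ss_total, ss_within, a = _ss_decomposition(d2, lab)
        return _pseudo_f(ss_total, ss_within, a, n)

    obs = f_for(tuple(np.flatnonzero(groups == groups[0])))
    fs = np.array([f_for(c) for c in idx_a])
    return float(np.mean(fs >= obs - 1e-12))


class TestPermanova:
    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(6, 2))
            pts[3:] += rng.normal(scale=2)
            d = _euclid_df(pts)
            groups = np.array(["a", "a", "a", "b", "b", "b"])
            res = gf.permanova(d, groups, n_perm="exact")
            assert res.p == pytest.approx(brute_force_permanova_p(d.to_numpy(), groups))

    def test_matches_skbio_pseudo_f(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = np.abs(rng.normal(size=(16, 4)))
        abund = pd.DataFrame(pts, index=[f"S{i}" for i in range(16)])
        d = gf.bray_curtis(abund)
        groups = np.repeat(["a", "b"], 8)
        ours = gf.permanova(d, groups, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=list(groups),
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_separated_clusters_attain_p_floor(self, rng):
        pts = np.vstack([rng.normal(size=(6, 2)), rng.normal(size=(6, 2)) + 50])
        d = _euclid_df(pts)
        res = gf.permanova(d, np.repeat(["a", "b"], 6), n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_stratified_permutations_stay_in_blocks(self, rng):
        from guildflow.ordination import _stratified_permutations

        donors = np.repeat(["D1", "D2", "D3"], 8)
        groups = np.tile(np.repeat(["x", "y"], 4), 3)
        perms = _stratified_permutations(groups, donors, 200, rng)
        for block in ["D1", "D2", "D3"]:
            mask = donors == block
            orig = np.sort(groups[mask])
            assert all(np.array_equal(np.sort(row[mask]), orig) for row in perms)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 500
        groups = np.repeat(["a", "b"], 10)
        for _ in range(n_sims):
            pts = rng.normal(size=(20, 3))
            d = _euclid_df(pts)
            res = gf.permanova(d, groups, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        rate = rejections / n_sims
        assert 0.03 <= rate <= 0.07

    def test_input_validation(self):
        d = _euclid_df([[0.0], [1.0], [2.0], [3.0]])
        with pytest.raises(ValueError):
            gf.permanova(d, ["a", "a", "a", "a"])
        with pytest.raises(ValueError):
            gf.permanova(d, ["a", "a", "a", "b"])


class TestPairwisePermanova:
    def test_two_groups_q_equals_p(self, rng):
        pts = rng.normal(size=(12, 2))
        d = _euclid_df(pts)
        out = gf.pairwise_permanova(d, np.repeat(["a", "b"], 6), n_perm=99, seed=0)
        assert len(out) == 1
        assert out.loc[0, "q"] == pytest.approx(out.loc[0, "p"])

    def test_all_pairs_present_with_bh(self, rng):
        pts = rng.normal(size=(24, 2))
        d = _euclid_df(pts)
        groups = np.repeat(["a", "b", "c", "d"], 6)
        out = gf.pairwise_permanova(d, groups, n_perm=49, seed=0)
        assert len(out) == 6
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestProcrustes:
    def test_rotated_scaled_copy_is_exact(self, rng):
        x = rng.normal(size=(15, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        y = 3.5 * x @ rot + 2.0
        res = gf.procrustes_protest(x, y, n_perm=49, seed=0)
        assert res.m2 < 1e-12
        assert res.correlation == pytest.approx(1.0)

    def test_agrees_with_scipy_disparity(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes

        x = rng.normal(size=(20, 2))
        y = rng.normal(size=(20, 2))
        _, _, disparity = scipy_procrustes(x, y)
        res = gf.procrustes_protest(x, y, n_perm=9, seed=0)
        assert res.m2 == pytest.approx(disparity, abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(31)
        pvals = [
            gf.procrustes_protest(
                rng.normal(size=(30, 2)), rng.normal(size=(30, 2)), n_perm=199, seed=int(s)
            ).p
            for s in rng.integers(2**31, size=200)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_sample_id_alignment(self, rng):
        x = rng.normal(size=(10, 2))
        ids = [f"S{i}" for i in range(10)]
        xo = gf.OrdinationResult(ids, x, np.ones(2), np.ones(2) / 2)
        perm = rng.permutation(10)
        yo = gf.OrdinationResult([ids[i] for i in perm], 2.0 * x[perm], np.ones(2), np.ones(2) / 2)
        res = gf.procrustes_protest(xo, yo, n_perm=9, seed=0)
        assert res.m2 < 1e-12
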