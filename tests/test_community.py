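"""Community statistics: filtering, transforms, diversity, ordination,
PERMANOVA and differential abundance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from towgrow.community import (
    CommunityTable,
    absolute_abundance,
    alpha_diversity,
    bray_curtis,
    differential_abundance,
    pcoa,
    permanova,
    prevalence_filter,
)
from towgrow.errors import InsufficientDataError, ValidationError


def make_table(rel, totals=None, sample_ids=None, taxa=None):
    rel = np.asarray(rel, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(rel.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(rel.shape[1])]
    df = pd.DataFrame(rel, index=sample_ids, columns=taxa)
    tot = pd.Series(totals if totals is not None else np.ones(rel.shape[0]),
                    index=sample_ids)
    meta = pd.DataFrame({
        "bag": 1, "erh": 50.0, "time_elevated": 24.0, "day": 14.0,
        "condition_class": "constant",
    }, index=sample_ids)
    return CommunityTable(rel_abundance=df, totals=tot, metadata=meta)


class TestPrevalenceFilter:
    def _table_with_prevalence(self, counts, n_samples=20):
        # counts[j] = number of samples in which taxon j is present
        rel = np.zeros((n_samples, len(counts)))
        for j, c in enumerate(counts):
            rel[:c, j] = 1.0
        rel = rel / np.maximum(rel.sum(axis=1, keepdims=True), 1e-300)
        # give empty rows mass on taxon 0 so rows sum to one
        empty = rel.sum(axis=1) == 0
        rel[empty, 0] = 1.0
        return make_table(rel)

    def test_boundary_is_inclusive(self):
        table = self._table_with_prevalence([20, 2, 1])
        out = prevalence_filter(table, 0.10)
        assert list(out.rel_abundance.columns) == ["t0", "t1"]  # 10% kept, 5% dropped

    def test_removed_mass_tracked_not_renormalized(self):
        rel = [[0.9, 0.1], [0.9, 0.1], [1.0, 0.0], [1.0, 0.0],
               [1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [1.0, 0.0],
               [1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [1.0, 0.0]]
        out = prevalence_filter(make_table(rel), 0.25)
        assert list(out.rel_abundance.columns) == ["t0"]
        assert out.other_fraction.iloc[0] == pytest.approx(0.1)
        assert out.rel_abundance.iloc[0, 0] == pytest.approx(0.9)

    def test_idempotent(self):
        table = self._table_with_prevalence([20, 5, 2, 1])
        once = prevalence_filter(table, 0.10)
        twice = prevalence_filter(once, 0.10)
        pd.testing.assert_frame_equal(once.rel_abundance, twice.rel_abundance)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            prevalence_filter(make_table(np.ones((0, 0))))


class TestAbsoluteAbundance:
    def test_asinh_values(self):
        table = make_table([[0.5, 0.5], [1.0, 0.0]], totals=[2e6, 1.0])
        out = absolute_abundance(table)
        assert out.iloc[0, 0] == pytest.approx(math.log(1e6 + math.sqrt(1e12 + 1)))
        assert out.iloc[0, 0] == pytest.approx(14.5087, abs=1e-4)
        assert out.iloc[1, 0] == pytest.approx(math.asinh(1.0), rel=1e-12)
        assert out.iloc[1, 0] == pytest.approx(0.8814, abs=1e-4)
        assert out.iloc[1, 1] == 0.0

    def test_missing_total_names_sample(self):
        table = make_table([[1.0], [1.0]])
        table = CommunityTable(
            rel_abundance=table.rel_abundance,
            totals=table.totals.drop("s1"),
            metadata=table.metadata,
        )
        with pytest.raises(ValidationError, match="s1"):
            absolute_abundance(table)


class TestAlphaDiversity:
    def test_uniform_single_and_mixed(self):
        table = make_table([
            [0.25, 0.25, 0.25, 0.25],
            [1.0, 0.0, 0.0, 0.0],
            [0.5, 0.25, 0.25, 0.0],
        ])
        res = {d.sample_id: d for d in alpha_diversity(table)}
        assert res["s0"].shannon == pytest.approx(math.log(4), rel=1e-12)
        assert res["s0"].richness == 4
        assert res["s1"].shannon == 0.0 and res["s1"].richness == 1
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert res["s2"].shannon == pytest.approx(expected, rel=1e-12)
        assert res["s2"].shannon == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(5)
        rel = rng.dirichlet(np.ones(10), size=8)
        for d in alpha_diversity(make_table(rel)):
            assert d.shannon <= math.log(max(d.richness, 1)) + 1e-9


class TestBrayCurtis:
    def test_hand_values(self):
        mat = [[1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 1.0, 0.0], [0.0, 0.0, 2.0]]
        d = bray_curtis(mat).to_numpy()
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 2] == 0.0
        assert d[0, 3] == pytest.approx(1.0)  # disjoint supports

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([[1.0, 0.0], [0.0, 0.0]])

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=40, deadline=None)
    def test_semimetric_properties_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.uniform(0, 10, size=(5, 7))
        mat[mat < 1.0] = 0.0
        mat += 1e-6  # avoid all-zero rows
        d = bray_curtis(mat).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= -1e-12) & (d <= 1.0 + 1e-12))


class TestPcoa:
    def test_collinear_points_recover_distances(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = pcoa(d)
        assert np.sum(res.eigenvalues > 1e-9) == 1
        coords = res.coordinates.to_numpy()
        recon = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        assert np.allclose(recon, d, atol=1e-10)

    def test_equilateral_distances_give_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_two_samples_symmetric_coordinates(self):
        res = pcoa([[0.0, 1.0], [1.0, 0.0]])
        coords = np.sort(res.coordinates.to_numpy()[:, 0])
        assert coords == pytest.approx([-0.5, 0.5])

    def test_euclidean_reconstruction_error_tiny(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.max(np.abs(recon - d)) <= 1e-8

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            pcoa([[0.0, 1.0], [0.5, 0.0]])

    def test_matches_skbio_on_random_distances(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 4))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        assert np.allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9])[::-1],
            np.sort(theirs.eigvals[theirs.eigvals > 1e-9])[::-1],
            atol=1e-8,
        )


class TestPermanova:
    def _two_clusters(self):
        # within-cluster distance 0, between 1
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        return d

    def test_separated_clusters_r2_one(self):
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(self._two_clusters(), labels, n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value >= 1 / 100  # permutation p is bounded below
        # exact enumeration: only the 2 labelings reproducing the partition
        # tie the unbounded pseudo-F, so p = 2/20
        exact = permanova(self._two_clusters(), labels, exact=True)
        assert exact.p_value == pytest.approx(2 / 20)

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, labels, exact=True)

        # independent brute-force oracle over all 20 distinct assignments
        import itertools

        def pseudo_f(assign):
            groups = {}
            for i, g in enumerate(assign):
                groups.setdefault(g, []).append(i)
            n = len(assign)
            sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
            ssw = 0.0
            for idx in groups.values():
                ssw += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
            ssb = sst - ssw
            return (ssb / 1) / (ssw / 4)

        f_obs = pseudo_f(labels)
        assigns = set(itertools.permutations(labels))
        count = sum(1 for a in assigns if pseudo_f(a) >= f_obs - 1e-12)
        assert res.p_value == pytest.approx(count / len(assigns))
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-12)

    def test_r2_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        base = permanova(d, labels, n_permutations=49, seed=1).r_squared
        perm = rng.permutation(10)
        shuffled = permanova(d[np.ix_(perm, perm)], labels[perm],
                             n_permutations=49, seed=1).r_squared
        assert base == pytest.approx(shuffled, rel=1e-12)

    def test_matches_skbio_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 3))
        pts[5:] += 0.8
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        labels = ["a"] * 5 + ["b"] * 4
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(d), grouping=labels,
                              permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_degenerate_groupings_rejected(self):
        d = self._two_clusters()
        with pytest.raises(ValidationError):
            permanova(d, ["a"] * 6, n_permutations=9, seed=0)
        with pytest.raises(ValidationError):
            permanova(d, ["a"] * 3 + ["b"] * 3, n_permutations=0, seed=0)

    def test_null_p_values_roughly_uniform(self):
        # exchangeable points with random labels: p should be ~U(0,1)
        from scipy.stats import kstest

        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            pts = rng.normal(size=(12, 3))
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            pvals.append(
                permanova(d, ["a"] * 6 + ["b"] * 6, n_permutations=99,
                          seed=int(rng.integers(2**31))).p_value
            )
        assert kstest(pvals, "uniform").pvalue > 1e-3


class TestDifferentialAbundance:
    def _null_frame(self, rng, n_taxa=50, n=6):
        mat = rng.normal(5.0, 1.0, size=(2 * n, n_taxa))
        idx = [f"s{i}" for i in range(2 * n)]
        return pd.DataFrame(mat, index=idx), idx[:n], idx[n:]

    def test_identical_groups_nothing_significant(self):
        df = pd.DataFrame(np.tile([[1.0, 2.0, 3.0]], (4, 1)),
                          index=["a1", "a2", "b1", "b2"])
        res = differential_abundance(df, ["a1", "a2"], ["b1", "b2"])
        assert all(r.direction == "none" for r in res)
        assert all("constant-in-both-groups" in r.flags for r in res)

    def test_spiked_taxon_detected_with_direction(self):
        rng = np.random.default_rng(9)
        df, ga, gb = self._null_frame(rng)
        df.loc[ga, df.columns[7]] += 5.0
        res = {r.taxon_id: r for r in differential_abundance(df, ga, gb)}
        spiked = res[str(df.columns[7])]
        assert spiked.q_value < 0.05
        assert spiked.direction == "group_a"
        others = [r for t, r in res.items() if t != str(df.columns[7])]
        assert sum(r.direction != "none" for r in others) <= 2

    def test_q_values_equal_brute_force_step_up(self):
        rng = np.random.default_rng(10)
        df, ga, gb = self._null_frame(rng, n_taxa=20)
        res = differential_abundance(df, ga, gb)
        p = np.array([r.p_value for r in res])
        m = p.size
        order = np.argsort(p, kind="mergesort")
        q_exp = np.empty(m)
        for pos, idx in enumerate(order):
            q_exp[idx] = min(1.0, min(p[order[j]] * m / (j + 1)
                                      for j in range(pos, m)))
        assert np.allclose([r.q_value for r in res], q_exp, atol=1e-12)

    def test_small_groups_rejected(self):
        df = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"])
        with pytest.raises(InsufficientDataError):
            differential_abundance(df, ["a"], ["b", "c"])

    def test_false_discovery_controlled_under_null(self):
        rng = np.random.default_rng(77)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            df, ga, gb = self._null_frame(rng, n_taxa=50)
            res = differential_abundance(df, ga, gb, alpha=0.05)
            hits += any(r.direction != "none" for r in res)
        # P(any false positive) under BH with independent nulls ~ alpha
        assert hits / n_sim <= 0.10
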