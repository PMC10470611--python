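import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from phylloside.stats import mantel, permanova, rank_tests
from phylloside.tables import SampleSheet


def _sheet_from(ids, **cols):
    df = pd.DataFrame({"sample_id": ids})
    df["plant_species"] = cols.get("plant_species", ["x"] * len(ids))
    df["plant_individual"] = cols.get("plant_individual", list(ids))
    df["leaf_side"] = cols.get("leaf_side", ["upper"] * len(ids))
    for k, v in cols.items():
        df[k] = v
    return SampleSheet(df)


def _oneway_F_from_distances(D, groups):
    """Independent one-way pseudo-F via the classical distance sums formula."""
    d2 = np.asarray(D.data) ** 2
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels = np.asarray(groups)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_perfect_separation_gives_unit_r_squared(self):
        # within-group distances 0, between-group 1
        D = DistanceMatrix(
            np.array(
                [
                    [0, 0, 1, 1],
                    [0, 0, 1, 1],
                    [1, 1, 0, 0],
                    [1, 1, 0, 0],
                ],
                dtype=float,
            ),
            ids=list("abcd"),
        )
        sheet = _sheet_from(list("abcd"), group=["g1", "g1", "g2", "g2"])
        res = permanova(D, sheet, ["group"], n_perm=99, seed=0)
        row = res.table.set_index("term")
        assert row.loc["group", "r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert row.loc["Residual", "sum_of_squares"] == pytest.approx(0.0, abs=1e-9)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(4, 3))
        pts[2:] += 1.5
        D = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        labels = ["g1", "g1", "g2", "g2"]
        sheet = _sheet_from(list("abcd"), group=labels)
        res = permanova(D, sheet, ["group"], exhaustive=True)
        p_impl = res.table.set_index("term").loc["group", "p_value"]
        # independent oracle: classical distance-sums F over all 4! relabelings
        F_obs = _oneway_F_from_distances(D, labels)
        count = 0
        total = 0
        for perm in itertools.permutations(range(4)):
            F_p = _oneway_F_from_distances(D, np.asarray(labels)[list(perm)])
            count += F_p >= F_obs - 1e-12
            total += 1
        assert p_impl == pytest.approx(count / total, abs=1e-12)

    def test_matches_classical_anova_on_euclidean_univariate(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.2, 1, 8), rng.normal(2, 1, 8)])
        groups = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        ids = [f"s{i}" for i in range(24)]
        D = DistanceMatrix(squareform(pdist(y[:, None])), ids=ids)
        sheet = _sheet_from(ids, group=groups)
        res = permanova(D, sheet, ["group"], n_perm=99, seed=0)
        F_perm = res.table.set_index("term").loc["group", "pseudo_F"]
        F_classic = f_oneway(y[:8], y[8:16], y[16:]).statistic
        assert F_perm == pytest.approx(F_classic, abs=1e-9)

    def test_matches_skbio_one_way_pseudo_F(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 4))
        D = DistanceMatrix(squareform(pdist(pts, metric="braycurtis")),
                           ids=[f"s{i}" for i in range(12)])
        groups = ["a"] * 6 + ["b"] * 6
        sheet = _sheet_from(list(D.ids), group=groups)
        ours = permanova(D, sheet, ["group"], n_perm=99, seed=0)
        theirs = skbio_permanova(D, grouping=groups, permutations=99)
        assert ours.table.set_index("term").loc["group", "pseudo_F"] == pytest.approx(
            theirs["test statistic"], abs=1e-9
        )

    def test_total_ss_invariant_to_term_order(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 5))
        D = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(20)])
        sheet = _sheet_from(
            list(D.ids),
            group=["a", "b"] * 10,
            cov=rng.normal(size=20),
        )
        r1 = permanova(D, sheet, ["group", "cov"], n_perm=9, seed=0).table
        r2 = permanova(D, sheet, ["cov", "group"], n_perm=9, seed=0).table
        tot1 = r1.set_index("term").loc["Total", "sum_of_squares"]
        tot2 = r2.set_index("term").loc["Total", "sum_of_squares"]
        assert tot1 == pytest.approx(tot2, abs=1e-9)
        # per-term SS may shift, but terms + residual always sum to total
        for r in (r1, r2):
            body = r[~r["term"].isin(["Total"])]
            assert body["sum_of_squares"].sum() == pytest.approx(tot1, abs=1e-9)
            assert r[~r["term"].isin(["Residual", "Total"])]["r_squared"].sum() + \
                r.set_index("term").loc["Residual", "r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_nested_term_absorbs_within_parent_variation(self):
        # individuals nested in species: df = n_ind - n_species
        rng = np.random.default_rng(4)
        n_sp, n_ind, n_rep = 3, 2, 2
        ids, sp, ind = [], [], []
        for s in range(n_sp):
            for i in range(n_ind):
                for r in range(n_rep):
                    ids.append(f"s{s}i{i}r{r}")
                    sp.append(f"sp{s}")
                    ind.append(f"sp{s}_p{i}")
        pts = rng.normal(size=(len(ids), 4))
        D = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        sheet = _sheet_from(ids, plant_species=sp, plant_individual=ind)
        res = permanova(D, sheet, ["plant_species", "plant_individual"], n_perm=9, seed=0)
        row = res.table.set_index("term")
        assert row.loc["plant_species", "df"] == n_sp - 1
        assert row.loc["plant_individual", "df"] == n_sp * n_ind - n_sp

    def test_single_level_term_rejected(self):
        D = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        sheet = _sheet_from(["a", "b"], group=["x", "x"])
        with pytest.raises(ValueError, match="single level"):
            permanova(D, sheet, ["group"], n_perm=9, seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        D = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        sheet = _sheet_from(list(D.ids), group=["a"] * 5 + ["b"] * 5)
        p1 = permanova(D, sheet, ["group"], n_perm=199, seed=42).table["p_value"][0]
        p2 = permanova(D, sheet, ["group"], n_perm=199, seed=42).table["p_value"][0]
        assert p1 == p2


class TestMantel:
    def _random_dm(self, rng, n, ids=None):
        pts = rng.normal(size=(n, 3))
        return DistanceMatrix(squareform(pdist(pts)), ids=ids or [f"s{i}" for i in range(n)])

    def test_self_correlation_is_one(self):
        D = self._random_dm(np.random.default_rng(0), 10)
        rho, p = mantel(D, D, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_monotone_transform_preserves_spearman(self):
        D = self._random_dm(np.random.default_rng(1), 10)
        D2 = DistanceMatrix(np.sqrt(D.data), ids=list(D.ids))
        rho, _ = mantel(D, D2, method="spearman", n_perm=49, seed=0)
        assert rho == pytest.approx(1.0)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(2)
        D1 = self._random_dm(rng, 12)
        D2 = self._random_dm(rng, 12)
        rho_ours, p_ours = mantel(D1, D2, method="spearman", n_perm=999, seed=0)
        rho_skb, p_skb, _ = skbio_mantel(D1, D2, method="spearman", permutations=999)
        assert rho_ours == pytest.approx(rho_skb, abs=1e-9)
        assert abs(p_ours - p_skb) < 0.1  # both permutation estimates of the same p

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(3)
        ps = []
        for rep in range(200):
            D1 = self._random_dm(rng, 12)
            D2 = self._random_dm(rng, 12)
            ps.append(mantel(D1, D2, n_perm=199, seed=rep)[1])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_size_mismatch_rejected(self):
        D1 = self._random_dm(np.random.default_rng(0), 5)
        D2 = self._random_dm(np.random.default_rng(0), 6)
        with pytest.raises(ValueError):
            mantel(D1, D2)


class TestRankTests:
    def test_kendall_perfect_agreement(self):
        tau, _ = rank_tests([1, 2, 3], [1, 2, 3], "kendall")
        assert tau == pytest.approx(1.0)
        tau, _ = rank_tests([1, 2, 3], [3, 2, 1], "kendall")
        assert tau == pytest.approx(-1.0)

    def test_paired_wilcoxon_degenerate(self):
        stat, p = rank_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "wilcoxon_paired")
        assert p == 1.0

    def test_unpaired_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        _, p = rank_tests(a, b, "wilcoxon_unpaired")
        assert p < 1e-6

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            rank_tests([1], [1], "ttest")
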