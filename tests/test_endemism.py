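import numpy as np
import pandas as pd
import pytest

from phylloside.endemism import (
    endemism_degrees,
    endemism_regression,
    side_comparison,
    weighted_endemism,
)
from phylloside.tables import CountTable, SampleSheet


def _sheet(n_species, n_ind=1, sides=("upper", "lower")):
    rows = []
    for i in range(n_species):
        for k in range(n_ind):
            for side in sides:
                rows.append(
                    {
                        "sample_id": f"sp{i}_p{k}_{side}",
                        "plant_species": f"sp{i}",
                        "plant_individual": f"sp{i}_p{k}",
                        "leaf_side": side,
                        "ph": 6.0,
                        "stomatal_density": 0.0 if side == "upper" else 100.0,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


class TestDegrees:
    def test_ubiquitous_taxon_scores_zero(self):
        sheet = _sheet(4)
        ids = tuple(sheet.sample_ids)
        counts = np.ones((1, len(ids)), dtype=int)
        t = CountTable(("everywhere",), ids, counts)
        res = endemism_degrees(t, sheet)
        assert res.degrees["everywhere"] == 0.0

    def test_one_of_four_species_scores_three_quarters(self):
        sheet = _sheet(4)
        ids = tuple(sheet.sample_ids)
        counts = np.zeros((1, len(ids)), dtype=int)
        counts[0, 0] = 5  # sp0 upper
        counts[0, 1] = 3  # sp0 lower -> detected in 2 samples, 1 species
        t = CountTable(("restricted",), ids, counts)
        res = endemism_degrees(t, sheet)
        assert res.degrees["restricted"] == pytest.approx(0.75)

    def test_singleton_taxon_excluded(self):
        sheet = _sheet(3)
        ids = tuple(sheet.sample_ids)
        counts = np.zeros((2, len(ids)), dtype=int)
        counts[0, :] = 1
        counts[1, 2] = 9  # exactly one sample
        t = CountTable(("keep", "singleton"), ids, counts)
        res = endemism_degrees(t, sheet)
        assert "singleton" in res.excluded_taxa
        assert "singleton" not in res.degrees.index

    def test_single_species_rejected(self):
        sheet = _sheet(1)
        ids = tuple(sheet.sample_ids)
        t = CountTable(("a",), ids, np.ones((1, len(ids)), dtype=int))
        with pytest.raises(ValueError, match="species"):
            endemism_degrees(t, sheet)

    def test_invariant_to_sample_permutation(self):
        sheet = _sheet(3, n_ind=2)
        ids = list(sheet.sample_ids)
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(8, len(ids)))
        t = CountTable(tuple(f"t{i}" for i in range(8)), tuple(ids), counts)
        perm = rng.permutation(len(ids))
        t2 = CountTable(t.taxon_ids, tuple(np.asarray(ids)[perm]), counts[:, perm])
        r1 = endemism_degrees(t, sheet)
        r2 = endemism_degrees(t2, sheet)
        pd.testing.assert_series_equal(r1.degrees, r2.degrees)


class TestWeightedEndemism:
    def test_hand_example(self):
        sheet = _sheet(2)
        ids = tuple(sheet.sample_ids)
        # build W from explicit degrees: e_A = 0, e_B = 0.8
        t = CountTable(("A", "B"), ids, np.array([[5] * 4, [5] * 4]))
        e = pd.Series([0.0, 0.8], index=["A", "B"])
        W = weighted_endemism(t, e)
        assert np.allclose(W["W"], 0.4)

    def test_all_zero_degrees_give_zero_W(self):
        sheet = _sheet(2)
        ids = tuple(sheet.sample_ids)
        t = CountTable(("A", "B"), ids, np.array([[1] * 4, [2] * 4]))
        e = pd.Series([0.0, 0.0], index=["A", "B"])
        assert np.allclose(weighted_endemism(t, e)["W"], 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n_taxa, n_samp = 20, 6
            counts = rng.integers(0, 40, size=(n_taxa, n_samp))
            counts[:, counts.sum(axis=0) == 0] += 1
            t = CountTable(
                tuple(f"t{i}" for i in range(n_taxa)),
                tuple(f"s{j}" for j in range(n_samp)),
                counts,
            )
            e = pd.Series(rng.random(n_taxa), index=t.taxon_ids)
            W = weighted_endemism(t, e)["W"].to_numpy()
            # independent double loop
            expected = np.zeros(n_samp)
            for j in range(n_samp):
                tot = counts[:, j].sum()
                for i in range(n_taxa):
                    expected[j] += counts[i, j] / tot * e.iloc[i]
            assert np.allclose(W, expected, atol=1e-12)

    def test_W_bounded_by_max_degree(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 20, size=(10, 5))
        t = CountTable(
            tuple(f"t{i}" for i in range(10)), tuple(f"s{j}" for j in range(5)), counts
        )
        e = pd.Series(rng.random(10), index=t.taxon_ids)
        W = weighted_endemism(t, e)["W"]
        assert (W >= 0).all() and (W <= e.max() + 1e-12).all()

    def test_zero_W_gets_log_floor(self):
        sheet = _sheet(2)
        ids = tuple(sheet.sample_ids)
        counts = np.array([[5, 5, 5, 5], [0, 3, 3, 3]])
        t = CountTable(("ubiq", "rare"), ids, counts)
        e = pd.Series([0.0, 0.5], index=["ubiq", "rare"])
        W = weighted_endemism(t, e)
        assert W.loc[ids[0], "W"] == 0.0
        assert np.isfinite(W.loc[ids[0], "log_W"])


class TestRegression:
    def _W_frame(self, sheet, values):
        return pd.DataFrame(
            {"sample_id": list(sheet.sample_ids), "W": values, "log_W": np.log(values)}
        ).set_index("sample_id", drop=False)

    def test_planted_side_effect_sign(self):
        sheet = _sheet(12, n_ind=3)
        rng = np.random.default_rng(2)
        df = sheet.df.copy().reset_index(drop=True)
        df["stomatal_density"] += np.abs(rng.normal(0, 20, len(df)))  # break collinearity w/ side
        df["ph"] = rng.normal(6, 0.3, len(df))  # non-constant covariate
        sheet = SampleSheet(df)
        side = sheet.df["leaf_side"].to_numpy()
        w = np.where(side == "lower", 0.05, 0.02) * np.exp(rng.normal(0, 0.2, len(side)))
        res = endemism_regression(self._W_frame(sheet, w), sheet)
        # dummy coding: leaf_side_upper coefficient negative (upper lower-endemism)
        side_terms = [c for c in res.coefficients.index if str(c).startswith("leaf_side")]
        assert side_terms and res.coefficients[side_terms[0]] < 0

    def test_duplicate_covariate_detected(self):
        sheet = _sheet(6, n_ind=2)
        df = sheet.df.copy().reset_index(drop=True)
        df["ph_copy"] = df["ph"] + df["stomatal_density"] * 0  # constant within: collinear w/ ph
        sheet2 = SampleSheet(df)
        rng = np.random.default_rng(0)
        w = np.exp(rng.normal(-3, 0.3, len(df)))
        with pytest.raises(ValueError, match="collinear|rank"):
            endemism_regression(
                self._W_frame(sheet2, w), sheet2, terms=("ph", "ph_copy", "leaf_side")
            )

    def test_null_noise_mostly_reduces_to_intercept(self):
        # with 3 terms eliminated at alpha=0.05 each, ~0.95^3 ~ 86% of null fits
        # should end intercept-only; assert a conservative lower band
        sheet = _sheet(12, n_ind=3)
        rng = np.random.default_rng(6)
        n_kept = 0
        n_rep = 100
        for _ in range(n_rep):
            # covariates jittered so the design is full rank every draw
            df = sheet.df.copy().reset_index(drop=True)
            df["ph"] = rng.normal(6, 0.4, len(df))
            df["stomatal_density"] = np.abs(rng.normal(60, 30, len(df)))
            s = SampleSheet(df)
            w = np.exp(rng.normal(-3, 0.5, len(df)))
            res = endemism_regression(self._W_frame(s, w), s)
            if not res.final_terms:
                n_kept += 1
        assert n_kept / n_rep >= 0.78


class TestSideComparison:
    def test_equal_sides_give_p_one(self):
        sheet = _sheet(6, n_ind=2)
        w = np.full(len(sheet.df), 0.03)
        W = pd.DataFrame(
            {"sample_id": list(sheet.sample_ids), "W": w, "log_W": np.log(w)}
        ).set_index("sample_id", drop=False)
        res = side_comparison(W, sheet)
        assert res["p_value"] == 1.0

    def test_too_few_pairs_rejected(self):
        sheet = _sheet(3)
        w = np.linspace(0.01, 0.06, len(sheet.df))
        W = pd.DataFrame(
            {"sample_id": list(sheet.sample_ids), "W": w, "log_W": np.log(w)}
        ).set_index("sample_id", drop=False)
        with pytest.raises(ValueError, match="pairs"):
            side_comparison(W, sheet)

    def test_sign_flip_symmetry(self):
        sheet = _sheet(10, n_ind=2)
        rng = np.random.default_rng(8)
        base = np.exp(rng.normal(-3, 0.3, len(sheet.df) // 2))
        side = sheet.df["leaf_side"].to_numpy()
        w = np.empty(len(sheet.df))
        w[side == "lower"] = base * 1.5
        w[side == "upper"] = base
        def frame(values):
            return pd.DataFrame(
                {"sample_id": list(sheet.sample_ids), "W": values, "log_W": np.log(values)}
            ).set_index("sample_id", drop=False)
        p_fwd = side_comparison(frame(w), sheet, alternative="greater")["p_value"]
        # negate the differences by swapping the side values
        w_swapped = np.empty_like(w)
        w_swapped[side == "lower"] = base
        w_swapped[side == "upper"] = base * 1.5
        p_rev = side_comparison(frame(w_swapped), sheet, alternative="less")["p_value"]
        assert p_fwd == pytest.approx(p_rev, abs=1e-12)

    def test_planted_study_direction(self, small_study_rarefied, small_study):
        table, sheet, _ = small_study
        from phylloside.tables import filter_low_counts

        filtered, _ = filter_low_counts(table)
        e = endemism_degrees(filtered, sheet)
        W = weighted_endemism(filtered, e)
        res = side_comparison(W, sheet, alternative="greater")
        assert res["p_value"] < 0.05
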