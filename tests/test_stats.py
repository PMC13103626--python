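import math

import numpy as np
import pandas as pd
import pytest

from beehex.stats import (
    CandidateFit,
    adjusted_visitation,
    adjusted_visitation_table,
    aicc,
    fit_candidate_set,
    fruits_per_plant,
    germination_rate,
    model_selection_table,
    morph_frequency_table,
    soil_pca,
    spearman_fdr,
)


class TestAdjustedVisitation:
    def test_formula_arithmetic(self):
        assert adjusted_visitation(30, 60, 0.25) == pytest.approx(2.0)

    def test_full_availability_equals_raw_rate(self):
        assert adjusted_visitation(12, 60, 1.0) == pytest.approx(0.2)

    def test_zero_availability_flagged_missing(self):
        assert math.isnan(adjusted_visitation(5, 60, 0.0))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            adjusted_visitation(5, 0, 0.5)
        with pytest.raises(ValueError):
            adjusted_visitation(-1, 60, 0.5)
        with pytest.raises(ValueError):
            adjusted_visitation(5, 60, 1.5)

    def test_identity_recovers_raw_rate(self, rng):
        df = pd.DataFrame(
            {
                "population": ["P"] * 3,
                "morph": ["violet", "pink", "white"],
                "visits": rng.integers(0, 50, 3),
                "minutes": [60.0] * 3,
                "proportion": [0.5, 0.3, 0.2],
            }
        )
        out = adjusted_visitation_table(df)
        np.testing.assert_allclose(
            out["adjusted_rate"] * out["proportion"] * out["minutes"], out["visits"]
        )
        # summing raw per-morph rates recovers the census total rate
        assert out["raw_rate"].sum() == pytest.approx(df["visits"].sum() / 60.0)

    def test_zero_availability_rows_flagged_not_dropped(self):
        df = pd.DataFrame(
            {
                "population": ["P", "P"],
                "morph": ["violet", "white"],
                "visits": [10, 0],
                "minutes": [60.0, 60.0],
                "proportion": [1.0, 0.0],
            }
        )
        with pytest.warns(UserWarning, match="zero-availability"):
            out = adjusted_visitation_table(df)
        assert len(out) == 2
        assert out["flagged_missing"].tolist() == [False, True]


class TestFitnessSummaries:
    def test_fruits_product(self):
        assert fruits_per_plant(10, 3) == 30
        assert fruits_per_plant(10, 0) == 0

    def test_fruits_rounding_rule(self):
        assert fruits_per_plant(15.5, 2) == 31
        assert fruits_per_plant(15.4, 1) == 15
        assert fruits_per_plant(15.5, 1) == 16  # half rounds up

    def test_fruits_negative_rejected(self):
        with pytest.raises(ValueError):
            fruits_per_plant(-1, 2)

    def test_germination_examples(self):
        assert germination_rate([15, 30]) == pytest.approx(0.75)
        assert germination_rate([0]) == 0.0
        assert germination_rate([10, 20, 30]) == pytest.approx(2.0 / 3.0)

    def test_germination_bounds(self):
        with pytest.raises(ValueError):
            germination_rate([31])
        with pytest.raises(ValueError):
            germination_rate([])


class TestAicc:
    def test_closed_form(self):
        assert aicc(-100.0, 6, 45) == pytest.approx(212.0 + 84.0 / 38.0)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 6, 10**9) == pytest.approx(212.0, abs=1e-5)

    def test_boundary_n(self):
        aicc(-10.0, 2, 4)  # n = k + 2 is allowed
        with pytest.raises(ValueError):
            aicc(-10.0, 2, 3)  # n = k + 1 is not

    def test_always_exceeds_aic(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 10))
            n = int(rng.integers(k + 2, 200))
            ll = float(rng.normal(-50, 20))
            assert aicc(ll, k, n) > -2 * ll + 2 * k


class TestModelSelectionTable:
    def test_two_model_weights_closed_form(self):
        # deltas {0, 2}: weights 1/(1+e^-1) and e^-1/(1+e^-1)
        cands = [
            CandidateFit("a", "gaussian", -50.0, 2, 100),
            CandidateFit("b", "gaussian", -51.0, 2, 100),
        ]
        out = model_selection_table(cands)
        assert out["delta_aicc"].tolist() == pytest.approx([0.0, 2.0])
        assert out["weight"].iloc[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-4)
        assert out["weight"].iloc[1] == pytest.approx(
            math.exp(-1) / (1 + math.exp(-1)), abs=1e-4
        )

    def test_single_candidate_weight_one(self):
        out = model_selection_table([CandidateFit("only", "poisson", -10.0, 2, 50)])
        assert out["weight"].iloc[0] == pytest.approx(1.0)

    def test_differing_n_rejected(self):
        with pytest.raises(ValueError, match="differing n"):
            model_selection_table(
                [
                    CandidateFit("a", "gaussian", -50.0, 2, 100),
                    CandidateFit("b", "gaussian", -50.0, 2, 99),
                ]
            )

    def test_five_candidates_match_arithmetic_oracle(self):
        lls = [-120.0, -116.5, -115.0, -114.2, -113.9]
        ks = [2, 4, 6, 8, 15]
        n = 60
        cands = [
            CandidateFit(f"m{i}", "gaussian", ll, k, n)
            for i, (ll, k) in enumerate(zip(lls, ks))
        ]
        out = model_selection_table(cands)
        # independent spreadsheet-style recomputation
        aiccs = [
            -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1) for ll, k in zip(lls, ks)
        ]
        deltas = [a - min(aiccs) for a in aiccs]
        rels = [math.exp(-d / 2) for d in deltas]
        weights = {f"m{i}": r / sum(rels) for i, r in enumerate(rels)}
        for _, row in out.iterrows():
            assert row["weight"] == pytest.approx(weights[row["model"]], abs=1e-12)
        assert out["weight"].sum() == pytest.approx(1.0)
        assert out["delta_aicc"].min() == 0.0
        assert out["aicc"].is_monotonic_increasing

    def test_weights_invariant_to_loglik_shift(self):
        cands = [
            CandidateFit("a", "gaussian", -50.0, 3, 80),
            CandidateFit("b", "gaussian", -48.0, 5, 80),
        ]
        shifted = [
            CandidateFit(c.model, c.family, c.log_likelihood + 17.3, c.k, c.n)
            for c in cands
        ]
        w0 = model_selection_table(cands)["weight"]
        w1 = model_selection_table(shifted)["weight"]
        np.testing.assert_allclose(w0, w1)


def _panel(rng, n_per=45, pops=("A", "B", "C", "D", "E")):
    rows = []
    for pop in pops:
        for _ in range(n_per):
            rows.append({"population": pop, "morph": rng.choice(["violet", "pink", "white"])})
    return pd.DataFrame(rows)


class TestFitCandidateSet:
    def test_population_effect_recovered(self):
        # small panels keep the AICc correction honest about junk params
        rng = np.random.default_rng(0)
        wins = 0
        reps = 100
        effects = {"A": 0.0, "B": 3.0, "C": -2.0, "D": 5.0, "E": 1.0}
        for _ in range(reps):
            df = _panel(rng, n_per=6)
            df["y"] = df["population"].map(effects) + rng.normal(0, 1, len(df))
            table = model_selection_table(fit_candidate_set(df, "y", "gaussian"))
            wins += table.iloc[0]["model"] == "population"
        assert wins >= 0.9 * reps

    def test_pure_noise_keeps_null_plausible(self, rng):
        hits = 0
        reps = 30
        for _ in range(reps):
            df = _panel(rng)
            df["y"] = rng.normal(0, 1, len(df))
            table = model_selection_table(fit_candidate_set(df, "y", "gaussian"))
            null_delta = float(
                table.loc[table["model"] == "null", "delta_aicc"].iloc[0]
            )
            hits += null_delta < 2.0
        assert hits >= 0.8 * reps

    def test_interaction_structure_recovered_for_rates(self, rng):
        wins = 0
        reps = 20
        for _ in range(reps):
            df = _panel(rng, n_per=60)
            base = {"A": 0.3, "B": 1.2, "C": 0.5, "D": 2.0, "E": 0.8}
            mu = df["population"].map(base).to_numpy()
            flip = ((df["morph"] == "pink") & df["population"].isin(["A", "D"])).to_numpy()
            mu = np.where(flip, mu * 4.0, mu)
            df["rate"] = rng.gamma(shape=8.0, scale=mu / 8.0)
            table = model_selection_table(fit_candidate_set(df, "rate", "gamma-log"))
            wins += table.iloc[0]["model"] == "interaction"
        assert wins >= 0.7 * reps

    def test_single_level_factor_excluded(self, rng):
        df = _panel(rng, pops=("A",))
        df["morph"] = "violet"
        df["y"] = rng.normal(0, 1, len(df))
        with pytest.warns(UserWarning, match="non-estimable"):
            fits = fit_candidate_set(df, "y", "gaussian")
        assert {f.model for f in fits} == {"null"}

    def test_missing_response_rows_dropped_with_warning(self, rng):
        df = _panel(rng)
        df["y"] = rng.normal(0, 1, len(df))
        df.loc[df.index[:10], "y"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            fits = fit_candidate_set(df, "y", "gaussian")
        assert all(f.n == len(df) - 10 for f in fits)

    def test_binomial_family_requires_failures(self, rng):
        df = _panel(rng)
        df["succ"] = rng.integers(0, 30, len(df))
        df["fail"] = 30 - df["succ"]
        fits = fit_candidate_set(df, "succ", "binomial", failures="fail")
        assert len(fits) == 5

    def test_k_counts_dispersion_where_estimated(self, rng):
        df = _panel(rng)
        df["y"] = rng.poisson(5.0, len(df)).astype(float)
        by_family = {}
        for fam in ("gaussian", "poisson", "negative binomial"):
            fits = fit_candidate_set(df, "y", fam)
            by_family[fam] = {f.model: f.k for f in fits}
        assert by_family["gaussian"]["null"] == 2  # intercept + variance
        assert by_family["poisson"]["null"] == 1
        assert by_family["negative binomial"]["null"] == 2


class TestSpearmanFdr:
    def test_perfect_monotone_pair(self):
        soil = pd.DataFrame({"ph": [4.0, 5.0, 6.0, 7.0, 8.0]})
        freq = pd.DataFrame({"violet": [0.1, 0.2, 0.3, 0.4, 0.5]})
        out = spearman_fdr(soil, freq)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_identical_raw_p_share_adjusted_value(self):
        soil = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        )
        freq = pd.DataFrame({"violet": [4.0, 3.0, 2.0, 1.0]})
        out = spearman_fdr(soil, freq)
        assert out["p_value"].nunique() == 1
        assert out["p_adjusted"].nunique() == 1
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()

    def test_against_rank_and_enumerate_oracle(self, rng):
        soil = pd.DataFrame(rng.normal(size=(5, 3)), columns=["w", "ph", "c"])
        freq = pd.DataFrame(rng.uniform(size=(5, 2)), columns=["violet", "pink"])
        out = spearman_fdr(soil, freq)

        def rank(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            r = [0.0] * len(v)
            for pos, i in enumerate(order):
                r[i] = pos + 1.0
            return r

        oracle_rho = {}
        for var in soil.columns:
            for m in freq.columns:
                rx, ry = rank(list(soil[var])), rank(list(freq[m]))
                mx, my = sum(rx) / 5, sum(ry) / 5
                num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
                den = math.sqrt(
                    sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
                )
                oracle_rho[(var, m)] = num / den
        for _, row in out.iterrows():
            assert row["rho"] == pytest.approx(
                oracle_rho[(row["soil_variable"], row["morph"])], abs=1e-12
            )
        # BH step-up oracle
        ps = list(out["p_value"])
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        adj = [0.0] * m
        prev = 1.0
        for rank_pos in range(m, 0, -1):
            i = order[rank_pos - 1]
            prev = min(prev, ps[i] * m / rank_pos)
            adj[i] = prev
        np.testing.assert_allclose(out["p_adjusted"], adj, atol=1e-12)

    def test_bh_monotone_after_sorting_by_raw_p(self, rng):
        soil = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        freq = pd.DataFrame(rng.uniform(size=(6, 3)), columns=["v", "p", "w"])
        out = spearman_fdr(soil, freq).sort_values("p_value")
        assert out["p_adjusted"].is_monotonic_increasing

    def test_constant_variable_flagged(self):
        soil = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]})
        freq = pd.DataFrame({"violet": [0.1, 0.2, 0.3, 0.4]})
        out = spearman_fdr(soil, freq)
        assert out["flagged_constant"].iloc[0]
        assert math.isnan(out["rho"].iloc[0])

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman_fdr(pd.DataFrame({"a": [1.0, 2.0]}), pd.DataFrame({"v": [1.0, 2.0]}))


class TestSoilPca:
    def test_perfectly_correlated_pair_gives_pc1_everything(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        loadings, props = soil_pca(df)
        assert props[0] == pytest.approx(1.0)
        assert props.sum() == pytest.approx(1.0)

    def test_uncorrelated_variables_share_variance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(3000, 4)), columns=list("abcd"))
        _, props = soil_pca(df)
        np.testing.assert_allclose(props, 0.25, atol=0.05)

    def test_proportions_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 5)), columns=list("abcde"))
        _, props = soil_pca(df)
        assert props.sum() == pytest.approx(1.0)
        assert np.all(np.diff(props) <= 1e-12)  # ordered by decreasing variance

    def test_sign_convention(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        loadings, _ = soil_pca(df)
        for col in loadings.columns:
            v = loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            soil_pca(df)


class TestMorphFrequencyTable:
    def test_printed_percentages(self):
        plants = pd.DataFrame(
            {
                "population": ["G1"] * 100,
                "morph": ["violet"] * 27 + ["pink"] * 43 + ["white"] * 30,
            }
        )
        out = morph_frequency_table(plants).set_index("population")
        assert out.loc["G1", "violet_pct"] == pytest.approx(27.0)
        assert out.loc["G1", "pink_pct"] == pytest.approx(43.0)
        assert out.loc["G1", "white_pct"] == pytest.approx(30.0)

    def test_single_morph_is_100pct(self):
        plants = pd.DataFrame({"population": ["P"] * 5, "morph": ["violet"] * 5})
        out = morph_frequency_table(plants)
        assert out["violet_pct"].iloc[0] == pytest.approx(100.0)

    def test_unlabeled_counted_as_unknown(self):
        plants = pd.DataFrame({"population": ["P", "P"], "morph": ["violet", None]})
        out = morph_frequency_table(plants)
        assert out["unknown"].iloc[0] == 1

    def test_empty_population_zero_row_with_warning(self):
        plants = pd.DataFrame({"population": ["P"], "morph": ["violet"]})
        with pytest.warns(UserWarning, match="no plants"):
            out = morph_frequency_table(plants, populations=["P", "Q"])
        q = out.set_index("population").loc["Q"]
        assert q["n_plants"] == 0
        assert q["violet_pct"] == 0.0
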