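"""REML fits: oracle agreement, parameter recovery, LRT, ANOVA, BLUPs."""

import numpy as np
import pandas as pd
import pytest

from provsel.exceptions import DesignError, ParameterError
from provsel.mixed_models import (
    MetFit,
    SiteFit,
    anova_fixed,
    fit_met_model,
    fit_site_model,
    lrt_random_effect,
    significance_stars,
    variance_proportions,
)
from provsel.simulate import TrialDataset, simulate_met

from conftest import make_design, one_trait_params


def _small_site_data(seed=0, n_prov=12, n_blocks=3, n_trees=6, v_p=4.0,
                     v_pb=0.0, v_r=9.0, blocks=(0.0, 2.0, -1.0)):
    design = make_design(n_prov, n_sites=1, n_blocks=n_blocks, n_trees=n_trees)
    params = one_trait_params(
        grand_mean=20.0, v_p=v_p, v_pb=v_pb, v_r=v_r,
        block_effects=tuple(blocks[:n_blocks]),
    )
    return simulate_met(design, params, seed=seed)


class TestSiteModelAgainstStatsmodels:
    """Independent oracle: statsmodels MixedLM random-intercept REML."""

    def test_variance_components_match(self):
        sm = pytest.importorskip("statsmodels.formula.api")
        data = _small_site_data(seed=1)
        ours = fit_site_model(data, "Y", exclude=("provenance:block",))
        md = sm.mixedlm("Y ~ C(block)", data.data,
                        groups=data.data["provenance"])
        ref = md.fit(reml=True)
        assert ours.v_p == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert ours.v_r == pytest.approx(float(ref.scale), rel=1e-3)
        ref_blups = pd.Series(
            {k: float(v.iloc[0]) for k, v in ref.random_effects.items()}
        ).sort_index()
        assert np.allclose(ours.blups.sort_index(), ref_blups, rtol=1e-3,
                           atol=1e-6)

    def test_fixed_effects_match(self):
        sm = pytest.importorskip("statsmodels.formula.api")
        data = _small_site_data(seed=2)
        ours = fit_site_model(data, "Y", exclude=("provenance:block",))
        md = sm.mixedlm("Y ~ C(block)", data.data,
                        groups=data.data["provenance"])
        ref = md.fit(reml=True)
        assert ours.fixed_effects.iloc[0] == pytest.approx(
            ref.fe_params.iloc[0], rel=1e-4)
        assert np.allclose(np.sort(ours.fixed_effects.iloc[1:]),
                           np.sort(ref.fe_params.iloc[1:]), rtol=1e-3,
                           atol=1e-6)


class TestSiteModelRecovery:
    def test_recovers_truth_within_15_percent(self, site_recovery):
        truth, fit = site_recovery
        assert abs(fit.v_p / truth["v_p"] - 1.0) < 0.15
        assert abs(fit.v_r / truth["v_r"] - 1.0) < 0.15

    def test_zero_provenance_variance_pins_boundary(self):
        """With true V_p = 0 the REML estimate sits at the boundary in a
        large share of replicates."""
        at_zero = 0
        n_rep = 20
        for rep in range(n_rep):
            data = _small_site_data(seed=100 + rep, n_prov=15, n_blocks=2,
                                    n_trees=3, v_p=0.0, v_r=4.0,
                                    blocks=(0.0, 0.0))
            fit = fit_site_model(data, "Y")
            if fit.v_p < 1e-6:
                at_zero += 1
        assert at_zero >= 0.4 * n_rep

    def test_duplicating_every_row_keeps_estimates(self):
        """Duplication only perturbs REML through per-plot residual df
        ((2n-2)/(2n-1)); at 25 trees per plot that is ~2%."""
        data = _small_site_data(seed=3, n_prov=8, n_trees=25)
        fit = fit_site_model(data, "Y")
        df2 = pd.concat([data.data, data.data]).reset_index(drop=True)
        df2["tree"] = [f"T{i}" for i in range(len(df2))]
        fit2 = fit_site_model(TrialDataset(df2, ("Y",)), "Y")
        assert fit2.v_p == pytest.approx(fit.v_p, rel=0.05, abs=1e-3)
        assert fit2.v_r == pytest.approx(fit.v_r, rel=0.05)

    def test_blups_sum_to_zero_and_shrink(self):
        data = _small_site_data(seed=4)
        fit = fit_site_model(data, "Y")
        sd = float(data.data["Y"].std())
        assert abs(fit.blups.sum()) < 1e-6 * fit.n_obs * sd
        # shrinkage: |BLUP| never exceeds the raw mean deviation
        raw = data.data.groupby("provenance")["Y"].mean()
        dev = raw - raw.mean()
        assert (fit.blups.abs() <= dev.abs() + 1e-8).all()

    def test_design_errors(self):
        data = _small_site_data(seed=5, n_prov=1)
        with pytest.raises(DesignError, match="provenance"):
            fit_site_model(data, "Y")
        multi = simulate_met(
            make_design(4, n_sites=2, n_blocks=2, n_trees=2),
            one_trait_params(grand_mean=0.0, v_r=1.0), seed=0,
        )
        with pytest.raises(DesignError, match="single site"):
            fit_site_model(multi, "Y")


class TestMetModel:
    def test_recovers_truth_within_15_percent(self, met_recovery):
        truth, fit = met_recovery
        assert abs(fit.v_p / truth["v_p"] - 1.0) < 0.15
        assert abs(fit.v_ge / truth["v_ge"] - 1.0) < 0.15
        assert abs(fit.v_r / truth["v_r"] - 1.0) < 0.15

    def test_zero_interaction_shrinks_theta(self):
        """V_ge = 0 truth: every interaction BLUP is tiny relative to the
        residual SD."""
        design = make_design(100, n_sites=3, n_blocks=2, n_trees=5)
        params = one_trait_params(grand_mean=10.0, v_p=2.0, v_ge=0.0, v_r=4.0)
        data = simulate_met(design, params, seed=6)
        fit = fit_met_model(data, "Y")
        assert (fit.interaction_blups.abs().to_numpy()
                < 0.05 * np.sqrt(fit.v_r)).all()

    def test_theta_zero_rows_for_unobserved_pairs(self, default_data):
        fit = fit_met_model(
            default_data, "DBH",
            analysis_set=default_data.data["provenance"].unique(),
        )
        present = default_data.data.groupby("provenance")["site"].agg(set)
        for prov, sites in present.items():
            absent = [s for s in fit.interaction_blups.columns
                      if s not in sites]
            for s in absent:
                assert fit.interaction_blups.loc[prov, s] == 0.0

    def test_record_order_invariance(self):
        design = make_design(8, n_sites=2, n_blocks=2, n_trees=3)
        params = one_trait_params(grand_mean=10.0, v_p=2.0, v_ge=1.0, v_r=4.0)
        data = simulate_met(design, params, seed=7)
        fit = fit_met_model(data, "Y")
        shuffled = TrialDataset(
            data.data.sample(frac=1.0, random_state=0).reset_index(drop=True),
            data.traits,
        )
        fit2 = fit_met_model(shuffled, "Y")
        assert fit2.v_p == pytest.approx(fit.v_p, rel=1e-4, abs=1e-8)
        assert fit2.v_ge == pytest.approx(fit.v_ge, rel=1e-4, abs=1e-8)
        assert np.allclose(fit2.blups, fit.blups, rtol=1e-4, atol=1e-8)

    def test_label_recoding_invariance(self):
        data = _small_site_data(seed=8)
        fit = fit_site_model(data, "Y")
        renamed = data.data.copy()
        renamed["provenance"] = "zz_" + renamed["provenance"]
        fit2 = fit_site_model(TrialDataset(renamed, ("Y",)), "Y")
        assert fit2.v_p == pytest.approx(fit.v_p, rel=1e-4, abs=1e-8)
        assert np.allclose(fit2.blups.to_numpy(), fit.blups.to_numpy(),
                           rtol=1e-4, atol=1e-8)

    def test_single_site_rejected(self):
        data = _small_site_data(seed=9)
        with pytest.raises(DesignError, match="2 sites"):
            fit_met_model(data, "Y")

    def test_empty_analysis_set_rejected(self, default_data):
        with pytest.raises(ParameterError, match="empty"):
            fit_met_model(default_data, "DBH", analysis_set=[])


class TestLrt:
    def test_null_case(self):
        r = lrt_random_effect(-100.0, -100.0, df=1)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_chi_square_quantile(self):
        r = lrt_random_effect(-10.0, -10.0 - 3.841 / 2.0, df=1)
        assert r.p_value == pytest.approx(0.050, abs=5e-4)

    def test_large_statistic_flags_significant(self):
        r = lrt_random_effect(0.0, -23.16 / 2.0, df=1)
        assert r.p_value < 0.001 and r.stars() == "***"

    def test_df_validation(self):
        with pytest.raises(ParameterError):
            lrt_random_effect(0.0, 0.0, df=0)

    def test_p_monotone_in_statistic(self):
        stats_ = [lrt_random_effect(s / 2.0, 0.0, df=1).p_value
                  for s in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(stats_, stats_[1:]))

    def test_full_loglik_never_below_reduced(self):
        """Adding a random term with positive true variance cannot lower the
        restricted likelihood (nested optimisation)."""
        ok = 0
        n_rep = 100
        for rep in range(n_rep):
            data = _small_site_data(seed=200 + rep, n_prov=10, n_blocks=2,
                                    n_trees=2, v_p=2.0, v_r=1.0,
                                    blocks=(0.0, 0.0))
            full = fit_site_model(data, "Y", exclude=("provenance:block",))
            red = fit_site_model(
                data, "Y", exclude=("provenance", "provenance:block"))
            if full.loglik >= red.loglik - 1e-6:
                ok += 1
        assert ok >= 95


def _stub_site_fit(v_p, v_r, v_pb=0.0):
    return SiteFit(
        trait="t", site="s", v_p=v_p, v_pb=v_pb, v_r=v_r,
        fixed_effects=pd.Series(dtype=float), loglik=0.0,
        blups=pd.Series(dtype=float), n_obs=0, fixed_mean=0.0,
    )


def _stub_met_fit(v_p, v_ge, v_r):
    return MetFit(
        trait="t", v_p=v_p, v_ge=v_ge, v_r=v_r,
        fixed_effects=pd.Series(dtype=float), loglik=0.0,
        blups=pd.Series(dtype=float), interaction_blups=pd.DataFrame(),
        n_obs=0, fixed_mean=0.0,
    )


class TestVarianceProportions:
    @pytest.mark.parametrize(
        "v_p,v_r,expected_pct",
        [(7.23, 60.77, 10.63), (3.36, 19.68, 14.58), (2.87, 56.16, 4.86),
         (1.73, 12.05, 12.55), (1.59, 15.29, 9.42), (1.93, 50.89, 3.65)],
    )
    def test_site_provenance_share(self, v_p, v_r, expected_pct):
        props = variance_proportions(_stub_site_fit(v_p, v_r))
        assert round(100.0 * props["provenance"], 2) == expected_pct
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_met_shares_integer_rounding(self):
        props = variance_proportions(_stub_met_fit(3.53, 3.91, 5.69))
        pct = {k: round(100.0 * v) for k, v in props.items()}
        assert pct == {"provenance": 27, "provenance:site": 30, "residual": 43}

    def test_single_nonzero_component(self):
        props = variance_proportions(_stub_site_fit(0.0, 5.0))
        assert props["residual"] == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ParameterError):
            variance_proportions(_stub_site_fit(0.0, 0.0))


class TestAnovaFixed:
    def test_null_blocks_rarely_significant(self):
        """Zero block effects: the block F test keeps its nominal size."""
        nonsig = 0
        n_rep = 30
        for rep in range(n_rep):
            data = _small_site_data(seed=300 + rep, n_prov=12, n_blocks=3,
                                    n_trees=4, v_p=2.0, v_r=6.0,
                                    blocks=(0.0, 0.0, 0.0))
            fit = fit_site_model(data, "Y")
            table = anova_fixed(fit).table
            if table.loc["block", "p_value"] > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_rep

    def test_duplicated_block_has_zero_ms(self):
        data = _small_site_data(seed=10, n_prov=6, n_blocks=2, n_trees=4,
                                blocks=(0.0, 0.0))
        df = data.data.copy()
        b1 = df[df["block"] == "B1"]
        df.loc[df["block"] == "B2", "Y"] = b1["Y"].to_numpy()
        fit = fit_site_model(TrialDataset(df, ("Y",)), "Y")
        table = anova_fixed(fit).table
        assert table.loc["block", "ms"] == pytest.approx(0.0, abs=1e-9)

    def test_large_site_offsets_flagged(self):
        design = make_design(10, n_sites=3, n_blocks=2, n_trees=5)
        params = one_trait_params(
            grand_mean=10.0,
            site_effects={"S1": -8.0, "S2": 0.0, "S3": 8.0},
            v_p=1.0, v_ge=0.5, v_r=2.0,
        )
        data = simulate_met(design, params, seed=12)
        fit = fit_met_model(data, "Y")
        table = anova_fixed(fit).table
        assert table.loc["site", "stars"] == "***"

    def test_star_mapping(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"
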