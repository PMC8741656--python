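"""Twin correlations, Falconer estimates, and ACE model fitting/selection."""

import numpy as np
import pandas as pd
import pytest

from netreliance import (
    AceModel,
    SimConfig,
    TraitSpec,
    aic,
    compare_models,
    falconer,
    heritability_report,
    simulate_twin_traits,
    twin_correlations,
)
from netreliance.errors import ConfigurationError
from netreliance.heritability import AceFit, pair_table

# Published twin-model comparison for network reliance (10 networks x 4
# models): (network, model, minus2LL, df, AIC) — used to pin down the
# AIC = minus2LL - 2*df bookkeeping convention.
PUBLISHED_MODEL_TABLE = [
    ("AUD", "ACE", 996.79, 395, 206.79), ("AUD", "AE", 996.80, 396, 204.80),
    ("AUD", "CE", 996.80, 396, 204.80), ("AUD", "E", 997.28, 397, 203.28),
    ("CING", "ACE", 1137.35, 395, 347.35), ("CING", "AE", 1137.55, 396, 345.55),
    ("CING", "CE", 1137.40, 396, 345.40), ("CING", "E", 1141.35, 397, 347.35),
    ("DAN", "ACE", 960.80, 395, 170.80), ("DAN", "AE", 960.81, 396, 168.81),
    ("DAN", "CE", 961.08, 396, 169.08), ("DAN", "E", 964.75, 397, 170.75),
    ("DMN", "ACE", 1811.11, 395, 1021.11), ("DMN", "AE", 1811.13, 396, 1019.13),
    ("DMN", "CE", 1811.30, 396, 1019.30), ("DMN", "E", 1815.23, 397, 1021.23),
    ("FPN", "ACE", 1322.36, 395, 532.36), ("FPN", "AE", 1327.02, 396, 535.02),
    ("FPN", "CE", 1329.61, 396, 537.61), ("FPN", "E", 1330.79, 397, 536.79),
    ("SMN", "ACE", 1821.84, 395, 1031.84), ("SMN", "AE", 1822.48, 396, 1030.48),
    ("SMN", "CE", 1823.00, 396, 1031.00), ("SMN", "E", 1823.54, 397, 1029.54),
    ("SN", "ACE", 1146.22, 395, 356.22), ("SN", "AE", 1146.48, 396, 354.48),
    ("SN", "CE", 1146.50, 396, 354.50), ("SN", "E", 1146.50, 397, 352.50),
    ("SUB", "ACE", 778.22, 395, -11.78), ("SUB", "AE", 778.22, 396, -13.78),
    ("SUB", "CE", 778.22, 396, -13.78), ("SUB", "E", 778.39, 397, -15.61),
    ("VAN", "ACE", 726.57, 395, -63.43), ("VAN", "AE", 728.98, 396, -63.02),
    ("VAN", "CE", 727.99, 396, -64.01), ("VAN", "E", 729.83, 397, -64.17),
    ("VIS", "ACE", 1696.06, 395, 906.06), ("VIS", "AE", 1696.82, 396, 904.82),
    ("VIS", "CE", 1697.30, 396, 905.30), ("VIS", "E", 1697.62, 397, 903.62),
]


def _twin_cohort(mz, dz):
    rows = []
    for zyg, pairs in (("MZ", mz), ("DZ", dz)):
        for i, (a, b) in enumerate(pairs):
            fam = f"{zyg}{i}"
            rows.append({"subject_id": f"{fam}_A", "family_id": fam,
                         "zygosity": zyg, "t": a})
            rows.append({"subject_id": f"{fam}_B", "family_id": fam,
                         "zygosity": zyg, "t": b})
    return pd.DataFrame(rows)


def _simulated_pairs(a2, c2, e2, n_pairs, seed):
    spec = TraitSpec.from_ace("t", a2, c2, e2)
    cfg = SimConfig(n_mz_pairs=n_pairs, n_dz_pairs=n_pairs, trait_specs=(spec,),
                    trait_correlations=np.array([[1.0]]), seed=seed)
    return simulate_twin_traits(cfg)


class TestTwinCorrelations:
    def test_identical_twins_give_unit_correlation(self, rng):
        vals = rng.normal(size=20)
        cohort = _twin_cohort(list(zip(vals, vals)),
                              list(zip(rng.normal(size=5), rng.normal(size=5))))
        tc = twin_correlations("t", cohort)
        assert tc.r_mz == pytest.approx(1.0)
        assert tc.n_mz_pairs == 20 and tc.n_dz_pairs == 5

    def test_independent_twins_near_zero(self, rng):
        pairs = list(zip(rng.normal(size=2000), rng.normal(size=2000)))
        tc = twin_correlations("t", _twin_cohort(pairs, pairs))
        assert abs(tc.r_mz) < 0.05 and abs(tc.r_dz) < 0.05

    def test_generative_recovery_at_target(self):
        cohort = _simulated_pairs(0.62, 0.19, 0.19, 1000, seed=4)
        tc = twin_correlations("t", cohort)
        assert tc.r_mz == pytest.approx(0.81, abs=0.04)

    def test_double_entry_is_order_invariant(self, rng):
        pairs = list(zip(rng.normal(size=30), rng.normal(size=30)))
        swapped = [(b, a) for a, b in pairs]
        r1 = twin_correlations("t", _twin_cohort(pairs, pairs)).r_mz
        r2 = twin_correlations("t", _twin_cohort(swapped, pairs)).r_mz
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_pairs_rejected(self, rng):
        cohort = _twin_cohort([(0.0, 1.0)],
                              list(zip(rng.normal(size=5), rng.normal(size=5))))
        with pytest.raises(ConfigurationError, match="pairs"):
            twin_correlations("t", cohort)

    def test_incomplete_pairs_dropped(self, rng):
        cohort = _twin_cohort(list(zip(rng.normal(size=6), rng.normal(size=6))),
                              list(zip(rng.normal(size=6), rng.normal(size=6))))
        cohort.loc[cohort.subject_id == "MZ0_B", "t"] = np.nan
        tc = twin_correlations("t", cohort)
        assert tc.n_mz_pairs == 5


class TestFalconer:
    @pytest.mark.parametrize("rmz, rdz, expected", [
        (0.81, 0.22, 1.18),   # common EF factor
        (0.65, 0.31, 0.68),   # updating-specific factor
        (0.5, 0.5, 0.0),
        (0.12, 0.18, -0.12),  # negative estimates reported as-is
    ])
    def test_printed_values(self, rmz, rdz, expected):
        assert falconer(rmz, rdz) == pytest.approx(expected, abs=1e-12)

    def test_no_clipping_above_one(self):
        assert falconer(0.9, -0.3) == pytest.approx(2.4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            falconer(1.2, 0.0)


class TestAic:
    @pytest.mark.parametrize("m2ll, df, expected", [
        (996.79, 395, 206.79),
        (996.80, 396, 204.80),
        (0.0, 0, 0.0),
    ])
    def test_convention(self, m2ll, df, expected):
        assert aic(m2ll, df) == pytest.approx(expected)

    def test_reproduces_all_published_cells(self):
        for net, model, m2ll, df, aic_val in PUBLISHED_MODEL_TABLE:
            assert aic(m2ll, df) == pytest.approx(aic_val, abs=0.005), (net, model)


class TestAceModel:
    def test_e_model_matches_closed_form(self, rng):
        cohort = _simulated_pairs(0.4, 0.2, 0.4, 200, seed=9)
        model = AceModel.from_cohort(cohort, "t")
        closed = model.fit_e_closed_form()
        optimized = model.fit("E")
        assert optimized.minus2ll == pytest.approx(closed.minus2ll, abs=1e-6)
        assert optimized.e2 == pytest.approx(closed.e2, rel=1e-4)

    def test_parameter_recovery(self):
        cohort = _simulated_pairs(0.6, 0.2, 0.2, 2000, seed=10)
        fit = AceModel.from_cohort(cohort, "t").fit("ACE")
        assert fit.a2 == pytest.approx(0.6, abs=0.08)
        assert fit.c2 == pytest.approx(0.2, abs=0.08)
        assert fit.e2 == pytest.approx(0.2, abs=0.05)

    def test_likelihood_nesting_holds(self, rng):
        for seed in (1, 2):
            cohort = _simulated_pairs(0.3, 0.3, 0.4, 150, seed=seed)
            comp = AceModel.from_cohort(cohort, "t").fit_all()
            ace = comp["ACE"].minus2ll
            for m in ("AE", "CE", "E"):
                assert comp[m].minus2ll >= ace - 1e-6

    def test_uncorrelated_twins_favor_e(self, rng):
        pairs = list(zip(rng.normal(size=300), rng.normal(size=300)))
        comp = AceModel.from_cohort(_twin_cohort(pairs, pairs), "t").fit_all()
        assert comp["ACE"].a2 < 0.1 and comp["ACE"].c2 < 0.1
        assert comp["E"].minus2ll - comp["ACE"].minus2ll < 2 * 3.84

    def test_scale_equivariance(self):
        cohort = _simulated_pairs(0.5, 0.2, 0.3, 300, seed=12)
        scaled = cohort.copy()
        scaled["t"] = scaled["t"] * 3.0
        c1 = AceModel.from_cohort(cohort, "t").fit_all()
        c2 = AceModel.from_cohort(scaled, "t").fit_all()
        for m in ("ACE", "AE", "CE", "E"):
            np.testing.assert_allclose(c2[m].standardized(),
                                       c1[m].standardized(), atol=2e-3)
            if m != "ACE":
                assert c2[m].comparison_p == pytest.approx(
                    c1[m].comparison_p, abs=2e-3)

    def test_zero_variance_trait_rejected(self):
        cohort = _twin_cohort([(1.0, 1.0)] * 10, [(1.0, 1.0)] * 10)
        with pytest.raises(ConfigurationError, match="variance"):
            AceModel.from_cohort(cohort, "t")

    def test_unknown_model_rejected(self):
        cohort = _simulated_pairs(0.5, 0.2, 0.3, 50, seed=1)
        with pytest.raises(ConfigurationError, match="unknown model"):
            AceModel.from_cohort(cohort, "t").fit("ADE")


class TestCompareModels:
    def _fit(self, model, m2ll, n_params, n_obs=400):
        df = n_obs - n_params
        return AceFit(model=model, a2=0.3, c2=0.2, e2=0.5, mean=0.0,
                      minus2ll=m2ll, n_obs=n_obs, n_params=n_params,
                      df=df, aic=aic(m2ll, df))

    def test_equal_likelihood_prefers_nested_by_aic(self):
        comp = compare_models([self._fit("ACE", 100.0, 4),
                               self._fit("AE", 100.0, 3)])
        assert comp["AE"].comparison_p == pytest.approx(1.0)
        assert comp.selected == "AE"

    def test_boundary_chi_square(self):
        comp = compare_models([self._fit("ACE", 100.0, 4),
                               self._fit("AE", 103.84, 3)])
        assert comp["AE"].comparison_p == pytest.approx(0.05, abs=5e-4)

    def test_all_nested_significant_selects_ace(self):
        comp = compare_models([
            self._fit("ACE", 1322.36, 4),
            self._fit("AE", 1327.02, 3),   # p ~ 0.03
            self._fit("CE", 1329.61, 3),   # p ~ 0.007
            self._fit("E", 1330.79, 2),    # p ~ 0.015
        ])
        assert comp.selected == "ACE"
        assert comp["AE"].comparison_p == pytest.approx(0.03, abs=0.005)

    def test_missing_ace_baseline_rejected(self):
        with pytest.raises(ConfigurationError, match="ACE"):
            compare_models([self._fit("AE", 100.0, 3)])


class TestHeritabilityReport:
    def test_row_count_traits_plus_networks(self):
        cfg = SimConfig(n_mz_pairs=30, n_dz_pairs=30, seed=3)
        cohort = simulate_twin_traits(cfg)
        rng = np.random.default_rng(0)
        reliance = pd.DataFrame(
            rng.normal(8, 2, size=(len(cohort), 2)),
            index=pd.Index(cohort["subject_id"], name="subject_id"),
            columns=["DMN", "FPN"])
        report = heritability_report(cohort, reliance_wide=reliance)
        assert len(report) == 3 + 2
        assert set(report["selected_model"]) <= {"ACE", "AE", "CE", "E"}
        np.testing.assert_allclose(
            report["AIC_ACE"], report["minus2LL_ACE"] - 2 * report["df_ACE"])

    def test_e_generated_reliance_selects_e_and_falconer_near_zero(self, rng):
        picks = []
        falc = []
        for _ in range(10):
            mz = list(zip(rng.normal(size=250), rng.normal(size=250)))
            dz = list(zip(rng.normal(size=250), rng.normal(size=250)))
            report = heritability_report(_twin_cohort(mz, dz), ef_traits=("t",))
            picks.append(report.iloc[0]["selected_model"])
            falc.append(report.iloc[0]["falconer_H"])
        assert picks.count("E") >= 6  # E selected most often under the null
        assert abs(np.mean(falc)) < 0.1
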