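"""Initial rates, Michaelis--Menten fitting, and pH-profile models."""

import numpy as np
import pandas as pd
import pytest

from dynazyme import kinetics as kin, synthetic as syn


def _rate_df(S, v_over_E0, E0=1e-8):
    return pd.DataFrame(
        {
            "variant": "x",
            "pH": 8.5,
            "substrate_M": S,
            "E0_M": E0,
            "v_Ms": np.asarray(v_over_E0) * E0,
            "replicate": 1,
        }
    )


class TestRatesFromAbsorbance:
    def test_beer_lambert_conversion(self):
        t = np.linspace(0, 10, 20)
        a = 0.0158 * t + 0.05
        v = kin.rates_from_absorbance(t, a)
        assert v == pytest.approx(1.0e-6, rel=1e-9)

    def test_blank_equal_to_slope_gives_zero(self):
        t = np.linspace(0, 5, 10)
        a = 0.01 * t
        assert kin.rates_from_absorbance(t, a, blank_slope=0.01) == 0.0

    def test_doubling_path_halves_rate(self):
        t = np.linspace(0, 5, 10)
        a = 0.02 * t
        v1 = kin.rates_from_absorbance(t, a, path_cm=1.0)
        v2 = kin.rates_from_absorbance(t, a, path_cm=2.0)
        assert v2 == pytest.approx(v1 / 2)

    def test_nonmonotonic_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            kin.rates_from_absorbance([0, 2, 1], [0, 1, 2])

    def test_negative_rate_clipped_with_warning(self):
        t = np.linspace(0, 5, 10)
        a = 0.001 * t
        with pytest.warns(UserWarning):
            assert kin.rates_from_absorbance(t, a, blank_slope=0.01) == 0.0


class TestMichaelisFit:
    def test_noiseless_recovery_to_high_precision(self):
        kcat, KM = 1700.0, 2e-3
        S = np.linspace(0.2e-3, 8e-3, 10)
        fit = kin.fit_michaelis(_rate_df(S, kcat * S / (KM + S)))
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.KM == pytest.approx(KM, rel=1e-6)
        assert fit.curvature_detected
        assert fit.kcat_over_KM == pytest.approx(kcat / KM, rel=1e-6)

    def test_no_curvature_when_substrate_below_km(self):
        kcat, KM = 1000.0, 0.1  # [S] << KM: first-order regime only
        S = np.linspace(1e-5, 1e-4, 6)
        fit = kin.fit_michaelis(_rate_df(S, kcat * S / (KM + S)))
        assert not fit.curvature_detected
        # kcat/KM still matches the linear slope of v/E0 vs [S]
        slope = np.polyfit(S, kcat * S / (KM + S), 1)[0]
        assert fit.kcat_over_KM == pytest.approx(slope, rel=0.02)

    def test_pooled_fit_equals_single_replicate_fit(self):
        kcat, KM = 500.0, 1e-3
        S = np.linspace(0.2e-3, 5e-3, 8)
        one = _rate_df(S, kcat * S / (KM + S))
        two = pd.concat([one, one.assign(replicate=2)], ignore_index=True)
        f1, f2 = kin.fit_michaelis(one), kin.fit_michaelis(two)
        assert f2.kcat == pytest.approx(f1.kcat, rel=1e-9)
        assert f2.KM == pytest.approx(f1.KM, rel=1e-9)

    def test_requires_four_distinct_concentrations(self):
        with pytest.raises(ValueError):
            kin.fit_michaelis(_rate_df([1e-3, 1e-3, 2e-3], [1, 1, 2]))

    def test_matches_grid_search_oracle(self):
        # independent coarse oracle: exhaustive RSS minimization on a grid
        for seed in range(10):
            rng = np.random.default_rng(seed)
            kcat = rng.uniform(100, 2000)
            KM = rng.uniform(0.5e-3, 3e-3)
            S = np.linspace(0.2e-3, 6e-3, 9)
            y = kcat * S / (KM + S) * (1 + 0.02 * rng.standard_normal(S.size))
            fit = kin.fit_michaelis(_rate_df(S, y))
            kg = np.linspace(0.5 * kcat, 1.5 * kcat, 81)
            mg = np.linspace(0.3 * KM, 3 * KM, 81)
            rss = [
                (np.sum((k * S / (m + S) - y) ** 2), k, m) for k in kg for m in mg
            ]
            _, k_best, m_best = min(rss)
            assert fit.kcat == pytest.approx(k_best, rel=np.diff(kg)[0] / k_best + 0.02)
            assert fit.KM == pytest.approx(m_best, rel=np.diff(mg)[0] / m_best + 0.02)


class TestPHModel:
    def test_value_at_pka(self):
        assert kin.eq1_log10P(7.0, 5.633, 7.0) == pytest.approx(
            5.633 - 0.30103, abs=1e-5
        )

    def test_plateau_limit(self):
        assert kin.eq1_log10P(10.0, 5.633, 7.0) == pytest.approx(5.633, abs=5e-4)

    def test_unit_slope_far_below_pka(self):
        h = 1e-4
        slope = (kin.eq1_log10P(3.0 + h, 2.0, 7.0) - kin.eq1_log10P(3.0 - h, 2.0, 7.0)) / (2 * h)
        assert slope == pytest.approx(1.000, abs=1e-3)

    def test_monotone_increasing_and_bounded(self):
        pH = np.linspace(-2, 16, 1000)
        y = kin.eq1_log10P(pH, 3.2, 7.1)
        assert np.all(np.diff(y) > 0)
        assert np.all(y < 3.2)


class TestSinglePKaFit:
    def test_noiseless_round_trip(self):
        pH = np.linspace(5.5, 9.0, 10)
        fit = kin.fit_single_pka(pH, kin.eq1_log10P(pH, 5.633, 7.0))
        assert fit.pKa == pytest.approx(7.00, abs=0.01)
        assert fit.log10_P0 == pytest.approx(5.633, abs=0.01)
        assert not fit.poorly_determined

    def test_straight_line_flagged_poorly_determined(self):
        pH = np.linspace(6.0, 8.5, 6)
        fit = kin.fit_single_pka(pH, 1.0 * pH - 4.0)  # pure unit slope, no kink
        assert fit.poorly_determined

    def test_shift_equivariance(self):
        pH = np.linspace(6.0, 8.5, 8)
        y = kin.eq1_log10P(pH, 4.0, 7.2)
        f0 = kin.fit_single_pka(pH, y)
        f1 = kin.fit_single_pka(pH, y + 1.3)
        assert f1.pKa == pytest.approx(f0.pKa, abs=1e-6)
        assert f1.log10_P0 == pytest.approx(f0.log10_P0 + 1.3, abs=1e-6)


class TestLogLinearSlope:
    def test_asymptotic_regime_slope_unity(self):
        pH = np.linspace(2.0, 4.0, 6)  # pKa - 5 .. pKa - 3
        slope, se = kin.loglinear_slope(pH, kin.eq1_log10P(pH, 3.0, 7.0))
        assert slope == pytest.approx(1.00, abs=0.01)

    def test_constant_profile_slope_zero(self):
        slope, _ = kin.loglinear_slope([6, 7, 8, 9], [2.0, 2.0, 2.0, 2.0])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_two_pka_ensemble_slope_between_zero_and_one(self):
        pH = np.linspace(6.0, 8.5, 8)
        P = 0.5 * 10 ** kin.eq1_log10P(pH, 3.0, 6.0) + 0.5 * 10 ** kin.eq1_log10P(
            pH, 3.0, 10.0
        )
        slope, _ = kin.loglinear_slope(pH, np.log10(P))
        assert 0.0 < slope < 1.0


class TestEnsembleFit:
    def test_two_component_round_trip_beats_single(self):
        pH = np.linspace(5.0, 10.0, 12)
        P = 0.6 * 10 ** kin.eq1_log10P(pH, 3.0, 6.5) + 0.4 * 10 ** kin.eq1_log10P(
            pH, 3.0, 9.0
        )
        y = np.log10(P)
        ens = kin.fit_pka_ensemble(pH, y, n_components=2, seed=1)
        single = kin.fit_single_pka(pH, y)
        assert ens.rss == pytest.approx(0.0, abs=1e-10)
        assert single.rss > 1e-5
        pkas = sorted(c["pKa"] for c in ens.components)
        assert pkas[0] == pytest.approx(6.5, abs=0.05)
        assert pkas[1] == pytest.approx(9.0, abs=0.05)

    def test_single_component_reduces_to_single_pka(self):
        pH = np.linspace(6.0, 9.0, 8)
        y = kin.eq1_log10P(pH, 2.0, 7.5)
        a = kin.fit_pka_ensemble(pH, y, n_components=1)
        b = kin.fit_single_pka(pH, y)
        assert a.model == "single-pKa"
        assert a.pKa == pytest.approx(b.pKa)

    def test_fitted_curve_invariant_to_component_order(self):
        pH = np.linspace(5.0, 10.0, 12)
        y = np.log10(
            0.5 * 10 ** kin.eq1_log10P(pH, 3.0, 6.0)
            + 0.5 * 10 ** kin.eq1_log10P(pH, 3.0, 9.5)
        )
        fit = kin.fit_pka_ensemble(pH, y, n_components=2, seed=3)
        swapped = kin.PKaFit(
            log10_P0=fit.log10_P0, pKa=fit.pKa, rss=fit.rss, model="ensemble",
            components=list(reversed(fit.components)),
        )
        np.testing.assert_allclose(fit.predict(pH), swapped.predict(pH), atol=1e-12)


def test_parameter_recovery_over_seeded_datasets():
    """Median relative error of kcat and KM below 5% at CV = 5% noise."""
    errs_kcat, errs_km, errs_pka = [], [], []
    for seed in range(1, 101):
        gt = syn.KineticGroundTruth(
            kcat0=1700.0, KM=2e-3,
            pH_grid=(8.5,), pKa_list=(3.0,),  # plateau regime at assay pH
            noise_cv=0.05, seed=seed,
        )
        df = syn.gen_kinetic_data(gt)
        fit = kin.fit_michaelis(df)
        errs_kcat.append(abs(fit.kcat - gt.kcat0) / gt.kcat0)
        errs_km.append(abs(fit.KM - gt.KM) / gt.KM)
    assert np.median(errs_kcat) < 0.05
    assert np.median(errs_km) < 0.05

    # pKa recovery with the kink inside the window
    rng = np.random.default_rng(0)
    for seed in range(20):
        pH = np.linspace(6.0, 8.5, 8)
        y = kin.eq1_log10P(pH, 5.633, 7.0) + rng.normal(0, 0.02, pH.size)
        errs_pka.append(abs(kin.fit_single_pka(pH, y).pKa - 7.0))
    assert np.median(errs_pka) < 0.1


def test_rate_table_round_trip(tmp_path):
    df = syn.gen_kinetic_data(syn.KineticGroundTruth(noise_cv=0.02, seed=4))
    path = tmp_path / "rates.csv"
    kin.write_rate_table(df, path)
    back = kin.read_rate_table(path)
    np.testing.assert_allclose(back["v_Ms"], df["v_Ms"])
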