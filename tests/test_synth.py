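"""Synthetic study generator: release model, noise, presets, and the
inverse quantitation used for round-trip testing."""

import math

import numpy as np
import pytest

from dissolvekit import (
    GenerationError,
    QuantConfig,
    ReleaseModelParams,
    TimeGrid,
    assess_equivalence,
    generate_area_table,
    generate_from_preset,
    generate_profile,
    generate_study,
    load_preset,
    mean_curve,
    percent_released,
)


class TestMeanCurve:
    def test_first_order_closed_form(self, grid5):
        p = ReleaseModelParams(f_inf=100, tau=3, beta=1, decay=0)
        m = mean_curve(p, grid5)
        expected = [100 * (1 - math.exp(-t / 3)) for t in (10, 15, 20, 30, 45)]
        np.testing.assert_allclose(m, expected, rtol=1e-12)
        assert m[0] == pytest.approx(96.43, abs=0.01)

    def test_short_times_release_little(self):
        p = ReleaseModelParams(f_inf=100, tau=3, beta=1)
        m = mean_curve(p, TimeGrid([1e-6, 2e-6, 3e-6]))
        assert np.all(m < 1e-3)

    def test_post_peak_linear_decline(self, grid5):
        p = ReleaseModelParams(f_inf=100, tau=3, beta=1, decay=0.05)
        m = mean_curve(p, grid5)
        # plateau reached by the first sampling time; the decay term
        # contributes exactly 0.05 %/min x 30 min = 1.5 % between 15 and
        # 45 min, partly offset by the still-rising Weibull base
        drop_15_to_45 = m[1] - m[4]
        base = mean_curve(ReleaseModelParams(f_inf=100, tau=3, beta=1), grid5)
        assert drop_15_to_45 == pytest.approx((base[1] - base[4]) + 0.05 * 30,
                                              abs=1e-9)
        assert drop_15_to_45 > 0  # net tail decline, like real profiles

    def test_monotone_and_bounded_without_decay(self, grid5):
        for beta in (0.7, 1.0, 1.8):
            m = mean_curve(ReleaseModelParams(f_inf=99, tau=5, beta=beta), grid5)
            assert np.all(np.diff(m) >= 0)
            assert np.all(m <= 99)

    @pytest.mark.parametrize("kw", [
        dict(f_inf=0), dict(f_inf=150), dict(tau=0), dict(beta=-1),
        dict(decay=-0.1), dict(n_reps=0),
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            ReleaseModelParams(**kw)


class TestGenerateProfile:
    def test_noiseless_profile_equals_mean_curve(self, grid5):
        p = ReleaseModelParams(f_inf=99, tau=3, noise_sd=0.0, n_reps=3)
        prof = generate_profile(p, grid5, "x", seed=5)
        m = mean_curve(p, grid5)
        np.testing.assert_array_equal(prof.replicates, np.tile(m[:, None], 3))

    def test_fixed_seed_is_deterministic(self, grid5):
        p = ReleaseModelParams(noise_sd=1.0)
        a = generate_profile(p, grid5, "x", seed=42)
        b = generate_profile(p, grid5, "x", seed=42)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        c = generate_profile(p, grid5, "x", seed=43)
        assert not np.array_equal(a.replicates, c.replicates)

    def test_noise_sd_is_calibrated(self, grid5):
        # pooled per-time SD over many regenerations recovers the nominal SD
        p = ReleaseModelParams(f_inf=95, tau=3, noise_sd=1.0, n_reps=3)
        ss = np.random.SeedSequence(777)
        draws = [
            generate_profile(p, grid5, "x", np.random.default_rng(s)).replicates
            for s in ss.spawn(1000)
        ]
        stacked = np.concatenate(draws, axis=1)  # (5, 3000)
        pooled = stacked.std(axis=1, ddof=1)
        np.testing.assert_allclose(pooled, 1.0, rtol=0.05)

    def test_per_time_noise_vector(self, grid5):
        sd = (0.9, 0.94, 0.94, 0.91, 0.97)
        p = ReleaseModelParams(noise_sd=sd, n_reps=3)
        prof = generate_profile(p, grid5, "x", seed=1)
        assert prof.replicates.shape == (5, 3)


class TestGenerateStudy:
    def test_zero_deltas_noiseless_yields_perfect_similarity(self, grid5):
        p = ReleaseModelParams(f_inf=99, tau=3, noise_sd=0.0)
        study = generate_study(p, [{"label": "T-1"}, {"label": "T-2"}],
                               grid5, seed=3)
        for res in assess_equivalence(study):
            assert res.f1 == 0.0
            assert res.f2 == pytest.approx(100.0, abs=1e-12)

    def test_plateau_shift_controls_the_verdict(self, grid5):
        # noiseless uniform shifts: f2 crosses 50 just above a 10 % offset
        p = ReleaseModelParams(f_inf=95, tau=0.5, noise_sd=0.0)  # flat at 95
        for shift, similar in [(5.0, True), (12.0, False)]:
            study = generate_study(p, [{"f_inf": shift}], grid5, seed=0)
            (res,) = assess_equivalence(study)
            delta = mean_curve(ReleaseModelParams(f_inf=95 + shift, tau=0.5,
                                                  noise_sd=0.0), grid5) \
                - mean_curve(p, grid5)
            expected_f2 = 50 * math.log10(100 / math.sqrt(1 + np.mean(delta ** 2)))
            assert res.f2 == pytest.approx(expected_f2, abs=1e-9)
            assert (res.verdict == "similar") is similar

    def test_identical_seed_identical_study(self, grid5):
        p = ReleaseModelParams(noise_sd=1.0)
        deltas = [{"f_inf": 1.0}, {"f_inf": -1.0}]
        a = generate_study(p, deltas, grid5, seed=11)
        b = generate_study(p, deltas, grid5, seed=11)
        np.testing.assert_array_equal(a.reference.replicates,
                                      b.reference.replicates)
        for ta, tb in zip(a.tests, b.tests):
            np.testing.assert_array_equal(ta.replicates, tb.replicates)


class TestPreset:
    def test_mimic_preset_structure(self):
        ps = load_preset("vildagliptin_mimic")
        assert ps.grid.times == (10, 15, 20, 30, 45)
        assert len(ps.test_deltas) == 6
        study = generate_from_preset(ps, seed=4)
        assert len(study.tests) == 6
        assert study.reference.n_reps == 3

    def test_mimic_reference_resembles_the_bundled_study(self):
        # mean at the first sampling time in the fast-release band and a
        # non-monotone tail like the bundled reference profile
        ps = load_preset("vildagliptin_mimic")
        m = mean_curve(ps.reference, ps.grid)
        assert 93 <= m[0] <= 103
        assert m[-1] < m.max()

    def test_mimic_factors_fall_in_the_similar_regime(self):
        ps = load_preset("vildagliptin_mimic")
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            study = generate_from_preset(ps, seed=seed)
            results = assess_equivalence(study)
            if all(r.f1 <= 5.5 and 60 <= r.f2 <= 100 for r in results):
                ok += 1
        assert ok / n_seeds >= 0.9

    def test_unknown_preset_lists_available(self):
        with pytest.raises(GenerationError, match="vildagliptin_mimic"):
            load_preset("no_such_preset")


class TestAreaRoundTrip:
    @pytest.mark.parametrize("replacement", ["replaced", "not_replaced"])
    def test_roundtrip_identity(self, grid5, replacement):
        cfg = QuantConfig(std_mass_mg=12.84, std_stock_vol_ml=25,
                          std_aliquot_ml=2, std_final_vol_ml=20,
                          label_claim_mg=50, medium_vol_ml=1000,
                          withdrawal_vol_ml=10, replacement=replacement)
        ps = load_preset("vildagliptin_mimic")
        for seed in range(10):
            prof = generate_profile(ps.reference, grid5, "x", seed=seed)
            table = generate_area_table(prof, cfg)
            back = percent_released(table, cfg)
            np.testing.assert_allclose(back.replicates, prof.replicates,
                                       atol=1e-9)

    def test_no_withdrawal_areas_proportional_to_percent(self, grid5):
        cfg = QuantConfig(std_mass_mg=12.84, std_stock_vol_ml=25,
                          std_aliquot_ml=2, std_final_vol_ml=20,
                          label_claim_mg=50, medium_vol_ml=1000,
                          withdrawal_vol_ml=0)
        p = ReleaseModelParams(f_inf=95, tau=3, noise_sd=0.0)
        prof = generate_profile(p, grid5, "x", seed=0)
        table = generate_area_table(prof, cfg)
        ratio = table.sample_areas / prof.replicates
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-12)

    def test_flat_profile_concentration_by_replacement_mode(self, grid5):
        # 100 % released at every time: without replacement each aliquot
        # removes drug and volume proportionally, so the concentration is
        # constant; with replacement fresh medium dilutes the vessel, so
        # it strictly decreases
        from dissolvekit import DissolutionProfile
        base = dict(std_mass_mg=12.84, std_stock_vol_ml=25,
                    std_aliquot_ml=2, std_final_vol_ml=20,
                    label_claim_mg=50, medium_vol_ml=1000,
                    withdrawal_vol_ml=10)
        prof = DissolutionProfile("flat", grid5,
                                  replicates=np.full((5, 1), 100.0))
        not_rep = generate_area_table(
            prof, QuantConfig(**base, replacement="not_replaced"))
        np.testing.assert_allclose(
            not_rep.sample_areas[:, 0], not_rep.sample_areas[0, 0], rtol=1e-12)
        rep = generate_area_table(
            prof, QuantConfig(**base, replacement="replaced"))
        assert np.all(np.diff(rep.sample_areas[:, 0]) < 0)

    def test_impossible_profile_is_rejected(self, grid5):
        # a collapse from 100 % to 1 % cannot come from any positive
        # concentration once withdrawn mass is accounted for
        from dissolvekit import DissolutionProfile
        cfg = QuantConfig(std_mass_mg=12.84, std_stock_vol_ml=25,
                          std_aliquot_ml=2, std_final_vol_ml=20,
                          label_claim_mg=50, medium_vol_ml=1000,
                          withdrawal_vol_ml=100, replacement="not_replaced")
        prof = DissolutionProfile(
            "bad", grid5,
            replicates=np.array([[100.0], [1.0], [1.0], [1.0], [1.0]]))
        with pytest.raises(GenerationError):
            generate_area_table(prof, cfg)
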