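"""Regression optimization: fitting, prediction, before/after accuracy."""

import math

import numpy as np
import pytest

from astigvec.cohort import EyeRecord
from astigvec.core import NetAstigmatism, net_to_polar
from astigvec.optimize import (
    PRESETS,
    RegressionModel,
    compare_before_after,
    fit_optimization,
    load_models,
    optimized_da,
    predict_kp_ra,
    save_models,
)
from astigvec.pipeline import eye_da_table
from astigvec.simulate import GeneratorConfig, generate_cohort, identity_config

RECOVERY_CFG = dict(
    modalities=("auto_ka",),
    modality_bias={"auto_ka": (0.0, 0.0)},
    noise_sd_ca=0.0,  # the fitted modality observes the true cornea exactly
)


class TestPredict:
    def test_wtr_canonical_input(self):
        model = PRESETS["pseudophakic_full"]["auto_ka"]
        assert predict_kp_ra(model, 1.0, 90.0) == pytest.approx(0.49, abs=1e-12)

    def test_atr_canonical_input(self):
        model = PRESETS["pseudophakic_full"]["auto_ka"]
        assert predict_kp_ra(model, 1.0, 0.0) == pytest.approx(1.27, abs=1e-12)

    def test_identity_model_returns_magnitude(self):
        ident = RegressionModel("auto_ka", 0.0, 1.0, 0.0)
        for mag, mer in [(0.5, 10.0), (2.0, 137.0)]:
            assert predict_kp_ra(ident, mag, mer) == pytest.approx(mag)

    def test_literature_presets_present(self):
        assert len(PRESETS["pseudophakic_full"]) == 14
        b = PRESETS["bregnhoj_ka"]["auto_ka"]
        assert (b.a, b.b, b.c) == (-0.09, 0.68, 0.33)
        s = PRESETS["savini_toric_ka"]["auto_ka"]
        assert (s.a, s.b, s.c) == (0.103, 0.836, 0.457)


class TestFit:
    def test_noise_free_data_recovered_exactly(self):
        cfg = GeneratorConfig(
            n_eyes=60,
            seed=1,
            true_coefficients=(-0.04, 0.92, 0.39),
            noise_sd_ra=0.0,
            noise_sd_ra_cross=0.0,
            **RECOVERY_CFG,
        )
        model = fit_optimization(generate_cohort(cfg), "auto_ka")
        assert model.a == pytest.approx(-0.04, abs=1e-9)
        assert model.b == pytest.approx(0.92, abs=1e-9)
        assert model.c == pytest.approx(0.39, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_parameter_recovery_within_3se_at_n500(self):
        cfg = GeneratorConfig(
            n_eyes=500, seed=17, true_coefficients=(-0.04, 0.92, 0.39), **RECOVERY_CFG
        )
        model = fit_optimization(generate_cohort(cfg), "auto_ka")
        for est, true, se in zip((model.a, model.b, model.c), (-0.04, 0.92, 0.39), model.bse):
            assert abs(est - true) < 3 * se

    def test_null_c_not_detected_spuriously(self):
        cfg = GeneratorConfig(
            n_eyes=500, seed=23, true_coefficients=(-0.04, 0.92, 0.0), **RECOVERY_CFG
        )
        model = fit_optimization(generate_cohort(cfg), "auto_ka")
        assert abs(model.c) < 3 * model.bse[2]

    def test_median_b_error_calibrated_at_n95(self):
        # 200 replicates at the study size with the clinical cylinder spread
        # (double-angle SD 0.7 -> magnitude SD ~0.55 D): the analytic OLS
        # covariance puts the median absolute slope error under 0.05 D/D
        errs = []
        for seed in range(200):
            cfg = GeneratorConfig(
                n_eyes=95,
                seed=seed,
                true_coefficients=(-0.04, 0.92, 0.39),
                ca_spread=0.7,
                **RECOVERY_CFG,
            )
            errs.append(abs(fit_optimization(generate_cohort(cfg), "auto_ka").b - 0.92))
        assert np.median(errs) < 0.05

    def test_rank_deficient_design_names_column(self):
        records = [
            EyeRecord(f"e{i}", 0.0, 0.5 + 0.1 * i, 90.0, {"auto_ka": NetAstigmatism(0.6 + 0.1 * i, 90.0)})
            for i in range(12)
        ]
        with pytest.raises(np.linalg.LinAlgError, match="cos"):
            fit_optimization(records, "auto_ka")

    def test_too_few_eyes_rejected(self, default_cohort):
        with pytest.raises(ValueError, match=">= 10"):
            fit_optimization(default_cohort[:5], "auto_ka")


class TestOptimizedDA:
    def test_in_sample_mean_residual_zero(self, default_cohort):
        model = fit_optimization(default_cohort, "auto_ka")
        das = optimized_da(default_cohort, model)
        assert np.mean([d.delta_kp_phi for d in das]) == pytest.approx(0.0, abs=1e-10)

    def test_identity_model_on_identity_cohort_zero_da(self, identity_cohort):
        das = optimized_da(identity_cohort, RegressionModel("auto_ka", 0.0, 1.0, 0.0))
        assert all(d.magnitude < 1e-9 for d in das)

    def test_oblique_component_bitwise_unchanged(self, default_cohort):
        model = fit_optimization(default_cohort, "tcrp_4.0_pupil_zone")
        before = eye_da_table(default_cohort, "tcrp_4.0_pupil_zone")
        after = optimized_da(default_cohort, model)
        assert [d.delta_kp_phi45 for d in after] == [d.delta_kp_phi45 for d in before]

    def test_variance_reduction(self, default_cohort):
        model = fit_optimization(default_cohort, "auto_ka")
        before = eye_da_table(default_cohort, "auto_ka")
        after = optimized_da(default_cohort, model)
        assert np.std([d.delta_kp_phi for d in after]) <= np.std(
            [d.delta_kp_phi for d in before]
        )

    def test_mean_da_magnitude_never_worse_across_seeds(self):
        for seed in range(5):
            records = generate_cohort(GeneratorConfig(n_eyes=95, seed=seed))
            rep = compare_before_after(records, "auto_ka")
            assert rep.after.mean_da_magnitude <= rep.before.mean_da_magnitude + 1e-12


class TestBeforeAfter:
    def test_exact_model_data_unchanged(self):
        # refraction generated exactly from the identity relation: the fitted
        # model reproduces it and optimization changes nothing
        cfg = identity_config(n_eyes=30, seed=3)
        records = generate_cohort(cfg)
        rep = compare_before_after(records, "auto_ka")
        assert rep.p_paired_dkp_phi == 1.0
        assert rep.after.mean_da_magnitude == pytest.approx(rep.before.mean_da_magnitude)

    def test_biased_modality_significant_shift_at_n95(self, default_cohort):
        # tcrp_2.0_apex_zone carries the largest radial bias: optimization
        # must shift its dKP(phi) distribution detectably
        rep = compare_before_after(default_cohort, "tcrp_2.0_apex_zone")
        assert rep.p_paired_dkp_phi < 0.05
        assert rep.after.mean_dkp_phi == pytest.approx(0.0, abs=1e-10)

    def test_after_block_mean_zero_for_every_modality(self, default_cohort):
        from astigvec.cohort import MODALITIES

        for m in MODALITIES:
            rep = compare_before_after(default_cohort, m)
            assert rep.after.mean_dkp_phi == pytest.approx(0.0, abs=1e-10)
            assert rep.after.mean_dkp_phi45 == rep.before.mean_dkp_phi45


def test_model_json_round_trip(tmp_path, default_cohort):
    model = fit_optimization(default_cohort, "auto_ka")
    save_models({"auto_ka": model}, tmp_path / "m.json")
    back = load_models(tmp_path / "m.json")["auto_ka"]
    assert (back.a, back.b, back.c) == (model.a, model.b, model.c)
    assert back.r_squared == model.r_squared


def test_design_uses_each_modalitys_own_meridian(default_cohort):
    """The cos(2 alpha) regressor comes from the fitted modality's steep
    meridian, so two modalities with different meridians fit different c."""
    m1 = fit_optimization(default_cohort, "auto_ka")
    m2 = fit_optimization(default_cohort, "tcrp_2.0_apex_zone")
    y1 = [
        net_to_polar(r.refractive_astigmatism, r.measurements["auto_ka"].meridian).kp_phi
        for r in default_cohort
    ]
    y2 = [
        net_to_polar(
            r.refractive_astigmatism, r.measurements["tcrp_2.0_apex_zone"].meridian
        ).kp_phi
        for r in default_cohort
    ]
    assert y1 != y2
    assert (m1.a, m1.b, m1.c) != (m2.a, m2.b, m2.c)
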