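import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from binovision.gain_control import (
    DEFAULT_CONSTANTS,
    DegenerateMaskingError,
    FixedModelConstants,
    GainControlParams,
    ThresholdQuartet,
    binocular_response,
    closed_form_fit,
    detection_threshold,
    fit_gain_control,
    mask_threshold,
    predict_quartet,
    sensory_imbalances,
    stage1_response,
    stage2_response,
    stage2_unit_root,
    suppression_strength,
)


class TestStageResponses:
    def test_stage1_no_mask_unit_drive(self):
        # numerator 1**m, denominator S + 1
        assert stage1_response(1.0, 0.0, 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_stage1_all_unit(self):
        assert stage1_response(1.0, 1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0 / 3.0)

    def test_stage1_drive_two(self):
        assert stage1_response(2.0, 0.0, 1.0, 1.0, 1.0) == pytest.approx(2**1.3 / 3.0)

    def test_stage1_rejects_negative_contrast(self):
        with pytest.raises(ValueError):
            stage1_response(-0.1, 0.0, 1.0, 1.0, 1.0)

    def test_stage2_values(self):
        assert stage2_response(1.0) == pytest.approx(0.5)
        assert stage2_response(0.0) == 0.0

    def test_stage2_unit_root_bracket(self):
        r = stage2_unit_root()
        assert 1.20 < r < 1.21
        assert stage2_response(r) == pytest.approx(1.0, abs=1e-9)

    @given(
        st.floats(min_value=0.01, max_value=5.0),
        st.floats(min_value=1e-3, max_value=5.0),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.05, max_value=2.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_target_and_mask(self, ct, cm, gt, gm, w):
        base = binocular_response(ct, cm, gt, gm, w)
        assert binocular_response(ct * 1.1, cm, gt, gm, w) > base
        if cm > 0:
            assert binocular_response(ct, cm * 1.1, gt, gm, w) < base


class TestDetectionThreshold:
    def test_defining_property(self):
        c = detection_threshold(3.0)
        assert binocular_response(c, 0.0, 3.0, 1.0, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_inverse_proportional_to_gain(self):
        assert detection_threshold(30.0) == pytest.approx(detection_threshold(3.0) / 10)

    def test_unit_drive_oracle(self):
        # independent bisection for x in x**1.3/(1+x) = r*
        rstar = stage2_unit_root()
        x = optimize.bisect(lambda v: v**1.3 / (1 + v) - rstar, 0.1, 50, xtol=1e-12)
        assert detection_threshold(1.0) == pytest.approx(x, abs=1e-8)
        assert 3.9 < x < 4.0


class TestMaskThreshold:
    def test_halves_when_weight_doubles(self):
        a = mask_threshold(3.0, 3.0, 0.4, 5.0)
        b = mask_threshold(3.0, 3.0, 0.8, 5.0)
        assert b == pytest.approx(a / 2)

    def test_matches_numeric_root(self):
        g_t, g_m, w, targ = 2.5, 3.5, 0.4, 6.0
        cm = mask_threshold(g_t, g_m, w, targ)
        f = lambda c: binocular_response(targ, c, g_t, g_m, w) - 1.0
        numeric = optimize.brentq(f, 1e-9, 1e4, xtol=1e-12)
        assert cm == pytest.approx(numeric, abs=1e-9)

    def test_target_at_own_threshold_is_degenerate(self):
        g = 3.0
        with pytest.raises(DegenerateMaskingError):
            mask_threshold(g, g, 0.4, detection_threshold(g))


def random_params(rng):
    # gains/weights spanning the plausible per-eye range (percent units)
    return GainControlParams.from_db(
        GR=rng.uniform(5, 20),
        GL=rng.uniform(5, 20),
        WR=rng.uniform(-18, -2),
        WL=rng.uniform(-18, -2),
    )


def quartet_from_params(params, offset_db=9.0, consts=DEFAULT_CONSTANTS):
    detR = detection_threshold(params.gR, consts)
    detL = detection_threshold(params.gL, consts)
    targR = detR * 10 ** (offset_db / 20)
    targL = detL * 10 ** (offset_db / 20)
    maskR = mask_threshold(params.gR, params.gL, params.wR, targR, consts)
    maskL = mask_threshold(params.gL, params.gR, params.wL, targL, consts)
    return ThresholdQuartet(detR, detL, maskR, maskL, targR, targL)


class TestFit:
    def test_round_trip_recovery(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            true = random_params(rng)
            q = quartet_from_params(true)
            fit = fit_gain_control(q)
            for attr in ("GR", "GL", "WR", "WL"):
                assert getattr(fit, attr) == pytest.approx(getattr(true, attr), abs=0.01)

    def test_symmetric_quartet_gives_symmetric_params(self):
        p = GainControlParams.from_db(GR=12.0, GL=12.0, WR=-9.0, WL=-9.0)
        fit = fit_gain_control(quartet_from_params(p))
        assert fit.gR == pytest.approx(fit.gL, rel=1e-6)
        assert fit.wR == pytest.approx(fit.wL, rel=1e-6)

    def test_optimizer_matches_closed_form_many(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            q = quartet_from_params(random_params(rng))
            cf = closed_form_fit(q)
            fit = fit_gain_control(q)
            for attr in ("GR", "GL", "WR", "WL"):
                assert getattr(fit, attr) == pytest.approx(getattr(cf, attr), abs=0.01)

    def test_noisy_recovery_median_error(self):
        # 0.5 dB threshold noise; median |error| of the dB parameters <= 1.5 dB
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(200):
            true = random_params(rng)
            q = quartet_from_params(true)
            db = lambda v: 20 * math.log10(v / 100.0)  # percent -> dB contrast
            noisy = [db(v) + rng.normal(0, 0.5) for v in (q.detR, q.detL, q.maskR, q.maskL)]
            qn = ThresholdQuartet.from_db(*noisy, target_offset_db=9.0)
            fit = fit_gain_control(qn, n_starts=1)
            errs.append(
                [abs(getattr(fit, a) - getattr(true, a)) for a in ("GR", "GL", "WR", "WL")]
            )
        med = np.median(np.asarray(errs), axis=0)
        assert (med <= 1.5).all(), med

    def test_predicted_threshold_rises_with_mask(self):
        # no facilitation: target threshold is non-decreasing in mask contrast
        p = GainControlParams.from_db(GR=12, GL=12, WR=-8, WL=-8)
        thr = []
        for cm in (0.0, 1.0, 3.0, 10.0):
            f = lambda c: binocular_response(c, cm, p.gR, p.gL, p.wR) - 1.0
            thr.append(optimize.brentq(f, 1e-9, 1e5))
        assert all(b >= a for a, b in zip(thr, thr[1:]))


class TestDerived:
    def test_suppression_strength_sums(self):
        p = GainControlParams.from_db(GR=5.0, GL=10.0, WR=-8.0, WL=-3.0)
        s = suppression_strength(p)
        assert s.supstrR == pytest.approx(2.0)
        assert s.supstrL == pytest.approx(2.0)

    def test_symmetric_params_equal_strengths(self):
        p = GainControlParams.from_db(GR=9.0, GL=9.0, WR=-6.0, WL=-6.0)
        s = suppression_strength(p)
        assert s.supstrR == s.supstrL

    def test_identical_eyes_zero_imbalance(self):
        p = GainControlParams.from_db(GR=9.0, GL=9.0, WR=-6.0, WL=-6.0)
        imb = sensory_imbalances(-40.0, -40.0, p, 0.0)
        assert imb.threshold_imbalance == 0
        assert imb.weight_imbalance == 0
        assert imb.strength_imbalance == 0

    def test_eye_swap_antisymmetry(self):
        p = GainControlParams.from_db(GR=8.0, GL=11.0, WR=-4.0, WL=-9.0)
        swapped = GainControlParams.from_db(GR=11.0, GL=8.0, WR=-9.0, WL=-4.0)
        a = sensory_imbalances(-38.0, -41.0, p, 2.0)
        b = sensory_imbalances(-41.0, -38.0, swapped, -2.0)
        assert b.threshold_imbalance == pytest.approx(-a.threshold_imbalance)
        assert b.weight_imbalance == pytest.approx(-a.weight_imbalance)
        assert b.strength_imbalance == pytest.approx(-a.strength_imbalance)
        assert b.fusion_imbalance == pytest.approx(-a.fusion_imbalance)

    def test_threshold_imbalance_subtraction(self):
        p = GainControlParams.from_db(GR=10, GL=10, WR=-8, WL=-8)
        imb = sensory_imbalances(-38.0, -41.0, p, 0.0)
        assert imb.threshold_imbalance == pytest.approx(3.0)

    def test_strength_imbalance_identity(self):
        p = GainControlParams.from_db(GR=8.0, GL=11.0, WR=-4.0, WL=-9.0)
        imb = sensory_imbalances(-38.0, -41.0, p, 1.0)
        assert imb.strength_imbalance == pytest.approx(
            (p.GL + p.WR) - (p.GR + p.WL)
        )


class TestConstants:
    def test_rejects_p_not_greater_than_q(self):
        with pytest.raises(ValueError):
            FixedModelConstants(p=6.0, q=6.6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            FixedModelConstants(m=0.0)

    def test_serialization_keys(self):
        p = GainControlParams.from_db(GR=10, GL=10, WR=-8, WL=-8)
        d = p.to_dict()
        for k in ("m", "p", "q", "S", "Z", "gR", "gL", "wR", "wL",
                  "GR", "GL", "WR", "WL", "supstrR", "supstrL"):
            assert k in d
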