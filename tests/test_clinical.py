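"""Clinical scoring: Gensini tables, CAD rules, volumes, curves, work."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iecad.clinical import (
    CadLabel, CoronaryLesion, Segment, classify_significant, ef_curve,
    gensini_score, gwe_from_loop, is_severe, make_cad_label,
    metrics_from_masks, simpson_biplane_volume, strain_curve,
)

L = CoronaryLesion


class TestGensini:
    def test_empty_lesion_list_scores_zero(self):
        res = gensini_score([])
        assert res.total == 0.0 and not res.severe

    @pytest.mark.parametrize("lesions,expected", [
        ([L(Segment.LM, 100.0)], 32 * 5.0),            # 160
        ([L(Segment.LAD_PROX, 50.0)], 2 * 2.5),        # 5
        ([L(Segment.LAD_PROX, 75.0)], 4 * 2.5),        # 10
        ([L(Segment.LAD_PROX, 75.0), L(Segment.RCA_MID, 75.0)], 10 + 4),
        ([L(Segment.LAD_PROX, 75.0), L(Segment.RCA_MID, 90.0)], 10 + 8),
        ([L(Segment.LAD_MID, 25.0)], 1 * 1.5),
        ([L(Segment.D2, 100.0)], 32 * 0.5),
        ([L(Segment.PLB, 99.0)], 16 * 0.5),
    ])
    def test_worked_examples_match_hand_computation(self, lesions, expected):
        res = gensini_score(lesions)
        assert res.total == pytest.approx(expected)
        assert res.total == pytest.approx(sum(res.contributions))

    def test_severity_cutoff_at_15_points(self):
        assert not gensini_score([L(Segment.LAD_PROX, 75.0),
                                  L(Segment.RCA_MID, 75.0)]).severe  # 14
        assert gensini_score([L(Segment.LAD_PROX, 75.0),
                              L(Segment.RCA_MID, 90.0)]).severe      # 18

    def test_collateral_demotes_total_occlusion_to_90_bin(self):
        assert gensini_score([L(Segment.RCA_PROX, 100.0,
                                collaterals=True)]).total == 8.0
        assert gensini_score([L(Segment.RCA_PROX, 100.0)]).total == 32.0
        # near-total stenosis gets the same adjustment
        assert gensini_score([L(Segment.RCA_PROX, 99.0,
                                collaterals=True)]).total == 8.0
        # collaterals on a sub-critical lesion change nothing
        assert gensini_score([L(Segment.RCA_PROX, 80.0,
                                collaterals=True)]).total == 8.0

    @given(st.lists(st.tuples(
        st.sampled_from(list(Segment)),
        st.floats(min_value=0, max_value=100)), max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_additive_and_nonnegative(self, raw):
        lesions = [L(seg, pct) for seg, pct in raw]
        res = gensini_score(lesions)
        assert res.total >= 0
        assert res.total == pytest.approx(
            sum(gensini_score([les]).total for les in lesions))

    def test_monotone_in_stenosis_within_segment(self):
        scores = [gensini_score([L(Segment.LAD_MID, p)]).total
                  for p in range(0, 101, 5)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_unknown_segment_rejected(self):
        with pytest.raises(ValueError):
            L("LAD_prox2", 50.0)


class TestSignificance:
    @pytest.mark.parametrize("seg,pct,expected", [
        (Segment.LM, 50.0, True), (Segment.LM, 49.0, False),
        (Segment.RCA_PROX, 70.0, True), (Segment.RCA_PROX, 69.0, False),
        (Segment.LAD_DIST, 70.0, True), (Segment.LCX_PROX, 69.9, False),
    ])
    def test_printed_thresholds(self, seg, pct, expected):
        assert classify_significant([L(seg, pct)]) is expected

    def test_no_lesions_not_significant(self):
        assert classify_significant([]) is False

    @given(st.lists(st.tuples(
        st.sampled_from(list(Segment)),
        st.floats(min_value=0, max_value=100)), max_size=5),
        st.sampled_from(list(Segment)),
        st.floats(min_value=0, max_value=100))
    @settings(deadline=None, max_examples=50)
    def test_monotone_adding_lesions(self, raw, seg, pct):
        base = [L(s, p) for s, p in raw]
        if classify_significant(base):
            assert classify_significant(base + [L(seg, pct)])


class TestCadLabel:
    @pytest.mark.parametrize("sig,sev,a", [
        (True, False, (True, False, True, False)),
        (False, True, (False, True, True, False)),
        (True, True, (True, True, False, True)),
        (False, False, (False, False, False, False)),
    ])
    def test_assignment_logic(self, sig, sev, a):
        lab = CadLabel(significant=sig, severe=sev)
        assert (lab.assignment1, lab.assignment2,
                lab.assignment3, lab.assignment4) == a

    def test_label_from_lesions(self):
        lab = make_cad_label([L(Segment.LAD_PROX, 80.0)])  # 8*2.5 = 20 pts
        assert lab.significant and lab.severe

    def test_severity_rule_boundary(self):
        assert not is_severe(14.999) and is_severe(15.0)


class TestVolumesAndCurves:
    def test_cylinder_closed_form(self):
        d = np.full(10, 4.0)
        v = simpson_biplane_volume(d, d, 30.0)
        assert v == pytest.approx(np.pi / 4 * 16 * 30)

    def test_zero_diameter_disks_contribute_nothing(self):
        a = np.array([2.0, 0.0, 2.0])
        b = np.array([3.0, 5.0, 3.0])
        v = simpson_biplane_volume(a, b, 3.0)
        assert v == pytest.approx(np.pi / 4 * 1.0 * (6 + 0 + 6))

    def test_hemiellipsoid_against_closed_form(self):
        # half-ellipsoid z in [0, c], cross-section diameters 2a, 2b
        a, b, c, n = 20.0, 15.0, 40.0, 20
        z = (np.arange(n) + 0.5) / n * c
        da = 2 * a * np.sqrt(1 - (z / c) ** 2)
        db = 2 * b * np.sqrt(1 - (z / c) ** 2)
        v = simpson_biplane_volume(da, db, c)
        analytic = 2.0 / 3.0 * np.pi * a * b * c
        assert v == pytest.approx(analytic, rel=0.02)

    def test_volume_equals_brute_force_riemann_sum(self):
        rng = np.random.default_rng(0)
        for n in (1, 3, 17):
            a = rng.uniform(0, 5, n)
            b = rng.uniform(0, 5, n)
            length = 12.0
            brute = sum(np.pi / 4 * ai * bi * (length / n)
                        for ai, bi in zip(a, b))
            assert simpson_biplane_volume(a, b, length) == pytest.approx(brute)

    def test_mismatched_disk_counts_rejected(self):
        with pytest.raises(ValueError):
            simpson_biplane_volume([1.0, 2.0], [1.0], 10.0)

    def test_ef_curve_arithmetic(self):
        v = np.full(20, 80.0)
        assert np.allclose(ef_curve(v), 0.0)
        v[10] = 0.4 * 80.0
        ef = ef_curve(v)
        assert ef[0] == 0.0 and ef.max() == pytest.approx(60.0)
        with pytest.raises(ValueError):
            ef_curve(np.r_[0.0, v[1:]])

    def test_strain_curve_arithmetic_and_scale_invariance(self):
        ln = np.full(20, 120.0)
        assert np.allclose(strain_curve(ln), 0.0)
        ln[10] = 0.8 * 120.0
        eps = strain_curve(ln)
        assert eps[0] == 0.0 and eps.min() == pytest.approx(-20.0)
        assert np.allclose(strain_curve(3.7 * ln), eps)


class TestGwe:
    def _pressure(self):
        return np.full(20, 100.0)

    def test_pure_shortening_is_fully_constructive(self):
        eps = np.r_[np.linspace(0, -20, 11), np.linspace(-18, 0, 9)]
        assert gwe_from_loop(eps, self._pressure()) == pytest.approx(100.0)

    def test_pure_lengthening_is_fully_wasted(self):
        eps = np.r_[np.linspace(0, 20, 11), np.linspace(18, 0, 9)]
        assert gwe_from_loop(eps, self._pressure()) == pytest.approx(0.0)

    def test_balanced_steps_give_half(self):
        eps = np.zeros(20)
        eps[1] = -5.0  # one shortening then one equal lengthening step
        eps[2] = 0.0
        assert gwe_from_loop(eps, self._pressure()) == pytest.approx(50.0)

    def test_invariant_to_uniform_pressure_scaling(self):
        rng = np.random.default_rng(3)
        eps = np.r_[0.0, np.cumsum(rng.normal(size=19))]
        p = rng.uniform(10, 120, 20)
        assert gwe_from_loop(eps, p) == pytest.approx(
            gwe_from_loop(eps, 7.3 * p))

    def test_no_motion_is_undefined(self):
        with pytest.raises(ValueError):
            gwe_from_loop(np.zeros(20), self._pressure())


class TestMaskMetrics:
    def test_identical_frames_give_zero_ef_and_strain(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.hypot(yy - 32, xx - 32)
        mask[r < 20] = 1
        mask[r < 12] = 2
        block = np.repeat(mask[None], 20, axis=0)
        mm = metrics_from_masks(block, block)
        assert mm.lvef == pytest.approx(0.0)
        assert mm.gls == pytest.approx(0.0)

    def test_empty_class_names_the_frame(self):
        mask = np.zeros((20, 32, 32), dtype=np.uint8)
        mask[:, 10:20, 10:20] = 2
        mask[:, 8:10, 10:20] = 1
        mask[7] = 0  # frame 7 loses both classes
        with pytest.raises(ValueError, match="frame 7"):
            metrics_from_masks(mask, mask)
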