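"""Phantom generator: determinism, geometry oracles, disease coupling."""

import numpy as np
import pytest

from iecad.clinical import CoronaryLesion, Segment, metrics_from_masks
from iecad.synthetic import (
    CONTRACTILITY_FLOOR, HeartPhantom, cycle_phase, make_cohort, make_phantom,
    render_subject,
)

HEALTHY = {"LAD": 1.0, "LCx": 1.0, "RCA": 1.0}


@pytest.fixture(scope="module")
def small_subject():
    phantom = make_phantom(3, 0.4)
    return render_subject(phantom, [], noise_seed=9, frame_size=64)


class TestPhantom:
    def test_healthy_limit_has_unit_contractility(self):
        p = make_phantom(0, 0.0)
        assert all(c == 1.0 for c in p.contractility.values())

    def test_full_disease_reaches_documented_floor(self):
        p = make_phantom(0, 1.0)
        assert min(p.contractility.values()) == pytest.approx(
            CONTRACTILITY_FLOOR)

    def test_same_seed_same_phantom(self):
        a, b = make_phantom(7, 0.5), make_phantom(7, 0.5)
        assert a == b

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_phantom(0, 1.5)
        with pytest.raises(ValueError):
            HeartPhantom(a0=10, b0=50, h0=12, alpha=0.2,
                         contractility=HEALTHY)  # wall thicker than cavity

    def test_cycle_phase_convention(self):
        t = np.arange(20)
        phi = cycle_phase(t)
        assert phi[0] == 0.0 and phi[10] == 1.0
        assert np.all(np.diff(phi[:11]) > 0)
        assert np.all(np.diff(phi[10:]) < 0)


class TestRenderSubject:
    def test_motionless_heart_has_flat_curves(self):
        phantom = HeartPhantom(a0=80, b0=50, h0=12, alpha=0.0,
                               contractility=dict(HEALTHY))
        rec = render_subject(phantom, [], noise_seed=1, frame_size=64)
        assert np.allclose(rec.strain, 0.0)
        assert np.allclose(rec.ef, 0.0)

    def test_clip_and_mask_contracts(self, small_subject):
        for view in ("A4C", "A3C", "A2C"):
            clip = small_subject.clips[view].data
            mask = small_subject.masks[view].data
            assert clip.shape == (20, 64, 64)
            assert clip.min() >= 0.0 and clip.max() <= 1.0
            assert mask.shape == (20, 64, 64)
            assert set(np.unique(mask)) <= {0, 1, 2}

    def test_cavity_strictly_inside_annulus_every_frame(self, small_subject):
        from scipy.ndimage import binary_dilation
        for view in ("A4C", "A3C", "A2C"):
            mask = small_subject.masks[view].data
            for t in range(20):
                cavity = mask[t] == 2
                ring = binary_dilation(cavity) & ~cavity
                assert cavity.any()
                # every pixel bordering the cavity is myocardium
                assert np.all(mask[t][ring] == 1)

    def test_curves_start_at_zero_with_extrema_at_es(self):
        phantom = HeartPhantom(a0=80, b0=50, h0=12, alpha=0.25,
                               contractility=dict(HEALTHY))
        rec = render_subject(phantom, [], noise_seed=2, frame_size=64)
        assert rec.strain[0] == 0.0 and rec.ef[0] == 0.0
        assert np.argmin(rec.strain) == 10
        assert np.argmax(rec.ef) == 10
        assert rec.gls == rec.strain.min() < 0
        assert rec.lvef == rec.ef.max() > 0

    def test_circular_uniform_phantom_matches_closed_form_lvef(self):
        # cavity scales isotropically by (1 - alpha) at ES -> EF = 1 - (1-a)^3
        alpha = 0.2
        phantom = HeartPhantom(a0=60.0, b0=59.99, h0=12, alpha=alpha,
                               contractility=dict(HEALTHY))
        rec = render_subject(phantom, [], noise_seed=1, frame_size=64)
        assert rec.lvef == pytest.approx(100 * (1 - (1 - alpha) ** 3),
                                         abs=0.05)

    def test_determinism_bit_identical(self):
        phantom = make_phantom(5, 0.3)
        a = render_subject(phantom, [], noise_seed=4, frame_size=64)
        b = render_subject(phantom, [], noise_seed=4, frame_size=64)
        for view in ("A4C", "A3C", "A2C"):
            assert np.array_equal(a.clips[view].data, b.clips[view].data)
            assert np.array_equal(a.masks[view].data, b.masks[view].data)
        assert np.array_equal(a.strain, b.strain)
        assert a.gwe == b.gwe

    def test_monotone_disease_effect(self):
        for seed in (1, 7):
            metrics = []
            for level in (0.0, 0.33, 0.66, 1.0):
                rec = render_subject(make_phantom(seed, level), [],
                                     noise_seed=3, frame_size=64)
                metrics.append((abs(rec.gls), rec.lvef, rec.gwe))
            arr = np.array(metrics)
            assert np.all(np.diff(arr, axis=0) <= 1e-9)

    def test_labels_follow_lesions(self):
        lesions = [CoronaryLesion(Segment.LAD_PROX, 80.0)]  # 20 points
        rec = render_subject(make_phantom(2, 0.0), lesions, noise_seed=5,
                             frame_size=64)
        assert rec.significant and rec.severe
        assert rec.gensini == pytest.approx(20.0)


class TestCohort:
    def test_three_clips_per_subject(self):
        recs = make_cohort(5, prevalence=0.4, rng_seed=0, frame_size=32)
        assert sum(len(r.clips) for r in recs) == 15

    def test_prevalence_count_is_exact(self):
        recs = make_cohort(29, prevalence=122.0 / 290.0, rng_seed=1,
                           frame_size=32)
        assert sum(r.significant for r in recs) == round(29 * 122 / 290)

    def test_significant_subgroup_scores_higher_gensini(self):
        recs = make_cohort(50, prevalence=0.42, rng_seed=4, frame_size=32)
        sig = [r.gensini for r in recs if r.significant]
        non = [r.gensini for r in recs if not r.significant]
        assert np.mean(sig) > np.mean(non)

    def test_disease_lowers_function_at_cohort_level(self):
        recs = make_cohort(40, prevalence=0.5, rng_seed=7, frame_size=32)
        sig = [r for r in recs if r.significant]
        non = [r for r in recs if not r.significant]
        assert np.mean([abs(r.gls) for r in sig]) < \
            np.mean([abs(r.gls) for r in non])
        assert np.mean([r.lvef for r in sig]) < np.mean([r.lvef for r in non])
        assert np.mean([r.gwe for r in sig]) <= np.mean([r.gwe for r in non])


class TestMaskRecovery:
    def test_mask_derived_lvef_close_to_analytic(self):
        phantom = make_phantom(3, 0.4)
        rec = render_subject(phantom, [], noise_seed=9, frame_size=256)
        mm = metrics_from_masks(rec.masks["A4C"].data, rec.masks["A2C"].data)
        assert mm.lvef == pytest.approx(rec.lvef, abs=3.0)

    def test_recovered_lvef_monotone_in_ejection_amplitude(self):
        lvefs = []
        for alpha in (0.15, 0.22, 0.28):
            phantom = HeartPhantom(a0=80, b0=50, h0=12, alpha=alpha,
                                   contractility=dict(HEALTHY))
            rec = render_subject(phantom, [], noise_seed=1, frame_size=256)
            mm = metrics_from_masks(rec.masks["A4C"].data,
                                    rec.masks["A2C"].data)
            lvefs.append(mm.lvef)
        assert lvefs[0] < lvefs[1] < lvefs[2]
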