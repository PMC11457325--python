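"""Synthetic cohort generator: anatomy, margins, filling, perturbation, dose."""

import numpy as np
import pytest

from oarteval.core import ValidationError, mask_volume
from oarteval.geometry import dice, mda, pooled_surface_distances
from oarteval.phantom import (
    PhantomConfig,
    expand_margin,
    generate_cohort,
    generate_reference_anatomy,
    iter_cohort,
    make_noise_field,
    perturb_contour,
    simulate_filling,
    synth_dose,
)
from conftest import make_grid, sphere_mask


@pytest.fixture(scope="module")
def anatomy():
    config = PhantomConfig(master_seed=5)
    sset, ref = generate_reference_anatomy(config, 42)
    return config, sset, ref


class TestReferenceAnatomy:
    def test_bladder_volume_within_tolerance(self, anatomy):
        config, sset, ref = anatomy
        # the rasterized ellipsoid hits its target volume to ~2% at 2 mm voxels
        lo, hi = config.bladder_reference_volume_range
        assert lo * 0.98 <= ref["bladder"] <= hi * 1.02

    def test_containment_chain_and_body_superset(self, anatomy):
        _, sset, _ = anatomy
        sset.validate()  # raises on violation

    def test_margin_construction(self, anatomy):
        config, sset, _ = anatomy
        gtv, ctv = sset["GTV"].require_binary(), sset["CTV_boost"].require_binary()
        ptv = sset["PTV_boost"].require_binary()
        assert not np.any(gtv & ~ctv) and not np.any(ctv & ~ptv)
        # CTV_elective is bladder ∪ CTV_boost
        elect = sset["CTV_elective"].require_binary()
        assert np.array_equal(elect, sset["bladder"].require_binary() | ctv)

    def test_deterministic_under_seed(self):
        config = PhantomConfig()
        a, _ = generate_reference_anatomy(config, 7)
        b, _ = generate_reference_anatomy(config, 7)
        for role in a.masks:
            assert np.array_equal(a[role].values, b[role].values)


class TestExpandMargin:
    def test_zero_margin_is_identity(self):
        m = make_grid(sphere_mask((20, 20, 20), (9.5, 9.5, 9.5), 5))
        out = expand_margin(m, 0.0)
        assert np.array_equal(out.values, m.values)

    def test_single_voxel_ball_count(self):
        # lattice points with x²+y²+z² ≤ 25 at 1 mm spacing (enumeration oracle)
        m = np.zeros((15, 15, 15), bool)
        m[7, 7, 7] = True
        out = expand_margin(make_grid(m), 5.0)
        r = np.arange(-7, 8)
        oracle = int(
            ((r[:, None, None] ** 2 + r[None, :, None] ** 2 + r[None, None, :] ** 2) <= 25).sum()
        )
        assert out.values.sum() == oracle == 515

    def test_sphere_dilation_matches_analytic_volume(self):
        # center-rule dilation loses about half a voxel of radius, so the
        # sub-2% comparison against the analytic ball needs 0.5 mm voxels
        sp = 0.5
        n = 69
        c = (n // 2) * sp
        m = make_grid(
            sphere_mask((n, n, n), (c, c, c), 10.0, spacing=(sp,) * 3),
            spacing=(sp,) * 3,
        )
        out = expand_margin(m, 5.0)
        expected = 4.0 / 3.0 * np.pi * 15.0**3 / 1000.0
        assert mask_volume(out) == pytest.approx(expected, rel=0.02)

    def test_anisotropic_spacing_respected(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        out = expand_margin(make_grid(m, spacing=(1, 1, 3)), 3.0)
        # reachable voxels: |dx|,|dy| ≤ 3 with dx²+dy²+9dz² ≤ 9
        r = np.arange(-4, 5)
        d2 = r[:, None, None] ** 2 + r[None, :, None] ** 2 + 9 * r[None, None, :] ** 2
        assert out.values.sum() == int((d2 <= 9).sum())


class TestSimulateFilling:
    def _bladder(self):
        return make_grid(
            sphere_mask((60, 60, 60), (59, 59, 59), 36.3, spacing=(2, 2, 2)),
            spacing=(2, 2, 2),
        )

    def test_growth_arithmetic(self):
        bl = self._bladder()
        v0 = mask_volume(bl)
        grown = simulate_filling(bl, rate=2.0, minutes=10.0)
        assert mask_volume(grown) == pytest.approx(v0 + 20.0, rel=0.02)

    def test_zero_rate_is_identity(self):
        bl = self._bladder()
        out = simulate_filling(bl, 0.0, 15.0)
        assert np.array_equal(out.values, bl.values)

    def test_volume_accuracy_for_large_organs(self):
        bl = self._bladder()
        for target in (120.0, 160.0, 220.0):
            from oarteval.phantom import scale_mask_to_volume

            out = scale_mask_to_volume(bl, target)
            assert mask_volume(out) == pytest.approx(target, rel=0.02)


class TestPerturbContour:
    def _mask(self):
        return make_grid(
            sphere_mask((50, 50, 46), (49, 49, 45), 36.0, spacing=(2, 2, 2)),
            spacing=(2, 2, 2),
        )

    def test_zero_amplitude_identity_and_dsc_one(self):
        m = self._mask()
        out = perturb_contour(m, 0.0, seed=1)
        assert np.array_equal(out.values, m.values)
        assert dice(out, m) == 1.0

    def test_mda_bounded_by_amplitude_plus_voxel(self):
        m = self._mask()
        out = perturb_contour(m, 3.0, seed=2)
        d = pooled_surface_distances(out, m)
        diag = np.sqrt(3 * 2.0**2)
        assert 0 < mda(d) <= 3.0 + diag
        assert d.max() <= 3.0 + diag

    def test_dsc_decreases_with_amplitude(self):
        m = self._mask()
        noise = make_noise_field(m.shape, m.spacing, 15.0, np.random.default_rng(3))
        dscs = [
            dice(perturb_contour(m, a, noise_field=noise), m) for a in (1.0, 3.0, 6.0)
        ]
        assert dscs[0] > dscs[1] > dscs[2]

    def test_emptying_perturbation_raises(self):
        tiny = np.zeros((12, 12, 12), bool)
        tiny[6, 6, 6] = True
        with pytest.raises(ValidationError):
            perturb_contour(make_grid(tiny), 0.0, bias_mm=10.0)


class TestSynthDose:
    def test_prescriptions_inside_ptvs_and_falloff(self, anatomy):
        config, sset, _ = anatomy
        dose = synth_dose(sset["PTV_boost"], sset["PTV_elective"],
                          falloff_half_mm=config.dose_falloff_half_mm)
        vals = np.asarray(dose.values)
        assert np.all(vals[sset["PTV_boost"].require_binary()] >= 2.75 - 1e-6)
        assert np.all(vals[sset["PTV_elective"].require_binary()] >= 2.0 - 1e-6)
        # far corner of the grid receives essentially nothing
        assert vals[0, 0, 0] < 0.05

    def test_half_distance_definition(self):
        # an isolated PTV: one voxel-step outside at the half-distance → Rx/2
        ptv = np.zeros((31, 31, 31), bool)
        ptv[10:21, 10:21, 10:21] = True
        g = make_grid(ptv)
        dose = synth_dose(g, g, falloff_half_mm=1.0)
        assert dose.values[21, 15, 15] == pytest.approx(2.75 / 2)
        assert dose.values[22, 15, 15] == pytest.approx(2.75 / 4)

    def test_full_coverage_of_own_elective_ptv(self, anatomy):
        from oarteval.dosimetry import v_at_threshold

        config, sset, _ = anatomy
        dose = synth_dose(sset["PTV_boost"], sset["PTV_elective"])
        pct, _ = v_at_threshold(sset["PTV_elective"], np.asarray(dose.values), 1.9)
        assert pct == 100.0


class TestCohort:
    def test_shape_and_validity(self, tiny_cohort):
        config, sessions, log = tiny_cohort
        assert len(sessions) == config.patients * config.fractions
        assert len(log.entries) == len(sessions)
        for s in sessions:
            s.validate()

    def test_determinism_bit_identical(self):
        config = PhantomConfig(patients=1, fractions=2, master_seed=9)
        a, loga = generate_cohort(config)
        b, logb = generate_cohort(config)
        assert loga.entries == logb.entries
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.dose_auto.values, sb.dose_auto.values)
            for role in sa.contours_auto.masks:
                assert np.array_equal(
                    sa.contours_auto[role].values, sb.contours_auto[role].values
                )

    def test_zero_perturbation_degenerate_cohort(self):
        config = PhantomConfig(
            patients=1, fractions=2, master_seed=3,
            perturb_amplitude_range=(0.0, 0.0), amplitude_volume_coupling=0.0,
            boost_bias_mm=0.0, boost_shift_base_range=(0.0, 0.0),
            boost_shift_per_100cm3=0.0,
        )
        from oarteval.pipeline import evaluate_sessions

        res = evaluate_sessions(iter_cohort(config))
        assert np.all(res.geometric["dsc"] == 1.0)
        assert np.all(res.geometric["mda"] == 0.0)
        piv = res.dosimetric.pivot_table(
            index=["patient_id", "fraction", "structure"],
            columns="arm", values="v95_percent",
        )
        assert np.allclose(piv["clin"], piv["auto"])

    def test_session_volume_changes_logged(self, tiny_cohort):
        _, sessions, log = tiny_cohort
        for s, e in zip(sessions, log.entries):
            dv = abs(mask_volume(s.contours_clin["bladder"]) - s.reference_volumes["bladder"])
            assert dv == pytest.approx(e["bladder_volume_change_cm3"], abs=1e-6)
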