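"""Scan-time AEC simulation: dose law, target aggregation, current
selection, projected noise, and the switching rule."""

import numpy as np
import pytest

from gsiprofile import (
    PatientModel,
    Recommendation,
    Role,
    choose_current,
    generate_cohort,
    generate_patient,
    published_profile,
    projected_ni,
    required_ctdi,
    simulate_exam,
    target_ctdi,
    technologist_rule,
)
from conftest import bounds_family


def flat_patient(d=30.0, n=10, **kw):
    return PatientModel(z=tuple(np.linspace(0, 40, n)), d=(d,) * n, **kw)


class TestRequiredCtdi:
    def test_calibration_point(self):
        p = flat_patient()
        assert required_ctdi(p.d_ref, p, p.ni_ref) == pytest.approx(p.ctdi_ref)

    def test_five_cm_doubles_dose(self):
        """Adding d_double (5 cm) of tissue exactly doubles the dose
        needed to hold the noise level."""
        p = flat_patient()
        assert required_ctdi(p.d_ref + 5.0, p, p.ni_ref) == pytest.approx(2 * p.ctdi_ref)

    def test_halving_ni_quadruples_dose(self):
        p = flat_patient()
        base = required_ctdi(p.d_ref, p, p.ni_ref)
        assert required_ctdi(p.d_ref, p, p.ni_ref / 2) == pytest.approx(4 * base)

    def test_rejects_nonpositive(self):
        p = flat_patient()
        with pytest.raises(ValueError):
            required_ctdi(-1.0, p, 18.0)
        with pytest.raises(ValueError):
            required_ctdi(30.0, p, 0.0)


class TestTargetCtdi:
    def test_constant_patient(self):
        p = flat_patient(d=33.0)
        assert target_ctdi(p, 18.0) == pytest.approx(required_ctdi(33.0, p, 18.0))

    def test_two_slab_patient_mean(self):
        """Half the scan at d_ref, half at d_ref+5 cm: the mean of 1x and
        2x the reference dose is 1.5x."""
        p = PatientModel(z=tuple(range(8)), d=(30.0,) * 4 + (35.0,) * 4)
        assert target_ctdi(p, p.ni_ref) == pytest.approx(1.5 * p.ctdi_ref)

    def test_mean_between_extremes_and_rules_ordered(self):
        p = generate_patient(seed=5, taper_cm=6.0, d_sd=0.3)
        lo = required_ctdi(min(p.d), p, 18.0)
        hi = required_ctdi(max(p.d), p, 18.0)
        t_mean = target_ctdi(p, 18.0, rule="mean")
        assert lo < t_mean < hi
        assert t_mean <= target_ctdi(p, 18.0, rule="quantile", quantile=0.95)
        assert target_ctdi(p, 18.0, rule="max") == pytest.approx(hi)


class TestChooseCurrent:
    def test_clamps_to_range(self):
        fam = bounds_family(7.3, 18.6)
        assert choose_current(fam, 1.0)[1] == 7.3
        assert choose_current(fam, 99.0)[1] == 18.6

    def test_returns_generating_current(self, grid_family):
        ma, actual = choose_current(grid_family, 3.2)
        assert (ma, actual) == (300.0, 3.0)

    def test_random_targets_match_scan(self, grid_family):
        rng = np.random.default_rng(0)
        from oracles import nearest_by_scan
        from gsiprofile import ctdi_grid

        grid = list(ctdi_grid(grid_family).values)
        for t in rng.uniform(0.2, 8.0, size=200):
            assert choose_current(grid_family, float(t))[1] == nearest_by_scan(grid, t)


class TestProjectedNi:
    def test_self_consistency(self):
        """Delivering exactly the required dose projects exactly the
        prescribed noise index everywhere."""
        p = flat_patient(d=32.0)
        actual = required_ctdi(32.0, p, 18.0)
        pni, avg, above = projected_ni(p, actual, 18.0)
        np.testing.assert_allclose(pni, 18.0)
        assert avg == pytest.approx(18.0)

    def test_inverse_square_quartering(self):
        p = flat_patient()
        actual = 4.0 * required_ctdi(30.0, p, 18.0)
        pni, avg, above = projected_ni(p, actual, 18.0)
        np.testing.assert_allclose(pni, 9.0)
        assert not above.any()

    def test_underdosed_scan_flagged_everywhere(self):
        p = flat_patient()
        actual = 0.5 * required_ctdi(30.0, p, 18.0)
        _pni, avg, above = projected_ni(p, actual, 18.0)
        assert above.all()
        assert avg > 18.0


class TestTechnologistRule:
    @pytest.mark.parametrize(
        "avg_pni, expected",
        [
            (18.0, Recommendation.KEEP_PRIMARY),
            (21.0, Recommendation.SWITCH_LARGE),
            (16.0, Recommendation.KEEP_PRIMARY),  # exactly 2 below: not "more than"
            (20.0, Recommendation.KEEP_PRIMARY),  # exactly 2 above
            (15.9, Recommendation.SWITCH_SMALL),
        ],
    )
    def test_boundaries(self, avg_pni, expected):
        assert technologist_rule(avg_pni, 18.0) is expected


@pytest.fixture(scope="module")
def profile():
    return published_profile("liver")


class TestSimulateExam:

    def test_well_matched_patient_keeps_primary(self, profile):
        """Patient sized so the primary family covers the target dose."""
        p = flat_patient(d=30.0)  # target 12 mGy, inside the primary 7.3-18.6
        res = simulate_exam(profile, p, 18.0)
        assert res.recommendation is Recommendation.KEEP_PRIMARY
        assert res.selected_role is Role.MEDIUM

    def test_very_large_patient_switches_large(self, profile):
        p = flat_patient(d=42.0)  # target ~63 mGy, far above primary ceiling
        res = simulate_exam(profile, p, 18.0)
        primary = next(a for a in res.per_family if a.role is Role.MEDIUM)
        assert primary.avg_pni > 18.0 + 2.0
        assert res.recommendation is Recommendation.SWITCH_LARGE
        assert res.selected_role is Role.LARGE

    def test_small_patient_switches_small(self, profile):
        p = flat_patient(d=18.0)
        res = simulate_exam(profile, p, 18.0)
        assert res.recommendation is Recommendation.SWITCH_SMALL
        assert res.selected_role is Role.SMALL

    def test_constant_patient_closed_form(self, profile):
        """For constant-thickness patients the pipeline's AvgPNI equals
        ni*sqrt(target/actual) exactly."""
        for d in (20.0, 26.0, 30.0, 36.0, 44.0):
            p = flat_patient(d=d)
            res = simulate_exam(profile, p, 18.0)
            target = res.target_ctdi
            for a in res.per_family:
                assert a.avg_pni == pytest.approx(
                    18.0 * np.sqrt(target / a.actual_ctdi), rel=1e-9
                )

    def test_selected_dose_within_family_range(self, profile):
        for seed in range(10):
            p = generate_patient(seed=seed, d_mean=float(20 + seed * 2.5), taper_cm=4.0)
            res = simulate_exam(profile, p, 18.0)
            chosen = next(a for a in res.per_family if a.role is res.selected_role)
            fam = profile.member(res.selected_role).family
            assert fam.dose_min - 1e-9 <= chosen.actual_ctdi <= fam.dose_max + 1e-9

    def test_recommendation_monotone_in_patient_size(self, profile):
        """Across a cohort ordered by habitus the recommendation can only
        move small -> keep -> large, never backwards."""
        order = {
            Recommendation.SWITCH_SMALL: 0,
            Recommendation.KEEP_PRIMARY: 1,
            Recommendation.SWITCH_LARGE: 2,
        }
        cohort = generate_cohort(seed=11, n=40, d_sd=0.0, taper_cm=0.0)
        ranks = [order[simulate_exam(profile, p, 18.0).recommendation] for p in cohort]
        assert ranks == sorted(ranks)

    def test_switch_maps_to_keep_when_role_absent(self, profile):
        from gsiprofile import GsiProfile

        no_large = GsiProfile(
            name="truncated",
            members=tuple(m for m in profile.members if m.role is not Role.LARGE),
            primary_role=Role.MEDIUM,
        )
        res = simulate_exam(no_large, flat_patient(d=42.0), 18.0)
        assert res.recommendation is Recommendation.SWITCH_LARGE
        assert res.selected_role is Role.MEDIUM

    def test_small_patient_excess_dose_when_floor_too_high(self):
        """A ladder whose lowest rung exceeds a small patient's need must
        deliver more dose than required (the clinical floor problem)."""
        from gsiprofile import GsiProfile, ProfileMember

        high_floor = GsiProfile(
            name="floor",
            members=(ProfileMember(role=Role.MEDIUM, family=bounds_family(7.3, 18.6)),),
            primary_role=Role.MEDIUM,
        )
        p = flat_patient(d=20.0)
        res = simulate_exam(high_floor, p, 18.0)
        assert res.per_family[0].actual_ctdi == 7.3
        assert res.target_ctdi < 7.3
        assert res.per_family[0].avg_pni < 18.0  # quieter image than asked = excess dose
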