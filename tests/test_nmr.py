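"""NMR restraints: flat-bottom penalties, ambiguity, φψ conversion and
file formats."""

import math

import numpy as np
import pytest

from cgres.fixtures import FixtureSpec, make_nmr_restraints, make_reference
from cgres.nmr import (
    AngularRestraint, DistanceRestraint, NMRRestraintSet, ambiguous_penalty,
    angular_penalty, convert_phi_psi_bounds, distance_penalty, nmr_total,
    read_nef, read_plain, read_star, write_nef, write_plain, _ca_trace,
)
from cgres.geometry import bond_angle, dihedral_angle

from conftest import perturbed


class TestAngularPenalty:
    def test_zero_at_band_center_and_edges(self):
        v, d = angular_penalty(1.5, 1.0, 2.0)
        assert v == 0.0 and d == 0.0
        v, d = angular_penalty(2.0, 1.0, 2.0)
        assert v == 0.0 and d == 0.0

    def test_quartic_branch_value(self):
        """x_l=1, x_u=2, x=2.5 → (1/4)(0.5)^4 = 0.015625."""
        v, _ = angular_penalty(2.5, 1.0, 2.0)
        assert v == pytest.approx(0.015625, abs=1e-14)

    @pytest.mark.parametrize("k", [-2, -1, 1, 3])
    def test_2pi_periodicity(self, k):
        for x in np.linspace(-3, 3, 25):
            v0, d0 = angular_penalty(x, 1.0, 2.0)
            v1, d1 = angular_penalty(x + 2 * math.pi * k, 1.0, 2.0)
            assert v1 == pytest.approx(v0, abs=1e-10)
            assert d1 == pytest.approx(d0, abs=1e-10)

    def test_wrapped_band_across_pi(self):
        # band [π−0.2, −π+0.2 mod 2π] crossing the branch cut
        lo, hi = math.pi - 0.2, math.pi + 0.2
        v, _ = angular_penalty(-math.pi + 0.1, lo, hi)
        assert v == 0.0
        v, _ = angular_penalty(math.pi - 0.1, lo, hi)
        assert v == 0.0
        v, _ = angular_penalty(0.0, lo, hi)
        assert v > 0.0

    def test_c1_continuity_at_band_edge(self):
        eps = 1e-7
        v1, d1 = angular_penalty(2.0 + eps, 1.0, 2.0)
        assert v1 < 1e-20 and abs(d1) < 1e-18


class TestDistancePenalty:
    def test_exactly_zero_inside_bounds(self):
        for d in np.linspace(2.0, 5.0, 17):
            v, g = distance_penalty(d, 2.0, 5.0)
            assert v == 0.0 and g == 0.0

    def test_half_height_at_sigma_offset(self):
        """κ=0, A=1, σ=0.5: V(d_u + σ) = A/2."""
        v, _ = distance_penalty(5.5, 2.0, 5.0, A=1.0, sigma=0.5, kappa=0.0)
        assert v == pytest.approx(0.5, abs=1e-12)

    def test_asymptotic_slope_is_A_kappa(self):
        """With A=1, κ=0.01 the slope at d_u + 50 Å is ≈ 0.01."""
        h = 1e-4
        vp, _ = distance_penalty(55.0 + h, 2.0, 5.0, kappa=0.01)
        vm, _ = distance_penalty(55.0 - h, 2.0, 5.0, kappa=0.01)
        assert (vp - vm) / (2 * h) == pytest.approx(0.01, rel=1e-3)

    def test_derivative_matches_finite_differences(self):
        h = 1e-6
        for d in np.linspace(0.3, 12.0, 60):
            v, g = distance_penalty(d, 2.0, 5.0, A=1.3, sigma=0.7, kappa=0.02)
            vp, _ = distance_penalty(d + h, 2.0, 5.0, A=1.3, sigma=0.7, kappa=0.02)
            vm, _ = distance_penalty(d - h, 2.0, 5.0, A=1.3, sigma=0.7, kappa=0.02)
            assert (vp - vm) / (2 * h) == pytest.approx(g, rel=1e-6, abs=1e-9)

    def test_nonnegative_and_monotone_in_excess(self):
        prev = -1.0
        for d in np.linspace(5.0, 30.0, 80):
            v, _ = distance_penalty(d, 2.0, 5.0, kappa=0.01)
            assert v >= prev - 1e-12
            prev = v


class TestAmbiguousPenalty:
    PRM = {"d_l": 2.0, "d_u": 5.0, "A": 1.0, "sigma": 0.5, "kappa": 0.01}

    def test_single_member_equals_vcont(self):
        v, _ = ambiguous_penalty([(7.0, self.PRM)], alpha=20.0)
        ref, _ = distance_penalty(7.0, **{
            "d_l": 2.0, "d_u": 5.0, "A": 1.0, "sigma": 0.5, "kappa": 0.01})
        assert v == pytest.approx(ref, abs=1e-12)

    def test_satisfied_member_bounds_group_near_zero(self):
        members = [(3.0, self.PRM), (9.0, self.PRM), (12.0, self.PRM)]
        v, _ = ambiguous_penalty(members, alpha=20.0)
        assert -math.log(3) / 20.0 <= v <= 0.0

    def test_logsumexp_sandwich_and_alpha_tightening(self):
        """V ≤ min V_i with gap ≤ ln(n)/α, monotone tighter in α."""
        rng = np.random.default_rng(7)
        ds = rng.uniform(5.1, 10.0, 8)
        members = [(d, self.PRM) for d in ds]
        vmin = min(distance_penalty(d, 2.0, 5.0, 1.0, 0.5, 0.01)[0] for d in ds)
        gaps = []
        for alpha in (1.0, 5.0, 20.0, 100.0):
            v, _ = ambiguous_penalty(members, alpha=alpha)
            assert v <= vmin + 1e-12
            gap = vmin - v
            assert gap <= math.log(len(ds)) / alpha + 1e-12
            gaps.append(gap)
        assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))

    def test_fast_path_matches_full_summation_on_200_members(self):
        """Skip-optimization changes neither value nor gradient."""
        rng = np.random.default_rng(42)
        for trial in range(5):
            ds = np.concatenate([
                rng.uniform(2.5, 6.0, 20), rng.uniform(6.0, 80.0, 180)
            ])
            rng.shuffle(ds)
            members = [(d, self.PRM) for d in ds]
            v_full, g_full = ambiguous_penalty(members, alpha=20.0, fast=False)
            v_fast, g_fast = ambiguous_penalty(members, alpha=20.0, fast=True)
            assert abs(v_full - v_fast) < 1e-8
            denom = np.maximum(np.abs(g_full), 1e-12)
            mask = np.abs(g_full) > 1e-10
            assert np.all(np.abs(g_full - g_fast)[mask] / denom[mask] < 1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ambiguous_penalty([], alpha=20.0)


class TestPhiPsiConversion:
    def test_degenerate_box_collapses_to_point(self):
        out = convert_phi_psi_bounds({2: (-60.0, -60.0, -45.0, -45.0)})
        th = [r for r in out if r.kind == "theta"][0]
        width = (th.upper - th.lower) % (2 * math.pi)
        assert width < 1e-6

    def test_widening_box_never_narrows_envelope(self):
        small = convert_phi_psi_bounds({2: (-70.0, -50.0, -50.0, -40.0)})
        big = convert_phi_psi_bounds({2: (-90.0, -30.0, -70.0, -20.0)})
        tw_s = (small[0].upper - small[0].lower) % (2 * math.pi)
        tw_b = (big[0].upper - big[0].lower) % (2 * math.pi)
        assert tw_b >= tw_s - 1e-9

    def test_envelope_contains_structures_built_inside_box(self):
        """Rejection-sampling oracle: any backbone with dihedrals drawn
        inside the box has (θ, γ) inside the returned bands."""
        rng = np.random.default_rng(5)
        boxes = {1: (-80.0, -40.0, -60.0, -20.0), 2: (-80.0, -40.0, -60.0, -20.0)}
        out = convert_phi_psi_bounds(boxes, grid=9)
        th_r = {r.residue: r for r in out if r.kind == "theta"}
        ga_r = {r.residue: r for r in out if r.kind == "gamma"}
        from cgres.nmr import angular_penalty as ap

        for _ in range(1000):
            ph = rng.uniform(-80, -40, 2)
            ps = rng.uniform(-60, -20, 2)
            ca = _ca_trace([0.0, ph[0], ph[1], 0.0], [0.0, ps[0], ps[1], 0.0])
            th1 = bond_angle(ca[0], ca[1], ca[2])
            v, _ = ap(th1, th_r[1].lower, th_r[1].upper)
            assert v == 0.0
            g1, _ = dihedral_angle(ca[0], ca[1], ca[2], ca[3])
            v, _ = ap(g1, ga_r[1].lower, ga_r[1].upper)
            assert v == 0.0


class TestNMRTotal:
    def test_zero_at_reference_with_noise_free_restraints(self, helix12, helix12_nmr):
        V, gca, gsc, blocks = nmr_total(helix12, helix12_nmr)
        assert V == 0.0
        assert np.all(gca == 0) and np.all(gsc == 0)

    def test_additive_over_disjoint_subsets(self, helix12, helix12_nmr, rng):
        chain = perturbed(helix12, rng)
        half = len(helix12_nmr.distance) // 2
        s1 = NMRRestraintSet(helix12_nmr.angular, helix12_nmr.distance[:half])
        s2 = NMRRestraintSet([], helix12_nmr.distance[half:])
        v_all = nmr_total(chain, helix12_nmr)[0]
        assert v_all == pytest.approx(nmr_total(chain, s1)[0] + nmr_total(chain, s2)[0],
                                      rel=1e-12, abs=1e-12)

    def test_gradient_with_ambiguous_mix_matches_fd(self, rng):
        """15-residue fixture with ~20% ambiguous groups."""
        from cgres.pipeline import RestrainedPotential, RestraintWeights
        from conftest import fd_full, zero_weight_ff

        spec = FixtureSpec(topology="helix", length=15, group_size=3,
                           decoy_fraction=0.25, seed=3)
        ref = make_reference(spec)
        rset = make_nmr_restraints(ref, spec)
        pot = RestrainedPotential(ref.sequence, ff=zero_weight_ff(), nmr=rset,
                                  weights=RestraintWeights(1, 1, 1, 0, 0))
        chain = perturbed(ref, rng, scale=0.25)
        assert fd_full(pot, chain) < 1e-6

    def test_out_of_range_restraint_named_in_error(self, helix12):
        bad = NMRRestraintSet(distance=[DistanceRestraint(0, "HN", 99, "HA", 2.0, 5.0)])
        with pytest.raises(ValueError, match="residue 100"):
            nmr_total(helix12, bad)


class TestFileFormats:
    def _sample(self):
        return NMRRestraintSet(
            angular=[AngularRestraint(3, "theta", 1.4, 1.8),
                     AngularRestraint(3, "gamma", 0.6, 1.1)],
            distance=[
                DistanceRestraint(0, "HN", 4, "HA", 2.0, 5.0),
                DistanceRestraint(1, "SCH", 5, "SCH", 3.0, 6.0, group=7),
                DistanceRestraint(2, "HN", 5, "HN", 3.0, 6.0, group=7),
            ],
        )

    def test_plain_round_trip(self, tmp_path):
        rset = self._sample()
        p = tmp_path / "r.txt"
        write_plain(rset, p)
        back = read_plain(p)
        assert len(back.distance) == 3
        for a, b in zip(rset.distance, back.distance):
            assert (a.res1, a.cls1, a.res2, a.cls2) == (b.res1, b.cls1, b.res2, b.cls2)
            assert a.d_l == pytest.approx(b.d_l, abs=1e-3)
            assert (a.group is None) == (b.group is None)

    def test_nef_round_trip(self, tmp_path):
        rset = self._sample()
        p = tmp_path / "r.nef"
        write_nef(rset, p)
        back = read_nef(p)
        assert len(back.distance) == 3
        assert len(back.angular) == 2
        groups = [r.group for r in back.distance]
        assert groups[0] is None and groups[1] == groups[2] is not None
        for a, b in zip(rset.angular, back.angular):
            assert a.kind == b.kind and a.residue == b.residue
            assert a.lower == pytest.approx(b.lower, abs=1e-3)

    def test_nef_fixture_round_trip_preserves_grouping(self, tmp_path):
        spec = FixtureSpec(topology="helix", length=10, group_size=3,
                           decoy_fraction=0.3, seed=2)
        ref = make_reference(spec)
        rset = make_nmr_restraints(ref, spec)
        p = tmp_path / "fix.nef"
        write_nef(rset, p)
        back = read_nef(p)
        assert len(back.distance) == len(rset.distance)
        def sig(rs):
            return sorted(
                (r.res1, r.cls1, r.res2, r.cls2, round(r.d_l, 3), round(r.d_u, 3))
                for r in rs.distance
            )
        assert sig(back) == sig(rset)

    def test_nmr_star_subset_with_or_logic(self, tmp_path):
        star = """\
data_restraints
save_constraints
   loop_
      _Gen_dist_constraint.ID
      _Gen_dist_constraint.Member_logic_code
      _Gen_dist_constraint.Comp_index_ID_1
      _Gen_dist_constraint.Atom_ID_1
      _Gen_dist_constraint.Comp_index_ID_2
      _Gen_dist_constraint.Atom_ID_2
      _Gen_dist_constraint.Distance_lower_bound_val
      _Gen_dist_constraint.Distance_upper_bound_val

      1 OR 1 H 5 HA 2.0 5.0
      1 OR 2 H 5 HA 2.0 5.0
      2 .  3 HB 6 HB 3.0 6.0
   stop_
save_
"""
        p = tmp_path / "r.str"
        p.write_text(star)
        rset = read_star(p)
        assert len(rset.distance) == 3
        assert rset.distance[0].group == rset.distance[1].group is not None
        assert rset.distance[2].group is None
        assert rset.distance[2].cls1 == "SCH"

    def test_distance_only_switch_drops_angular(self):
        rset = self._sample()
        only = rset.without_angular()
        assert len(only.angular) == 0
        assert len(only.distance) == len(rset.distance)
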