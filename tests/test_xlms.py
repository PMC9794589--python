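"""Crosslink restraints: statistical potential, anchors and the
MD-derived pseudopotentials."""

import math

import numpy as np
import pytest

from cgres.constants import RT_298
from cgres.fixtures import FixtureSpec, make_reference, make_xlms_restraints
from cgres.geometry import CGChain
from cgres.pipeline import RestrainedPotential, RestraintWeights
from cgres.xlms import (
    CrosslinkRestraint, XLMDParams, XLMSRestraintSet, XLStatParams,
    anchor_point, md_derived_potential, read_crosslinks, statistical_potential,
    write_crosslinks, xlms_total,
)
from cgres import _kernels as K

from conftest import fd_full, perturbed, zero_weight_ff


class TestStatisticalPotential:
    PRM = XLStatParams(a=0.02, b=1.0, c=0.01, sigma=8.0)

    def test_linear_in_confidence_weight(self):
        for d in np.linspace(1.0, 60.0, 30):
            w1, _ = statistical_potential(d, self.PRM, A=15.0)
            w2, _ = statistical_potential(d, self.PRM, A=30.0)
            assert w2 == pytest.approx(2 * w1, rel=1e-12)

    def test_argmin_independent_of_confidence(self):
        ds = np.linspace(1.0, 60.0, 2000)
        ref_min = None
        for A in (1.0, 15.0, 40.0):
            vals = [statistical_potential(d, self.PRM, A)[0] for d in ds]
            dmin = ds[int(np.argmin(vals))]
            if ref_min is None:
                ref_min = dmin
            assert dmin == pytest.approx(ref_min, abs=1e-9)

    def test_derivative_matches_finite_differences(self):
        h = 1e-5
        for d in np.linspace(1.0, 60.0, 120):
            _, g = statistical_potential(d, self.PRM, 15.0)
            vp, _ = statistical_potential(d + h, self.PRM, 15.0)
            vm, _ = statistical_potential(d - h, self.PRM, 15.0)
            fd = (vp - vm) / (2 * h)
            assert abs(fd - g) / max(1.0, abs(fd)) < 1e-6

    def test_force_vanishes_at_distribution_mode(self):
        ds = np.linspace(1.0, 60.0, 200001)
        vals = np.array([statistical_potential(d, self.PRM, 15.0)[0] for d in ds])
        dmin = ds[int(np.argmin(vals))]
        _, g = statistical_potential(float(dmin), self.PRM, 15.0)
        assert abs(g) < 1e-3

    def test_rt_convention(self):
        assert RT_298 == 0.591


class TestAnchorPoint:
    def test_zero_offset_is_calpha(self, helix12):
        X, _ = anchor_point(helix12, 3, t=0.0, mode="absolute")
        assert np.allclose(X, helix12.calpha[3])

    def test_full_length_offset_is_sc_site(self, helix12):
        b = float(np.linalg.norm(helix12.sc[3] - helix12.calpha[3]))
        X, _ = anchor_point(helix12, 3, t=b, mode="absolute")
        assert np.allclose(X, helix12.sc[3], atol=1e-12)
        X2, _ = anchor_point(helix12, 3)  # default: fraction 1
        assert np.allclose(X2, helix12.sc[3], atol=1e-12)

    @pytest.mark.parametrize("mode,t", [("fraction", 0.7), ("absolute", 1.9)])
    def test_gradient_matches_finite_differences(self, helix12, rng, mode, t):
        h = 1e-6
        for _ in range(5):
            chain = perturbed(helix12, rng)
            X, grads = anchor_point(chain, 4, t=t, mode=mode)
            for (kind, idx), J in grads.items():
                arr = chain.calpha if kind == "ca" else chain.sc
                for a in range(3):
                    arr[idx, a] += h
                    xp, _ = anchor_point(chain, 4, t=t, mode=mode)
                    arr[idx, a] -= 2 * h
                    xm, _ = anchor_point(chain, 4, t=t, mode=mode)
                    arr[idx, a] += h
                    fd = (xp - xm) / (2 * h)
                    assert np.abs(J[:, a] - fd).max() < 1e-6

    def test_glycine_anchor_rejected(self):
        ca = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.0, 2, 0]])
        chain = CGChain("AGA", ca, np.array([[0.0, 2, 0], [3.8, 0, 0], [7.0, 4, 0]]))
        with pytest.raises(ValueError, match="zero-length"):
            anchor_point(chain, 1)


class TestMDDeriveredPotential:
    def test_single_well_reduces_to_harmonic(self):
        """N_d = 1: V_d = a₁ + ½k₁(d−d°₁)² exactly (empty products = 1)."""
        wa = np.array([0.3])
        wk = np.array([2.0])
        wd0 = np.array([7.0])
        for d in np.linspace(1.0, 15.0, 40):
            v, _ = K.xl_vd(d, wa, wk, wd0, 1)
            assert v == pytest.approx(0.3 + 0.5 * 2.0 * (d - 7.0) ** 2, rel=1e-12)

    def test_multiwell_equals_product_sum_transcription(self):
        """Harmonic smooth-min identity vs the direct product/sum form."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            nw = int(rng.integers(2, 6))
            wa = rng.uniform(0.05, 2.0, nw)
            wk = rng.uniform(0.1, 5.0, nw)
            wd0 = rng.uniform(2.0, 20.0, nw)
            for d in rng.uniform(0.5, 25.0, 10):
                w = wa + 0.5 * wk * (d - wd0) ** 2
                num = np.prod(w)
                den = sum(np.prod(np.delete(w, i)) for i in range(nw))
                direct = num / den
                v, _ = K.xl_vd(float(d), wa, wk, wd0, nw)
                assert v == pytest.approx(direct, rel=1e-12)

    def test_smooth_min_sandwich(self):
        rng = np.random.default_rng(11)
        nw = 4
        wa = rng.uniform(0.05, 2.0, nw)
        wk = rng.uniform(0.1, 5.0, nw)
        wd0 = rng.uniform(2.0, 20.0, nw)
        for d in np.linspace(0.5, 30.0, 100):
            w = wa + 0.5 * wk * (d - wd0) ** 2
            v, _ = K.xl_vd(float(d), wa, wk, wd0, nw)
            assert w.min() / nw - 1e-12 <= v <= w.min() + 1e-12

    def test_vgamma_tends_to_v0_as_theta_vanishes(self):
        cv = np.array([0.2, -0.1, 0.05])
        for ga in np.linspace(-3, 3, 7):
            v, _, _, _ = K.xl_vgamma(ga, 1e-9, 1.2, 0.3, cv, 3)
            assert v == pytest.approx(0.3, abs=1e-8)

    def test_vgamma_periodic_and_bounded(self):
        cv = np.array([0.2, -0.1, 0.05])
        bound = np.abs(cv).sum()
        for ga in np.linspace(-math.pi, math.pi, 17):
            v0, _, _, _ = K.xl_vgamma(ga, 1.1, 1.4, 0.3, cv, 3)
            v1, _, _, _ = K.xl_vgamma(ga + 2 * math.pi, 1.1, 1.4, 0.3, cv, 3)
            assert v1 == pytest.approx(v0, abs=1e-10)
            assert 0.3 - bound - 1e-12 <= v0 <= 0.3 + bound + 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        spec = FixtureSpec(topology="helix", length=10)
        ref = make_reference(spec)
        r = CrosslinkRestraint(0, 7, linker="ZL", family="md_derived")
        prm = XLMDParams()
        h = 1e-6
        for _ in range(5):
            chain = perturbed(ref, rng)
            V, gca, gsc = md_derived_potential(chain, r, prm)
            for arr, g in ((chain.calpha, gca), (chain.sc, gsc)):
                for i in (0, 7):
                    for a in range(3):
                        arr[i, a] += h
                        vp, _, _ = md_derived_potential(chain, r, prm)
                        arr[i, a] -= 2 * h
                        vm, _, _ = md_derived_potential(chain, r, prm)
                        arr[i, a] += h
                        fd = (vp - vm) / (2 * h)
                        assert abs(fd - g[i, a]) < 1e-6 * max(1.0, abs(fd))


class TestXLMSTotal:
    def _mixed_set(self, n=20):
        spec = FixtureSpec(topology="helix", length=n)
        ref = make_reference(spec)
        rs = make_xlms_restraints(ref, spec, linker="DSS")
        rs.restraints = rs.restraints[:3]
        seq = ref.sequence
        acid = [i for i, a in enumerate(seq) if a in "DE"]
        rs.restraints.append(CrosslinkRestraint(acid[0], acid[-1], linker="ZL",
                                                family="statistical"))
        rs.restraints.append(CrosslinkRestraint(acid[0], acid[-1], linker="ADH",
                                                family="md_derived"))
        lys = [i for i, a in enumerate(seq) if a == "K"]
        rs.restraints.append(CrosslinkRestraint(lys[0], lys[-1], linker="BS3",
                                                family="md_derived"))
        return ref, rs

    def test_no_restraints_zero(self, helix12):
        v, gca, gsc, pv = xlms_total(helix12, XLMSRestraintSet())
        assert v == 0.0 and np.all(gca == 0) and np.all(gsc == 0)

    def test_additive_over_restraints(self, rng):
        ref, rs = self._mixed_set()
        chain = perturbed(ref, rng)
        v_all = xlms_total(chain, rs)[0]
        v_sum = sum(
            xlms_total(chain, XLMSRestraintSet([r], rs.stat_params, rs.md_params))[0]
            for r in rs.restraints
        )
        assert v_all == pytest.approx(v_sum, rel=1e-10)

    def test_full_gradient_matches_fd_on_mixed_families(self, rng):
        """20-residue fixture with 6 mixed-family restraints."""
        ref, rs = self._mixed_set()
        pot = RestrainedPotential(ref.sequence, ff=zero_weight_ff(), xlms=rs,
                                  weights=RestraintWeights(0, 0, 0, 1, 0))
        chain = perturbed(ref, rng, scale=0.25)
        assert fd_full(pot, chain) < 1e-6

    def test_zero_flatbottom_penalty_at_reference(self):
        spec = FixtureSpec(topology="helix", length=20)
        ref = make_reference(spec)
        rs = make_xlms_restraints(ref, spec, linker="DSS")
        assert len(rs) > 0
        v, _, _, pv = xlms_total(ref, rs)
        assert v == 0.0 and np.all(pv == 0)

    def test_count_monotone_in_cutoff(self):
        import cgres.fixtures as fx

        spec = FixtureSpec(topology="helix", length=20)
        ref = make_reference(spec)
        counts = []
        orig = dict(fx._XL_CUTOFF)
        try:
            for cut in (10.0, 15.0, 20.0, 25.0):
                fx._XL_CUTOFF["DSS"] = cut
                counts.append(len(make_xlms_restraints(ref, spec, linker="DSS")))
        finally:
            fx._XL_CUTOFF.update(orig)
        assert counts == sorted(counts)

    def test_strict_mode_rejects_noncrosslinkable_residue(self, helix12):
        rs = XLMSRestraintSet([CrosslinkRestraint(1, 5, linker="DSS",
                                                  family="statistical")], strict=True)
        with pytest.raises(ValueError, match="not a crosslinkable"):
            xlms_total(helix12, rs)

    def test_file_round_trip(self, tmp_path):
        spec = FixtureSpec(topology="helix", length=20)
        ref = make_reference(spec)
        rs = make_xlms_restraints(ref, spec, linker="DSS")
        p = tmp_path / "xl.txt"
        write_crosslinks(rs, p)
        back = read_crosslinks(p)
        assert [(r.i, r.j, r.linker, r.family) for r in back.restraints] == \
               [(r.i, r.j, r.linker, r.family) for r in rs.restraints]
        forced = read_crosslinks(p, family="statistical")
        assert all(r.family == "statistical" for r in forced.restraints)
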