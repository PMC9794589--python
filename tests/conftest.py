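"""Shared fixtures: small synthetic chains, restraint sets and a
finite-difference gradient checker used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from cgres.energy import ForceFieldParams
from cgres.fixtures import FixtureSpec, make_reference, make_nmr_restraints
from cgres.geometry import CGChain
from cgres.pipeline import RestrainedPotential, RestraintWeights


@pytest.fixture(scope="session")
def helix12():
    return make_reference(FixtureSpec(topology="helix", length=12))


@pytest.fixture(scope="session")
def helix20():
    return make_reference(FixtureSpec(topology="helix", length=20))


@pytest.fixture(scope="session")
def helix12_nmr(helix12):
    return make_nmr_restraints(helix12, FixtureSpec(topology="helix", length=12))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def perturbed(chain: CGChain, rng, scale: float = 0.3) -> CGChain:
    """Random non-degenerate configuration near a reference chain."""
    return CGChain(
        chain.sequence,
        chain.calpha + scale * rng.standard_normal(chain.calpha.shape),
        chain.sc + scale * rng.standard_normal(chain.sc.shape),
    )


def zero_weight_ff() -> ForceFieldParams:
    return ForceFieldParams(
        **{w: 0.0 for w in (
            "w_sc", "w_scp", "w_pp_vdw", "w_pp_el", "w_tor", "w_b",
            "w_rot", "w_bond", "w_ssbond", "w_corr3", "w_turn3",
        )}
    )


def single_term_ff(name: str) -> ForceFieldParams:
    ff = zero_weight_ff()
    setattr(ff, name, 1.0)
    return ff


NO_RESTRAINTS = RestraintWeights(0, 0, 0, 0, 0)


def fd_directional(pot: RestrainedPotential, chain: CGChain, rng,
                   T: float = 300.0, h: float = 1e-5) -> float:
    """Relative error of the analytic gradient against a central
    finite-difference directional derivative along a random direction."""
    n = len(chain)
    _, gca, gsc = pot.evaluate(chain, T)
    g = np.concatenate([gca.ravel(), gsc.ravel()])
    d = rng.standard_normal(g.shape)
    d /= np.linalg.norm(d)
    x0 = np.concatenate([chain.calpha.ravel(), chain.sc.ravel()])

    def val(x):
        return pot.evaluate(
            CGChain(chain.sequence, x[: 3 * n].reshape(n, 3), x[3 * n:].reshape(n, 3)), T
        )[0]

    fd = (val(x0 + h * d) - val(x0 - h * d)) / (2 * h)
    an = float(g @ d)
    return abs(an - fd) / max(1.0, abs(fd))


def fd_full(pot: RestrainedPotential, chain: CGChain, T: float = 300.0,
            h: float = 1e-6) -> float:
    """Max relative component-wise finite-difference gradient error."""
    n = len(chain)
    _, gca, gsc = pot.evaluate(chain, T)
    g = np.concatenate([gca.ravel(), gsc.ravel()])
    x0 = np.concatenate([chain.calpha.ravel(), chain.sc.ravel()])
    maxe = 0.0
    for k in range(len(x0)):
        xp = x0.copy()
        xp[k] += h
        xm = x0.copy()
        xm[k] -= h
        vp = pot.evaluate(
            CGChain(chain.sequence, xp[: 3 * n].reshape(n, 3), xp[3 * n:].reshape(n, 3)), T
        )[0]
        vm = pot.evaluate(
            CGChain(chain.sequence, xm[: 3 * n].reshape(n, 3), xm[3 * n:].reshape(n, 3)), T
        )[0]
        fd = (vp - vm) / (2 * h)
        maxe = max(maxe, abs(fd - g[k]) / max(1.0, abs(fd)))
    return maxe
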