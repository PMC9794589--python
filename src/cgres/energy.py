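"""Simplified united-residue effective energy.

The potential is a weighted sum over the standard coarse-grained term
inventory

    U = w_SC ΣU_SCSC + w_SCp ΣU_SCp + w_pp^VdW ΣU_pp^VdW
      + w_pp^el f₂(T) ΣU_pp^el + w_tor f₂(T) ΣU_tor + w_b ΣU_b
      + w_rot ΣU_rot + w_bond ΣU_bond + w_ssbond ΣU_ssbond
      + w_corr3 f₃(T) ΣU_corr(3) + w_turn3 f₃(T) ΣU_turn(3)

with temperature factors f_n(T) attached to the mean-field
electrostatic, torsional and third-order correlation terms (these
correspond to higher orders of the underlying cluster-cumulant
expansion of the potential of mean force and therefore carry an
explicit temperature dependence).

The individual term forms here are documented simplified stand-ins
(isotropic 6-12 SC–SC, repulsive r⁻⁶ SC–p, point-dipole peptide
electrostatics, sinθ-damped Fourier torsions, harmonic bond/angle/
rotamer terms, minimal dipole-alignment correlation terms); the full
published tables are not reproduced.  All parameters are
user-replaceable; the shipped defaults are a toy set chosen for
numerically well-behaved chains, not a calibrated force field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .constants import B0_SC, T0_DEFAULT, table
from .geometry import CGChain

TERM_NAMES = (
    "sc_sc", "sc_p", "pp_vdw", "pp_el", "tor", "b", "rot",
    "bond", "ssbond", "corr3", "turn3",
)

#: terms multiplied by f2(T) / f3(T)
F2_TERMS = (K.T_PPEL, K.T_TOR)
F3_TERMS = (K.T_CORR3, K.T_TURN3)

_SC_EPS_DEFAULT = {a: 0.30 for a in "ACDEFGHIKLMNPQRSTVWY"}
# slightly stickier hydrophobics
for _a in "FILMVWY":
    _SC_EPS_DEFAULT[_a] = 0.45
_SC_SIG_DEFAULT = {
    "A": 4.0, "C": 4.4, "D": 4.6, "E": 4.9, "F": 5.3, "G": 3.6, "H": 5.0,
    "I": 5.0, "K": 5.0, "L": 5.0, "M": 5.0, "N": 4.6, "P": 4.4, "Q": 4.9,
    "R": 5.3, "S": 4.1, "T": 4.4, "V": 4.7, "W": 5.6, "Y": 5.4,
}


def temperature_factor(n: int, T: float, T0: float = T0_DEFAULT) -> float:
    """Temperature factor f_n(T) of order-n cumulant terms.

    f_n(T) = ln[e + e⁻¹] / ln[exp((T/T°)^(n−1)) + exp(−(T/T°)^(n−1))].

    f₁ ≡ 1, f_n(T°) = 1, and f_n is non-increasing in T for n ≥ 2,
    vanishing as T → ∞.
    """
    if T <= 0 or T0 <= 0:
        raise ValueError("temperatures must be positive")
    if n < 1:
        raise ValueError("order must be >= 1")
    x = (T / T0) ** (n - 1)
    num = math.log(math.e + math.exp(-1.0))
    # ln(e^x + e^-x) evaluated overflow-safely
    den = x + math.log1p(math.exp(-2.0 * x))
    return num / den


@dataclass
class ForceFieldParams:
    """Weights, per-term parameters and the reference temperature T°.

    Pair tables are per-residue-type arrays in one-letter alphabetical
    order (see :data:`cgres.constants.AA1`); SC–SC pairs use geometric-
    mean ε and arithmetic-mean σ mixing.
    """

    w_sc: float = 1.0
    w_scp: float = 1.0
    w_pp_vdw: float = 1.0
    w_pp_el: float = 1.0
    w_tor: float = 1.0
    w_b: float = 1.0
    w_rot: float = 1.0
    w_bond: float = 1.0
    w_ssbond: float = 1.0
    w_corr3: float = 1.0
    w_turn3: float = 1.0
    T0: float = T0_DEFAULT

    sc_eps: np.ndarray = field(default_factory=lambda: table(_SC_EPS_DEFAULT))
    sc_sig: np.ndarray = field(default_factory=lambda: table(_SC_SIG_DEFAULT))
    b0_sc: np.ndarray = field(default_factory=lambda: table(B0_SC))

    eps_scp: float = 0.20      # kcal/mol, SC-p repulsion
    sig_scp: float = 4.0       # Å
    pp_eps: float = 0.20       # kcal/mol, peptide VdW well
    pp_sig: float = 4.2        # Å
    mu2: float = 2.0           # kcal/mol·Å³, peptide dipole strength
    k_theta: float = 5.0       # kcal/mol/rad², virtual-bond-angle force const
    theta0: float = 1.90       # rad, reference virtual-bond angle
    k_alpha: float = 2.0       # kcal/mol/rad², rotamer polar
    alpha0: float = 2.10       # rad
    k_beta: float = 0.5        # kcal/mol/rad², rotamer azimuth
    beta0: float = 0.0         # rad
    k_bond: float = 50.0       # kcal/mol/Å², Cα-Cα bond
    d0_bond: float = 3.8       # Å
    k_bsc: float = 10.0        # kcal/mol/Å², Cα-SC bond
    a_corr: float = 0.10       # kcal/mol, dipole-alignment correlation
    sig_corr: float = 5.0      # Å
    a_turn: float = 0.20       # kcal/mol, local turn correlation
    r_soft: float = 0.25       # Å, soft-core regularization radius
    tor_c: np.ndarray = field(
        default_factory=lambda: np.array([0.4, 0.2, 0.1])
    )  # torsional Fourier coefficients, kcal/mol

    def __post_init__(self) -> None:
        self.sc_eps = np.asarray(self.sc_eps, dtype=np.float64)
        self.sc_sig = np.asarray(self.sc_sig, dtype=np.float64)
        self.b0_sc = np.asarray(self.b0_sc, dtype=np.float64)
        self.tor_c = np.asarray(self.tor_c, dtype=np.float64)
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array(
            [
                self.w_sc, self.w_scp, self.w_pp_vdw, self.w_pp_el,
                self.w_tor, self.w_b, self.w_rot, self.w_bond,
                self.w_ssbond, self.w_corr3, self.w_turn3,
            ]
        )

    def scalars(self) -> np.ndarray:
        s = np.zeros(K.N_SCAL)
        s[K.S_EPS_SCP] = self.eps_scp
        s[K.S_SIG_SCP] = self.sig_scp
        s[K.S_PP_EPS] = self.pp_eps
        s[K.S_PP_SIG] = self.pp_sig
        s[K.S_MU2] = self.mu2
        s[K.S_K_THETA] = self.k_theta
        s[K.S_THETA0] = self.theta0
        s[K.S_K_ALPHA] = self.k_alpha
        s[K.S_ALPHA0] = self.alpha0
        s[K.S_K_BETA] = self.k_beta
        s[K.S_BETA0] = self.beta0
        s[K.S_K_BOND] = self.k_bond
        s[K.S_D0_BOND] = self.d0_bond
        s[K.S_K_BSC] = self.k_bsc
        s[K.S_A_CORR] = self.a_corr
        s[K.S_SIG_CORR] = self.sig_corr
        s[K.S_A_TURN] = self.a_turn
        s[K.S_RSOFT2] = self.r_soft**2
        return s

    def prefactors(self, T: float) -> np.ndarray:
        """Effective per-term prefactors weight × f_n(T)."""
        pref = self.weights.copy()
        f2 = temperature_factor(2, T, self.T0)
        f3 = temperature_factor(3, T, self.T0)
        for t in F2_TERMS:
            pref[t] *= f2
        for t in F3_TERMS:
            pref[t] *= f3
        return pref

    def with_weights(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


def energy_and_gradient(
    chain: CGChain,
    params: ForceFieldParams,
    T: float = 300.0,
    return_terms: bool = False,
):
    """Total effective energy (kcal/mol) and analytic site gradient.

    Gradient arrays have the shapes of ``chain.calpha`` / ``chain.sc``.
    With ``return_terms`` also returns a dict of the weighted,
    temperature-scaled per-term contributions.
    """
    if len(chain) < 2:
        raise ValueError("chain must have at least 2 residues")
    from .constants import seq_to_idx

    tidx = seq_to_idx(chain.sequence)
    pref = params.prefactors(T)
    terms, gca, gsc = K.ff_energy(
        chain.calpha, chain.sc, tidx, params.sc_eps, params.sc_sig,
        params.b0_sc, params.scalars(), params.tor_c, pref,
    )
    total = float(np.dot(pref, terms))
    if not np.isfinite(total):
        bad = [TERM_NAMES[t] for t in range(K.N_TERMS) if not np.isfinite(terms[t])]
        raise FloatingPointError(f"non-finite energy in term(s): {', '.join(bad)}")
    if return_terms:
        contrib = {TERM_NAMES[t]: float(pref[t] * terms[t]) for t in range(K.N_TERMS)}
        return total, gca, gsc, contrib
    return total, gca, gsc


def minimize(
    chain: CGChain,
    potential,
    tol: float = 1e-6,
    max_iter: int = 2000,
):
    """Local minimization of a (V, gca, gsc)-valued potential.

    ``potential(chain) -> (V, gca, gsc)``; L-BFGS on the stacked site
    coordinates until the projected gradient norm falls below ``tol``
    or ``max_iter`` iterations.  Returns (chain, final energy, info).
    """
    from scipy.optimize import minimize as _sp_min

    n = len(chain)
    x0 = np.concatenate([chain.calpha.ravel(), chain.sc.ravel()])

    def fg(x):
        c = CGChain(chain.sequence, x[: 3 * n].reshape(n, 3), x[3 * n:].reshape(n, 3))
        V, gca, gsc = potential(c)
        return V, np.concatenate([gca.ravel(), gsc.ravel()])

    res = _sp_min(
        fg, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    out = CGChain(
        chain.sequence,
        res.x[: 3 * n].reshape(n, 3),
        res.x[3 * n:].reshape(n, 3),
    )
    info = {
        "converged": bool(res.success or np.max(np.abs(res.jac)) <= tol),
        "n_iter": int(res.nit),
        "grad_inf_norm": float(np.max(np.abs(res.jac))),
        "message": str(res.message),
    }
    return out, float(res.fun), info
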