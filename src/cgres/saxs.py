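"""SAXS distance-distribution restraint.

The experimental pair-distance distribution P(r) (obtained upstream by
indirect Fourier transform of the scattering intensity) is compared
with a distribution computed from the coarse-grained conformation as a
sum of log-normal kernels over Cα pairs,

    P^calc(r_k) = (1/A) Σ_{i<j} exp[−(ln r_ij − ln r_k)²/(2σ_ij²)],
    σ_ij = (r°_i + r°_j)/r_ij,
    r°_i = ρ_i + σ_max + (σ_min − σ_max)(x_i + 1)/2,

where ρ_i is the residue Stokes radius and x_i ∈ [0, 1] the clamped
neighbor occupancy: the effective kernel width interpolates the
solvation shell between σ_min (buried, x=1) and (σ_min+σ_max)/2
(exposed, x=0).  The penalty is the maximum-likelihood cross-entropy

    V_SAXS = −Δr Σ_k P^exp(r_k) ln P^calc(r_k),

minimized (Gibbs' inequality) exactly when P^calc matches P^exp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .constants import stokes_radius
from .geometry import CGChain

log = logging.getLogger(__name__)

#: floor for ln P^calc arguments, 1/Å
EPS_FLOOR = 1e-12


@dataclass
class DistanceDistribution:
    """Binned P(r): equally spaced bin centers r (Å), values p (1/Å)."""

    r: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.r.ndim != 1 or self.r.shape != self.p.shape or len(self.r) < 2:
            raise ValueError("need matching 1-D r/p arrays with >= 2 bins")
        dr = np.diff(self.r)
        # tolerance accommodates print-precision-limited input files
        if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-4, atol=1e-7):
            raise ValueError("bin centers must be strictly increasing, equally spaced")
        if np.any(self.p < 0):
            raise ValueError("negative probability values")

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def d_max(self) -> float:
        return float(self.r[-1] + 0.5 * self.dr)

    def normalized(self) -> "DistanceDistribution":
        """Copy with Δr·Σp = 1."""
        s = self.dr * self.p.sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return DistanceDistribution(self.r.copy(), self.p / s)

    def resampled(self, r_new: np.ndarray) -> "DistanceDistribution":
        p_new = np.interp(r_new, self.r, self.p, left=0.0, right=0.0)
        return DistanceDistribution(r_new, p_new).normalized()


@dataclass
class SolvationParams:
    """Solvation-shell model parameters."""

    sigma_min: float = 1.0   # Å
    sigma_max: float = 3.0   # Å
    r_cut: float = 8.0       # Å neighbor cutoff
    n_sat: int = 10          # saturation neighbor count
    rho: dict[str, float] | None = None  # per-type Stokes radii override

    def __post_init__(self) -> None:
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must be <= sigma_max")

    def rho_for(self, sequence: str) -> np.ndarray:
        if self.rho is not None:
            return np.array([self.rho[a] for a in sequence], dtype=np.float64)
        return np.array([stokes_radius(a) for a in sequence], dtype=np.float64)


def neighbor_occupancy(chain: CGChain, i: int, params: SolvationParams | None = None) -> float:
    """x_i = min(1, n_i/N_sat): clamped count of non-bonded residues
    within the neighbor cutoff of residue i's Cα."""
    prm = params or SolvationParams()
    x = K.saxs_occupancy(chain.calpha, prm.r_cut, float(prm.n_sat))
    return float(x[int(i)])


def default_bins(d_max: float, n_bins: int = 50) -> np.ndarray:
    """Bin centers covering (0, d_max] with Δr = d_max/n_bins."""
    dr = d_max / n_bins
    return (np.arange(n_bins) + 0.5) * dr


def calc_distribution(
    chain: CGChain,
    bins: np.ndarray,
    solvation: SolvationParams | None = None,
) -> DistanceDistribution:
    """Log-normal P^calc on the given bin centers, normalized Δr·Σp = 1."""
    if len(chain) < 2:
        raise ValueError("need at least 2 residues")
    prm = solvation or SolvationParams()
    bins = np.asarray(bins, dtype=np.float64)
    d = np.linalg.norm(
        chain.calpha[:, None, :] - chain.calpha[None, :, :], axis=-1
    )
    iu = np.triu_indices(len(chain), k=1)
    if np.any(d[iu] < 1e-9):
        raise ValueError("coincident Cα positions (r_ij = 0)")
    if d[iu].max() > bins[-1] + 0.5 * (bins[1] - bins[0]):
        log.warning(
            "bins do not cover the largest Cα distance (%.1f Å > d_max %.1f Å); "
            "distribution renormalized over the covered range",
            d[iu].max(), bins[-1],
        )
    x = K.saxs_occupancy(chain.calpha, prm.r_cut, float(prm.n_sat))
    r0 = K.saxs_r0(x, prm.rho_for(chain.sequence), prm.sigma_min, prm.sigma_max)
    dr = float(bins[1] - bins[0])
    p, _, _ = K.saxs_pcalc(chain.calpha, r0, bins, dr)
    return DistanceDistribution(bins, p)


def saxs_penalty(
    p_exp: DistanceDistribution,
    p_calc: DistanceDistribution,
    eps: float = EPS_FLOOR,
) -> float:
    """Discrete cross-entropy −Δr Σ P^exp ln P^calc (kcal/mol units by
    convention of the restraint weight)."""
    if p_exp.r.shape != p_calc.r.shape or not np.allclose(p_exp.r, p_calc.r, atol=1e-6):
        if abs(p_exp.d_max - p_calc.d_max) > 0.5 * max(p_exp.dr, p_calc.dr) * 4:
            raise ValueError(
                f"d_max mismatch: {p_exp.d_max:.1f} vs {p_calc.d_max:.1f} Å"
            )
        log.warning("bin grids differ; resampling the experimental P(r)")
        p_exp = p_exp.resampled(p_calc.r)
    pc = np.maximum(p_calc.p, eps)
    return float(-p_exp.dr * np.sum(p_exp.p * np.log(pc)))


def saxs_gradient(
    chain: CGChain,
    p_exp: DistanceDistribution,
    solvation: SolvationParams | None = None,
    weight: float = 1.0,
):
    """Penalty of the chain against P^exp and its analytic Cα gradient.

    The chain rule runs through the σ_ij(r_ij) dependence of the
    kernels; the neighbor occupancy (a clamped discrete count) is
    treated as locally constant.  Returns (V, gca).
    """
    prm = solvation or SolvationParams()
    n = len(chain)
    x = K.saxs_occupancy(chain.calpha, prm.r_cut, float(prm.n_sat))
    r0 = K.saxs_r0(x, prm.rho_for(chain.sequence), prm.sigma_min, prm.sigma_max)
    gca = np.zeros((n, 3))
    V = K.saxs_energy_grad(
        chain.calpha, r0, p_exp.r, p_exp.dr, p_exp.p, EPS_FLOOR, weight, gca
    )
    return float(V), gca


# ---------------------------------------------------------------------------
# CRYSOL-layout file I/O
# ---------------------------------------------------------------------------

def read_pr(path) -> DistanceDistribution:
    """Read a P(r) file in the CRYSOL output layout.

    Whitespace-separated columns r, P(r) (optional third error column);
    header/comment lines that do not parse as two floats are skipped.
    The input is renormalized to Δr·Σp = 1.
    """
    rs, ps = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                continue
            try:
                r, p = float(parts[0]), float(parts[1])
            except ValueError:
                continue
            rs.append(r)
            ps.append(p)
    if len(rs) < 2:
        raise ValueError(f"{path}: no parsable P(r) rows")
    r = np.array(rs)
    p = np.array(ps)
    if r[0] == 0.0:  # CRYSOL includes the r=0 row; drop it to keep log-bins valid
        r, p = r[1:], p[1:]
    dist = DistanceDistribution(r, p).normalized()
    log.info("read %d P(r) bins from %s (renormalized to Δr·Σp = 1)", len(r), path)
    return dist


def write_pr(dist: DistanceDistribution, path) -> None:
    """Write P(r) in the CRYSOL three-column layout."""
    with open(path, "w") as fh:
        fh.write("          Distance distribution  P(r)\n")
        fh.write("       R              P(R)            ERROR\n")
        fh.write(f"  {0.0:14.6e}  {0.0:14.6e}  {0.0:14.6e}\n")
        for r, p in zip(dist.r, dist.p):
            fh.write(f"  {r:14.6e}  {p:14.6e}  {0.0:14.6e}\n")
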