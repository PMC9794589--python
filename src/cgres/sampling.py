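"""Conformational sampling: MD, temperature replica exchange, binless
WHAM reweighting and RMSD clustering.

Dynamics runs on the Cα and SC site coordinates with diagonal
effective masses (backbone sites carry the CO–NH–CαH mass, SC sites
the side-chain mass) — a documented simplification of the full
coarse-grained Lagrangian, whose inertia couples neighboring sites.
Integrators: velocity Verlet (NVE), Berendsen weak coupling, and
Langevin dynamics via BAOAB splitting.  Replica exchange swaps
temperatures between neighboring replicas with the Metropolis
criterion P = min(1, exp[(β_i − β_j)(E_i − E_j)]), rescaling
velocities by √(T_new/T_old).  Multi-temperature ensembles are
combined by the standard binless WHAM (self-consistent free-energy
iteration), giving per-sample weights at any target temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import _kernels as K
from .constants import ACCEL_UNIT, BACKBONE_MASS, KB, SC_MASS, DT_DEFAULT
from .geometry import CGChain, kabsch

log = logging.getLogger(__name__)

THERMOSTATS = {"none": 0, "berendsen": 1, "langevin": 2}


def site_masses(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal effective masses (amu) for backbone and SC sites."""
    mca = np.full(len(sequence), BACKBONE_MASS)
    msc = np.array([SC_MASS[a] for a in sequence])
    return mca, msc


@dataclass
class MDState:
    """Coordinates, velocities (Å/fs), masses (amu) and bath settings."""

    chain: CGChain
    vca: np.ndarray
    vsc: np.ndarray
    mca: np.ndarray
    msc: np.ndarray
    temperature: float = 300.0
    step: int = 0

    @classmethod
    def from_chain(cls, chain: CGChain, temperature: float = 300.0, seed: int = 0) -> "MDState":
        """Maxwell–Boltzmann velocities at the bath temperature."""
        rng = np.random.default_rng(seed)
        mca, msc = site_masses(chain.sequence)
        n = len(chain)
        vca = rng.standard_normal((n, 3)) * np.sqrt(KB * temperature * ACCEL_UNIT / mca)[:, None]
        vsc = rng.standard_normal((n, 3)) * np.sqrt(KB * temperature * ACCEL_UNIT / msc)[:, None]
        return cls(chain.copy(), vca, vsc, mca, msc, temperature)

    def kinetic_energy(self) -> float:
        return float(K.kinetic_energy(self.vca, self.vsc, self.mca, self.msc))

    def kinetic_temperature(self) -> float:
        ndof = 6 * len(self.chain)
        return 2.0 * self.kinetic_energy() / (KB * ndof)

    def copy(self) -> "MDState":
        return MDState(
            self.chain.copy(), self.vca.copy(), self.vsc.copy(),
            self.mca.copy(), self.msc.copy(), self.temperature, self.step,
        )


@dataclass
class Trajectory:
    frames: list[CGChain] = field(default_factory=list)
    epot: np.ndarray = None  # type: ignore[assignment]
    ekin: np.ndarray = None  # type: ignore[assignment]
    times: np.ndarray = None  # type: ignore[assignment]


class EnergyExplosion(RuntimeError):
    pass


def md_run(
    state: MDState,
    potential,
    n_steps: int,
    dt: float = DT_DEFAULT,
    thermostat: str = "langevin",
    seed: int = 0,
    tau: float = 1000.0,
    friction: float = 1e-3,
    log_interval: int = 100,
    frame_interval: int = 0,
) -> Trajectory:
    """Run MD in place on ``state``; returns the sampled trajectory.

    ``potential`` must provide ``kernel_args(T)`` (the compiled force
    argument tuple).  thermostat: 'none' (NVE), 'berendsen' (coupling
    time tau, fs) or 'langevin' (friction, 1/fs).  Bitwise reproducible
    for a given seed.
    """
    code = THERMOSTATS[thermostat]
    args = potential.kernel_args(state.temperature)
    rng = np.random.default_rng(seed)
    frames: list[CGChain] = []
    epot_all: list[float] = []
    ekin_all: list[float] = []
    chunk = frame_interval if frame_interval > 0 else n_steps
    done = 0
    while done < n_steps:
        todo = min(chunk, n_steps - done)
        ntr_max = todo // log_interval + 1 if log_interval > 0 else 1
        ep = np.zeros(ntr_max)
        ek = np.zeros(ntr_max)
        status, ntr = K.md_chunk(
            state.chain.calpha, state.chain.sc, state.vca, state.vsc,
            state.mca, state.msc, args,
            todo, dt, code, state.temperature, tau, friction,
            int(rng.integers(0, 2**31 - 1)), log_interval, ep, ek,
        )
        if status != 0:
            raise EnergyExplosion(
                f"energy explosion after ~{state.step + done} steps "
                f"(|U| > 1e8 kcal/mol or non-finite)"
            )
        epot_all.extend(ep[:ntr])
        ekin_all.extend(ek[:ntr])
        done += todo
        if frame_interval > 0:
            frames.append(state.chain.copy())
    state.step += n_steps
    m = len(epot_all)
    times = dt * log_interval * (1 + np.arange(m))
    return Trajectory(frames, np.array(epot_all), np.array(ekin_all), times)


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

def exchange_sweep(
    energies: np.ndarray,
    temperatures: np.ndarray,
    parity: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One sweep of neighbor-pair Metropolis exchanges.

    ``energies[k]`` is the potential energy of the walker currently at
    temperature slot k.  Pairs (k, k+1) with k ≡ parity (mod 2) attempt
    a swap with acceptance min(1, exp[(β_k − β_{k+1})(E_k − E_{k+1})]).
    Returns (permutation of slot occupants, attempted mask, accepted
    mask), each per neighbor pair.
    """
    nrep = len(energies)
    beta = 1.0 / (KB * np.asarray(temperatures, dtype=float))
    perm = np.arange(nrep)
    attempted = np.zeros(nrep - 1, dtype=bool)
    accepted = np.zeros(nrep - 1, dtype=bool)
    e = np.asarray(energies, dtype=float).copy()
    for k in range(parity % 2, nrep - 1, 2):
        attempted[k] = True
        delta = (beta[k] - beta[k + 1]) * (e[k] - e[k + 1])
        if delta >= 0 or rng.random() < np.exp(delta):
            accepted[k] = True
            perm[k], perm[k + 1] = perm[k + 1], perm[k]
            e[k], e[k + 1] = e[k + 1], e[k]
    return perm, attempted, accepted


@dataclass
class ReplicaEnsemble:
    """Per-replica MD states on a strictly increasing temperature ladder."""

    states: list[MDState]
    temperatures: np.ndarray
    exchange_interval: int = 1000
    attempted: np.ndarray = None  # type: ignore[assignment]
    accepted: np.ndarray = None  # type: ignore[assignment]
    # samples per temperature slot: (coords-chain, potential energy)
    samples: list[list[tuple[CGChain, float]]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature ladder must be strictly increasing")
        if len(self.states) != len(self.temperatures):
            raise ValueError("one state per temperature required")
        if self.attempted is None:
            self.attempted = np.zeros(len(self.states) - 1, dtype=np.int64)
            self.accepted = np.zeros(len(self.states) - 1, dtype=np.int64)
        if self.samples is None:
            self.samples = [[] for _ in self.states]

    @classmethod
    def from_chain(
        cls, chain: CGChain, temperatures, exchange_interval: int = 1000, seed: int = 0
    ) -> "ReplicaEnsemble":
        temps = np.asarray(temperatures, dtype=float)
        states = [
            MDState.from_chain(chain, T, seed=seed + 17 * k)
            for k, T in enumerate(temps)
        ]
        return cls(states, temps, exchange_interval)

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempted > 0, self.accepted / self.attempted, np.nan)


def remd_run(
    ensemble: ReplicaEnsemble,
    potential,
    n_steps: int,
    seed: int = 0,
    dt: float = DT_DEFAULT,
    thermostat: str = "langevin",
    friction: float = 1e-3,
    tau: float = 1000.0,
    sample_interval: int | None = None,
) -> ReplicaEnsemble:
    """Temperature REMD: alternating even/odd neighbor sweeps every
    ``exchange_interval`` steps; temperatures migrate between replicas
    and velocities are rescaled by √(T_new/T_old).  Samples (structure,
    energy) are recorded per temperature slot at each exchange point
    (or every ``sample_interval`` steps).  With a single replica this
    reduces exactly to :func:`md_run`."""
    rng = np.random.default_rng(seed)
    nrep = len(ensemble.states)
    interval = ensemble.exchange_interval
    sample_interval = sample_interval or interval
    n_rounds = max(n_steps // interval, 1)
    parity = 0
    for rnd in range(n_rounds):
        energies = np.empty(nrep)
        for k, st in enumerate(ensemble.states):
            md_run(
                st, potential, interval, dt=dt, thermostat=thermostat,
                seed=int(rng.integers(0, 2**31 - 1)), tau=tau,
                friction=friction, log_interval=0,
            )
            args = potential.kernel_args(st.temperature)
            V, _, _, _ = K.total_force(st.chain.calpha, st.chain.sc, args)
            energies[k] = V
        # record samples at the current slot assignment
        order = np.argsort([st.temperature for st in ensemble.states])
        for slot, k in enumerate(order):
            st = ensemble.states[k]
            ensemble.samples[slot].append((st.chain.copy(), float(energies[k])))
        if nrep > 1:
            slot_e = energies[order]
            perm, att, acc = exchange_sweep(
                slot_e, ensemble.temperatures, parity, rng
            )
            ensemble.attempted += att
            ensemble.accepted += acc
            for slot in range(nrep):
                k = order[perm[slot]]
                st = ensemble.states[k]
                t_new = ensemble.temperatures[slot]
                if st.temperature != t_new:
                    scale = np.sqrt(t_new / st.temperature)
                    st.vca *= scale
                    st.vsc *= scale
                    st.temperature = t_new
            parity ^= 1
    return ensemble


# ---------------------------------------------------------------------------
# binless WHAM
# ---------------------------------------------------------------------------

def wham_reweight(
    energies: np.ndarray,
    source_temps: np.ndarray,
    target_T: float,
    tol: float = 1e-8,
    max_iter: int = 10000,
):
    """Binless WHAM weights at ``target_T``.

    ``energies[n]`` sampled at ``source_temps[n]`` (K).  Iterates the
    self-consistent dimensionless free energies f_k of each source
    temperature until max|Δf| < tol, then returns

        w_n ∝ exp(−β_t E_n) / Σ_k N_k exp(f_k − β_k E_n),

    normalized to Σw = 1, plus a dict with the free energies and an
    effective-sample-size diagnostic.  A single source temperature
    reduces to plain Boltzmann reweighting.
    """
    E = np.asarray(energies, dtype=float)
    Ts = np.asarray(source_temps, dtype=float)
    if E.shape != Ts.shape or E.size == 0:
        raise ValueError("need matching non-empty energies and source temperatures")
    uT, inv = np.unique(Ts, return_inverse=True)
    Nk = np.bincount(inv).astype(float)
    beta_k = 1.0 / (KB * uT)
    beta_t = 1.0 / (KB * target_T)
    f = np.zeros(len(uT))
    # iterate: exp(-f_k) = Σ_n exp(-β_k E_n) / Σ_m N_m exp(f_m - β_m E_n)
    A = -np.outer(beta_k, E)  # (K, N)
    for it in range(max_iter):
        denom = logsumexp(
            (f + np.log(Nk))[:, None] + A, axis=0
        )  # log Σ_m N_m exp(f_m - β_m E_n)
        newf = -logsumexp(A - denom[None, :], axis=1)
        newf = newf - newf[0]
        delta = np.max(np.abs(newf - f))
        f = newf
        if delta < tol:
            break
    else:
        log.warning("WHAM did not converge to %g in %d iterations", tol, max_iter)
    denom = logsumexp((f + np.log(Nk))[:, None] + A, axis=0)
    logw = -beta_t * E - denom
    logw -= logsumexp(logw)
    w = np.exp(logw)
    ess = 1.0 / np.sum(w**2)
    if len(uT) > 1:
        # overlap diagnostic: effective samples contributed per window
        if ess < 10:
            log.warning(
                "poor temperature overlap: effective sample size %.1f of %d",
                ess, len(E),
            )
    info = {"free_energies": f, "temperatures": uT, "ess": float(ess), "n_iter": it + 1}
    return w, info


def ensemble_average(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean and its standard error (effective-sample-size based)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = float(np.sum(w * v))
    var = float(np.sum(w * (v - mean) ** 2))
    ess = 1.0 / np.sum(w**2)
    return mean, np.sqrt(var / max(ess, 1.0))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_ensemble(
    conformations: list[CGChain],
    weights: np.ndarray | None = None,
    n_clusters: int | None = None,
    cutoff: float | None = None,
):
    """Hierarchical (average-linkage) clustering on pairwise Cα RMSD.

    Returns a list of cluster dicts sorted by summed weight, each with
    the member indices, total weight and the representative index (the
    member with minimal weighted RMSD to its cluster mates).
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    m = len(conformations)
    if m == 0:
        raise ValueError("no conformations to cluster")
    if weights is None:
        weights = np.full(m, 1.0 / m)
    weights = np.asarray(weights, dtype=float)
    if n_clusters is not None and n_clusters > m:
        raise ValueError(f"requested {n_clusters} clusters from {m} conformations")
    if m == 1:
        return [{"members": [0], "weight": float(weights[0]), "representative": 0}]
    D = np.zeros((m, m))
    coords = [c.calpha for c in conformations]
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = kabsch(coords[i], coords[j])[2]
    Z = linkage(squareform(D, checks=False), method="average")
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(Z, t=cutoff if cutoff is not None else 2.0, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        wsum = float(weights[idx].sum())
        # representative: min weighted mean RMSD to cluster mates
        best, best_score = int(idx[0]), np.inf
        for i in idx:
            score = float(np.sum(weights[idx] * D[i, idx]))
            if score < best_score:
                best, best_score = int(i), score
        clusters.append({"members": idx.tolist(), "weight": wsum, "representative": best})
    clusters.sort(key=lambda c: c["weight"], reverse=True)
    return clusters
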