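"""Restrained potential assembly and end-to-end job driving.

The working potential is

    V = U + w_NMR^θ V_NMR^θ + w_NMR^γ V_NMR^γ + w_NMR^dist V_NMR^dist
          + w_XLMS^dist V_XLMS^dist + w_SAXS V_SAXS,

the effective coarse-grained energy U plus the five experimental
restraint blocks, each individually reportable.  Three job types are
driven end-to-end: energy minimization, plain MD (with Cα fluctuation
profile and RMSD-vs-time against an optional reference), and REMD with
binless-WHAM reweighting, clustering and a per-family
restraint-satisfaction report.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels as K
from .constants import RT_298, seq_to_idx
from .energy import ForceFieldParams
from .geometry import CGChain, cartesian_from_internal, cg_from_pdb, kabsch, write_cg_pdb, InternalCoords
from .nmr import NMRRestraintSet
from .protons import DEFAULT_ESTIMATOR, ProtonEstimator
from .sampling import (
    MDState, ReplicaEnsemble, Trajectory, cluster_ensemble, md_run,
    remd_run, wham_reweight,
)
from .saxs import DistanceDistribution, EPS_FLOOR, SolvationParams
from .xlms import XLMSRestraintSet, _FLAT_KEYS, _MD_KEYS, _STAT_KEYS

log = logging.getLogger(__name__)

BLOCK_NAMES = ("energy", "nmr_theta", "nmr_gamma", "nmr_dist", "xlms", "saxs")


@dataclass
class RestraintWeights:
    """Weights of the five restraint blocks (all default 1)."""

    nmr_theta: float = 1.0
    nmr_gamma: float = 1.0
    nmr_dist: float = 1.0
    xlms: float = 1.0
    saxs: float = 1.0

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("restraint weights must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.nmr_theta, self.nmr_gamma, self.nmr_dist, self.xlms, self.saxs]
        )


_EMPTY_I = np.zeros(0, dtype=np.int32)
_EMPTY_F = np.zeros(0, dtype=np.float64)


def _empty_xlms() -> dict:
    return XLMSRestraintSet().pack(1, "A")


@dataclass
class RestrainedPotential:
    """Compiled V = U + Σ w·V_block for one chain topology.

    Packs the force field and restraint sets into the argument tuple
    consumed by the JIT force kernel; argument tuples are cached per
    temperature.
    """

    sequence: str
    ff: ForceFieldParams = field(default_factory=ForceFieldParams)
    nmr: NMRRestraintSet | None = None
    xlms: XLMSRestraintSet | None = None
    saxs_pr: DistanceDistribution | None = None
    solvation: SolvationParams = field(default_factory=SolvationParams)
    weights: RestraintWeights = field(default_factory=RestraintWeights)
    estimator: ProtonEstimator = field(default_factory=lambda: DEFAULT_ESTIMATOR)
    fast_ambiguous: bool = True

    def __post_init__(self) -> None:
        self._cache: dict[float, tuple] = {}
        n = len(self.sequence)
        self._tidx = seq_to_idx(self.sequence)
        p = (self.nmr or NMRRestraintSet()).pack(n)
        self._nmr = p
        self._xl = (self.xlms.pack(n, self.sequence) if self.xlms else _empty_xlms())
        if self.xlms is None:
            for k in ("xf_i", "xf_j", "xs_i", "xs_j", "xm_i", "xm_j"):
                self._xl[k] = _EMPTY_I
        if self.saxs_pr is not None:
            self._sx = (
                self.solvation.rho_for(self.sequence),
                float(self.solvation.sigma_min), float(self.solvation.sigma_max),
                float(self.solvation.r_cut), float(self.solvation.n_sat),
                self.saxs_pr.r, self.saxs_pr.dr, self.saxs_pr.p, EPS_FLOOR,
            )
        else:
            self._sx = (_EMPTY_F, 1.0, 3.0, 8.0, 10.0, _EMPTY_F, 1.0, _EMPTY_F, EPS_FLOOR)

    def kernel_args(self, T: float) -> tuple:
        T = float(T)
        if T not in self._cache:
            est = self.estimator
            p = self._nmr
            x = self._xl
            self._cache[T] = (
                self._tidx, self.ff.sc_eps, self.ff.sc_sig, self.ff.b0_sc,
                self.ff.scalars(), self.ff.tor_c, self.ff.prefactors(T),
                p["ang_kind"], p["ang_idx"], p["ang_xl"], p["ang_xu"],
                p["uq_res"], p["uq_cls"], p["mem_p1"], p["mem_p2"],
                p["gs"], p["m_dl"], p["m_du"], p["m_A"], p["m_sig"], p["m_kap"],
                p["g_alpha"], est.hn_offset, est.ha_offset, est.pads,
                self.fast_ambiguous,
                *(x[k] for k in _FLAT_KEYS),
                *(x[k] for k in _STAT_KEYS), RT_298,
                *(x[k] for k in _MD_KEYS),
                *self._sx,
                self.weights.as_array(),
            )
        return self._cache[T]

    def evaluate(self, chain: CGChain, T: float = 300.0, blocks: bool = False):
        """(V, gca, gsc) and optionally the per-block breakdown."""
        if chain.sequence != self.sequence:
            raise ValueError("chain sequence does not match the compiled potential")
        V, gca, gsc, b = K.total_force(chain.calpha, chain.sc, self.kernel_args(T))
        if not np.isfinite(V):
            bad = [BLOCK_NAMES[i] for i in range(6) if not np.isfinite(b[i])]
            raise FloatingPointError(f"non-finite potential in block(s): {', '.join(bad)}")
        if blocks:
            return float(V), gca, gsc, dict(zip(BLOCK_NAMES, b.tolist()))
        return float(V), gca, gsc

    def __call__(self, chain: CGChain):
        return self.evaluate(chain)


def total_potential(
    chain: CGChain,
    ff: ForceFieldParams,
    nmr: NMRRestraintSet | None = None,
    xlms: XLMSRestraintSet | None = None,
    saxs_pr: DistanceDistribution | None = None,
    weights: RestraintWeights | None = None,
    T: float = 300.0,
    solvation: SolvationParams | None = None,
):
    """One-shot restrained potential evaluation with block breakdown."""
    pot = RestrainedPotential(
        chain.sequence, ff, nmr, xlms, saxs_pr,
        solvation or SolvationParams(), weights or RestraintWeights(),
    )
    return pot.evaluate(chain, T, blocks=True)


# ---------------------------------------------------------------------------
# structure metrics
# ---------------------------------------------------------------------------

def structure_metrics(model: CGChain, reference: CGChain) -> dict:
    """Cα RMSD (Å) and GDT_TS of model vs reference.

    GDT_TS is the mean over the 1/2/4/8 Å cutoffs of the maximal
    fraction of Cα within the cutoff, maximized over superpositions
    seeded from all contiguous 4-residue segments and iteratively
    refined on the within-cutoff subset (standard approximation of the
    exhaustive search), ×100.
    """
    P = model.calpha
    Q = reference.calpha
    if P.shape != Q.shape:
        raise ValueError("model and reference have different residue counts")
    n = len(P)
    _, _, rmsd = kabsch(P, Q)
    cutoffs = (1.0, 2.0, 4.0, 8.0)
    best = {c: 0.0 for c in cutoffs}
    seeds = [np.arange(i, i + 4) for i in range(0, max(n - 3, 1))]
    seeds.append(np.arange(n))
    for seed_idx in seeds:
        R, t, _ = kabsch(P[seed_idx], Q[seed_idx])
        for c in cutoffs:
            sel = seed_idx
            for _ in range(4):
                d = np.linalg.norm(P @ R.T + t - Q, axis=1)
                new = np.where(d <= c)[0]
                frac = len(new) / n
                if frac > best[c]:
                    best[c] = frac
                if len(new) < 3 or len(new) == len(sel) and np.array_equal(new, sel):
                    break
                sel = new
                R, t, _ = kabsch(P[sel], Q[sel])
    gdt = 100.0 * float(np.mean([best[c] for c in cutoffs]))
    return {"rmsd": float(rmsd), "gdt_ts": gdt}


def fluctuation_profile(frames: list[CGChain]) -> np.ndarray:
    """Per-residue Cα RMS fluctuation about the superposed trajectory mean."""
    if not frames:
        raise ValueError("empty trajectory")
    ref = frames[len(frames) // 2].calpha
    aligned = []
    for fr in frames:
        R, t, _ = kabsch(fr.calpha, ref)
        aligned.append(fr.calpha @ R.T + t)
    arr = np.array(aligned)
    mean = arr.mean(axis=0)
    return np.sqrt(np.mean(np.sum((arr - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# job driving
# ---------------------------------------------------------------------------

@dataclass
class JobConfig:
    """Configuration of one end-to-end run."""

    job: str = "minimize"                  # minimize | md | remd
    sequence: str | None = None
    pdb: str | None = None
    start: str = "pdb"                     # pdb | extended | random
    temperatures: tuple[float, ...] = (300.0,)
    n_steps: int = 10000
    dt: float = 9.78
    seed: int = 0
    exchange_interval: int = 1000
    thermostat: str = "langevin"
    n_clusters: int = 5
    min_tol: float = 1e-4
    max_min_iter: int = 500
    reference_pdb: str | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        if self.job not in ("minimize", "md", "remd"):
            raise ValueError(f"unknown job type {self.job!r}")
        if self.start == "pdb" and not self.pdb:
            raise ValueError("start='pdb' requires a pdb path")
        if self.start != "pdb" and not self.sequence:
            raise ValueError(f"start={self.start!r} requires a sequence")
        if self.job == "remd" and len(self.temperatures) < 2:
            raise ValueError("remd requires at least 2 temperatures")
        if self.n_steps <= 0 or self.dt <= 0:
            raise ValueError("n_steps and dt must be positive")


def make_start_chain(config: JobConfig) -> CGChain:
    from .fixtures import extended_chain, random_chain

    if config.start == "pdb":
        return cg_from_pdb(config.pdb)
    if config.start == "extended":
        return extended_chain(config.sequence)
    if config.start == "random":
        return random_chain(config.sequence, seed=config.seed)
    raise ValueError(f"unknown start {config.start!r}")


def restraint_satisfaction(
    potential: RestrainedPotential, chain: CGChain, T: float = 300.0
) -> dict:
    """Fraction of restraints with (numerically) zero penalty, per family."""
    out = {}
    p = potential._nmr
    n = len(chain)
    tidx = potential._tidx
    if len(p["ang_kind"]):
        cnt = 0
        for r in range(len(p["ang_kind"])):
            i = int(p["ang_idx"][r])
            if p["ang_kind"][r] == 0:
                from .geometry import bond_angle
                x = bond_angle(chain.calpha[i - 1], chain.calpha[i], chain.calpha[i + 1])
            else:
                from .geometry import dihedral_angle
                x, _ = dihedral_angle(
                    chain.calpha[i - 1], chain.calpha[i],
                    chain.calpha[i + 1], chain.calpha[i + 2],
                )
            v, _ = K.angular_flatbottom(x, p["ang_xl"][r], p["ang_xu"][r])
            cnt += v < 1e-9
        out["angular"] = cnt / len(p["ang_kind"])
    if len(p["gs"]) > 1:
        gv = np.zeros(len(p["gs"]) - 1)
        gca = np.zeros((n, 3))
        gsc = np.zeros((n, 3))
        est = potential.estimator
        K.nmr_distance_energy(
            chain.calpha, chain.sc, p["uq_res"], p["uq_cls"], p["mem_p1"], p["mem_p2"],
            p["gs"], p["m_dl"], p["m_du"], p["m_A"], p["m_sig"], p["m_kap"],
            p["g_alpha"], est.hn_offset, est.ha_offset, est.pads, tidx,
            0.0, potential.fast_ambiguous, gca, gsc, gv,
        )
        out["distance"] = float(np.mean(np.abs(gv) < 1e-6))
    if potential.xlms is not None and len(potential.xlms):
        from .xlms import xlms_total

        _, _, _, pv = xlms_total(chain, potential.xlms, 1.0)
        flat = [r.family == "flatbottom" for r in potential.xlms.restraints]
        nflat = sum(flat)
        if nflat:
            out["xlms_flatbottom"] = float(np.mean(np.abs(pv[:nflat]) < 1e-9))
    return out


def run_job(config: JobConfig, potential_factory=None, **pot_kwargs) -> dict:
    """Run a configured job end to end; returns the result bundle.

    ``potential_factory(sequence) -> RestrainedPotential`` may be given
    to supply pre-built restraints; otherwise ``pot_kwargs`` are passed
    to :class:`RestrainedPotential`.
    """
    config.validate()
    chain = make_start_chain(config)
    if potential_factory is not None:
        pot = potential_factory(chain.sequence)
    else:
        pot = RestrainedPotential(chain.sequence, **pot_kwargs)
    reference = cg_from_pdb(config.reference_pdb) if config.reference_pdb else None
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    T0 = config.temperatures[0]
    result: dict = {"job": config.job, "sequence": chain.sequence}

    if config.job == "minimize" or config.start in ("extended", "random"):
        from .energy import minimize as _min

        chain, e_min, info = _min(
            chain, lambda c: pot.evaluate(c, T0),
            tol=config.min_tol, max_iter=config.max_min_iter,
        )
        result["minimized_energy"] = e_min
        result["minimize_info"] = info

    if config.job == "minimize":
        V, _, _, blocks = pot.evaluate(chain, T0, blocks=True)
        result["energy"] = V
        result["blocks"] = blocks
        result["structure"] = chain
        if reference is not None:
            result["metrics"] = structure_metrics(chain, reference)
        if out_dir:
            write_cg_pdb(chain, out_dir / "minimized.pdb")
            (out_dir / "report.json").write_text(
                json.dumps({k: v for k, v in result.items() if k != "structure"},
                           default=str, indent=1)
            )
        return result

    if config.job == "md":
        state = MDState.from_chain(chain, T0, seed=config.seed)
        traj = md_run(
            state, pot, config.n_steps, dt=config.dt,
            thermostat=config.thermostat, seed=config.seed,
            frame_interval=max(config.n_steps // 200, 1), log_interval=100,
        )
        result["structure"] = state.chain
        result["epot"] = traj.epot
        result["ekin"] = traj.ekin
        result["fluctuations"] = fluctuation_profile(traj.frames)
        if reference is not None:
            result["rmsd_t"] = np.array(
                [kabsch(fr.calpha, reference.calpha)[2] for fr in traj.frames]
            )
            result["metrics"] = structure_metrics(state.chain, reference)
        if out_dir:
            write_cg_pdb(state.chain, out_dir / "final.pdb", models=traj.frames)
            np.savetxt(
                out_dir / "energies.dat",
                np.column_stack([traj.times, traj.epot, traj.ekin]),
                header="time_fs epot ekin",
            )
        return result

    # REMD protocol: production run, WHAM, clustering, satisfaction report
    ens = ReplicaEnsemble.from_chain(
        chain, config.temperatures, config.exchange_interval, seed=config.seed
    )
    remd_run(
        ens, pot, config.n_steps, seed=config.seed, dt=config.dt,
        thermostat=config.thermostat,
    )
    confs: list[CGChain] = []
    energies: list[float] = []
    temps: list[float] = []
    # discard the first fifth as equilibration
    for slot, samp in enumerate(ens.samples):
        skip = len(samp) // 5
        for c, e in samp[skip:]:
            confs.append(c)
            energies.append(e)
            temps.append(ens.temperatures[slot])
    w, wham_info = wham_reweight(np.array(energies), np.array(temps), T0)
    n_cl = min(config.n_clusters, len(confs))
    clusters = cluster_ensemble(confs, w, n_clusters=n_cl)
    reps = [confs[c["representative"]] for c in clusters]
    result["clusters"] = clusters
    result["representatives"] = reps
    result["wham"] = wham_info
    result["acceptance"] = ens.acceptance_rates()
    result["satisfaction"] = restraint_satisfaction(pot, reps[0], T0)
    if reference is not None:
        result["metrics"] = [structure_metrics(r, reference) for r in reps]
    if out_dir:
        for k, rep in enumerate(reps):
            write_cg_pdb(rep, out_dir / f"cluster_{k + 1}.pdb")
        report = {
            "acceptance": result["acceptance"].tolist(),
            "satisfaction": result["satisfaction"],
            "cluster_weights": [c["weight"] for c in clusters],
        }
        if reference is not None:
            report["metrics"] = result["metrics"]
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return result


# ---------------------------------------------------------------------------
# secondary-structure restraints
# ---------------------------------------------------------------------------

#: canonical (θ, γ) windows (rad) for helix (H) and strand (E) states
SS_WINDOWS = {
    "H": {"theta": (1.45, 1.75), "gamma": (0.60, 1.10)},
    "E": {"theta": (1.95, 2.45), "gamma": (2.60, 3.60)},
}


def secondary_structure_restraints(ss: str) -> NMRRestraintSet:
    """Angular restraints from a per-residue secondary-structure string
    (H = helix, E = strand, other = unrestrained)."""
    from .nmr import AngularRestraint

    rset = NMRRestraintSet()
    n = len(ss)
    for i, s in enumerate(ss):
        if s not in SS_WINDOWS:
            continue
        win = SS_WINDOWS[s]
        if 1 <= i < n - 1 and ss[i - 1] == s and ss[i + 1] == s:
            rset.angular.append(AngularRestraint(i, "theta", *win["theta"]))
        if 1 <= i < n - 2 and all(ss[j] == s for j in (i - 1, i + 1, i + 2)):
            rset.angular.append(AngularRestraint(i, "gamma", *win["gamma"]))
    return rset
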