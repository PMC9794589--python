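"""Synthetic reference structures and restraint sets.

Every pipeline stage is testable without external data: ideal-geometry
reference chains (helix, hairpin, two-domain), NMR restraint sets
derived from the reference's estimated interproton distances and
virtual-bond angles (with controllable bound padding, ambiguity and
decoy contamination), crosslink lists from crosslinkable residue pairs
within linker reach, and SAXS P(r) profiles computed from the
reference.  By construction, at zero noise and zero decoy fraction the
reference structure incurs zero restraint penalty.

Scales are NOE-like: interproton restraints are generated below a
5 Å cutoff with ±0.5 Å bounds; angular restraints get ±0.1 rad bands.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import CGChain, InternalCoords, cartesian_from_internal, write_cg_pdb
from .nmr import AngularRestraint, DistanceRestraint, NMRRestraintSet, write_nef, write_plain
from .protons import CLASS_NAMES, DEFAULT_ESTIMATOR
from .saxs import SolvationParams, calc_distribution, default_bins, write_pr
from .xlms import LINKER_TARGETS, CrosslinkRestraint, XLMSRestraintSet, write_crosslinks

#: ideal Cα-trace internal coordinates per topology (θ, γ in rad)
HELIX_THETA, HELIX_GAMMA = 1.58, 0.90
STRAND_THETA, STRAND_GAMMA = 2.20, 3.00

_SEQ_PATTERN = "KDAELVISRE"


def _default_sequence(length: int) -> str:
    return (_SEQ_PATTERN * (length // len(_SEQ_PATTERN) + 1))[:length]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic test system."""

    topology: str = "helix"          # helix | hairpin | two-domain
    length: int = 20
    sequence: str | None = None
    cutoff: float = 5.0              # Å, interproton restraint cutoff
    pad: float = 0.5                 # Å, distance bound half-width
    ang_pad: float = 0.1             # rad, angular bound half-width
    noise: float = 0.0               # Å, extra bound padding
    decoy_fraction: float = 0.0      # fraction of decoy members per group
    group_size: int = 1              # ambiguous group size (1 = unambiguous)
    xl_family: str = "flatbottom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("fixture length must be >= 4")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy fraction must be in [0, 1)")
        if self.topology not in ("helix", "hairpin", "two-domain"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.sequence is None:
            self.sequence = _default_sequence(self.length)
        if len(self.sequence) != self.length:
            raise ValueError("sequence length mismatch")


def _chain_from_angles(sequence: str, theta: np.ndarray, gamma: np.ndarray) -> CGChain:
    n = len(sequence)
    from .constants import B0_SC, table

    b0 = table(B0_SC)
    from .constants import seq_to_idx

    tidx = seq_to_idx(sequence)
    ic = InternalCoords(
        d=np.full(n - 1, 3.8),
        theta=theta,
        gamma=gamma,
        alpha=np.full(n, 2.10),
        beta=np.zeros(n),
        b_sc=np.array([b0[tidx[i]] for i in range(n)]),
    )
    return cartesian_from_internal(ic, sequence)


def make_reference(spec: FixtureSpec) -> CGChain:
    """Deterministic ideal-geometry reference for the topology."""
    n = spec.length
    seq = spec.sequence
    if spec.topology == "helix":
        theta = np.full(n - 2, HELIX_THETA)
        gamma = np.full(n - 3, HELIX_GAMMA)
    elif spec.topology == "hairpin":
        # two strands joined by a turn with reversed γ sign
        theta = np.full(n - 2, STRAND_THETA)
        gamma = np.full(n - 3, STRAND_GAMMA)
        mid = (n - 3) // 2
        turn = slice(max(mid - 1, 0), min(mid + 1, n - 3))
        gamma[turn] = -0.8
        theta[max(mid - 1, 0): min(mid + 2, n - 2)] = 1.65
    else:  # two-domain: two helices joined by an extended linker
        theta = np.full(n - 2, HELIX_THETA)
        gamma = np.full(n - 3, HELIX_GAMMA)
        mid = n // 2
        lo = max(mid - 3, 0)
        hi = min(mid + 2, n - 3)
        theta[max(mid - 3, 0): min(mid + 3, n - 2)] = 2.9
        gamma[lo:hi] = math.pi - 0.05
    return _chain_from_angles(seq, theta, gamma)


def extended_chain(sequence: str) -> CGChain:
    """Near-straight starting structure."""
    n = len(sequence)
    return _chain_from_angles(
        sequence, np.full(n - 2, 2.7), np.full(n - 3, math.pi - 0.05)
    )


def random_chain(sequence: str, seed: int = 0) -> CGChain:
    """Random self-avoiding-ish starting structure (rebuild may still
    clash; jobs pre-minimize such starts)."""
    rng = np.random.default_rng(seed)
    n = len(sequence)
    theta = rng.uniform(1.4, 2.6, n - 2)
    gamma = rng.uniform(-math.pi, math.pi, n - 3)
    return _chain_from_angles(sequence, theta, gamma)


# ---------------------------------------------------------------------------
# NMR restraints
# ---------------------------------------------------------------------------

def make_nmr_restraints(reference: CGChain, spec: FixtureSpec) -> NMRRestraintSet:
    """Restraints the reference satisfies exactly (modulo decoys).

    All estimated interproton distances below ``spec.cutoff`` become
    restraints with bounds [d − pad − noise, d + pad + noise]; the
    reference θ/γ values become angular bands of half-width
    ang_pad + noise.  With ``group_size`` > 1 or ``decoy_fraction`` > 0
    each distance restraint is embedded in an ambiguous group that
    keeps the reference-satisfied member and adds decoy members whose
    reference distance violates the shared bounds.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(reference)
    est = DEFAULT_ESTIMATOR
    pos = est.all_positions(reference)
    rset = NMRRestraintSet()
    pad = spec.pad + spec.noise

    from .geometry import internal_from_cartesian

    ic = internal_from_cartesian(reference)
    apad = spec.ang_pad + spec.noise
    for i in range(1, n - 1):
        rset.angular.append(
            AngularRestraint(i, "theta", ic.theta[i - 1] - apad, ic.theta[i - 1] + apad)
        )
    for i in range(1, n - 2):
        rset.angular.append(
            AngularRestraint(i, "gamma", ic.gamma[i - 1] - apad, ic.gamma[i - 1] + apad)
        )

    pairs = []
    for i in range(n):
        for j in range(i + 2, n):
            for c1 in range(3):
                for c2 in range(3):
                    d = float(np.linalg.norm(pos[i, c1] - pos[j, c2]))
                    if d < spec.cutoff:
                        pairs.append((i, c1, j, c2, d))

    group_id = 0
    ambiguous = spec.group_size > 1 or spec.decoy_fraction > 0
    for (i, c1, j, c2, d) in pairs:
        dl = max(0.0, d - pad)
        du = d + pad
        if not ambiguous:
            rset.distance.append(
                DistanceRestraint(i, CLASS_NAMES[c1], j, CLASS_NAMES[c2], dl, du)
            )
            continue
        k = max(spec.group_size, 2 if spec.decoy_fraction > 0 else 1)
        n_decoy = int(round(spec.decoy_fraction * k))
        n_decoy = min(max(n_decoy, 1 if spec.decoy_fraction > 0 else 0), k - 1)
        group_id += 1
        rset.distance.append(
            DistanceRestraint(i, CLASS_NAMES[c1], j, CLASS_NAMES[c2], dl, du, group=group_id)
        )
        made = 0
        attempts = 0
        while made < n_decoy and attempts < 200:
            attempts += 1
            a = int(rng.integers(0, n))
            b = int(rng.integers(0, n))
            if abs(a - b) < 2:
                continue
            ca_, cb_ = int(rng.integers(0, 3)), int(rng.integers(0, 3))
            dd = float(np.linalg.norm(pos[a, ca_] - pos[b, cb_]))
            if dd <= du + 2.0:  # must genuinely violate the shared bounds
                continue
            rset.distance.append(
                DistanceRestraint(a, CLASS_NAMES[ca_], b, CLASS_NAMES[cb_], dl, du, group=group_id)
            )
            made += 1
    return rset


# ---------------------------------------------------------------------------
# XL-MS restraints
# ---------------------------------------------------------------------------

#: per-linker Cα-Cα emission cutoffs (Å)
_XL_CUTOFF = {"ADH": 20.0, "PDH": 22.0, "DSS": 20.0, "ZL": 12.0, "BS2G": 18.0, "BS3": 20.0}


def make_xlms_restraints(
    reference: CGChain, spec: FixtureSpec, linker: str = "DSS"
) -> XLMSRestraintSet:
    """Crosslinks between linker-compatible residue pairs within reach."""
    targets = LINKER_TARGETS[linker]
    cutoff = _XL_CUTOFF[linker]
    rs = XLMSRestraintSet()
    n = len(reference)
    for i in range(n):
        if reference.sequence[i] not in targets:
            continue
        for j in range(i + 3, n):
            if reference.sequence[j] not in targets:
                continue
            d = float(np.linalg.norm(reference.calpha[i] - reference.calpha[j]))
            if d < cutoff:
                rs.restraints.append(
                    CrosslinkRestraint(
                        i, j, linker=linker, family=spec.xl_family,
                        d_l=0.0, d_u=cutoff + spec.noise,
                    )
                )
    return rs


# ---------------------------------------------------------------------------
# SAXS profile
# ---------------------------------------------------------------------------

def make_saxs_profile(
    reference: CGChain,
    solvation: SolvationParams | None = None,
    n_bins: int = 50,
):
    """P(r) of the reference on bins covering its size (plus margin)."""
    d = np.linalg.norm(
        reference.calpha[:, None, :] - reference.calpha[None, :, :], axis=-1
    )
    d_max = float(d.max()) * 1.15
    bins = default_bins(d_max, n_bins)
    return calc_distribution(reference, bins, solvation)


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def write_fixture_bundle(spec: FixtureSpec, out_dir) -> dict:
    """Emit reference PDB + restraint files + manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = make_reference(spec)
    nmr = make_nmr_restraints(ref, spec)
    xl = make_xlms_restraints(ref, spec)
    pr = make_saxs_profile(ref)
    paths = {
        "reference": str(out / "reference.pdb"),
        "nmr_plain": str(out / "nmr_restraints.txt"),
        "nmr_nef": str(out / "nmr_restraints.nef"),
        "xlms": str(out / "crosslinks.txt"),
        "saxs": str(out / "saxs_pr.dat"),
    }
    write_cg_pdb(ref, paths["reference"])
    write_plain(nmr, paths["nmr_plain"])
    write_nef(nmr, paths["nmr_nef"])
    write_crosslinks(xl, paths["xlms"])
    write_pr(pr, paths["saxs"])
    manifest = {
        "spec": {k: getattr(spec, k) for k in (
            "topology", "length", "sequence", "cutoff", "pad", "ang_pad",
            "noise", "decoy_fraction", "group_size", "xl_family", "seed")},
        "files": paths,
        "counts": {"nmr_angular": len(nmr.angular), "nmr_distance": len(nmr.distance),
                   "crosslinks": len(xl)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
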