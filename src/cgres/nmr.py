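"""NMR angular and (ambiguous) interproton-distance restraints.

Angular restraints are periodic flat-bottom penalties on the
virtual-bond angles θ and dihedrals γ:

    g(x; x_l, x_u) = 0                         inside [x_l, x_u] (mod 2π)
    g(x; x_l, x_u) = (1/4)(|δ| − (x_u−x_l)/2)⁴  outside,

with δ the offset from the band center wrapped to (−π, π].

Distance restraints act on estimated interproton distances through the
flat-bottom well V_cont (zero on [d_l, d_u], quartic-ratio walls of
height A and thickness σ, asymptote A + κ(d − d_u)).  An ambiguous set
{d_i} sharing one NOE signal is scored by the log-exp soft minimum

    V = −(1/α) ln Σ_i exp(−α V_cont(d_i)),

which is ≈ min_i V_cont(d_i) for large α (default 20): the set is
satisfied as soon as any one assignment is satisfied.

File formats: a plain-text dialect (one restraint per line), an NEF
subset (``nef_distance_restraint_list`` / ``nef_dihedral_restraint_list``
saveframes, ``restraint_id`` driving ambiguity grouping) and an
NMR-STAR subset (``Gen_dist_constraint`` loops with OR member logic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .constants import seq_to_idx
from .geometry import CGChain, dihedral_angle, bond_angle
from .protons import CLASS_CODES, CLASS_NAMES, DEFAULT_ESTIMATOR, ProtonEstimator

log = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# restraint types
# ---------------------------------------------------------------------------

@dataclass
class AngularRestraint:
    """Flat-bottom restraint on θ (vertex at `residue`) or γ (axis
    residue→residue+1); bounds in radians, reduced mod 2π."""

    residue: int
    kind: str  # "theta" | "gamma"
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in ("theta", "gamma"):
            raise ValueError(f"unknown angular restraint kind {self.kind!r}")
        self.lower = float(self.lower) % TWO_PI
        self.upper = float(self.upper) % TWO_PI


@dataclass
class DistanceRestraint:
    """Interproton distance restraint between (residue, proton class)
    selectors; members sharing a ``group`` form one ambiguous set."""

    res1: int
    cls1: str
    res2: int
    cls2: str
    d_l: float
    d_u: float
    A: float = 1.0
    sigma: float = 0.5
    kappa: float = 0.01
    group: int | None = None
    alpha: float = 20.0

    def __post_init__(self) -> None:
        if self.cls1 not in CLASS_CODES or self.cls2 not in CLASS_CODES:
            raise ValueError(f"unknown proton class in restraint {self}")
        if not (0 <= self.d_l <= self.d_u):
            raise ValueError(f"invalid bounds 0 <= d_l <= d_u in {self}")
        if self.A <= 0 or self.sigma <= 0 or self.kappa < 0 or self.alpha <= 0:
            raise ValueError(f"invalid parameters in {self}")


@dataclass
class NMRRestraintSet:
    angular: list[AngularRestraint] = field(default_factory=list)
    distance: list[DistanceRestraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.angular) + len(self.distance)

    def without_angular(self) -> "NMRRestraintSet":
        """Distance-only view (the ``--distance-only`` switch)."""
        return NMRRestraintSet([], list(self.distance))

    # -- kernel packing ----------------------------------------------------

    def validate(self, n: int) -> None:
        for r in self.angular:
            lo = 1 if r.kind == "theta" else 1
            hi = n - 1 if r.kind == "theta" else n - 2
            if not (lo <= r.residue < hi):
                raise ValueError(
                    f"angular restraint on {r.kind} at residue {r.residue + 1} "
                    f"outside the valid range for a {n}-residue chain"
                )
        for r in self.distance:
            for res in (r.res1, r.res2):
                if not 0 <= res < n:
                    raise ValueError(
                        f"distance restraint references residue {res + 1} "
                        f"of a {n}-residue chain"
                    )
            if abs(r.res1 - r.res2) < 2:
                log.warning(
                    "restraint between protons of residues %d and %d "
                    "(fewer than 2 residues apart) accepted but unusual",
                    r.res1 + 1, r.res2 + 1,
                )

    def pack(self, n: int) -> dict:
        """Arrays consumed by the distance/angular kernels."""
        self.validate(n)
        ang = self.angular
        kind = np.array([0 if r.kind == "theta" else 1 for r in ang], dtype=np.int32)
        idx = np.array([r.residue for r in ang], dtype=np.int32)
        xl = np.array([r.lower for r in ang], dtype=np.float64)
        xu = np.array([r.upper for r in ang], dtype=np.float64)

        # group members; singletons get their own group
        groups: dict[object, list[DistanceRestraint]] = {}
        order: list[object] = []
        auto = 0
        for r in self.distance:
            key = ("g", r.group) if r.group is not None else ("s", auto)
            if r.group is None:
                auto += 1
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(r)
        uniq: dict[tuple[int, int], int] = {}
        uq_res: list[int] = []
        uq_cls: list[int] = []

        def uid(res: int, cls: str) -> int:
            k = (res, CLASS_CODES[cls])
            if k not in uniq:
                uniq[k] = len(uq_res)
                uq_res.append(res)
                uq_cls.append(CLASS_CODES[cls])
            return uniq[k]

        p1, p2, dl, du, A, sig, kap = [], [], [], [], [], [], []
        gs = [0]
        alpha = []
        for key in order:
            members = groups[key]
            shared = {(m.d_l, m.d_u, m.A) for m in members}
            if len(shared) > 1:
                log.warning(
                    "ambiguous group %s mixes per-member bounds/heights "
                    "(extension beyond the shared-parameter form)", key,
                )
            for m in members:
                p1.append(uid(m.res1, m.cls1))
                p2.append(uid(m.res2, m.cls2))
                dl.append(m.d_l)
                du.append(m.d_u)
                A.append(m.A)
                sig.append(m.sigma)
                kap.append(m.kappa)
            gs.append(gs[-1] + len(members))
            alpha.append(members[0].alpha)
        return {
            "ang_kind": kind, "ang_idx": idx, "ang_xl": xl, "ang_xu": xu,
            "uq_res": np.array(uq_res, dtype=np.int32),
            "uq_cls": np.array(uq_cls, dtype=np.int32),
            "mem_p1": np.array(p1, dtype=np.int32),
            "mem_p2": np.array(p2, dtype=np.int32),
            "gs": np.array(gs, dtype=np.int32),
            "m_dl": np.array(dl, dtype=np.float64),
            "m_du": np.array(du, dtype=np.float64),
            "m_A": np.array(A, dtype=np.float64),
            "m_sig": np.array(sig, dtype=np.float64),
            "m_kap": np.array(kap, dtype=np.float64),
            "g_alpha": np.array(alpha, dtype=np.float64),
        }


# ---------------------------------------------------------------------------
# penalty functions (scalar API)
# ---------------------------------------------------------------------------

def angular_penalty(x: float, x_l: float, x_u: float) -> tuple[float, float]:
    """Periodic flat-bottom angular penalty and its derivative."""
    return K.angular_flatbottom(float(x), float(x_l) % TWO_PI, float(x_u) % TWO_PI)


def distance_penalty(
    d: float, d_l: float, d_u: float,
    A: float = 1.0, sigma: float = 0.5, kappa: float = 0.01,
) -> tuple[float, float]:
    """Flat-bottom distance penalty V_cont and its derivative."""
    if d <= 0:
        raise ValueError("distance must be positive")
    return K.vcont(float(d), float(d_l), float(d_u), float(A), float(sigma), float(kappa))


def ambiguous_penalty(
    members: list[tuple[float, dict]],
    alpha: float = 20.0,
    fast: bool = True,
) -> tuple[float, np.ndarray]:
    """Log-exp soft minimum over an ambiguous set.

    ``members`` is a list of (distance, params) with params holding
    d_l, d_u and optionally A, sigma, kappa.  Returns (V, dV/dd per
    member).  The fast path skips members whose individual penalty is
    large enough that their exponential changes V by < 1e−8 kcal/mol.
    """
    if not members:
        raise ValueError("empty ambiguous group")
    vals = np.empty(len(members))
    dvs = np.empty(len(members))
    for i, (d, prm) in enumerate(members):
        vals[i], dvs[i] = K.vcont(
            float(d), prm["d_l"], prm["d_u"],
            prm.get("A", 1.0), prm.get("sigma", 0.5), prm.get("kappa", 0.01),
        )
    V, w = K.ambiguous_logexp(vals, float(alpha), fast)
    return float(V), w * dvs


# ---------------------------------------------------------------------------
# φ/ψ → θ/γ conversion (grid-envelope method)
# ---------------------------------------------------------------------------

# ideal backbone geometry (Å, degrees)
_B_NCA, _B_CAC, _B_CN = 1.458, 1.525, 1.329
_A_NCAC, _A_CACN, _A_CNCA = 111.0, 116.6, 121.7
_OMEGA = 180.0


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of the next atom from three predecessors."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    nrm = np.cross(ab, bc)
    nn = np.linalg.norm(nrm)
    if nn < 1e-10:
        nrm = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        nn = np.linalg.norm(nrm)
        if nn < 1e-10:
            nrm = np.cross(bc, np.array([0.0, 1.0, 0.0]))
            nn = np.linalg.norm(nrm)
    nrm = nrm / nn
    m = np.cross(nrm, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * nrm


def _ca_trace(phis, psis):
    """Cα positions of an ideal-geometry backbone with the given
    per-residue (φ, ψ), ω = 180°.  len(phis) == len(psis) == n."""
    n = len(phis)
    # seed atoms: C(-1), N(0), CA(0)
    C_prev = np.array([0.0, 0.0, 0.0])
    N = np.array([_B_CN, 0.0, 0.0])
    CA = _place(
        np.array([0.0, 1.0, 0.0]), C_prev, N, _B_NCA, _A_CNCA, 0.0
    )
    cas = [CA]
    a, b, c = C_prev, N, CA
    for i in range(n):
        C = _place(a, b, c, _B_CAC, _A_NCAC, phis[i])
        if i == n - 1:
            break
        N2 = _place(b, c, C, _B_CN, _A_CACN, psis[i])
        CA2 = _place(c, C, N2, _B_NCA, _A_CNCA, _OMEGA)
        cas.append(CA2)
        a, b, c = C, N2, CA2
    return np.array(cas)


def convert_phi_psi_bounds(
    boxes: dict[int, tuple[float, float, float, float]],
    degrees: bool = True,
    grid: int = 9,
) -> list[AngularRestraint]:
    """Convert per-residue (φ, ψ) bound boxes to θ/γ restraints.

    ``boxes`` maps residue index → (φ_l, φ_u, ψ_l, ψ_u).  The box is
    sampled on a grid, each sample is mapped to the virtual-bond
    geometry through an ideal-geometry all-atom backbone construction,
    and the min/max envelope (padded by 1.5 grid spacings against
    discretization) is returned: a θ restraint per restrained residue,
    and a γ restraint for every pair of consecutive restrained
    residues (γ_i depends on the dihedrals of residues i and i+1).
    """
    if not boxes:
        return []
    conv = math.radians(1.0) if degrees else 1.0

    def axis(lo, hi):
        lo, hi = lo * conv, hi * conv
        if hi < lo:
            raise ValueError("empty feasible (φ,ψ) box")
        pts = np.linspace(lo, hi, grid) if hi > lo else np.array([lo])
        step = (hi - lo) / max(grid - 1, 1)
        return np.degrees(pts), step

    out: list[AngularRestraint] = []
    for i, (pl, pu, sl, su) in sorted(boxes.items()):
        phis, dphi = axis(pl, pu)
        psis, dpsi = axis(sl, su)
        ths = []
        for ph in phis:
            for ps in psis:
                ca = _ca_trace([0.0, ph, 0.0], [0.0, ps, 0.0])
                ths.append(bond_angle(ca[0], ca[1], ca[2]))
        margin = 1.5 * max(dphi, dpsi)
        out.append(AngularRestraint(i, "theta", min(ths) - margin, max(ths) + margin))
    keys = sorted(boxes)
    for i in keys:
        if i + 1 not in boxes:
            continue
        pl1, pu1, sl1, su1 = boxes[i]
        pl2, pu2, sl2, su2 = boxes[i + 1]
        ph1, d1 = axis(pl1, pu1)
        ps1, d2 = axis(sl1, su1)
        ph2, d3 = axis(pl2, pu2)
        ps2, d4 = axis(sl2, su2)
        gams = []
        for a_ in ph1:
            for b_ in ps1:
                for c_ in ph2:
                    for e_ in ps2:
                        ca = _ca_trace([0.0, a_, c_, 0.0], [0.0, b_, e_, 0.0])
                        g, _ = dihedral_angle(ca[0], ca[1], ca[2], ca[3])
                        gams.append(g)
        # circular envelope: the band is the complement of the largest gap
        vals = np.sort(np.mod(np.array(gams), TWO_PI))
        gaps = np.diff(np.concatenate([vals, [vals[0] + TWO_PI]]))
        k = int(np.argmax(gaps))
        lo = float(vals[(k + 1) % len(vals)])
        hi = float(vals[k])
        if hi < lo:
            hi += TWO_PI
        margin = 1.5 * max(d1, d2, d3, d4)
        out.append(AngularRestraint(i, "gamma", float(lo - margin), float(hi + margin)))
    return out


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

def nmr_total(
    chain: CGChain,
    restraints: NMRRestraintSet,
    w_theta: float = 1.0,
    w_gamma: float = 1.0,
    w_dist: float = 1.0,
    estimator: ProtonEstimator | None = None,
    fast: bool = True,
):
    """Weighted NMR penalty and its analytic gradient.

    Returns (V, gca, gsc, blocks) with blocks the raw (unweighted)
    (V_theta, V_gamma, V_dist) sums.
    """
    est = estimator or DEFAULT_ESTIMATOR
    n = len(chain)
    p = restraints.pack(n)
    tidx = seq_to_idx(chain.sequence)
    gca = np.zeros((n, 3))
    gsc = np.zeros((n, 3))
    vth = vga = vdi = 0.0
    if len(p["ang_kind"]):
        vth, vga = K.nmr_angular_energy(
            chain.calpha, p["ang_kind"], p["ang_idx"], p["ang_xl"], p["ang_xu"],
            gca, w_theta, w_gamma,
        )
    if len(p["gs"]) > 1:
        gv = np.zeros(len(p["gs"]) - 1)
        vdi = K.nmr_distance_energy(
            chain.calpha, chain.sc,
            p["uq_res"], p["uq_cls"], p["mem_p1"], p["mem_p2"],
            p["gs"], p["m_dl"], p["m_du"], p["m_A"], p["m_sig"], p["m_kap"],
            p["g_alpha"], est.hn_offset, est.ha_offset, est.pads, tidx,
            w_dist, fast, gca, gsc, gv,
        )
    V = w_theta * vth + w_gamma * vga + w_dist * vdi
    return V, gca, gsc, (vth, vga, vdi)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _map_atom(name: str) -> str:
    name = name.upper()
    if name in ("H", "HN"):
        return "HN"
    if name == "HA":
        return "HA"
    return "SCH"


def read_plain(path) -> NMRRestraintSet:
    """Plain-text dialect: ``res1 atom1 res2 atom2 d_l d_u [group]``,
    1-based residues; lines starting with # are comments."""
    rset = NMRRestraintSet()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) not in (6, 7):
                raise ValueError(f"{path}:{ln}: expected 6 or 7 fields, got {len(parts)}")
            r1, a1, r2, a2 = int(parts[0]) - 1, _map_atom(parts[1]), int(parts[2]) - 1, _map_atom(parts[3])
            dl, du = float(parts[4]), float(parts[5])
            grp = int(parts[6]) if len(parts) == 7 else None
            rset.distance.append(DistanceRestraint(r1, a1, r2, a2, dl, du, group=grp))
    return rset


def write_plain(rset: NMRRestraintSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# res1 atom1 res2 atom2 d_l d_u [group]\n")
        for r in rset.distance:
            grp = f" {r.group}" if r.group is not None else ""
            fh.write(
                f"{r.res1 + 1} {CLASS_NAMES[CLASS_CODES[r.cls1]]} "
                f"{r.res2 + 1} {CLASS_NAMES[CLASS_CODES[r.cls2]]} "
                f"{r.d_l:.3f} {r.d_u:.3f}{grp}\n"
            )


_NEF_ATOM = {"HN": "H", "HA": "HA", "SCH": "HB"}


def write_nef(rset: NMRRestraintSet, path) -> None:
    """Write the restraint set as an NEF subset (STAR syntax)."""
    lines = ["data_cgres_restraints", ""]
    if rset.distance:
        lines += [
            "save_nef_distance_restraint_list_1",
            "   _nef_distance_restraint_list.sf_category   nef_distance_restraint_list",
            "   _nef_distance_restraint_list.sf_framecode  nef_distance_restraint_list_1",
            "   _nef_distance_restraint_list.potential_type  flat-bottom",
            "",
            "   loop_",
            "      _nef_distance_restraint.index",
            "      _nef_distance_restraint.restraint_id",
            "      _nef_distance_restraint.restraint_combination_id",
            "      _nef_distance_restraint.chain_code_1",
            "      _nef_distance_restraint.sequence_code_1",
            "      _nef_distance_restraint.atom_name_1",
            "      _nef_distance_restraint.chain_code_2",
            "      _nef_distance_restraint.sequence_code_2",
            "      _nef_distance_restraint.atom_name_2",
            "      _nef_distance_restraint.weight",
            "      _nef_distance_restraint.lower_limit",
            "      _nef_distance_restraint.upper_limit",
            "",
        ]
        # NEF restraint_id: one id per ambiguous group, unique ids for
        # singleton restraints
        gid_of: dict[int, int] = {}
        for r in rset.distance:
            if r.group is not None and r.group not in gid_of:
                gid_of[r.group] = len(gid_of) + 1
        auto_gid = len(gid_of)
        idx = 0
        for r in rset.distance:
            idx += 1
            if r.group is not None:
                rid = gid_of[r.group]
            else:
                auto_gid += 1
                rid = auto_gid
            lines.append(
                f"      {idx} {rid} . A {r.res1 + 1} {_NEF_ATOM[r.cls1]} "
                f"A {r.res2 + 1} {_NEF_ATOM[r.cls2]} {r.A:.2f} "
                f"{r.d_l:.3f} {r.d_u:.3f}"
            )
        lines += ["   stop_", "save_", ""]
    if rset.angular:
        lines += [
            "save_nef_dihedral_restraint_list_1",
            "   _nef_dihedral_restraint_list.sf_category   nef_dihedral_restraint_list",
            "   _nef_dihedral_restraint_list.sf_framecode  nef_dihedral_restraint_list_1",
            "",
            "   loop_",
            "      _nef_dihedral_restraint.index",
            "      _nef_dihedral_restraint.restraint_id",
            "      _nef_dihedral_restraint.name",
            "      _nef_dihedral_restraint.sequence_code_1",
            "      _nef_dihedral_restraint.lower_limit",
            "      _nef_dihedral_restraint.upper_limit",
            "",
        ]
        for i, r in enumerate(rset.angular, start=1):
            name = "THETA" if r.kind == "theta" else "GAMMA"
            lines.append(
                f"      {i} {i} {name} {r.residue + 1} "
                f"{math.degrees(r.lower):.2f} {math.degrees(r.upper):.2f}"
            )
        lines += ["   stop_", "save_", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _star_blocks(doc):
    """All data blocks and their saveframes of a STAR document."""
    for block in doc:
        yield block
        for item in block:
            if item.frame is not None:
                yield item.frame


def read_nef(path) -> NMRRestraintSet:
    """Parse the NEF subset (distance + dihedral restraint lists)."""
    import gemmi

    doc = gemmi.cif.read(str(path))
    rset = NMRRestraintSet()
    for block in _star_blocks(doc):
        tab = block.find(
            "_nef_distance_restraint.",
            ["restraint_id", "sequence_code_1", "atom_name_1",
             "sequence_code_2", "atom_name_2", "lower_limit", "upper_limit"],
        )
        by_id: dict[int, int] = {}
        for row in tab:
            rid = int(row[0])
            rset.distance.append(
                DistanceRestraint(
                    int(row[1]) - 1, _map_atom(row[2]),
                    int(row[3]) - 1, _map_atom(row[4]),
                    float(row[5]), float(row[6]), group=rid,
                )
            )
            by_id[rid] = by_id.get(rid, 0) + 1
        # singleton ids do not need a group
        for r in rset.distance:
            if r.group is not None and by_id.get(r.group, 0) == 1:
                r.group = None
        dtab = block.find(
            "_nef_dihedral_restraint.",
            ["name", "sequence_code_1", "lower_limit", "upper_limit"],
        )
        for row in dtab:
            name = row[0].upper()
            res = int(row[1]) - 1
            lo, hi = math.radians(float(row[2])), math.radians(float(row[3]))
            if name in ("THETA", "GAMMA"):
                rset.angular.append(
                    AngularRestraint(res, "theta" if name == "THETA" else "gamma", lo, hi)
                )
            elif name in ("PHI", "PSI"):
                # collected below via box conversion
                rset.angular.extend(
                    convert_phi_psi_bounds(
                        {res: (float(row[2]), float(row[3]), -180.0, 180.0)}
                        if name == "PHI"
                        else {res: (-180.0, 180.0, float(row[2]), float(row[3]))},
                        degrees=True,
                    )
                )
    return rset


def read_star(path) -> NMRRestraintSet:
    """Parse an NMR-STAR subset: Gen_dist_constraint loops.

    Rows sharing a constraint ID with OR member logic form one
    ambiguous group.
    """
    import gemmi

    doc = gemmi.cif.read(str(path))
    rset = NMRRestraintSet()
    for block in _star_blocks(doc):
        tab = block.find(
            "_Gen_dist_constraint.",
            ["ID", "Member_logic_code", "Comp_index_ID_1", "Atom_ID_1",
             "Comp_index_ID_2", "Atom_ID_2",
             "Distance_lower_bound_val", "Distance_upper_bound_val"],
        )
        counts: dict[int, int] = {}
        rows = []
        for row in tab:
            rows.append(
                (int(row[0]), row[1], int(row[2]) - 1, _map_atom(row[3]),
                 int(row[4]) - 1, _map_atom(row[5]), float(row[6]), float(row[7]))
            )
            counts[rows[-1][0]] = counts.get(rows[-1][0], 0) + 1
        for rid, logic, r1, a1, r2, a2, dl, du in rows:
            grp = rid if counts[rid] > 1 and logic.upper() == "OR" else None
            rset.distance.append(
                DistanceRestraint(r1, a1, r2, a2, dl, du, group=grp)
            )
    return rset


def read_restraints(path, fmt: str = "plain") -> NMRRestraintSet:
    """Dispatch on format: 'plain', 'nef' or 'star'."""
    if fmt == "plain":
        return read_plain(path)
    if fmt == "nef":
        return read_nef(path)
    if fmt == "star":
        return read_star(path)
    raise ValueError(f"unknown NMR restraint format {fmt!r}")
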