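"""Coarse-grained chain representation and coordinate conversions.

A polypeptide is reduced to two sites per residue: the α-carbon (Cα),
which defines the backbone trace, and a united side-chain site (SC)
attached to it.  United peptide sites sit implicitly at the midpoints of
consecutive Cα atoms.  Backbone geometry is described by virtual-bond
lengths d_i = |Cα_i Cα_{i+1}|, virtual-bond angles θ_i (vertex at Cα_i)
and virtual-bond dihedrals γ_i (axis through Cα_i and Cα_{i+1}).  Side
chain placement is described by a polar angle α_i (from the local
bisector direction) and an azimuth β_i, plus the Cα–SC length b_i.

Conventions
-----------
* θ ∈ (0, π]; γ, β ∈ (−π, π], right-handed (IUPAC-like) dihedral sign.
* Collinearity is detected at sin θ < 1e−9; the affected dihedral is set
  to 0 and flagged rather than raising.
* Residue indices are 0-based in the API, 1-based in file I/O.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AA1TO3, AA3TO1, B0_SC

log = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-9

#: Acceptable Cα–Cα virtual-bond window for chain-break detection, Å.
CA_CA_WINDOW = (2.6, 4.6)


@dataclass
class CGChain:
    """Two-site-per-residue coarse-grained chain.

    Attributes
    ----------
    sequence : str
        One-letter residue codes.
    calpha : (n, 3) float array
        Cα coordinates, Å.
    sc : (n, 3) float array
        Side-chain-site coordinates, Å.  For glycine the SC site
        coincides with the Cα.
    """

    sequence: str
    calpha: np.ndarray
    sc: np.ndarray

    def __post_init__(self) -> None:
        self.calpha = np.ascontiguousarray(self.calpha, dtype=np.float64)
        self.sc = np.ascontiguousarray(self.sc, dtype=np.float64)
        n = len(self.sequence)
        if self.calpha.shape != (n, 3) or self.sc.shape != (n, 3):
            raise ValueError(
                f"coordinate shapes {self.calpha.shape}/{self.sc.shape} do not "
                f"match sequence length {n}"
            )
        if not (np.isfinite(self.calpha).all() and np.isfinite(self.sc).all()):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def peptide_sites(self) -> np.ndarray:
        """United-peptide-group positions: Cα–Cα midpoints, (n−1, 3)."""
        return 0.5 * (self.calpha[:-1] + self.calpha[1:])

    def copy(self) -> "CGChain":
        return CGChain(self.sequence, self.calpha.copy(), self.sc.copy())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CGChain":
        """Rigid-body copy: x -> R x + t."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return CGChain(self.sequence, self.calpha @ rot.T + t, self.sc @ rot.T + t)


@dataclass
class InternalCoords:
    """Internal coordinates of a CG chain of n residues.

    d (n−1) Cα–Cα bond lengths; theta (n−2) virtual-bond angles;
    gamma (n−3) virtual-bond dihedrals; alpha/beta/b_sc (n) side-chain
    polar/azimuth angles and Cα–SC lengths; degenerate flags mark
    dihedrals that were undefined (collinear points).
    """

    d: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    b_sc: np.ndarray
    degenerate_gamma: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("d", "theta", "gamma", "alpha", "beta", "b_sc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.b_sc)
        if len(self.d) != n - 1 or len(self.theta) != max(n - 2, 0) or len(
            self.gamma
        ) != max(n - 3, 0):
            raise ValueError("inconsistent internal-coordinate counts")
        if np.any(self.d <= 0):
            raise ValueError("non-positive virtual-bond length")
        if len(self.theta) and (np.any(self.theta <= 0) or np.any(self.theta > np.pi + 1e-12)):
            raise ValueError("virtual-bond angle outside (0, pi]")
        if self.degenerate_gamma is None:
            self.degenerate_gamma = np.zeros(len(self.gamma), dtype=bool)

    @property
    def n_residues(self) -> int:
        return len(self.b_sc)


def wrap_angle(x):
    """Wrap angle(s) to (−π, π]."""
    y = np.mod(np.asarray(x, dtype=float) + np.pi, 2 * np.pi) - np.pi
    y = np.where(y == -np.pi, np.pi, y)
    return float(y) if np.isscalar(x) else y


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, radians in [0, π]."""
    u = a - b
    v = c - b
    c_ = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.acos(min(1.0, max(-1.0, c_)))


def dihedral_angle(a, b, c, d) -> tuple[float, bool]:
    """Right-handed dihedral over four points, (−π, π].

    Returns (angle, degenerate); a degenerate (collinear) configuration
    yields angle 0 with the flag set.
    """
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    m1 = np.linalg.norm(n1)
    m2 = np.linalg.norm(n2)
    if m1 < _COLLINEAR_TOL * nb2 * np.linalg.norm(b1) or m2 < _COLLINEAR_TOL * nb2 * np.linalg.norm(b3):
        return 0.0, True
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return math.atan2(y, x), False


def _local_frame(ca: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bisector frame (b̂, ê1, ê2) at residue i.

    b̂ bisects the θ_i angle, ê1 is the in-plane direction toward the
    preceding Cα, ê2 = b̂ × ê1 completes a right-handed triad.  Terminal
    residues use a virtual neighbor extrapolated from the two nearest
    bonds so the frame stays rotation-equivariant.  Requires n ≥ 3.
    """
    n = len(ca)
    if n < 3:
        raise ValueError("local frame requires at least 3 residues")
    if i == 0:
        prev_p = ca[0] + ca[1] - ca[2]
        nxt = ca[1]
    elif i == n - 1:
        prev_p = ca[n - 2]
        nxt = ca[n - 1] + ca[n - 2] - ca[n - 3]
    else:
        prev_p = ca[i - 1]
        nxt = ca[i + 1]
    u = prev_p - ca[i]
    v = nxt - ca[i]
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    b = u + v
    nb = np.linalg.norm(b)
    if nb < 1e-8:  # straight angle: bisector undefined, pick any normal
        b = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(b) < 1e-8:
            b = np.cross(u, np.array([0.0, 1.0, 0.0]))
    bhat = b / np.linalg.norm(b)
    e1 = u - np.dot(u, bhat) * bhat
    ne1 = np.linalg.norm(e1)
    if ne1 < 1e-8:
        e1 = np.cross(bhat, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(bhat, np.array([0.0, 1.0, 0.0]))
        ne1 = np.linalg.norm(e1)
    e1 = e1 / ne1
    e2 = np.cross(bhat, e1)
    return bhat, e1, e2


def internal_from_cartesian(chain: CGChain) -> InternalCoords:
    """Extract internal coordinates from a Cartesian CG chain.

    Requires ≥ 2 residues (≥ 3 for θ, ≥ 4 for γ).  Collinear triples
    produce θ = π; collinear quadruples produce γ = 0 with the
    ``degenerate_gamma`` flag set.
    """
    ca = chain.calpha
    n = len(ca)
    if n < 2:
        raise ValueError("need at least 2 residues")
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    theta = np.array([bond_angle(ca[i - 1], ca[i], ca[i + 1]) for i in range(1, n - 1)])
    theta = np.where(theta < 1e-12, 1e-12, theta)  # keep θ in (0, π]
    gam = np.zeros(max(n - 3, 0))
    deg = np.zeros(max(n - 3, 0), dtype=bool)
    for k in range(n - 3):
        gam[k], deg[k] = dihedral_angle(ca[k], ca[k + 1], ca[k + 2], ca[k + 3])
    alpha = np.zeros(n)
    beta = np.zeros(n)
    b_sc = np.linalg.norm(chain.sc - ca, axis=1)
    if n >= 3:
        for i in range(n):
            if b_sc[i] < 1e-8:
                continue
            bhat, e1, e2 = _local_frame(ca, i)
            w = (chain.sc[i] - ca[i]) / b_sc[i]
            alpha[i] = math.acos(min(1.0, max(-1.0, float(np.dot(w, bhat)))))
            beta[i] = math.atan2(float(np.dot(w, e2)), float(np.dot(w, e1)))
    return InternalCoords(d, theta, gam, alpha, beta, b_sc, deg)


def cartesian_from_internal(
    ic: InternalCoords,
    sequence: str,
    anchor_frame: np.ndarray | None = None,
) -> CGChain:
    """Rebuild Cartesian coordinates from internal ones.

    The chain is laid out in a canonical frame (first Cα at the origin,
    first bond along +x, second bond in the xy-plane) unless
    ``anchor_frame`` (a 4x4 homogeneous transform) is given.  Inverse of
    :func:`internal_from_cartesian` up to rigid-body motion.
    """
    n = ic.n_residues
    if len(sequence) != n:
        raise ValueError("sequence length does not match internal coordinates")
    ca = np.zeros((n, 3))
    if n >= 2:
        ca[1] = [ic.d[0], 0.0, 0.0]
    if n >= 3:
        th = ic.theta[0]
        ca[2] = ca[1] + ic.d[1] * np.array([-math.cos(th), math.sin(th), 0.0])
    for k in range(3, n):
        # natural-extension placement of Cα_k from d, θ, γ
        th = ic.theta[k - 2]
        ga = ic.gamma[k - 3]
        b2 = ca[k - 1] - ca[k - 2]
        b1 = ca[k - 2] - ca[k - 3]
        u2 = b2 / np.linalg.norm(b2)
        nvec = np.cross(b1, b2)
        nn = np.linalg.norm(nvec)
        if nn < 1e-10:  # previous triple collinear: pick arbitrary normal
            nvec = np.cross(u2, np.array([1.0, 0.0, 0.0]))
            if np.linalg.norm(nvec) < 1e-8:
                nvec = np.cross(u2, np.array([0.0, 1.0, 0.0]))
            nn = np.linalg.norm(nvec)
        nhat = nvec / nn
        mhat = np.cross(nhat, u2)
        dloc = ic.d[k - 1] * np.array(
            [
                -math.cos(th),
                math.sin(th) * math.cos(ga),
                math.sin(th) * math.sin(ga),
            ]
        )
        ca[k] = ca[k - 1] + dloc[0] * u2 + dloc[1] * mhat + dloc[2] * nhat
    sc = ca.copy()
    if n >= 3:
        for i in range(n):
            if ic.b_sc[i] < 1e-8:
                continue
            bhat, e1, e2 = _local_frame(ca, i)
            a, b = ic.alpha[i], ic.beta[i]
            w = (
                math.cos(a) * bhat
                + math.sin(a) * (math.cos(b) * e1 + math.sin(b) * e2)
            )
            sc[i] = ca[i] + ic.b_sc[i] * w
    if anchor_frame is not None:
        T = np.asarray(anchor_frame, dtype=float)
        if T.shape != (4, 4):
            raise ValueError("anchor_frame must be a 4x4 homogeneous transform")
        ca = ca @ T[:3, :3].T + T[:3, 3]
        sc = sc @ T[:3, :3].T + T[:3, 3]
    return CGChain(sequence, ca, sc)


# ---------------------------------------------------------------------------
# Atomic-model mapping (PDB)
# ---------------------------------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def cg_from_pdb(path_or_structure, chain_id: str | None = None) -> CGChain:
    """Map an atomic model (PDB file or gemmi Structure) to a CG chain.

    First model only; altloc 'A' (or blank) preferred.  The SC site is
    the centroid of side-chain heavy atoms (Cβ and beyond); glycine SC
    sits at the Cα; a residue with no side-chain heavy atoms falls back
    to Cβ, then Cα, with a logged warning.  Chain breaks (Cα–Cα distance
    outside ``CA_CA_WINDOW``) raise with the offending residue indices.
    """
    import gemmi

    if isinstance(path_or_structure, gemmi.Structure):
        st = path_or_structure
    else:
        st = gemmi.read_structure(str(path_or_structure))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]
    chains = [c for c in model if chain_id is None or c.name == chain_id]
    if not chains:
        raise ValueError(f"chain {chain_id!r} not found")
    chain = chains[0]

    seq = []
    ca_xyz = []
    sc_xyz = []
    for res in chain:
        if res.name not in AA3TO1:
            continue
        one = AA3TO1[res.name]
        atoms = {}
        for atom in res:
            if atom.altloc not in ("", "\x00", "A"):
                continue
            if atom.element.is_hydrogen:
                continue
            atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if "CA" not in atoms:
            raise ValueError(f"residue {res.seqid.num} {res.name}: missing CA atom")
        ca = atoms["CA"]
        side = [p for nm, p in atoms.items() if nm not in _BACKBONE]
        if one == "G":
            sc = ca
        elif side:
            sc = np.mean(side, axis=0)
        elif "CB" in atoms:
            sc = atoms["CB"]
            log.warning("residue %d %s: no side-chain atoms beyond CB, using CB", res.seqid.num, res.name)
        else:
            sc = ca
            log.warning("residue %d %s: no side-chain atoms, SC site set to CA", res.seqid.num, res.name)
        seq.append(one)
        ca_xyz.append(ca)
        sc_xyz.append(sc)
    if not seq:
        raise ValueError("no standard amino-acid residues found")
    ca_arr = np.array(ca_xyz)
    if len(ca_arr) > 1:
        d = np.linalg.norm(np.diff(ca_arr, axis=0), axis=1)
        bad = np.where((d < CA_CA_WINDOW[0]) | (d > CA_CA_WINDOW[1]))[0]
        if len(bad):
            pairs = ", ".join(f"{i + 1}-{i + 2}" for i in bad)
            raise ValueError(f"chain break(s) between residues (1-based): {pairs}")
    return CGChain("".join(seq), ca_arr, np.array(sc_xyz))


def write_cg_pdb(chain: CGChain, path, models: list[CGChain] | None = None) -> None:
    """Write a CG chain (or trajectory) in the package's PDB dialect.

    Cα sites are written as ``CA`` atoms and SC sites as pseudo-atoms
    named ``CB`` with residue-correct names; glycine gets no CB record.
    Passing ``models`` writes a multi-model file.
    """
    frames = models if models is not None else [chain]
    with open(path, "w") as fh:
        multi = len(frames) > 1
        for m, fr in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for i, aa in enumerate(fr.sequence):
                resn = AA1TO3[aa]
                x, y, z = fr.calpha[i]
                fh.write(
                    f"ATOM  {serial:5d}  CA  {resn} A{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
                if aa != "G":
                    x, y, z = fr.sc[i]
                    fh.write(
                        f"ATOM  {serial:5d}  CB  {resn} A{i + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                    serial += 1
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_cg_pdb(path) -> list[CGChain]:
    """Read chains written by :func:`write_cg_pdb` (one per MODEL)."""
    frames: list[CGChain] = []
    seq: list[str] = []
    ca: list[np.ndarray] = []
    sc: dict[int, np.ndarray] = {}

    def flush():
        nonlocal seq, ca, sc
        if seq:
            sc_arr = np.array([sc.get(i, ca[i]) for i in range(len(seq))])
            frames.append(CGChain("".join(seq), np.array(ca), sc_arr))
        seq, ca, sc = [], [], {}

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                flush()
            elif rec == "ATOM  ":
                name = line[12:16].strip()
                resn = line[17:20]
                xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                if name == "CA":
                    seq.append(AA3TO1[resn])
                    ca.append(xyz)
                elif name == "CB":
                    sc[len(seq) - 1] = xyz
    flush()
    return frames


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of P onto Q (both (n,3)).

    Returns (R, t, rmsd) minimizing ||P R^T + t − Q||.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def ca_rmsd(a: CGChain | np.ndarray, b: CGChain | np.ndarray) -> float:
    """Cα RMSD after optimal superposition, Å."""
    pa = a.calpha if isinstance(a, CGChain) else np.asarray(a, float)
    pb = b.calpha if isinstance(b, CGChain) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError("structures have different residue counts")
    return kabsch(pa, pb)[2]
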