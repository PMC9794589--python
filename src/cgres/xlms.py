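"""Chemical-crosslink (XL-MS) restraint pseudopotentials.

Three restraint families are supported, matching the menu of a
crosslink-assisted coarse-grained simulation setup:

* ``flatbottom`` — a bounded flat-bottom well on the Cα⋯Cα or SC⋯SC
  distance (the κ=0 variant of the NMR distance well), suited to
  non-specific crosslinks with a generous upper bound.
* ``statistical`` — a knowledge-based potential on the Cα⋯Cα distance,
  W(d) = −A·RT·ln[a + b·(d⁴/σ⁴)·exp(−d²/(2σ²)) + c], derived from
  distance distributions of crosslinked residue pairs in known
  structures; A (default 15) carries the confidence of the crosslink
  and RT is fixed at the 298 K value 0.591 kcal/mol.
* ``md_derived`` — pseudopotentials on the internal coordinates of the
  Cα_i⋯X_i⋯X_j⋯Cα_j moiety, where the anchor X sits on the Cα→SC axis
  near the linker attachment atom: three multi-well distance terms
  (harmonic smooth-min form), two Fourier bond-angle terms and one
  sinθ-damped dihedral term.

Shipped parameter tables are toy defaults (documented, editable);
published calibrated tables can be dropped in via YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .constants import RT_298
from .geometry import CGChain

log = logging.getLogger(__name__)

LINKERS = ("ADH", "PDH", "DSS", "ZL", "BS2G", "BS3")
FAMILIES = ("flatbottom", "statistical", "md_derived")

#: residue types each linker can attach to
LINKER_TARGETS = {
    "ADH": set("DE"), "PDH": set("DE"),
    "DSS": set("K"), "BS2G": set("K"), "BS3": set("K"),
    "ZL": set("DEK"),
}

#: default flat-bottom upper bounds per linker (Å), Cα–Cα
FLATBOTTOM_DU = {"ADH": 25.0, "PDH": 25.0, "DSS": 25.0, "ZL": 16.0, "BS2G": 22.0, "BS3": 25.0}


@dataclass
class XLStatParams:
    """Statistical-potential shape parameters per linker."""

    a: float = 0.02
    b: float = 1.0
    c: float = 0.01
    sigma: float = 8.0
    rt: float = RT_298

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.a + self.c <= 0:
            raise ValueError(
                "statistical potential requires a + c > 0 (log argument floor)"
            )


@dataclass
class XLMDParams:
    """MD-derived pseudopotential coefficient tables for one linker.

    ``dist`` holds three (a_j, k_j, d°_j) well lists for the d_Xi,
    d_Xj and d_XiXj terms; ``theta`` two Fourier series (a°, a_j, b_j);
    ``gamma`` the dihedral series (V°, c_j).
    """

    dist: list[list[tuple[float, float, float]]] = field(
        default_factory=lambda: [
            [(0.1, 2.0, 2.5)],                    # d_Xi (side-chain extent)
            [(0.1, 2.0, 2.5)],                    # d_Xj
            [(0.2, 0.5, 8.0), (0.5, 0.3, 12.0)],  # d_XiXj (linker span)
        ]
    )
    theta: list[tuple[float, list[float], list[float]]] = field(
        default_factory=lambda: [
            (0.5, [0.3, 0.1], [-0.2, 0.05]),
            (0.5, [0.3, 0.1], [-0.2, 0.05]),
        ]
    )
    gamma: tuple[float, list[float]] = (0.3, [0.2, -0.1, 0.05])

    def validate(self) -> None:
        if len(self.dist) != 3 or len(self.theta) != 2:
            raise ValueError("need 3 distance-well sets and 2 theta series")
        for wells in self.dist:
            if not wells:
                raise ValueError("empty distance-well set")
            for a, k, d0 in wells:
                if a <= 0 or k <= 0:
                    raise ValueError("distance wells require a_j > 0, k_j > 0")


@dataclass
class CrosslinkRestraint:
    """One crosslink between residues i and j (0-based)."""

    i: int
    j: int
    linker: str = "DSS"
    family: str = "statistical"
    site: str = "CA"          # flat-bottom family: CA or SC distance
    A: float = 15.0           # confidence weight (statistical family)
    d_l: float = 0.0          # flat-bottom bounds (Å)
    d_u: float | None = None
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("crosslink must join two distinct residues")
        if self.linker not in LINKERS:
            raise ValueError(f"unknown linker {self.linker!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.A <= 0:
            raise ValueError("confidence weight A must be positive")
        if self.d_u is None:
            self.d_u = FLATBOTTOM_DU[self.linker]


def default_stat_params() -> dict[str, XLStatParams]:
    """Toy per-linker statistical parameters (editable)."""
    base = {
        "ADH": XLStatParams(sigma=9.0), "PDH": XLStatParams(sigma=10.0),
        "DSS": XLStatParams(sigma=8.0), "ZL": XLStatParams(sigma=5.0),
        "BS2G": XLStatParams(sigma=7.0), "BS3": XLStatParams(sigma=8.0),
    }
    return base


def default_md_params() -> dict[str, XLMDParams]:
    return {lk: XLMDParams() for lk in LINKERS}


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def statistical_potential(
    d: float, params: XLStatParams, A: float = 15.0
) -> tuple[float, float]:
    """W(d) = −A·RT·ln[a + b(d⁴/σ⁴)e^(−d²/2σ²) + c] and dW/dd."""
    if d <= 0:
        raise ValueError("distance must be positive")
    return K.xl_statistical(
        float(d), params.a, params.b, params.c, params.sigma, float(A), params.rt
    )


def anchor_point(
    chain: CGChain, residue: int, t: float | None = None, mode: str = "fraction"
):
    """Anchor point X on the Cα→SC axis of ``residue``.

    mode 'fraction': X = Cα + t·(SC−Cα), default t=1 (X at the SC
    site, appropriate for linkers anchored at the side-chain tip).
    mode 'absolute': X = Cα + t·û with t in Å.

    Returns (X, grads) with grads the dict {('ca', i): 3x3, ('sc', i):
    3x3} of ∂X/∂site.  Raises for a zero-length Cα–SC vector
    (glycine), which cannot carry an anchor-family restraint.
    """
    ca = chain.calpha[residue]
    sc = chain.sc[residue]
    w = sc - ca
    r = float(np.linalg.norm(w))
    if r < 1e-8:
        raise ValueError(
            f"residue {residue + 1} ({chain.sequence[residue]}) has a "
            "zero-length Cα–SC vector; anchor-family restraints need a side chain"
        )
    if mode == "fraction":
        f = 1.0 if t is None else float(t)
        X = ca + f * w
        M = f * np.eye(3)
    elif mode == "absolute":
        tt = r if t is None else float(t)
        u = w / r
        X = ca + tt * u
        M = tt * (np.eye(3) - np.outer(u, u)) / r
    else:
        raise ValueError(f"unknown anchor mode {mode!r}")
    return X, {("ca", residue): np.eye(3) - M, ("sc", residue): M}


def md_derived_potential(
    chain: CGChain,
    restraint: CrosslinkRestraint,
    params: XLMDParams,
    t_i: float = 1.0,
    t_j: float = 1.0,
):
    """Anchor-geometry pseudopotential of one crosslink.

    Returns (V, gca, gsc) for the single restraint (unweighted).
    """
    params.validate()
    arrs = _pack([], [restraint], {}, {restraint.linker: params}, strict=False,
                 n=len(chain), sequence=chain.sequence)
    n = len(chain)
    gca = np.zeros((n, 3))
    gsc = np.zeros((n, 3))
    pv = np.zeros(1)
    V = K.xlms_energy(
        chain.calpha, chain.sc,
        *(arrs[k] for k in _FLAT_KEYS), *(arrs[k] for k in _STAT_KEYS), RT_298,
        *(arrs[k] for k in _MD_KEYS),
        1.0, gca, gsc, pv,
    )
    return float(V), gca, gsc


# ---------------------------------------------------------------------------
# packing for the kernels
# ---------------------------------------------------------------------------

_FLAT_KEYS = ("xf_i", "xf_j", "xf_site", "xf_dl", "xf_du", "xf_A", "xf_sig")
_STAT_KEYS = ("xs_i", "xs_j", "xs_a", "xs_b", "xs_c", "xs_sig", "xs_A")
_MD_KEYS = (
    "xm_i", "xm_j", "xm_mode", "xm_vi", "xm_vj", "xm_p",
    "mdw_a", "mdw_k", "mdw_d0", "mdw_n",
    "mth_a0", "mth_a", "mth_b", "mth_n",
    "mg_v0", "mg_c", "mg_n",
)


def _pack(flat, other, stat_params, md_params, strict, n, sequence):
    """Build kernel arrays from restraint lists (internal)."""
    out = {}
    out["xf_i"] = np.array([r.i for r in flat], dtype=np.int32)
    out["xf_j"] = np.array([r.j for r in flat], dtype=np.int32)
    out["xf_site"] = np.array([0 if r.site == "CA" else 1 for r in flat], dtype=np.int32)
    out["xf_dl"] = np.array([r.d_l for r in flat], dtype=np.float64)
    out["xf_du"] = np.array([r.d_u for r in flat], dtype=np.float64)
    out["xf_A"] = np.array([1.0 for _ in flat], dtype=np.float64)
    out["xf_sig"] = np.array([r.sigma for r in flat], dtype=np.float64)

    stat = [r for r in other if r.family == "statistical"]
    md = [r for r in other if r.family == "md_derived"]
    out["xs_i"] = np.array([r.i for r in stat], dtype=np.int32)
    out["xs_j"] = np.array([r.j for r in stat], dtype=np.int32)
    sp = [stat_params.get(r.linker, XLStatParams()) for r in stat]
    out["xs_a"] = np.array([p.a for p in sp], dtype=np.float64)
    out["xs_b"] = np.array([p.b for p in sp], dtype=np.float64)
    out["xs_c"] = np.array([p.c for p in sp], dtype=np.float64)
    out["xs_sig"] = np.array([p.sigma for p in sp], dtype=np.float64)
    out["xs_A"] = np.array([r.A for r in stat], dtype=np.float64)

    linkers = sorted({r.linker for r in md})
    lmap = {lk: i for i, lk in enumerate(linkers)}
    L = max(len(linkers), 1)
    ps = [md_params.get(lk, XLMDParams()) for lk in linkers] or [XLMDParams()]
    for p in ps:
        p.validate()
    ND = max(max(len(w) for w in p.dist) for p in ps)
    NT = max(max(len(t[1]) for t in p.theta) for p in ps)
    NG = max(len(p.gamma[1]) for p in ps)
    mdw_a = np.zeros((L, 3, ND))
    mdw_k = np.ones((L, 3, ND))
    mdw_d0 = np.zeros((L, 3, ND))
    mdw_n = np.zeros((L, 3), dtype=np.int32)
    mth_a0 = np.zeros((L, 2))
    mth_a = np.zeros((L, 2, NT))
    mth_b = np.zeros((L, 2, NT))
    mth_n = np.zeros((L, 2), dtype=np.int32)
    mg_v0 = np.zeros(L)
    mg_c = np.zeros((L, NG))
    mg_n = np.zeros(L, dtype=np.int32)
    for li, p in enumerate(ps):
        for leg in range(3):
            wells = p.dist[leg]
            mdw_n[li, leg] = len(wells)
            for wi, (a, k, d0) in enumerate(wells):
                mdw_a[li, leg, wi] = a
                mdw_k[li, leg, wi] = k
                mdw_d0[li, leg, wi] = d0
        for ti, (a0, av, bv) in enumerate(p.theta):
            mth_a0[li, ti] = a0
            mth_n[li, ti] = len(av)
            for m, v in enumerate(av):
                mth_a[li, ti, m] = v
            for m, v in enumerate(bv):
                mth_b[li, ti, m] = v
        mg_v0[li] = p.gamma[0]
        mg_n[li] = len(p.gamma[1])
        for m, v in enumerate(p.gamma[1]):
            mg_c[li, m] = v
    out["xm_i"] = np.array([r.i for r in md], dtype=np.int32)
    out["xm_j"] = np.array([r.j for r in md], dtype=np.int32)
    out["xm_mode"] = np.zeros(len(md), dtype=np.int32)  # fraction mode
    out["xm_vi"] = np.ones(len(md), dtype=np.float64)
    out["xm_vj"] = np.ones(len(md), dtype=np.float64)
    out["xm_p"] = np.array([lmap.get(r.linker, 0) for r in md], dtype=np.int32)
    out["mdw_a"], out["mdw_k"], out["mdw_d0"], out["mdw_n"] = mdw_a, mdw_k, mdw_d0, mdw_n
    out["mth_a0"], out["mth_a"], out["mth_b"], out["mth_n"] = mth_a0, mth_a, mth_b, mth_n
    out["mg_v0"], out["mg_c"], out["mg_n"] = mg_v0, mg_c, mg_n

    # validation
    for r in list(flat) + list(other):
        for res in (r.i, r.j):
            if not 0 <= res < n:
                raise ValueError(
                    f"crosslink references residue {res + 1} of a {n}-residue chain"
                )
        targets = LINKER_TARGETS[r.linker]
        for res in (r.i, r.j):
            if sequence[res] not in targets:
                msg = (
                    f"crosslink {r.i + 1}-{r.j + 1} ({r.linker}): residue "
                    f"{res + 1} ({sequence[res]}) is not a crosslinkable type "
                    f"for this linker"
                )
                if strict:
                    raise ValueError(msg)
                log.warning(msg)
        if r.family == "md_derived":
            for res in (r.i, r.j):
                if sequence[res] == "G":
                    raise ValueError(
                        f"crosslink {r.i + 1}-{r.j + 1}: glycine has no Cα–SC "
                        "axis for an anchor-family restraint"
                    )
    return out


@dataclass
class XLMSRestraintSet:
    restraints: list[CrosslinkRestraint] = field(default_factory=list)
    stat_params: dict[str, XLStatParams] = field(default_factory=default_stat_params)
    md_params: dict[str, XLMDParams] = field(default_factory=default_md_params)
    strict: bool = False

    def __len__(self) -> int:
        return len(self.restraints)

    def pack(self, chain_or_n, sequence: str | None = None) -> dict:
        if isinstance(chain_or_n, CGChain):
            n, seq = len(chain_or_n), chain_or_n.sequence
        else:
            n, seq = int(chain_or_n), sequence or ""
        flat = [r for r in self.restraints if r.family == "flatbottom"]
        other = [r for r in self.restraints if r.family != "flatbottom"]
        return _pack(flat, other, self.stat_params, self.md_params, self.strict, n, seq)


def xlms_total(
    chain: CGChain,
    restraints: XLMSRestraintSet,
    w_xlms: float = 1.0,
):
    """Weighted crosslink penalty, analytic gradient and per-restraint
    energies (order: flat-bottom, then statistical, then MD-derived)."""
    n = len(chain)
    arrs = restraints.pack(chain)
    gca = np.zeros((n, 3))
    gsc = np.zeros((n, 3))
    nr = len(restraints)
    pv = np.zeros(max(nr, 1))
    V = K.xlms_energy(
        chain.calpha, chain.sc,
        *(arrs[k] for k in _FLAT_KEYS),
        *(arrs[k] for k in _STAT_KEYS), RT_298,
        *(arrs[k] for k in _MD_KEYS),
        w_xlms, gca, gsc, pv,
    )
    return w_xlms * float(V), gca, gsc, pv[:nr]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_crosslinks(path, family: str | None = None) -> XLMSRestraintSet:
    """Delimited text: ``res_i res_j linker family [confidence]``,
    1-based residues; ``family`` overrides the per-line family (the
    global crosslink-type menu)."""
    rs = XLMSRestraintSet()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >= 4 fields")
            fam = family or parts[3]
            conf = float(parts[4]) if len(parts) > 4 else 15.0
            rs.restraints.append(
                CrosslinkRestraint(
                    int(parts[0]) - 1, int(parts[1]) - 1,
                    linker=parts[2], family=fam, A=conf,
                )
            )
    return rs


def write_crosslinks(rs: XLMSRestraintSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# res_i res_j linker family confidence\n")
        for r in rs.restraints:
            fh.write(f"{r.i + 1} {r.j + 1} {r.linker} {r.family} {r.A:g}\n")
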