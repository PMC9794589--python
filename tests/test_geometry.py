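"""Chain geometry: internal↔Cartesian conversion, PDB mapping and the
proton estimator."""

import math

import numpy as np
import pytest

from cgres.geometry import (
    CGChain, InternalCoords, bond_angle, ca_rmsd, cartesian_from_internal,
    cg_from_pdb, dihedral_angle, internal_from_cartesian, kabsch,
    read_cg_pdb, write_cg_pdb,
)
from cgres.protons import DEFAULT_ESTIMATOR

from conftest import perturbed


def _rigid(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return R, rng.standard_normal(3) * 10


def test_collinear_triple_gives_straight_angle():
    ca = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    chain = CGChain("AAA", ca, ca.copy())
    ic = internal_from_cartesian(chain)
    assert ic.theta[0] == pytest.approx(math.pi, abs=1e-9)


def test_cis_planar_quadruple_gives_zero_gamma():
    # A and D on the same side of the B-C axis, all coplanar
    ca = np.array([[0.0, 1, 0], [0, 0, 0], [3.8, 0, 0], [3.8, 1, 0]])
    chain = CGChain("AAAA", ca, ca.copy())
    ic = internal_from_cartesian(chain)
    assert ic.gamma[0] == pytest.approx(0.0, abs=1e-12)


def test_trans_quadruple_gives_pi():
    ca = np.array([[0.0, 1, 0], [0, 0, 0], [3.8, 0, 0], [3.8, -1, 0]])
    ic = internal_from_cartesian(CGChain("AAAA", ca, ca.copy()))
    assert abs(ic.gamma[0]) == pytest.approx(math.pi, abs=1e-12)


@pytest.mark.parametrize("theta,gamma", [(1.58, 0.90), (2.0, -2.5), (1.2, 3.0)])
def test_helical_internals_round_trip(theta, gamma):
    """Chains built from fixed (θ*, γ*) return exactly those internals."""
    n = 10
    seq = "KDAELVISRE"
    ic = InternalCoords(
        d=np.full(n - 1, 3.8), theta=np.full(n - 2, theta),
        gamma=np.full(n - 3, gamma), alpha=np.full(n, 2.0),
        beta=np.full(n, 0.7), b_sc=np.full(n, 2.0),
    )
    chain = cartesian_from_internal(ic, seq)
    back = internal_from_cartesian(chain)
    assert np.allclose(back.theta, theta, atol=1e-10)
    assert np.allclose(back.gamma, gamma, atol=1e-10)
    assert np.allclose(back.alpha, 2.0, atol=1e-10)
    assert np.allclose(back.beta, 0.7, atol=1e-10)


def test_random_internals_round_trip_cartesian(rng):
    """Rebuild from extracted internals matches up to rigid motion."""
    for _ in range(5):
        n = 8
        ic = InternalCoords(
            d=rng.uniform(3.5, 4.0, n - 1),
            theta=rng.uniform(1.0, 2.8, n - 2),
            gamma=rng.uniform(-math.pi + 0.05, math.pi - 0.05, n - 3),
            alpha=rng.uniform(0.3, 2.8, n),
            beta=rng.uniform(-3.0, 3.0, n),
            b_sc=rng.uniform(1.5, 3.5, n),
        )
        seq = "KDAELVIS"
        chain = cartesian_from_internal(ic, seq)
        back = internal_from_cartesian(chain)
        rebuilt = cartesian_from_internal(back, seq)
        allp = np.vstack([chain.calpha, chain.sc])
        allq = np.vstack([rebuilt.calpha, rebuilt.sc])
        assert kabsch(allp, allq)[2] < 1e-8


def test_all_straight_angles_give_collinear_trace():
    n = 5
    ic = InternalCoords(
        d=np.full(n - 1, 3.8), theta=np.full(n - 2, math.pi),
        gamma=np.zeros(n - 3), alpha=np.zeros(n), beta=np.zeros(n),
        b_sc=np.zeros(n),
    )
    chain = cartesian_from_internal(ic, "GGGGG")
    d = np.diff(chain.calpha, axis=0)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    assert np.allclose(d, d[0], atol=1e-6)


def test_two_residue_chain_is_single_bond():
    ic = InternalCoords(
        d=np.array([3.8]), theta=np.zeros(0), gamma=np.zeros(0),
        alpha=np.zeros(2), beta=np.zeros(2), b_sc=np.zeros(2),
    )
    chain = cartesian_from_internal(ic, "GG")
    assert np.linalg.norm(chain.calpha[1] - chain.calpha[0]) == pytest.approx(3.8)


def test_internals_invariant_under_rigid_motion(helix12, rng):
    ic0 = internal_from_cartesian(helix12)
    R, t = _rigid(rng)
    ic1 = internal_from_cartesian(helix12.transformed(R, t))
    for name in ("d", "theta", "gamma", "alpha", "beta", "b_sc"):
        assert np.allclose(getattr(ic0, name), getattr(ic1, name), atol=1e-9)


# ---------------------------------------------------------------------------
# PDB mapping
# ---------------------------------------------------------------------------

_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800   1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.300   1.500   0.100  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.000   2.800   0.200  1.00  0.00           C
ATOM      8  C   GLY A   2       5.500   2.600   0.300  1.00  0.00           C
ATOM      9  O   GLY A   2       6.000   1.500   0.400  1.00  0.00           O
ATOM     10  N   TRP A   3       6.200   3.700   0.300  1.00  0.00           N
ATOM     11  CA  TRP A   3       7.650   3.700   0.400  1.00  0.00           C
ATOM     12  C   TRP A   3       8.200   5.100   0.500  1.00  0.00           C
ATOM     13  O   TRP A   3       7.500   6.100   0.500  1.00  0.00           O
ATOM     14  CB  TRP A   3       8.200   2.900   1.600  1.00  0.00           C
ATOM     15  CG  TRP A   3       7.900   1.400   1.600  1.00  0.00           C
ATOM     16  CD1 TRP A   3       6.700   0.900   2.000  1.00  0.00           C
ATOM     17  CD2 TRP A   3       8.800   0.400   1.200  1.00  0.00           C
ATOM     18  NE1 TRP A   3       6.800  -0.500   1.900  1.00  0.00           N
ATOM     19  CE2 TRP A   3       8.100  -0.800   1.400  1.00  0.00           C
ATOM     20  CE3 TRP A   3      10.100   0.400   0.700  1.00  0.00           C
ATOM     21  CZ2 TRP A   3       8.700  -2.000   1.100  1.00  0.00           C
ATOM     22  CZ3 TRP A   3      10.700  -0.800   0.400  1.00  0.00           C
ATOM     23  CH2 TRP A   3      10.000  -2.000   0.600  1.00  0.00           C
END
"""


def test_cg_from_pdb_sc_mapping(tmp_path):
    """Alanine SC at CB; glycine SC at CA; tryptophan SC at the
    10-heavy-atom centroid (hand-computed mean)."""
    p = tmp_path / "toy.pdb"
    p.write_text(_PDB)
    chain = cg_from_pdb(p)
    assert chain.sequence == "AGW"
    assert np.allclose(chain.sc[0], [2.0, -0.8, 1.2])
    assert np.allclose(chain.sc[1], chain.calpha[1])
    trp_side = np.array([
        [8.2, 2.9, 1.6], [7.9, 1.4, 1.6], [6.7, 0.9, 2.0], [8.8, 0.4, 1.2],
        [6.8, -0.5, 1.9], [8.1, -0.8, 1.4], [10.1, 0.4, 0.7], [8.7, -2.0, 1.1],
        [10.7, -0.8, 0.4], [10.0, -2.0, 0.6],
    ])
    assert np.allclose(chain.sc[2], trp_side.mean(axis=0), atol=1e-9)


def test_cg_from_pdb_chain_break_detection(tmp_path):
    broken = _PDB.replace("       7.650   3.700   0.400", "      27.650   3.700   0.400")
    p = tmp_path / "broken.pdb"
    p.write_text(broken)
    with pytest.raises(ValueError, match="chain break"):
        cg_from_pdb(p)


def test_cg_pdb_write_read_round_trip(helix12, tmp_path):
    p = tmp_path / "cg.pdb"
    write_cg_pdb(helix12, p)
    frames = read_cg_pdb(p)
    assert len(frames) == 1
    assert frames[0].sequence == helix12.sequence
    assert np.allclose(frames[0].calpha, helix12.calpha, atol=2e-3)
    assert np.allclose(frames[0].sc, helix12.sc, atol=2e-3)


# ---------------------------------------------------------------------------
# proton estimator
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cls", ["HN", "HA", "SCH"])
def test_proton_gradients_match_finite_differences(helix12, rng, cls):
    est = DEFAULT_ESTIMATOR
    h = 1e-6
    for trial in range(10):
        chain = perturbed(helix12, rng)
        res = int(rng.integers(0, len(chain)))
        pos, grads = est.positions(chain, res, cls)
        for (kind, idx), J in grads.items():
            arr = chain.calpha if kind == "ca" else chain.sc
            for a in range(3):
                arr[idx, a] += h
                pp, _ = est.positions(chain, res, cls)
                arr[idx, a] -= 2 * h
                pm, _ = est.positions(chain, res, cls)
                arr[idx, a] += h
                fd = (pp - pm) / (2 * h)
                assert np.abs(J[:, a] - fd).max() < 1e-6 * max(1.0, np.abs(fd).max())


def test_proton_positions_translate_with_chain(helix12, rng):
    est = DEFAULT_ESTIMATOR
    t = rng.standard_normal(3) * 7
    moved = helix12.transformed(np.eye(3), t)
    for res in (0, 5, len(helix12) - 1):
        for cls in ("HN", "HA", "SCH"):
            p0, _ = est.positions(helix12, res, cls)
            p1, _ = est.positions(moved, res, cls)
            assert np.allclose(p1, p0 + t, atol=1e-9)


def test_sidechain_proton_pad_distance_exact(helix12):
    from cgres.constants import AA_INDEX

    est = DEFAULT_ESTIMATOR
    for res in range(len(helix12)):
        p, _ = est.positions(helix12, res, "SCH")
        pad = est.pads[AA_INDEX[helix12.sequence[res]]]
        assert np.linalg.norm(p - helix12.sc[res]) == pytest.approx(pad, abs=1e-10)
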