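"""Analytic proton-position estimation from coarse-grained geometry.

Interproton NMR distance restraints require proton coordinates that the
two-site model does not carry.  The default estimator places backbone
protons by fixed-geometry rules in the local bisector frame of each Cα
(amide H near the backbone nitrogen, Hα on the far side of the
bisector) and represents side-chain protons by the SC site pushed
radially outward by a per-residue-type pad.  Every position is an
analytic function of at most four site coordinates, so exact gradients
are available for molecular dynamics.

The estimator is pluggable: any object with the same
``positions(chain, residue, proton_class)`` contract (for example a
faithful port of a published analytical proton estimator) can be
substituted wherever a :class:`ProtonEstimator` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .constants import PROTON_PAD, seq_to_idx, table
from .geometry import CGChain

#: proton class codes used throughout the restraint machinery
CLASS_CODES = {"HN": 0, "HA": 1, "SCH": 2}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

#: default local-frame offsets (b̂, ê1, ê2 components, Å)
HN_OFFSET = np.array([0.90, 1.20, -0.90])
HA_OFFSET = np.array([-0.95, -0.25, 0.45])


@dataclass
class ProtonEstimator:
    """Fixed-geometry proton estimator with analytic gradients.

    ``pads`` is the per-residue-type radial pad of the side-chain
    pseudo-proton (Å, one entry per type in AA1 order).
    """

    hn_offset: np.ndarray = field(default_factory=lambda: HN_OFFSET.copy())
    ha_offset: np.ndarray = field(default_factory=lambda: HA_OFFSET.copy())
    pads: np.ndarray = field(default_factory=lambda: table(PROTON_PAD))

    def __post_init__(self) -> None:
        self.hn_offset = np.asarray(self.hn_offset, dtype=np.float64)
        self.ha_offset = np.asarray(self.ha_offset, dtype=np.float64)
        self.pads = np.asarray(self.pads, dtype=np.float64)

    def positions(
        self, chain: CGChain, residue: int, proton_class: str
    ) -> tuple[np.ndarray, dict[tuple[str, int], np.ndarray]]:
        """Estimated proton position and its exact gradient.

        Returns ``(position (3,), grads)`` where ``grads`` maps
        ``("ca"|"sc", site index)`` to the 3x3 Jacobian
        ∂position/∂site.  Terminal residues use a virtual neighbor
        extrapolated from the two nearest virtual bonds (documented
        fallback), so the dependency set can include up to three Cα
        sites.
        """
        n = len(chain)
        if n < 3:
            raise ValueError("proton estimation requires at least 3 residues")
        if not 0 <= residue < n:
            raise IndexError(f"residue {residue} out of range")
        cls = CLASS_CODES[proton_class]
        tidx = seq_to_idx(chain.sequence)
        pos, J = K.proton_one(
            chain.calpha, chain.sc, residue, cls,
            self.hn_offset, self.ha_offset, self.pads[tidx[residue]],
        )
        # unfold the 3x12 local Jacobian (slots: prev, Cα, next, SC)
        grads: dict[tuple[str, int], np.ndarray] = {}

        def add(key, block):
            if key in grads:
                grads[key] = grads[key] + block
            else:
                grads[key] = block.copy()

        i = residue
        if i == 0:
            add(("ca", 0), J[:, 0:3])
            add(("ca", 1), J[:, 0:3])
            add(("ca", 2), -J[:, 0:3])
        else:
            add(("ca", i - 1), J[:, 0:3])
        add(("ca", i), J[:, 3:6])
        if i == n - 1:
            add(("ca", n - 1), J[:, 6:9])
            add(("ca", n - 2), J[:, 6:9])
            add(("ca", n - 3), -J[:, 6:9])
        else:
            add(("ca", i + 1), J[:, 6:9])
        add(("sc", i), J[:, 9:12])
        return pos, grads

    def all_positions(self, chain: CGChain) -> np.ndarray:
        """(n, 3, 3) array of positions for classes (HN, HA, SCH)."""
        n = len(chain)
        out = np.empty((n, 3, 3))
        tidx = seq_to_idx(chain.sequence)
        for i in range(n):
            for cls in range(3):
                out[i, cls], _ = K.proton_one(
                    chain.calpha, chain.sc, i, cls,
                    self.hn_offset, self.ha_offset, self.pads[tidx[i]],
                )
        return out


DEFAULT_ESTIMATOR = ProtonEstimator()
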