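"""Side-chain packing features for the s^SC collective variable.

A side-chain feature is a rational switch on the distance between the
mass-weighted centres of two residues' side chains (backbone atoms excluded;
glycine is represented by its Cα). Native features come from the folded
basin, non-native ones from the unfolded basin; side-chain features never
touch the solvent, so they are trivially invariant under water relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hbond import SwitchParams, rational_switch
from .trajectory_io import Frame, Topology, minimum_image

__all__ = [
    "SideChainFeature",
    "DEFAULT_SC_SWITCH",
    "BACKBONE_NAMES",
    "sidechain_atoms",
    "sidechain_com",
    "evaluate_sc_feature",
    "evaluate_sc_feature_many",
]

# backbone = N, CA, C, O (+ chain-terminal variants) and their hydrogens
BACKBONE_NAMES = frozenset({
    "N", "CA", "C", "O", "OXT", "OT1", "OT2",
    "H", "HN", "H1", "H2", "H3", "HA", "HA1", "HA2", "HA3",
})

DEFAULT_SC_SWITCH = SwitchParams(r0=6.5, n=6, m=10)


@dataclass(frozen=True)
class SideChainFeature:
    """One side-chain contact feature F_i^SC between residues i and j."""

    residue_i: int
    residue_j: int
    params: SwitchParams = DEFAULT_SC_SWITCH
    kind: str = "native"     # native | non-native
    origin: str = "folded"   # folded | unfolded
    min_separation: int = 2

    def __post_init__(self) -> None:
        if abs(self.residue_i - self.residue_j) < self.min_separation:
            raise ValueError(
                f"residues {self.residue_i},{self.residue_j} closer in sequence "
                f"than the separation floor ({self.min_separation})")
        if self.kind not in ("native", "non-native"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.origin not in ("folded", "unfolded"):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def identity(self) -> tuple[str, int, int]:
        i, j = sorted((self.residue_i, self.residue_j))
        return ("SC", i, j)


def sidechain_atoms(top: Topology, residue: int) -> np.ndarray:
    """Atom indices of a residue's side chain (Cα proxy for glycine)."""
    atoms = top.residue_atoms(residue)
    if len(atoms) == 0:
        raise ValueError(f"no residue with index {residue}")
    if not np.all(top.is_protein[atoms]):
        raise ValueError(f"residue {residue} is not a protein residue")
    side = atoms[~np.isin(top.names[atoms], list(BACKBONE_NAMES))]
    if len(side) == 0:  # glycine (or stripped residue): fall back to Cα
        side = atoms[top.names[atoms] == "CA"]
    if len(side) == 0:
        raise ValueError(f"residue {residue} has neither side chain nor CA")
    return side


def sidechain_com(top: Topology, frame: Frame, residue: int) -> np.ndarray:
    """Mass-weighted centre of the residue's side-chain atoms, in Å."""
    side = sidechain_atoms(top, residue)
    w = top.masses[side]
    return np.average(frame.coords[side], axis=0, weights=w)


def _com_many(top: Topology, coords: np.ndarray, residue: int) -> np.ndarray:
    side = sidechain_atoms(top, residue)
    w = top.masses[side]
    return np.einsum("...ij,i->...j", coords[..., side, :], w) / w.sum()


def evaluate_sc_feature(f: SideChainFeature, frame: Frame, top: Topology) -> float:
    """Switch value on the COM–COM distance (minimum image); in [0, 1]."""
    return float(evaluate_sc_feature_many(f, frame.coords[None], frame.box, top)[0])


def evaluate_sc_feature_many(f: SideChainFeature, coords: np.ndarray,
                             box: np.ndarray | None, top: Topology) -> np.ndarray:
    """Vectorised evaluation over stacked coordinates (F, n_atoms, 3)."""
    ci = _com_many(top, coords, f.residue_i)
    cj = _com_many(top, coords, f.residue_j)
    d = np.linalg.norm(minimum_image(ci - cj, box), axis=-1)
    return np.asarray(rational_switch(d, f.params), dtype=float)
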