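"""Hydrogen-bond features for the s^HB collective variable.

Each native feature describes one donor–acceptor hydrogen bond and acts as a
switch: ≈ its plateau value when the native bond is formed, ≈ 0 when the bond
is absent, and negative when a competing interaction has seized the donor or
acceptor — either a water molecule (protein–water competition) or another
protein acceptor (protein–protein competition). Whole contacts harvested from
the unfolded basin become separate non-native features that the CV subtracts
with coefficient −1.

The switching function is the PLUMED RATIONAL form

    s(r) = (1 - x^n) / (1 - x^m),   x = (r - d0) / r0,

so that the emitted PLUMED input evaluates identically to this module. Note
s(d0 + r0) = n/m (removable singularity), i.e. the switch passes through 0.6
at the reference distance for the default exponents n=6, m=10; a bond at its
equilibrium distance therefore scores ≈ 0.6, the "formed" plateau of this
functional form, not 1.0.

The angular term is the same rational switch applied to a = (1 + cos θ)/2,
where θ is the D–H···A angle at the hydrogen: a = 0 (value 1) for a collinear
bond, with the default reference a0 = (1 + cos 150°)/2 putting the half-height
near θ = 150° and < 0.05 below θ = 120°.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory_io import Frame, Topology, minimum_image

__all__ = [
    "SwitchParams",
    "HBondFeature",
    "ConfigurationError",
    "GeometryError",
    "DEFAULT_HB_SWITCH",
    "DEFAULT_ANGULAR_SWITCH",
    "DEFAULT_WATER_SWITCH",
    "rational_switch",
    "angular_term",
    "identify_donors_acceptors",
    "water_competition",
    "evaluate_hbond_feature",
]

POLAR_ELEMENTS = ("N", "O", "S")
COVALENT_H_CUTOFF = 1.2  # Å, hydrogen-to-donor assignment when no bond table


class ConfigurationError(ValueError):
    """Input lacks information the featurizer needs (e.g. hydrogens)."""


class GeometryError(ValueError):
    """Degenerate geometry (coincident points)."""


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of the rational switching function (distances in Å)."""

    r0: float
    n: int = 6
    m: int = 10
    d0: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("exponents must satisfy 0 < n < m")


DEFAULT_HB_SWITCH = SwitchParams(r0=3.0, n=6, m=10)
DEFAULT_WATER_SWITCH = SwitchParams(r0=3.0, n=6, m=10)
# switch on a = (1 + cos θ)/2; reference a0 = (1 + cos 150°)/2
DEFAULT_ANGULAR_SWITCH = SwitchParams(r0=(1.0 + np.cos(5.0 * np.pi / 6.0)) / 2.0,
                                      n=6, m=10)


def rational_switch(r: np.ndarray | float, p: SwitchParams) -> np.ndarray | float:
    """Evaluate the rational switch; total on r ≥ 0, including x = 1.

    Uses the factored form (Σ_{k<n} x^k) / (Σ_{k<m} x^k), which is the same
    rational function with the removable singularity at x = 1 eliminated, so
    the value there is exactly n/m without branching.
    """
    r = np.asarray(r, dtype=float)
    x = np.maximum((r - p.d0) / p.r0, 0.0)
    small = x < 2.0
    out = np.empty_like(x)
    # geometric-sum form, exact and stable around x = 1
    xs = np.where(small, x, 0.0)
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    pow_ = np.ones_like(x)
    for k in range(p.m):
        if k < p.n:
            num += pow_
        den += pow_
        pow_ = pow_ * xs
    out = num / den
    if np.any(~small):
        xl = np.where(small, 2.0, x)
        direct = (1.0 - xl ** p.n) / (1.0 - xl ** p.m)
        out = np.where(small, out, direct)
    return out if out.ndim else float(out)


def angular_term(donor_heavy: np.ndarray, hydrogen: np.ndarray,
                 acceptor: np.ndarray, params: SwitchParams = DEFAULT_ANGULAR_SWITCH,
                 box: np.ndarray | None = None) -> np.ndarray | float:
    """Directionality of a D–H···A arrangement: 1 when collinear (θ = π).

    θ is the angle at the hydrogen; the switch acts on a = (1 + cos θ)/2 which
    is 0 for a straight bond and grows as the bond bends. Broadcasts over
    leading axes.
    """
    hd = minimum_image(np.asarray(donor_heavy, float) - np.asarray(hydrogen, float), box)
    ha = minimum_image(np.asarray(acceptor, float) - np.asarray(hydrogen, float), box)
    n1 = np.linalg.norm(hd, axis=-1)
    n2 = np.linalg.norm(ha, axis=-1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise GeometryError("coincident points in angular term")
    cos_theta = np.clip(np.sum(hd * ha, axis=-1) / (n1 * n2), -1.0, 1.0)
    return rational_switch((1.0 + cos_theta) / 2.0, replace(params, d0=0.0))


# ---------------------------------------------------------------------------
# donor/acceptor identification
# ---------------------------------------------------------------------------

def identify_donors_acceptors(
    top: Topology, frame: Frame | None = None
) -> tuple[list[tuple[int, int]], list[int]]:
    """Polar donors and acceptors of the protein.

    Returns ``(donors, acceptors)`` where donors are ``(heavy, hydrogen)``
    pairs — one entry per donated hydrogen — and acceptors are heavy-atom
    indices. Donors/acceptors are protein N, O, S atoms; a hydrogen belongs to
    the heavy atom closer than 1.2 Å (requires ``frame``) or, without
    coordinates, to the nearest preceding polar heavy atom in its residue by
    file order.
    """
    protein = top.is_protein
    polar = np.flatnonzero(protein & np.isin(top.elements, POLAR_ELEMENTS))
    hydrogens = np.flatnonzero(protein & (top.elements == "H"))
    acceptors = [int(i) for i in polar]
    if len(polar) and not len(hydrogens):
        raise ConfigurationError(
            "topology has no protein hydrogens; supply an H-complete structure "
            "(e.g. from gmx pdb2gmx or reduce) to define donors")

    donors: list[tuple[int, int]] = []
    if frame is not None:
        for h in hydrogens:
            d = np.linalg.norm(frame.coords[polar] - frame.coords[h], axis=1)
            j = int(np.argmin(d)) if len(d) else -1
            if j >= 0 and d[j] < COVALENT_H_CUTOFF:
                donors.append((int(polar[j]), int(h)))
    else:
        # PDB naming: a hydrogen's name is H + the suffix of its heavy atom
        # (H→N backbone, HG1→OG/SG, HE21→NE2, ...); HA/HB* hang off carbons
        # and never match a polar heavy atom.
        for h in hydrogens:
            res = top.resindices[h]
            suffix = str(top.names[h])[1:].rstrip("0123456789")
            for i in polar:
                if top.resindices[i] != res:
                    continue
                if str(top.names[i])[1:] == suffix:
                    donors.append((int(i), int(h)))
                    break
    donors.sort()
    return donors, acceptors


# ---------------------------------------------------------------------------
# feature definition and evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondFeature:
    """One hydrogen-bond feature F_i^HB (native or non-native)."""

    donor_heavy: int
    donor_h: int
    acceptor: int
    distance_params: SwitchParams = DEFAULT_HB_SWITCH
    angular_params: SwitchParams = DEFAULT_ANGULAR_SWITCH
    water_params: SwitchParams = DEFAULT_WATER_SWITCH
    competing_acceptors: tuple[int, ...] = ()
    origin: str = "folded"          # folded | unfolded
    kind: str = "native"            # native | non-native

    def __post_init__(self) -> None:
        if self.kind not in ("native", "non-native"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.origin not in ("folded", "unfolded"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.kind == "native" and self.origin != "folded":
            raise ValueError("native features originate from the folded basin")
        if self.kind == "non-native" and self.origin != "unfolded":
            raise ValueError("non-native features originate from the unfolded basin")
        if self.donor_heavy == self.acceptor:
            raise ValueError("donor and acceptor must be distinct atoms")

    @property
    def identity(self) -> tuple[str, int, int, int]:
        return ("HB", self.donor_heavy, self.donor_h, self.acceptor)


def _check_indices(top: Topology, *indices: int) -> None:
    for i in indices:
        if not (0 <= i < top.n_atoms):
            raise IndexError(f"atom index {i} out of range for topology "
                             f"of {top.n_atoms} atoms")


def _coords(frame_or_coords) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a Frame or a stacked (F, n, 3) array (vacuum)."""
    if isinstance(frame_or_coords, Frame):
        return frame_or_coords.coords, frame_or_coords.box
    return np.asarray(frame_or_coords, float), None


def bare_switch_value(f: HBondFeature, coords: np.ndarray,
                      box: np.ndarray | None) -> np.ndarray | float:
    """Distance × angular part of the feature (no competition terms).

    ``coords`` may be (n, 3) or stacked (F, n, 3).
    """
    d = np.linalg.norm(
        minimum_image(coords[..., f.donor_heavy, :] - coords[..., f.acceptor, :], box),
        axis=-1)
    s_dist = rational_switch(d, f.distance_params)
    s_ang = angular_term(coords[..., f.donor_heavy, :], coords[..., f.donor_h, :],
                         coords[..., f.acceptor, :], f.angular_params, box)
    return s_dist * s_ang


def water_competition(polar_atom: int, frame: Frame, top: Topology,
                      p: SwitchParams = DEFAULT_WATER_SWITCH) -> float:
    """Coordination of a protein polar atom with water oxygens.

    Sum over water oxygens of the rational switch on the minimum-image
    distance; 0 when no water is in range. Invariant under water relabelling
    (a plain sum) and under translating any water by a full box vector.
    """
    _check_indices(top, polar_atom)
    wox = np.flatnonzero(top.is_water & (top.elements == "O"))
    if len(wox) == 0:
        return 0.0
    d = np.linalg.norm(
        minimum_image(frame.coords[wox] - frame.coords[polar_atom], frame.box),
        axis=-1)
    return float(np.sum(rational_switch(d, p)))


def _water_competition_many(polar_atom: int, coords: np.ndarray,
                            box: np.ndarray | None, top: Topology,
                            p: SwitchParams) -> np.ndarray:
    wox = np.flatnonzero(top.is_water & (top.elements == "O"))
    if len(wox) == 0:
        return np.zeros(coords.shape[:-2])
    d = np.linalg.norm(
        minimum_image(coords[..., wox, :] - coords[..., polar_atom:polar_atom + 1, :],
                      box), axis=-1)
    return np.sum(rational_switch(d, p), axis=-1)


def evaluate_hbond_feature(f: HBondFeature, frame: Frame, top: Topology,
                           lambda_w: float = 1.0, lambda_p: float = 1.0) -> float:
    """Evaluate one hydrogen-bond feature on a frame.

    value = s_native − λ_w · (water competition on donor + acceptor)
                     − λ_p · Σ switch(donor → competing protein acceptor)

    Bounded above by 1; equals the bare switch when λ_w = λ_p = 0 (the
    native-only ablation).
    """
    return float(evaluate_hbond_feature_many(
        f, frame.coords[None], frame.box, top, lambda_w, lambda_p)[0])


def evaluate_hbond_feature_many(f: HBondFeature, coords: np.ndarray,
                                box: np.ndarray | None, top: Topology,
                                lambda_w: float = 1.0,
                                lambda_p: float = 1.0) -> np.ndarray:
    """Vectorised evaluation over stacked coordinates (F, n_atoms, 3)."""
    _check_indices(top, f.donor_heavy, f.donor_h, f.acceptor,
                   *f.competing_acceptors)
    value = np.asarray(bare_switch_value(f, coords, box), dtype=float)
    if lambda_w != 0.0:
        wc = (_water_competition_many(f.donor_heavy, coords, box, top, f.water_params)
              + _water_competition_many(f.acceptor, coords, box, top, f.water_params))
        value = value - lambda_w * wc
    if lambda_p != 0.0 and f.competing_acceptors:
        comp = np.array(f.competing_acceptors)
        d = np.linalg.norm(
            minimum_image(coords[..., comp, :]
                          - coords[..., f.donor_heavy:f.donor_heavy + 1, :], box),
            axis=-1)
        value = value - lambda_p * np.sum(rational_switch(d, f.distance_params), axis=-1)
    return value
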