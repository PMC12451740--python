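"""Self-contained two-state peptide-in-water test systems.

The generator builds a small antiparallel β-hairpin (two strands of ``k``
residues each, alanine-like with one glycine to exercise the Cα side-chain
proxy) in two reference configurations:

* a *folded* frame where the planted native cross-strand hydrogen bonds have
  ideal geometry (donor–acceptor ≈ 2.9 Å, D–H···A ≈ 180°) and the planted
  native side-chain pairs sit at ≈ 0.8 of the side-chain switch reference
  distance;
* a *misfolded* frame with the register of the second strand shifted so a
  competing, non-native set of hydrogen bonds and side-chain contacts is
  satisfied instead (the strand-B residue whose misfolded partner would
  coincide with its folded partner is displaced out of plane so no native
  contact survives).

Waters are placed on a seeded pool of sites kept clear of the protein in both
reference configurations and are resampled (repositioned and relabelled)
every frame, which exercises water-permutation invariance. Frames are the
reference geometry plus isotropic Gaussian noise — these are geometric
constructions, not molecular dynamics: they test featurization and
estimators, not force fields.

``telegraph`` sampling flips between the two basins as a two-state Markov
chain with stationary folded probability ``p_fold``, so the ground-truth
free-energy difference is ΔF = −kT·ln(p_fold/(1−p_fold)) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import FOLDED, UNFOLDED
from .trajectory_io import Frame, Topology, Trajectory

__all__ = ["FixtureSpec", "GenerationError", "make_topology",
           "sample_trajectory", "sample_coordinate_array"]

# hairpin geometry constants (Å)
_RES_SPACING = 7.0        # N–N spacing along a strand
_STRAND_GAP = 4.13        # strand separation: 2.9 (H-bond) + 1.23 (C=O)
_HB_DA = 2.9              # planted donor–acceptor distance
_SC_TARGET = 5.2          # planted side-chain COM distance (0.8 × 6.5)
_DISPLACE_Z = 7.0         # out-of-plane shift of the degenerate residue


class GenerationError(RuntimeError):
    """Planted-contact geometry could not be realised."""


@dataclass
class FixtureSpec:
    """Parameters of the synthetic two-state system.

    The planted contact lists are derived from the hairpin construction when
    left as ``None``; residue pairs are (donor_res, acceptor_res) for
    hydrogen bonds and unordered pairs for side chains.
    """

    n_residues: int = 6
    n_waters: int = 30
    p_fold: float = 0.7
    sigma: float = 0.05          # Å, per-atom coordinate noise
    n_frames: int = 500
    seed: int = 0
    stride_ps: float = 100.0
    switch_prob: float = 0.1     # telegraph: total flip-rate scale per frame
    water_exclusion: float = 6.0  # Å, water-to-protein clearance
    box_length: float = 36.0      # Å, cubic box
    native_hb: list[tuple[int, int]] | None = None
    native_sc: list[tuple[int, int]] | None = None
    nonnative_hb: list[tuple[int, int]] | None = None
    nonnative_sc: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 6 or self.n_residues % 2:
            raise ValueError("hairpin fixture needs an even residue count ≥ 6")
        if not 0.0 < self.p_fold < 1.0:
            raise ValueError("p_fold must lie strictly between 0 and 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        k = self.n_residues // 2
        last = self.n_residues - 1
        if self.native_hb is None:
            pairs = [(i, last - i) for i in range(k - 1)]
            self.native_hb = sorted(pairs + [(j, i) for i, j in pairs])
        if self.native_sc is None:
            self.native_sc = [(i, last - i) for i in range(k - 1)]
        displaced = self._displaced_residues()
        if self.nonnative_hb is None:
            pairs = [(i, i + k) for i in range(k) if i + k not in displaced]
            self.nonnative_hb = sorted(pairs + [(j, i) for i, j in pairs])
        if self.nonnative_sc is None:
            self.nonnative_sc = [(i, i + k) for i in range(k)
                                 if i + k not in displaced]

    def _displaced_residues(self) -> set[int]:
        """Strand-B residues whose misfolded partner equals their folded one."""
        k = self.n_residues // 2
        last = self.n_residues - 1
        # j's folded partner is last - j, its misfolded partner is j - k;
        # both coincide when 2j = last + k
        return {j for j in range(k, self.n_residues) if 2 * j == last + k}


# ---------------------------------------------------------------------------
# topology and reference frames
# ---------------------------------------------------------------------------

def _residue_atoms(resname: str) -> list[tuple[str, str]]:
    atoms = [("N", "N"), ("H", "H"), ("CA", "C"), ("HA", "H")]
    if resname != "GLY":
        atoms += [("CB", "C"), ("HB1", "H")]
    atoms += [("C", "C"), ("O", "O")]
    return atoms


def _place_residue(origin_x: float, *, strand: str, resname: str,
                   gap: float = _STRAND_GAP) -> dict[str, np.ndarray]:
    """Local atom positions for one residue of strand A (y=0, pointing +y)
    or strand B (y=gap, pointing −y, x running backwards)."""
    if strand == "A":
        pos = {
            "N": (origin_x, 0.0, 0.0),
            "H": (origin_x, 1.0, 0.0),
            "CA": (origin_x + 1.5, -0.8, 0.0),
            "HA": (origin_x + 1.5, -1.4, 0.85),
            "CB": (origin_x + 1.5, -1.1, -1.35),
            "HB1": (origin_x + 2.4, -1.1, -1.95),
            "C": (origin_x + 3.0, 0.0, 0.0),
            "O": (origin_x + 3.0, 1.23, 0.0),
        }
    else:
        # mirrored so H and O point toward strand A; side chain lowered to
        # put the COM–COM distance of planted pairs near the 5.2 Å target
        pos = {
            "N": (origin_x, gap, 0.0),
            "H": (origin_x, gap - 1.0, 0.0),
            "CA": (origin_x - 1.5, gap + 0.8, 0.0),
            "HA": (origin_x - 1.5, gap + 1.4, 0.85),
            "CB": (origin_x - 1.5, gap - 0.03, -1.35),
            "HB1": (origin_x - 2.4, gap - 0.03, -1.95),
            "C": (origin_x - 3.0, gap, 0.0),
            "O": (origin_x - 3.0, gap - 1.23, 0.0),
        }
    return {k: np.array(v) for k, v in pos.items()}


def _build_frame(spec: FixtureSpec, arrangement: str) -> np.ndarray:
    """Protein coordinates (n_protein_atoms, 3) for one arrangement."""
    k = spec.n_residues // 2
    last = spec.n_residues - 1
    displaced = spec._displaced_residues()
    coords: list[np.ndarray] = []
    for res in range(spec.n_residues):
        resname = "GLY" if res == 2 else "ALA"
        if res < k:  # strand A, identical in both arrangements
            pos = _place_residue(_RES_SPACING * res, strand="A", resname=resname)
        else:
            if arrangement == "folded":
                # partner i = last - res sits below: origin above its C=O
                x = 3.0 + _RES_SPACING * (last - res)
            else:
                x = 3.0 + _RES_SPACING * (res - k)
            pos = _place_residue(x, strand="B", resname=resname)
            if arrangement == "misfolded" and res in displaced:
                for key in pos:
                    pos[key] = pos[key] + np.array([0.0, 0.0, _DISPLACE_Z])
        for name, _el in _residue_atoms(resname):
            coords.append(pos[name])
    return np.array(coords)


def _water_sites(spec: FixtureSpec, protein_union: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Pool of water-oxygen sites clear of the protein in both basins."""
    n_sites = max(4 * spec.n_waters, spec.n_waters + 20)
    sites: list[np.ndarray] = []
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 200000:
            raise GenerationError("could not place the requested waters; "
                                  "box too small for the exclusion distance")
        p = rng.uniform(0.0, spec.box_length, size=3)
        if np.min(np.linalg.norm(protein_union - p, axis=1)) < spec.water_exclusion:
            continue
        if sites and np.min(np.linalg.norm(np.array(sites) - p, axis=1)) < 2.5:
            continue
        sites.append(p)
    return np.array(sites)


_WATER_OFFSETS = np.array([[0.0, 0.0, 0.0],      # O
                           [0.96, 0.0, 0.0],     # H1
                           [-0.24, 0.93, 0.0]])  # H2


def make_topology(spec: FixtureSpec) -> tuple[Topology, Frame, Frame]:
    """Build the fixture topology and its folded / misfolded reference frames.

    The returned frames are validated against the planted contact lists:
    every native hydrogen bond must have ideal geometry in the folded frame,
    every planted non-native contact must be satisfied in the misfolded
    frame. A violated target raises :class:`GenerationError`.
    """
    names, elements, resindices, resnames = [], [], [], []
    for res in range(spec.n_residues):
        rn = "GLY" if res == 2 else "ALA"
        for name, el in _residue_atoms(rn):
            names.append(name)
            elements.append(el)
            resindices.append(res)
            resnames.append(rn)
    for w in range(spec.n_waters):
        for name, el in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            names.append(name)
            elements.append(el)
            resindices.append(spec.n_residues + w)
            resnames.append("SOL")

    from .trajectory_io import ATOMIC_MASSES
    elements_arr = np.array(elements)
    resnames_arr = np.array(resnames)
    top = Topology(
        names=np.array(names), elements=elements_arr,
        resindices=np.array(resindices), resnames=resnames_arr,
        chain_ids=np.full(len(names), "A"),
        masses=np.array([ATOMIC_MASSES[e] for e in elements]),
        is_protein=(resnames_arr != "SOL"),
        is_water=(resnames_arr == "SOL"))

    shift = np.array([9.0, 14.0, 14.0])  # centre the hairpin in the box
    folded_p = _build_frame(spec, "folded") + shift
    misfolded_p = _build_frame(spec, "misfolded") + shift
    extent = float(np.ptp(np.vstack([folded_p, misfolded_p]), axis=0).max())
    if extent >= spec.box_length / 2 - 0.5:
        raise GenerationError(
            f"protein extent {extent:.1f} Å too large for a "
            f"{spec.box_length:.0f} Å box under the minimum-image convention; "
            "increase box_length")

    rng = np.random.default_rng(spec.seed)
    sites = _water_sites(spec, np.vstack([folded_p, misfolded_p]), rng)
    water0 = (sites[:spec.n_waters, None, :] + _WATER_OFFSETS).reshape(-1, 3)

    box = np.full(3, spec.box_length)
    folded = Frame(coords=np.vstack([folded_p, water0]), box=box, time=0.0)
    misfolded = Frame(coords=np.vstack([misfolded_p, water0]), box=box, time=0.0)

    _validate(spec, top, folded, misfolded)
    # stash the site pool for the samplers (derived, deterministic)
    top_sites = sites
    folded.water_sites = top_sites  # type: ignore[attr-defined]
    misfolded.water_sites = top_sites  # type: ignore[attr-defined]
    return top, folded, misfolded


def _validate(spec: FixtureSpec, top: Topology, folded: Frame,
              misfolded: Frame) -> None:
    def atom(res: int, name: str) -> int:
        idx = top.residue_atoms(res)
        hit = idx[top.names[idx] == name]
        if len(hit) != 1:
            raise GenerationError(f"residue {res} has no unique atom {name}")
        return int(hit[0])

    from .sidechain import sidechain_com

    for frame, hbs, scs, label in (
            (folded, spec.native_hb, spec.native_sc, "folded"),
            (misfolded, spec.nonnative_hb, spec.nonnative_sc, "misfolded")):
        for dres, ares in hbs:
            d = frame.coords[atom(dres, "N")]
            h = frame.coords[atom(dres, "H")]
            a = frame.coords[atom(ares, "O")]
            da = np.linalg.norm(d - a)
            v1, v2 = d - h, a - h
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if not (2.6 <= da <= 3.2) or theta < 165.0:
                raise GenerationError(
                    f"planted H-bond {dres}->{ares} off target in {label} "
                    f"frame (d={da:.2f} Å, θ={theta:.0f}°)")
        for ri, rj in scs:
            dist = np.linalg.norm(sidechain_com(top, frame, ri)
                                  - sidechain_com(top, frame, rj))
            if dist > 5.6:
                raise GenerationError(
                    f"planted side-chain pair ({ri},{rj}) off target in "
                    f"{label} frame (COM distance {dist:.2f} Å)")


# ---------------------------------------------------------------------------
# trajectory sampling
# ---------------------------------------------------------------------------

def _telegraph_labels(spec: FixtureSpec, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    p_uf = spec.switch_prob * spec.p_fold          # U → F per frame
    p_fu = spec.switch_prob * (1.0 - spec.p_fold)  # F → U per frame
    labels = np.empty(n, dtype=int)
    state = FOLDED if rng.random() < spec.p_fold else UNFOLDED
    u = rng.random(n)
    for i in range(n):
        labels[i] = state
        if state == FOLDED:
            if u[i] < p_fu:
                state = UNFOLDED
        elif u[i] < p_uf:
            state = FOLDED
    return labels


def sample_coordinate_array(spec: FixtureSpec, basin: str,
                            n_frames: int | None = None,
                            seed: int | None = None
                            ) -> tuple[Topology, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised sampler: (topology, coords (F,n,3), box, labels).

    ``basin`` is ``folded``, ``unfolded`` (both resident in one reference
    configuration) or ``telegraph`` (Markov switching with stationary folded
    probability ``p_fold``). Water molecules are drawn from the site pool
    independently every frame.
    """
    if basin not in ("folded", "unfolded", "telegraph"):
        raise ValueError(f"unknown basin {basin!r}")
    n = spec.n_frames if n_frames is None else n_frames
    top, folded, misfolded = make_topology(spec)
    sites = folded.water_sites  # type: ignore[attr-defined]
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    if basin == "folded":
        labels = np.full(n, FOLDED)
    elif basin == "unfolded":
        labels = np.full(n, UNFOLDED)
    else:
        labels = _telegraph_labels(spec, n, rng)

    n_protein = int(np.sum(top.is_protein))
    refs = np.where((labels == FOLDED)[:, None, None],
                    folded.coords[None, :n_protein, :],
                    misfolded.coords[None, :n_protein, :])
    coords = np.empty((n, top.n_atoms, 3))
    coords[:, :n_protein, :] = refs
    # per-frame water resampling: a random subset of sites in random order
    order = np.argsort(rng.random((n, len(sites))), axis=1)[:, :spec.n_waters]
    wat = sites[order]                      # (n, n_waters, 3)
    wat = wat[:, :, None, :] + _WATER_OFFSETS[None, None, :, :]
    coords[:, n_protein:, :] = wat.reshape(n, -1, 3)
    if spec.sigma > 0:
        coords += rng.normal(0.0, spec.sigma, size=coords.shape)
    return top, coords, folded.box, labels


def sample_trajectory(spec: FixtureSpec, basin: str,
                      n_frames: int | None = None, seed: int | None = None
                      ) -> tuple[Trajectory, np.ndarray]:
    """Sample a :class:`Trajectory` plus ground-truth per-frame labels."""
    top, coords, box, labels = sample_coordinate_array(spec, basin, n_frames, seed)
    frames = [Frame(coords=c, box=box.copy(), time=i * spec.stride_ps)
              for i, c in enumerate(coords)]
    return Trajectory(topology=top, frames=frames), labels
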