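"""Reference folding-landscape analysis.

The protocol mirrors how long unbiased folding trajectories are reduced to
thermodynamic numbers: a Cα-RMSD series against the native structure is
labelled folded/unfolded with a hysteretic dual-cutoff rule (the state flips
only after the RMSD dwells beyond a cutoff for a full time window, which
suppresses spurious recrossings), transitions and residence times are counted
on the labels, the folding free energy comes from the basin populations,
ΔF = −kB·T·ln(P_F/P_U), the enthalpy difference from partitioning a per-frame
energy series into the basins, and free-energy surfaces from (re)weighted
histograms over one or two collective variables. Replica aggregation follows
the mean ± population standard deviation over independent runs.

Units: Å, ps in; free energies in kcal/mol; residence times reported in µs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Frame, TimeSeries, Topology, Trajectory

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "FOLDED", "UNFOLDED", "TRANSIT",
    "StateSeries", "BasinStats", "FESGrid", "ReplicaStats",
    "rmsd_ca", "rmsd_ca_series",
    "assign_states_dual_cutoff", "count_transitions",
    "delta_F", "delta_H", "fes", "weights_from_bias", "replica_stats",
]

KB_KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant, kcal mol^-1 K^-1

# state codes
FOLDED, UNFOLDED, TRANSIT = 1, 0, -1


# ---------------------------------------------------------------------------
# Cα RMSD (Kabsch superposition)
# ---------------------------------------------------------------------------

def _ca_coords(frame: Frame, top: Topology) -> np.ndarray:
    ca = top.select({"CA"}, protein=True)
    return frame.coords[ca]


def rmsd_ca(frame: Frame, reference: Frame, top: Topology) -> float:
    """Minimal Cα RMSD (Å) after optimal rigid superposition.

    The optimal rotation is the Kabsch solution, obtained from
    :func:`scipy.spatial.transform.Rotation.align_vectors` on the centred
    coordinate sets.
    """
    from scipy.spatial.transform import Rotation

    a = _ca_coords(frame, top)
    b = _ca_coords(reference, top)
    if len(a) != len(b):
        raise ValueError("frame and reference have different Cα counts")
    if len(a) < 3:
        raise ValueError("need at least 3 Cα atoms for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _rot, rssd = Rotation.align_vectors(b, a)
    return float(rssd / np.sqrt(len(a)))


def rmsd_ca_series(traj: Trajectory, reference: Frame) -> TimeSeries:
    """Per-frame Cα RMSD against a native reference, as a TimeSeries."""
    values = [rmsd_ca(fr, reference, traj.topology) for fr in traj]
    data = np.column_stack([traj.times, values])
    return TimeSeries(names=["time", "rmsd_ca"], data=data)


# ---------------------------------------------------------------------------
# dual-cutoff state assignment
# ---------------------------------------------------------------------------

@dataclass
class StateSeries:
    """Per-frame basin labels plus the assignment parameters that made them."""

    labels: np.ndarray              # (n,) int: FOLDED / UNFOLDED / TRANSIT
    times: np.ndarray               # (n,) ps
    folded_cut: float | None = None     # Å
    unfolded_cut: float | None = None   # Å
    window_ns: float | None = None
    rmsd: np.ndarray | None = None      # source series, Å

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.labels) != len(self.times):
            raise ValueError("labels and times length mismatch")
        if (self.folded_cut is not None and self.unfolded_cut is not None
                and not self.folded_cut < self.unfolded_cut):
            raise ValueError("folded cutoff must be below the unfolded cutoff")

    def __len__(self) -> int:
        return len(self.labels)

    def populations(self) -> dict[str, float]:
        """Basin populations over all frames; transit frames count in the
        denominator only, so folded + unfolded ≤ 1."""
        n = len(self.labels)
        return {
            "folded": float(np.mean(self.labels == FOLDED)) if n else 0.0,
            "unfolded": float(np.mean(self.labels == UNFOLDED)) if n else 0.0,
        }


def assign_states_dual_cutoff(rmsd: TimeSeries, folded_cut: float,
                              unfolded_cut: float, window: float,
                              column: str = "rmsd_ca") -> StateSeries:
    """Hysteretic two-threshold labelling of an RMSD series.

    The state flips to folded only once the RMSD has stayed ≤ ``folded_cut``
    for a full ``window`` (ns), and to unfolded only once it has stayed ≥
    ``unfolded_cut`` for a full window; the flip is recorded at the frame
    where the dwell requirement completes. Frames between flips inherit the
    current state; frames before the first commitment are transit. A series
    oscillating strictly between the two cutoffs never commits.
    """
    if not folded_cut < unfolded_cut:
        raise ValueError("folded cutoff must be below the unfolded cutoff")
    t = rmsd.column("time")
    try:
        r = rmsd.column(column)
    except KeyError:
        value_cols = [n for n in rmsd.names if n != "time"]
        if len(value_cols) != 1:
            raise
        r = rmsd.column(value_cols[0])
    stride_ps = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    window_ps = window * 1000.0
    if stride_ps > 0 and window_ps < stride_ps:
        raise ValueError("window must be at least one frame stride")
    wf = max(1, int(round(window_ps / stride_ps))) if stride_ps > 0 else 1

    labels = np.full(len(r), TRANSIT, dtype=int)
    state = TRANSIT
    below = above = 0
    for i, ri in enumerate(r):
        below = below + 1 if ri <= folded_cut else 0
        above = above + 1 if ri >= unfolded_cut else 0
        if below >= wf and state != FOLDED:
            state = FOLDED
        elif above >= wf and state != UNFOLDED:
            state = UNFOLDED
        labels[i] = state
    return StateSeries(labels=labels, times=t, folded_cut=folded_cut,
                       unfolded_cut=unfolded_cut, window_ns=window, rmsd=np.asarray(r))


# ---------------------------------------------------------------------------
# transitions, residence times, ΔF, ΔH
# ---------------------------------------------------------------------------

@dataclass
class BasinStats:
    """Transition counts, residence times and basin thermodynamics."""

    n_folding: int
    n_unfolding: int
    mean_folding_time_us: float | None
    mean_unfolding_time_us: float | None
    populations: dict[str, float]
    temperature: float | None = None    # K
    delta_F: float | None = None        # kcal/mol
    delta_H: float | None = None        # kcal/mol


def count_transitions(s: StateSeries) -> BasinStats:
    """Count folding (U→F) and unfolding (F→U) events and residence times.

    The mean folding time is the mean duration of the unfolded residence
    segments that end in a folding flip (symmetrically for unfolding). With
    zero events the corresponding time is reported as ``None``, never 0.
    """
    lab = s.labels
    committed = np.flatnonzero(lab != TRANSIT)
    if len(committed) == 0:
        raise ValueError("state series has no committed frames")
    idx = committed
    stride_ps = float(np.median(np.diff(s.times))) if len(s.times) > 1 else 1.0

    n_fold = n_unfold = 0
    fold_waits: list[float] = []
    unfold_waits: list[float] = []
    seg_start = idx[0]
    prev = lab[idx[0]]
    for i in idx[1:]:
        cur = lab[i]
        if cur != prev:
            dwell_ps = s.times[i] - s.times[seg_start]
            if prev == UNFOLDED and cur == FOLDED:
                n_fold += 1
                fold_waits.append(dwell_ps)
            elif prev == FOLDED and cur == UNFOLDED:
                n_unfold += 1
                unfold_waits.append(dwell_ps)
            seg_start = i
            prev = cur

    to_us = 1.0e-6
    return BasinStats(
        n_folding=n_fold, n_unfolding=n_unfold,
        mean_folding_time_us=(float(np.mean(fold_waits)) * to_us
                              if fold_waits else None),
        mean_unfolding_time_us=(float(np.mean(unfold_waits)) * to_us
                                if unfold_waits else None),
        populations=s.populations())


def delta_F(s: StateSeries, T: float) -> float:
    """Folding free energy ΔF = −kB·T·ln(P_folded / P_unfolded), kcal/mol.

    Negative when the folded basin is favoured. Raises if either basin is
    unpopulated (the ratio, hence ΔF, would be infinite).
    """
    pops = s.populations()
    if pops["folded"] == 0.0 or pops["unfolded"] == 0.0:
        raise ValueError(
            "both basins must be populated to define a finite "
            f"free-energy difference (populations: {pops})")
    return float(-KB_KCAL_PER_MOL_K * T * np.log(pops["folded"] / pops["unfolded"]))


def delta_H(energy: TimeSeries, s: StateSeries, column: str | None = None) -> float:
    """Enthalpy difference ΔH = ⟨E⟩_unfolded − ⟨E⟩_folded, kcal/mol.

    The energy series is partitioned by the per-frame basin labels (transit
    frames excluded); positive ΔH means the unfolded basin sits higher in
    energy. ``column`` selects the energy column; by default the single
    non-time column is used.
    """
    if column is None:
        value_cols = [n for n in energy.names if n != "time"]
        if len(value_cols) != 1:
            raise ValueError("energy series has several columns; name one")
        column = value_cols[0]
    e = energy.column(column)
    if len(e) != len(s.labels):
        raise ValueError("energy series and state series are not frame-aligned")
    ef = e[s.labels == FOLDED]
    eu = e[s.labels == UNFOLDED]
    if len(ef) == 0 or len(eu) == 0:
        raise ValueError("both basins must be populated to define ΔH")
    return float(eu.mean() - ef.mean())


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FESGrid:
    """Binned free-energy surface over one or two CVs, min-shifted to 0."""

    cv_names: list[str]
    edges: list[np.ndarray]
    free_energy: np.ndarray   # kcal/mol; empty bins are +inf
    kT: float                 # kcal/mol
    weight_total: float = 1.0

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def to_table(self) -> str:
        """Plain-text table: bin centres then free energy, one bin per row."""
        lines = ["#! FIELDS " + " ".join(self.cv_names) + " free_energy"]
        cs = self.centers
        if len(cs) == 1:
            for x, f in zip(cs[0], self.free_energy):
                lines.append(f"{x:.6g} {f:.6g}")
        else:
            for i, x in enumerate(cs[0]):
                for j, y in enumerate(cs[1]):
                    lines.append(f"{x:.6g} {y:.6g} {self.free_energy[i, j]:.6g}")
        return "\n".join(lines) + "\n"


def weights_from_bias(ts: TimeSeries, bias_column: str, kT: float) -> np.ndarray:
    """Reweighting factors exp(V_bias/kT) from a COLVAR bias column.

    The maximum bias is subtracted before exponentiation; the overall scale
    of the weights is immaterial to the FES.
    """
    v = ts.column(bias_column)
    return np.exp((v - v.max()) / kT)


def fes(series: TimeSeries, columns: list[str] | str,
        kT: float, weights: np.ndarray | None = None,
        bins: int | tuple[int, ...] = 50,
        ranges: list[tuple[float, float]] | None = None) -> FESGrid:
    """Free-energy surface F(bin) = −kT·ln(Σw in bin / Σw), min-shifted to 0.

    One or two CV columns; unit weights for unbiased input (pass
    :func:`weights_from_bias` factors for biased input). Empty bins carry
    +inf. Default binning is 50 per axis over the observed range.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    if isinstance(columns, str):
        columns = [columns]
    if not 1 <= len(columns) <= 2:
        raise ValueError("FES supports one or two CV columns")
    data = [series.column(c) for c in columns]
    n = len(data[0])
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != n:
        raise ValueError("weights length must match the series")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    wtot = weights.sum()
    if wtot == 0:
        raise ValueError("weights sum to zero")

    if isinstance(bins, int):
        bins = (bins,) * len(columns)
    hist, edges = np.histogramdd(np.column_stack(data), bins=bins,
                                 range=ranges, weights=weights)
    with np.errstate(divide="ignore"):
        F = -kT * np.log(hist / wtot)
    F = F - F.min()
    if len(columns) == 1:
        F = F.ravel()
    return FESGrid(cv_names=list(columns), edges=[np.asarray(e) for e in edges],
                   free_energy=F, kT=kT, weight_total=float(wtot))


# ---------------------------------------------------------------------------
# replica aggregation
# ---------------------------------------------------------------------------

@dataclass
class ReplicaStats:
    """Element-wise mean and population standard deviation over replicas."""

    mean: np.ndarray | float
    std: np.ndarray | float
    n_replicas: int
    incomplete_bins: np.ndarray | None = None  # bins empty in ≥1 replica


def replica_stats(estimates: list) -> ReplicaStats:
    """Aggregate per-replica scalars or FESGrids as mean ± population std.

    For grids, bins that are empty (infinite) in any replica are flagged in
    ``incomplete_bins`` and reported as +inf mean rather than silently
    averaged over the subset of replicas that populated them.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 replicas")
    if isinstance(estimates[0], FESGrid):
        ref = estimates[0]
        for g in estimates[1:]:
            if (len(g.edges) != len(ref.edges)
                    or any(not np.allclose(a, b) for a, b in zip(g.edges, ref.edges))):
                raise ValueError("replica grids have incompatible binning")
        stack = np.stack([g.free_energy for g in estimates])
        incomplete = ~np.all(np.isfinite(stack), axis=0)
        mean = np.where(incomplete, np.inf, np.nanmean(
            np.where(np.isfinite(stack), stack, np.nan), axis=0))
        std = np.where(incomplete, np.inf, np.nanstd(
            np.where(np.isfinite(stack), stack, np.nan), axis=0))
        return ReplicaStats(mean=mean, std=std, n_replicas=len(estimates),
                            incomplete_bins=incomplete)
    arr = np.asarray(estimates, dtype=float)
    return ReplicaStats(mean=float(arr.mean()), std=float(arr.std()),
                        n_replicas=len(estimates))
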