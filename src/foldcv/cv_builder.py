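"""Assemble the s^HB and s^SC collective variables and emit PLUMED input.

Each CV is a plain signed sum over its features:

    s^HB = Σ_i F_i^HB,F − Σ_i F_i^HB,U
    s^SC = Σ_i F_i^SC,F − Σ_i F_i^SC,U

native features (harvested from the folded basin) enter with coefficient +1
and non-native features (from the unfolded basin) with −1, always. Ablation
variants switch off parts of the non-native description:

* ``full`` — everything on;
* ``native_only`` — non-native features dropped and both competition weights
  zeroed (the abridged CV);
* ``no_water_nonnative`` — protein–water competition off (λ_w = 0);
* ``no_protein_nonnative`` — protein–protein competition off (λ_p = 0) and
  harvested non-native contact features dropped.

The emitted PLUMED (≥ 2.8) file builds both CVs from primitive actions
(DISTANCE/ANGLE/COORDINATION/COM/CUSTOM/COMBINE) with 1-based atom serials,
Å length units and a PRINT action, and embeds the feature-set provenance hash
in its header so any COLVAR it produces can be traced to its defining
features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .feature_select import FeatureSet
from .hbond import HBondFeature, SwitchParams, evaluate_hbond_feature_many
from .sidechain import SideChainFeature, evaluate_sc_feature_many, sidechain_atoms
from .trajectory_io import TimeSeries, Topology, Trajectory

__all__ = [
    "CVDefinition",
    "ABLATION_MODES",
    "assemble_cvs",
    "ablate",
    "evaluate_cv",
    "evaluate_cv_frames",
    "write_plumed",
]

ABLATION_MODES = ("full", "native_only", "no_water_nonnative",
                  "no_protein_nonnative")


@dataclass(frozen=True)
class CVDefinition:
    """One CV: ordered native (+1) and non-native (−1) feature lists."""

    name: str                      # "sHB" | "sSC"
    native: tuple
    nonnative: tuple
    mode: str = "full"
    lambda_w: float = 1.0          # protein–water competition weight
    lambda_p: float = 1.0          # protein–protein competition weight
    provenance_hash: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {self.mode!r}")
        if self.mode == "native_only":
            if self.nonnative or self.lambda_w or self.lambda_p:
                raise ValueError("native_only CV must have no non-native terms")
        for f in self.native:
            if f.kind != "native":
                raise ValueError("non-native feature in the +1 list")
        for f in self.nonnative:
            if f.kind != "non-native":
                raise ValueError("native feature in the −1 list")

    @property
    def features(self) -> tuple:
        return self.native + self.nonnative

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.native)),
                               -np.ones(len(self.nonnative))])


def assemble_cvs(fs: FeatureSet, lambda_w: float = 1.0, lambda_p: float = 1.0
                 ) -> tuple[CVDefinition, CVDefinition]:
    """Build (s^HB, s^SC) from a filtered feature set.

    Requires at least one native hydrogen-bond and one native side-chain
    feature; the two CVs share no features.
    """
    if not fs.native_hb:
        raise ValueError("feature set has no native hydrogen-bond features")
    if not fs.native_sc:
        raise ValueError("feature set has no native side-chain features")
    h = fs.provenance_hash()
    shb = CVDefinition(name="sHB", native=tuple(fs.native_hb),
                       nonnative=tuple(fs.nonnative_hb),
                       lambda_w=lambda_w, lambda_p=lambda_p, provenance_hash=h)
    ssc = CVDefinition(name="sSC", native=tuple(fs.native_sc),
                       nonnative=tuple(fs.nonnative_sc),
                       lambda_w=0.0, lambda_p=0.0, provenance_hash=h)
    return shb, ssc


def ablate(cv: CVDefinition, mode: str) -> CVDefinition:
    """Derive an ablated variant of a CV (see module docstring)."""
    if mode == "full":
        return replace(cv, mode="full")
    if mode == "native_only":
        return replace(cv, mode=mode, nonnative=(), lambda_w=0.0, lambda_p=0.0)
    if mode == "no_water_nonnative":
        return replace(cv, mode=mode, lambda_w=0.0)
    if mode == "no_protein_nonnative":
        return replace(cv, mode=mode, nonnative=(), lambda_p=0.0)
    raise ValueError(f"unknown ablation mode {mode!r}")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _feature_values(feature, coords: np.ndarray, box, top: Topology,
                    lambda_w: float, lambda_p: float) -> np.ndarray:
    if isinstance(feature, HBondFeature):
        return evaluate_hbond_feature_many(feature, coords, box, top,
                                           lambda_w, lambda_p)
    if isinstance(feature, SideChainFeature):
        return evaluate_sc_feature_many(feature, coords, box, top)
    raise TypeError(f"unknown feature type {type(feature).__name__}")


def evaluate_cv_frames(cv: CVDefinition, coords: np.ndarray, box,
                       top: Topology) -> np.ndarray:
    """CV values over stacked coordinates (n_frames, n_atoms, 3)."""
    if coords.shape[-2] != top.n_atoms:
        raise ValueError("coordinate array does not match the topology")
    total = np.zeros(coords.shape[:-2])
    for f in cv.native:
        total = total + _feature_values(f, coords, box, top,
                                        cv.lambda_w, cv.lambda_p)
    for f in cv.nonnative:
        total = total - _feature_values(f, coords, box, top, 0.0, 0.0)
    return total


def evaluate_cv(cv: CVDefinition, traj: Trajectory) -> TimeSeries:
    """Evaluate a CV on a trajectory: one value per frame, ±1 coefficients."""
    coords = traj.coordinate_array()
    box = traj[0].box if len(traj) else None
    values = evaluate_cv_frames(cv, coords, box, traj.topology)
    return TimeSeries(names=["time", cv.name],
                      data=np.column_stack([traj.times, values]))


# ---------------------------------------------------------------------------
# PLUMED emission
# ---------------------------------------------------------------------------

def _sw_expr(var: str, p: SwitchParams) -> str:
    """Rational switch as a PLUMED CUSTOM sub-expression (no spaces)."""
    x = f"(({var}-{p.d0:.6g})/{p.r0:.6g})"
    return f"((1-{x}^{p.n})/(1-{x}^{p.m}))"

def _sw_keyword(p: SwitchParams) -> str:
    return (f"RATIONAL R_0={p.r0:.6g} D_0={p.d0:.6g} "
            f"NN={p.n} MM={p.m}")


def _serials(indices) -> str:
    return ",".join(str(int(i) + 1) for i in indices)


def write_plumed(cvs: tuple[CVDefinition, ...] | list, top: Topology, path,
                 stride: int = 1, colvar_file: str = "COLVAR") -> None:
    """Emit one PLUMED input defining all given CVs plus a PRINT action.

    Deterministic given the definitions; 1-based serials; Å units declared
    explicitly (PLUMED's native length unit is nm). Water-group actions are
    emitted only when some feature actually uses water competition, so a
    native-only file contains none.
    """
    lines: list[str] = []
    hashes = sorted({cv.provenance_hash for cv in cvs if cv.provenance_hash})
    lines.append("# generated by foldcv")
    if hashes:
        lines.append(f"# feature-set provenance hash: {','.join(hashes)}")
    for cv in cvs:
        lines.append(f"# {cv.name}: {len(cv.native)} native (+1), "
                     f"{len(cv.nonnative)} non-native (-1), mode={cv.mode}")
    lines.append("UNITS LENGTH=A TIME=ps ENERGY=kcal/mol")

    needs_water = any(
        isinstance(f, HBondFeature) and cv.lambda_w != 0.0
        for cv in cvs for f in cv.native)
    if needs_water:
        wox = np.flatnonzero(top.is_water & (top.elements == "O"))
        if len(wox) == 0:
            raise ValueError("water competition requested but the topology "
                             "has no water oxygens")
        lines.append(f"wox: GROUP ATOMS={_serials(wox)}")

    cv_labels: dict[str, list[tuple[str, float]]] = {}
    counter = 0
    for cv in cvs:
        labels: list[tuple[str, float]] = []
        for f, coeff in zip(cv.features, cv.coefficients):
            lab = f"f{counter}"
            counter += 1
            if isinstance(f, HBondFeature):
                _emit_hbond(lines, lab, f, cv, top)
            else:
                _emit_sidechain(lines, lab, f, top)
            labels.append((lab, float(coeff)))
        cv_labels[cv.name] = labels

    for cv in cvs:
        labels = cv_labels[cv.name]
        args = ",".join(l for l, _c in labels)
        coeffs = ",".join(f"{c:g}" for _l, c in labels)
        lines.append(f"{cv.name}: COMBINE ARG={args} COEFFICIENTS={coeffs} "
                     f"PERIODIC=NO")

    names = ",".join(cv.name for cv in cvs)
    lines.append(f"PRINT ARG={names} STRIDE={stride} FILE={colvar_file}")
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)


def _emit_hbond(lines: list[str], lab: str, f: HBondFeature,
                cv: CVDefinition, top: Topology) -> None:
    if f.donor_h < 0:
        raise ValueError(f"feature {lab}: missing hydrogen index, cannot "
                         "serialise the angular term")
    d, h, a = f.donor_heavy, f.donor_h, f.acceptor
    lines.append(f"# {lab}: {f.kind} H-bond {top.names[d]}{d}-H{h}..."
                 f"{top.names[a]}{a}")
    lines.append(f"{lab}_d: DISTANCE ATOMS={d + 1},{a + 1}")
    lines.append(f"{lab}_t: ANGLE ATOMS={d + 1},{h + 1},{a + 1}")
    ang = f"((1+cos(y))/2)"
    xa = f"({ang}/{f.angular_params.r0:.9g})"
    func = (f"{_sw_expr('x', f.distance_params)}*"
            f"((1-{xa}^{f.angular_params.n})/(1-{xa}^{f.angular_params.m}))")
    args = [f"{lab}_d", f"{lab}_t"]
    terms = ""
    varnames = "xyzwvuts"
    nvar = 2
    use_w = f.kind == "native" and cv.lambda_w != 0.0
    use_p = (f.kind == "native" and cv.lambda_p != 0.0
             and len(f.competing_acceptors) > 0)
    if use_w:
        sw = _sw_keyword(f.water_params)
        lines.append(f"{lab}_wd: COORDINATION GROUPA={d + 1} GROUPB=wox "
                     f"SWITCH={{{sw}}}")
        lines.append(f"{lab}_wa: COORDINATION GROUPA={a + 1} GROUPB=wox "
                     f"SWITCH={{{sw}}}")
        args += [f"{lab}_wd", f"{lab}_wa"]
        terms += (f"-{cv.lambda_w:.6g}*({varnames[nvar]}+"
                  f"{varnames[nvar + 1]})")
        nvar += 2
    if use_p:
        sw = _sw_keyword(f.distance_params)
        lines.append(f"{lab}_p: COORDINATION GROUPA={d + 1} "
                     f"GROUPB={_serials(f.competing_acceptors)} "
                     f"SWITCH={{{sw}}}")
        args.append(f"{lab}_p")
        terms += f"-{cv.lambda_p:.6g}*{varnames[nvar]}"
        nvar += 1
    # PLUMED only defaults to x,y,z for ≤3 arguments; declare VAR explicitly
    var = f"VAR={','.join(varnames[:nvar])} " if nvar > 3 else ""
    lines.append(f"{lab}: CUSTOM ARG={','.join(args)} {var}FUNC={func}{terms} "
                 f"PERIODIC=NO")


def _emit_sidechain(lines: list[str], lab: str, f: SideChainFeature,
                    top: Topology) -> None:
    ai = sidechain_atoms(top, f.residue_i)
    aj = sidechain_atoms(top, f.residue_j)
    lines.append(f"# {lab}: {f.kind} side-chain contact "
                 f"res{f.residue_i}-res{f.residue_j}")
    lines.append(f"{lab}_ci: COM ATOMS={_serials(ai)}")
    lines.append(f"{lab}_cj: COM ATOMS={_serials(aj)}")
    lines.append(f"{lab}_d: DISTANCE ATOMS={lab}_ci,{lab}_cj")
    lines.append(f"{lab}: CUSTOM ARG={lab}_d FUNC={_sw_expr('x', f.params)} "
                 f"PERIODIC=NO")
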