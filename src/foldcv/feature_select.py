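"""Harvest candidate contacts from end-state trajectories and filter them.

The workflow needs only two short unbiased trajectories — one resident in the
folded basin, one in the unfolded basin. Every candidate hydrogen bond and
side-chain contact is evaluated on both; a candidate whose occupancy (fraction
of frames with switch value above 0.5) clears the folded threshold becomes a
native candidate, one that is occupied in the unfolded basin but essentially
absent from the folded one becomes a non-native candidate. Candidates are then
scored with a per-feature Fisher discriminant ratio — a one-dimensional
LDA-style criterion — and the discriminative ones are retained.

Occupancy is defined on the switch value rather than a raw distance cutoff so
that harvesting and CV evaluation share a single geometric definition of
"contact".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hbond import (DEFAULT_ANGULAR_SWITCH, DEFAULT_HB_SWITCH,
                    DEFAULT_WATER_SWITCH, HBondFeature, SwitchParams,
                    bare_switch_value, identify_donors_acceptors)
from .sidechain import (DEFAULT_SC_SWITCH, SideChainFeature,
                        evaluate_sc_feature_many)
from .trajectory_io import Topology, Trajectory, minimum_image

__all__ = [
    "HarvestConfig",
    "CandidateTable",
    "FeatureSet",
    "NoDiscriminativeFeaturesError",
    "harvest_contacts",
    "fisher_score",
    "filter_features",
]

FISHER_EPS = 1e-6  # variance regulariser in the discriminant ratio


class NoDiscriminativeFeaturesError(RuntimeError):
    """Every candidate was filtered out; the end states may be too similar."""


@dataclass(frozen=True)
class HarvestConfig:
    """Thresholds and switch parameters of the harvesting stage.

    Occupancy thresholds: a native candidate needs folded occupancy ≥
    ``theta_folded``; a non-native candidate needs unfolded occupancy ≥
    ``theta_unfolded`` and folded occupancy ≤ ``nonnative_folded_max``.
    Competing protein acceptors are those within ``competitor_distance`` of a
    donor in at least ``competitor_fraction`` of unfolded frames, capped at
    ``competitor_cap`` per feature.
    """

    theta_folded: float = 0.6
    theta_unfolded: float = 0.25
    nonnative_folded_max: float = 0.1
    contact_value: float = 0.5           # switch value defining "in contact"
    min_separation: int = 2              # residues, for both HB and SC pairs
    stride: int = 1                      # frame stride over the input runs
    hb_switch: SwitchParams = DEFAULT_HB_SWITCH
    angular_switch: SwitchParams = DEFAULT_ANGULAR_SWITCH
    water_switch: SwitchParams = DEFAULT_WATER_SWITCH
    sc_switch: SwitchParams = DEFAULT_SC_SWITCH
    competitor_distance: float = 6.0     # Å
    competitor_fraction: float = 0.05
    competitor_cap: int = 4
    lambda_w: float = 1.0                # protein–water competition weight
    lambda_p: float = 1.0                # protein–protein competition weight

    def to_dict(self) -> dict:
        return json.loads(json.dumps(asdict(self)))


@dataclass
class CandidateTable:
    """Classified candidate contacts with per-basin occupancies and moments.

    ``table`` columns: identity, kind (HB|SC), classification
    (native|non-native), index columns, occ_folded, occ_unfolded, and the
    per-basin mean/variance of the raw switch value. ``competitors`` maps a
    donor heavy-atom index to the protein acceptors eligible as competing
    acceptors for native HB features (unfolded-basin proximity rule).
    """

    table: pd.DataFrame
    competitors: dict[int, tuple[int, ...]]
    config: HarvestConfig
    topology: Topology

    def __len__(self) -> int:
        return len(self.table)


def fisher_score(values_folded: np.ndarray, values_unfolded: np.ndarray) -> float:
    """Per-feature Fisher discriminant ratio between the two basins.

    score = (μ_F − μ_U)² / (σ_F² + σ_U² + ε) with ε = 1e-6; symmetric under
    basin exchange and invariant under a common rescaling of the values.
    """
    vf = np.asarray(values_folded, dtype=float)
    vu = np.asarray(values_unfolded, dtype=float)
    if vf.size == 0 or vu.size == 0:
        raise ValueError("both samples must be non-empty")
    return float((vf.mean() - vu.mean()) ** 2
                 / (vf.var() + vu.var() + FISHER_EPS))


def _moment_score(mean_f: float, var_f: float, mean_u: float, var_u: float) -> float:
    return float((mean_f - mean_u) ** 2 / (var_f + var_u + FISHER_EPS))


def _check_shared_topology(folded: Trajectory, unfolded: Trajectory) -> Topology:
    tf, tu = folded.topology, unfolded.topology
    if tf.n_atoms != tu.n_atoms or not np.array_equal(tf.names, tu.names):
        raise ValueError("folded and unfolded trajectories must share a topology")
    return tf


def _hb_candidates(top: Topology, donors, acceptors, min_sep: int):
    for dh, h in donors:
        for a in acceptors:
            if a == dh:
                continue
            if abs(int(top.resindices[dh]) - int(top.resindices[a])) < min_sep:
                continue
            yield dh, h, a


def harvest_contacts(folded: Trajectory, unfolded: Trajectory,
                     config: HarvestConfig = HarvestConfig()) -> CandidateTable:
    """Evaluate every candidate contact on both end-state runs and classify.

    Frames are weighted uniformly within each trajectory (the end-state runs
    are unbiased). Contacts occupied in neither basin are dropped.
    """
    top = _check_shared_topology(folded, unfolded)
    if len(folded) == 0 or len(unfolded) == 0:
        raise ValueError("end-state trajectories must be non-empty")

    cf = folded.coordinate_array()[::config.stride]
    cu = unfolded.coordinate_array()[::config.stride]
    box_f = folded[0].box
    box_u = unfolded[0].box

    donors, acceptors = identify_donors_acceptors(top, folded[0])
    rows = []

    def classify(occ_f: float, occ_u: float) -> str | None:
        if occ_f >= config.theta_folded:
            return "native"
        if occ_u >= config.theta_unfolded and occ_f <= config.nonnative_folded_max:
            return "non-native"
        return None

    for dh, h, a in _hb_candidates(top, donors, acceptors, config.min_separation):
        feat = HBondFeature(dh, h, a, distance_params=config.hb_switch,
                            angular_params=config.angular_switch)
        vf = np.asarray(bare_switch_value(feat, cf, box_f))
        vu = np.asarray(bare_switch_value(feat, cu, box_u))
        occ_f = float(np.mean(vf > config.contact_value))
        occ_u = float(np.mean(vu > config.contact_value))
        cls = classify(occ_f, occ_u)
        if cls is None:
            continue
        rows.append(dict(
            identity=f"HB:{dh}:{h}:{a}", kind="HB", classification=cls,
            donor_heavy=dh, donor_h=h, acceptor=a, res_i=-1, res_j=-1,
            occ_folded=occ_f, occ_unfolded=occ_u,
            mean_folded=float(vf.mean()), var_folded=float(vf.var()),
            mean_unfolded=float(vu.mean()), var_unfolded=float(vu.var())))

    protein_res = sorted(set(int(r) for r in
                             np.unique(top.resindices[top.is_protein])))
    for ii, ri in enumerate(protein_res):
        for rj in protein_res[ii + 1:]:
            if rj - ri < config.min_separation:
                continue
            feat = SideChainFeature(ri, rj, params=config.sc_switch,
                                    min_separation=config.min_separation)
            vf = evaluate_sc_feature_many(feat, cf, box_f, top)
            vu = evaluate_sc_feature_many(feat, cu, box_u, top)
            occ_f = float(np.mean(vf > config.contact_value))
            occ_u = float(np.mean(vu > config.contact_value))
            cls = classify(occ_f, occ_u)
            if cls is None:
                continue
            rows.append(dict(
                identity=f"SC:{ri}:{rj}", kind="SC", classification=cls,
                donor_heavy=-1, donor_h=-1, acceptor=-1, res_i=ri, res_j=rj,
                occ_folded=occ_f, occ_unfolded=occ_u,
                mean_folded=float(vf.mean()), var_folded=float(vf.var()),
                mean_unfolded=float(vu.mean()), var_unfolded=float(vu.var())))

    table = pd.DataFrame(rows, columns=[
        "identity", "kind", "classification", "donor_heavy", "donor_h",
        "acceptor", "res_i", "res_j", "occ_folded", "occ_unfolded",
        "mean_folded", "var_folded", "mean_unfolded", "var_unfolded"])

    # competing protein acceptors per donor, from unfolded-basin proximity
    competitors: dict[int, tuple[int, ...]] = {}
    for dh, _h in donors:
        near = []
        for a in acceptors:
            if a == dh:
                continue
            if abs(int(top.resindices[dh]) - int(top.resindices[a])) < config.min_separation:
                continue
            d = np.linalg.norm(
                minimum_image(cu[:, a, :] - cu[:, dh, :], box_u), axis=-1)
            frac = float(np.mean(d < config.competitor_distance))
            if frac >= config.competitor_fraction:
                near.append((frac, a))
        near.sort(key=lambda t: (-t[0], t[1]))
        competitors[dh] = tuple(a for _f, a in near[:config.competitor_cap])

    return CandidateTable(table=table, competitors=competitors,
                          config=config, topology=top)


# ---------------------------------------------------------------------------
# filtering into a FeatureSet
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Retained, scored features plus the provenance needed to rebuild them."""

    hb_features: list[HBondFeature]
    sc_features: list[SideChainFeature]
    scores: dict[str, float]
    provenance: dict

    @property
    def native_hb(self) -> list[HBondFeature]:
        return [f for f in self.hb_features if f.kind == "native"]

    @property
    def nonnative_hb(self) -> list[HBondFeature]:
        return [f for f in self.hb_features if f.kind == "non-native"]

    @property
    def native_sc(self) -> list[SideChainFeature]:
        return [f for f in self.sc_features if f.kind == "native"]

    @property
    def nonnative_sc(self) -> list[SideChainFeature]:
        return [f for f in self.sc_features if f.kind == "non-native"]

    # -- manifest -----------------------------------------------------------
    def to_manifest(self) -> str:
        """Deterministic JSON manifest (the unit of provenance)."""
        def switch(p: SwitchParams) -> dict:
            return {"r0": p.r0, "n": p.n, "m": p.m, "d0": p.d0}

        doc = {
            "hb_features": [{
                "donor_heavy": f.donor_heavy, "donor_h": f.donor_h,
                "acceptor": f.acceptor, "kind": f.kind, "origin": f.origin,
                "distance": switch(f.distance_params),
                "angular": switch(f.angular_params),
                "water": switch(f.water_params),
                "competing_acceptors": list(f.competing_acceptors),
            } for f in self.hb_features],
            "sc_features": [{
                "residue_i": f.residue_i, "residue_j": f.residue_j,
                "kind": f.kind, "origin": f.origin,
                "switch": switch(f.params),
                "min_separation": f.min_separation,
            } for f in self.sc_features],
            "scores": {k: self.scores[k] for k in sorted(self.scores)},
            "provenance": {k: self.provenance[k] for k in sorted(self.provenance)},
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_manifest() + "\n")

    @classmethod
    def from_manifest(cls, text: str) -> "FeatureSet":
        doc = json.loads(text)

        def switch(d: dict) -> SwitchParams:
            return SwitchParams(r0=d["r0"], n=d["n"], m=d["m"], d0=d["d0"])

        hb = [HBondFeature(
            donor_heavy=d["donor_heavy"], donor_h=d["donor_h"],
            acceptor=d["acceptor"], kind=d["kind"], origin=d["origin"],
            distance_params=switch(d["distance"]),
            angular_params=switch(d["angular"]),
            water_params=switch(d["water"]),
            competing_acceptors=tuple(d["competing_acceptors"]))
            for d in doc["hb_features"]]
        sc = [SideChainFeature(
            residue_i=d["residue_i"], residue_j=d["residue_j"],
            kind=d["kind"], origin=d["origin"], params=switch(d["switch"]),
            min_separation=d["min_separation"])
            for d in doc["sc_features"]]
        return cls(hb_features=hb, sc_features=sc, scores=doc["scores"],
                   provenance=doc["provenance"])

    @classmethod
    def load(cls, path) -> "FeatureSet":
        with open(path) as fh:
            return cls.from_manifest(fh.read())

    def provenance_hash(self) -> str:
        return hashlib.sha256(self.to_manifest().encode()).hexdigest()[:16]


def filter_features(candidates: CandidateTable, score_threshold: float = 1.0,
                    max_features: int | None = None,
                    provenance: dict | None = None) -> FeatureSet:
    """Rank candidates by Fisher score and keep the discriminative ones.

    Ranking is by score descending with a deterministic lexicographic
    tie-break on the contact identity; ``max_features`` (if given) caps the
    retained list after thresholding.
    """
    df = candidates.table
    if len(df) == 0:
        raise NoDiscriminativeFeaturesError(
            "candidate table is empty — no contact is occupied in either basin")

    scored = df.assign(score=[
        _moment_score(r.mean_folded, r.var_folded, r.mean_unfolded, r.var_unfolded)
        for r in df.itertuples()])
    keep = scored[scored.score >= score_threshold]
    keep = keep.sort_values(["score", "identity"],
                            ascending=[False, True], kind="mergesort")
    if max_features is not None:
        keep = keep.head(max_features)
    if len(keep) == 0:
        raise NoDiscriminativeFeaturesError(
            f"no feature reached the score threshold {score_threshold}; "
            "the end-state runs may not be distinguishable")

    cfg = candidates.config
    hb, sc, scores = [], [], {}
    for r in keep.itertuples():
        scores[r.identity] = float(r.score)
        if r.kind == "HB":
            native = r.classification == "native"
            comp = candidates.competitors.get(int(r.donor_heavy), ())
            comp = tuple(a for a in comp if a != int(r.acceptor))
            hb.append(HBondFeature(
                donor_heavy=int(r.donor_heavy), donor_h=int(r.donor_h),
                acceptor=int(r.acceptor),
                distance_params=cfg.hb_switch, angular_params=cfg.angular_switch,
                water_params=cfg.water_switch,
                competing_acceptors=comp if native else (),
                kind="native" if native else "non-native",
                origin="folded" if native else "unfolded"))
        else:
            native = r.classification == "native"
            sc.append(SideChainFeature(
                residue_i=int(r.res_i), residue_j=int(r.res_j),
                params=cfg.sc_switch, min_separation=cfg.min_separation,
                kind="native" if native else "non-native",
                origin="folded" if native else "unfolded"))

    prov = dict(provenance or {})
    prov.setdefault("score_threshold", score_threshold)
    prov.setdefault("max_features", max_features)
    prov.setdefault("config", cfg.to_dict())
    return FeatureSet(hb_features=hb, sc_features=sc, scores=scores,
                      provenance=prov)
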