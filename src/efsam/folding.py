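"""Conformational clustering and rule-based folded-state calls.

The folded/unfolded call for each subdomain operationalises the criteria
used to dissect the unfolding profiles of the full-length construct:

* hEF folded  <=>  alpha3 and alpha4 keep their helical structure, and the
  probe Phe108 is buried in between alpha3, alpha4 and alpha10 (whole-residue
  SASA at or below the buried threshold, plus at least one heavy-atom contact
  with an alpha10 anchor leucine);
* cEF folded  <=>  alpha1 and alpha2 keep their helical structure, the Ca2+
  binding loop is not expanded (d1 within a margin of the reference), and
  alpha10 is anchored in between alpha1 and alpha2 (some anchor residue
  contacts both);
* SAM folded  <=>  its helical content alone is maintained.

"Maintains helical structure" is quantified as a DSSP helical fraction of at
least 0.7 of the segment. Clustering is Daura leader-style neighbour-count
clustering under a C-alpha RMSD cutoff; each cluster is represented by its
medoid ("median conformation"), whose verdict is attributed to all members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensembles import (
    EmptyInputError,
    Ensemble,
    EnsembleError,
    SubdomainMap,
    default_subdomain_map,
    select,
)
from .geometry import kabsch, distance_d1
from .surface import assign_ss, helical_fraction, residue_sasa

__all__ = [
    "ClusterSet",
    "StateCriteria",
    "StateLabel",
    "FoldedFractionRecord",
    "cluster_ensemble",
    "pairwise_rmsd_matrix",
    "classify_state",
    "folded_fraction",
]


@dataclass
class ClusterSet:
    """Partition of the models into leader clusters with medoid indices."""

    members: list          # list of np.ndarray of model indices
    medoids: list          # one model index per cluster
    cutoff_nm: float
    selection: str

    @property
    def n_clusters(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class StateCriteria:
    """Thresholds of the folded-state rules (all configurable).

    ``helical_threshold``: fraction of a helix segment that must be assigned
    H for the segment to "maintain helical structure". ``probe_buried_max_sasa``
    reuses the buried exposure threshold (nm^2). ``anchor_contact_cutoff`` is
    the minimum heavy-atom contact distance (A). ``loop_expansion_max_excess``
    is how far d1 may exceed the reference before the binding loop counts as
    expanded (A); expansions of order 12 A are what distinguish states, so
    4 A separates them with margin.
    """

    helical_threshold: float = 0.7
    probe_buried_max_sasa: float = 0.25
    anchor_contact_cutoff: float = 4.5
    loop_expansion_max_excess: float = 4.0

    def __post_init__(self):
        for f in (
            self.helical_threshold,
            self.probe_buried_max_sasa,
            self.anchor_contact_cutoff,
            self.loop_expansion_max_excess,
        ):
            if f <= 0:
                raise ValueError("all criteria thresholds must be positive")


@dataclass
class StateLabel:
    """Per-subdomain folded flags with the individual sub-verdicts."""

    folded: dict                     # {"cEF": bool, "hEF": bool, "SAM": bool}
    sub_verdicts: dict               # nested {subdomain: {criterion: bool}}


@dataclass
class FoldedFractionRecord:
    """Fraction of folded conformations per subdomain for one ensemble."""

    fraction: dict
    n_models: int
    via_clusters: bool
    replica: int | None = None
    effective_temperature: float | None = None


# --------------------------------------------------------------------------
# Clustering
# --------------------------------------------------------------------------

def pairwise_rmsd_matrix(
    ensemble: Ensemble,
    selection: str = "name CA",
    subdomain_map: SubdomainMap | None = None,
) -> np.ndarray:
    """All-pairs C-alpha RMSD (nm) after pairwise Kabsch superposition."""
    smap = subdomain_map or default_subdomain_map()
    idx = select(ensemble, selection, smap)
    if idx.size < 3:
        raise EnsembleError("pairwise RMSD needs at least 3 selected atoms")
    coords = ensemble.coords[:, idx, :]
    n = ensemble.n_models
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tf = kabsch(coords[j], coords[i])
            d = tf.apply(coords[j]) - coords[i]
            mat[i, j] = mat[j, i] = np.sqrt(np.mean(np.sum(d**2, axis=1))) / 10.0
    return mat


def cluster_ensemble(
    ensemble: Ensemble,
    selection: str = "name CA",
    cutoff: float = 0.2,
    subdomain_map: SubdomainMap | None = None,
) -> ClusterSet:
    """Daura leader clustering under an RMSD cutoff (nm).

    Iteratively the model with the most neighbours within the cutoff becomes
    a cluster centre and is removed together with its neighbours (ties break
    to the lowest model index). The reported representative of each cluster
    is its medoid: the member minimising summed RMSD to the other members.
    """
    if ensemble.n_models < 1:
        raise EmptyInputError("cannot cluster an empty ensemble")
    mat = pairwise_rmsd_matrix(ensemble, selection, subdomain_map)
    n = ensemble.n_models
    remaining = np.ones(n, dtype=bool)
    members, medoids = [], []
    neigh = mat <= cutoff
    while remaining.any():
        counts = (neigh & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        group = np.nonzero(neigh[center] & remaining)[0]
        sub = mat[np.ix_(group, group)]
        medoid = int(group[np.argmin(sub.sum(axis=1))])
        members.append(group)
        medoids.append(medoid)
        remaining[group] = False
    return ClusterSet(
        members=members, medoids=medoids, cutoff_nm=cutoff, selection=selection
    )


# --------------------------------------------------------------------------
# Folded-state classification
# --------------------------------------------------------------------------

def _segment_fraction(ss, smap: SubdomainMap, segment: str) -> float:
    residues = smap.residues(segment)
    present = np.isin(ss.residue_numbers, residues)
    if not present.any():
        raise EnsembleError(f"no residues of segment {segment} in the model")
    return helical_fraction(ss, ss.residue_numbers[present])


def _residue_heavy_coords(ensemble: Ensemble, model: int, residues) -> np.ndarray:
    mask = np.isin(ensemble.residue_numbers, np.asarray(residues, dtype=int)) & (
        ensemble.elements != "H"
    )
    return ensemble.coords[model, np.nonzero(mask)[0]]


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(
        np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2))
    )


def _probe_sasa(ensemble: Ensemble, model: int, probe: int) -> float:
    """Whole-residue SASA (nm^2) of the probe, occluded by the full model."""
    return residue_sasa(ensemble, probe, model)


def classify_state(
    ensemble: Ensemble,
    model: int = 0,
    subdomain_map: SubdomainMap | None = None,
    reference: Ensemble | None = None,
    reference_model: int = 0,
    criteria: StateCriteria | None = None,
    d1_ref: float | None = None,
) -> StateLabel:
    """Folded/unfolded call for cEF, hEF and SAM on one model.

    ``reference`` (or a precomputed ``d1_ref`` in Angstrom) provides the d1
    baseline for the binding-loop expansion rule. Each subdomain's folded
    flag is the conjunction of its sub-verdicts.
    """
    smap = subdomain_map or default_subdomain_map()
    criteria = criteria or StateCriteria()
    if d1_ref is None:
        if reference is None:
            raise EnsembleError("classify_state needs a reference model or d1_ref")
        d1_ref = float(distance_d1(reference).values[reference_model])

    ss = assign_ss(ensemble, model)
    probe = int(smap.named_residues["probe"])
    anchors = [int(a) for a in smap.named_residues["anchors"]]
    cut = criteria.anchor_contact_cutoff

    # --- hEF ------------------------------------------------------------
    h_a3 = _segment_fraction(ss, smap, "alpha3") >= criteria.helical_threshold
    h_a4 = _segment_fraction(ss, smap, "alpha4") >= criteria.helical_threshold
    probe_area = _probe_sasa(ensemble, model, probe)
    h_buried = probe_area <= criteria.probe_buried_max_sasa
    probe_xyz = _residue_heavy_coords(ensemble, model, [probe])
    anchor_xyz = _residue_heavy_coords(ensemble, model, anchors)
    h_anchor = _min_dist(probe_xyz, anchor_xyz) <= cut
    hef = {
        "alpha3_helical": h_a3,
        "alpha4_helical": h_a4,
        "probe_buried": h_buried,
        "probe_anchor_contact": h_anchor,
    }

    # --- cEF ------------------------------------------------------------
    c_a1 = _segment_fraction(ss, smap, "alpha1") >= criteria.helical_threshold
    c_a2 = _segment_fraction(ss, smap, "alpha2") >= criteria.helical_threshold
    d1 = float(distance_d1(ensemble).values[model])
    c_loop = d1 <= d1_ref + criteria.loop_expansion_max_excess
    a1_xyz = _residue_heavy_coords(ensemble, model, smap.residues("alpha1"))
    a2_xyz = _residue_heavy_coords(ensemble, model, smap.residues("alpha2"))
    c_anchor = False
    for a in anchors:
        axyz = _residue_heavy_coords(ensemble, model, [a])
        if axyz.size == 0:
            raise EnsembleError(f"anchor residue {a} missing from the model")
        if _min_dist(axyz, a1_xyz) <= cut and _min_dist(axyz, a2_xyz) <= cut:
            c_anchor = True
            break
    cef = {
        "alpha1_helical": c_a1,
        "alpha2_helical": c_a2,
        "loop_not_expanded": c_loop,
        "alpha10_anchored": c_anchor,
    }

    # --- SAM ------------------------------------------------------------
    sam = {"sam_helical": _segment_fraction(ss, smap, "SAM") >= criteria.helical_threshold}

    return StateLabel(
        folded={
            "cEF": all(cef.values()),
            "hEF": all(hef.values()),
            "SAM": all(sam.values()),
        },
        sub_verdicts={"cEF": cef, "hEF": hef, "SAM": sam},
    )


def folded_fraction(
    ensemble: Ensemble,
    subdomain_map: SubdomainMap | None = None,
    reference: Ensemble | None = None,
    criteria: StateCriteria | None = None,
    via_clusters: bool = False,
    cluster_cutoff: float = 0.2,
    d1_ref: float | None = None,
    replica: int | None = None,
    effective_temperature: float | None = None,
) -> FoldedFractionRecord:
    """Fraction of folded conformations per subdomain.

    With ``via_clusters`` the ensemble is leader-clustered first, only each
    cluster medoid is classified, and its verdict counts for every member
    (cluster sizes weight the percentages); otherwise every model is
    classified directly.
    """
    if ensemble.n_models < 1:
        raise EmptyInputError("empty ensemble")
    counts = {"cEF": 0, "hEF": 0, "SAM": 0}
    if via_clusters:
        clusters = cluster_ensemble(ensemble, cutoff=cluster_cutoff,
                                    subdomain_map=subdomain_map)
        for group, medoid in zip(clusters.members, clusters.medoids):
            label = classify_state(
                ensemble, medoid, subdomain_map, reference,
                criteria=criteria, d1_ref=d1_ref,
            )
            for k in counts:
                counts[k] += int(label.folded[k]) * group.size
    else:
        for m in range(ensemble.n_models):
            label = classify_state(
                ensemble, m, subdomain_map, reference,
                criteria=criteria, d1_ref=d1_ref,
            )
            for k in counts:
                counts[k] += int(label.folded[k])
    total = ensemble.n_models
    return FoldedFractionRecord(
        fraction={k: v / total for k, v in counts.items()},
        n_models=total,
        via_clusters=via_clusters,
        replica=replica,
        effective_temperature=effective_temperature,
    )
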