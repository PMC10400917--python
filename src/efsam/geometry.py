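"""Rigid-body superposition and geometric order parameters.

Implements the order parameters used to follow EF-SAM destabilisation:
RMSD to a reference after Kabsch superposition (global or local fit),
per-residue RMSF, mass-weighted radius of gyration, the binding-loop
expansion distances d1 (Asp76 CA - Glu87 CA) and d2 (Asn80 CA - Glu87 CD),
and minimum heavy-atom inter-residue contact maps.

RMSD/RMSF are unweighted over the selected atoms (C-alpha practice); the
radius of gyration is mass-weighted. Internal unit is Angstrom; RMSD, RMSF
and Rg report nm, pair distances report Angstrom.
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

__all__ = [
    "RigidTransform",
    "MetricSeries",
    "ResidueProfile",
    "ContactMatrix",
    "DegenerateFitError",
    "superpose",
    "kabsch",
    "rmsd_series",
    "rmsf_profile",
    "gyration_radius",
    "pair_distance",
    "distance_d1",
    "distance_d2",
    "contact_map",
    "hydrophobic_contacts",
    "ATOMIC_MASSES",
]

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "Ca": 40.078,
    "K": 39.098,
    "Cl": 35.45,
}


class DegenerateFitError(EnsembleError):
    """Superposition is ill-posed (fewer than 3 atoms, or collinear)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, y = R @ x + t (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-8:
            raise ValueError(f"rotation must be proper (det=+1), got det={det}")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class MetricSeries:
    """Per-model scalar series with measurement metadata."""

    values: np.ndarray
    metric_name: str
    selection: str
    units: str
    reference: str = ""
    fit_mode: str = ""


@dataclass
class ResidueProfile:
    """Per-residue scalar profile (e.g. RMSF)."""

    residue_numbers: np.ndarray
    values: np.ndarray
    metric_name: str
    units: str
    fit_mode: str


@dataclass
class ContactMatrix:
    """Symmetric matrix of minimum inter-residue heavy-atom distances, Angstrom."""

    residue_numbers: np.ndarray
    distances: np.ndarray


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal rigid transform mapping ``mobile`` onto ``reference`` (Kabsch/SVD).

    Both arrays are (n, 3); n >= 3 non-collinear points are required.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise EnsembleError("mobile and reference must have equal atom counts")
    if mobile.shape[0] < 3:
        raise DegenerateFitError("superposition requires at least 3 fit atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    if np.linalg.matrix_rank(x, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    return RigidTransform(rotation=rot, translation=trans)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[RigidTransform, np.ndarray]:
    """Superpose ``mobile`` onto ``reference`` using ``fit_indices``.

    Returns the transform (fitted on the given indices) and the whole mobile
    coordinate set with the transform applied.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    tf = kabsch(mobile[fit_indices], reference[fit_indices])
    return tf, tf.apply(mobile)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# --------------------------------------------------------------------------
# RMSD / RMSF / Rg
# --------------------------------------------------------------------------

def _resolve_selection(
    ensemble: Ensemble, sel: str | np.ndarray | None, default: str, smap: SubdomainMap
) -> tuple[np.ndarray, str]:
    if sel is None:
        sel = default
    if isinstance(sel, str):
        idx = select(ensemble, sel, smap)
        label = sel
    else:
        idx = np.asarray(sel, dtype=int)
        label = f"<{idx.size} indices>"
    if idx.size == 0:
        raise EmptyInputError(f"selection {label!r} matched no atoms")
    return idx, label


def rmsd_series(
    ensemble: Ensemble,
    reference_model: int = 0,
    fit_sel: str | np.ndarray | None = None,
    measure_sel: str | np.ndarray | None = None,
    subdomain_map: SubdomainMap | None = None,
    reference_coords: np.ndarray | None = None,
) -> MetricSeries:
    """Per-model RMSD (nm) to a reference after superposition on ``fit_sel``.

    Defaults fit and measure over the C-alpha atoms of the global fit range
    (Ser64-Leu199). ``reference_coords`` overrides ``reference_model`` when a
    reference outside the ensemble (e.g. the starting structure) is wanted.
    """
    smap = subdomain_map or default_subdomain_map()
    fit_idx, fit_label = _resolve_selection(
        ensemble, fit_sel, "segment fit_global and name CA", smap
    )
    if measure_sel is None:
        meas_idx, meas_label = fit_idx, fit_label
    else:
        meas_idx, meas_label = _resolve_selection(ensemble, measure_sel, "", smap)
    ref = (
        np.asarray(reference_coords, dtype=float)
        if reference_coords is not None
        else ensemble.coords[reference_model]
    )
    values = np.empty(ensemble.n_models)
    for m in range(ensemble.n_models):
        _, fitted = superpose(ensemble.coords[m], ref, fit_idx)
        values[m] = _rmsd(fitted[meas_idx], ref[meas_idx]) / 10.0  # A -> nm
    return MetricSeries(
        values=values,
        metric_name="rmsd",
        selection=meas_label,
        units="nm",
        reference=f"model {reference_model}" if reference_coords is None else "external",
        fit_mode=f"fit:{fit_label}",
    )


def rmsf_profile(
    ensemble: Ensemble,
    measure_sel: str | np.ndarray | None = None,
    fit_mode: str = "global",
    subdomain_map: SubdomainMap | None = None,
    units: str = "nm",
) -> ResidueProfile:
    """Per-residue RMSF after superposition.

    ``fit_mode`` is ``"global"`` (fit on C-alpha of the global fit range) or
    ``"local:SEGMENT"`` (fit on C-alpha of that segment only), mirroring the
    separate local fitting used to expose hinge-like flexibility. Each atom's
    RMSF is computed about its time-average position after fitting; residue
    values average the atoms within the residue.
    """
    if ensemble.n_models < 2:
        raise EnsembleError("RMSF is undefined for a single model")
    smap = subdomain_map or default_subdomain_map()
    if fit_mode == "global":
        fit_expr = "segment fit_global and name CA"
    elif fit_mode.startswith("local:"):
        fit_expr = f"segment {fit_mode.split(':', 1)[1]} and name CA"
    else:
        raise ValueError(f"fit_mode must be 'global' or 'local:SEGMENT', got {fit_mode!r}")
    fit_idx, _ = _resolve_selection(ensemble, fit_expr, "", smap)
    meas_idx, _ = _resolve_selection(
        ensemble, measure_sel, "segment fit_global and name CA", smap
    )
    ref = ensemble.coords[0]
    fitted = np.empty((ensemble.n_models, ensemble.n_atoms, 3))
    for m in range(ensemble.n_models):
        _, fitted[m] = superpose(ensemble.coords[m], ref, fit_idx)
    mean = fitted.mean(axis=0)
    # per-atom RMSF about the time-average position
    atom_rmsf = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    resnums = ensemble.residue_numbers[meas_idx]
    uniq = np.unique(resnums)
    values = np.array([atom_rmsf[meas_idx][resnums == r].mean() for r in uniq])
    if units == "nm":
        values = values / 10.0
    elif units != "A":
        raise ValueError("units must be 'nm' or 'A'")
    return ResidueProfile(
        residue_numbers=uniq,
        values=values,
        metric_name="rmsf",
        units=units,
        fit_mode=fit_mode,
    )


def gyration_radius(
    ensemble: Ensemble,
    selection: str | np.ndarray = "segment binding_loop",
    subdomain_map: SubdomainMap | None = None,
) -> MetricSeries:
    """Mass-weighted radius of gyration (nm) per model over a selection."""
    smap = subdomain_map or default_subdomain_map()
    idx, label = _resolve_selection(ensemble, selection, "", smap)
    elements = ensemble.elements[idx]
    try:
        masses = np.array([ATOMIC_MASSES[e] for e in elements])
    except KeyError as exc:
        raise EnsembleError(f"unknown element for mass lookup: {exc}") from exc
    total = masses.sum()
    values = np.empty(ensemble.n_models)
    for m in range(ensemble.n_models):
        xyz = ensemble.coords[m, idx]
        com = (masses[:, None] * xyz).sum(axis=0) / total
        values[m] = np.sqrt((masses * np.sum((xyz - com) ** 2, axis=1)).sum() / total)
    return MetricSeries(
        values=values / 10.0,
        metric_name="rg",
        selection=label,
        units="nm",
    )


# --------------------------------------------------------------------------
# Pair distances (d1 / d2 presets)
# --------------------------------------------------------------------------

AtomSpec = tuple[int, str]  # (author residue number, atom name)

D1_SPEC: tuple[AtomSpec, AtomSpec] = ((76, "CA"), (87, "CA"))   # Asp76 CA - Glu87 CA
D2_SPEC: tuple[AtomSpec, AtomSpec] = ((80, "CA"), (87, "CD"))   # Asn80 CA - Glu87 CD


def pair_distance(
    ensemble: Ensemble, atom_a: AtomSpec, atom_b: AtomSpec
) -> MetricSeries:
    """Euclidean distance (Angstrom) between two named atoms, per model."""
    try:
        ia = ensemble.find_atom(*atom_a)
        ib = ensemble.find_atom(*atom_b)
    except EnsembleError as exc:
        raise EnsembleError(f"pair_distance{atom_a, atom_b}: {exc}") from exc
    values = np.linalg.norm(
        ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :], axis=1
    )
    return MetricSeries(
        values=values,
        metric_name="distance",
        selection=f"{atom_a[0]}:{atom_a[1]}-{atom_b[0]}:{atom_b[1]}",
        units="A",
    )


def distance_d1(ensemble: Ensemble) -> MetricSeries:
    """Binding-loop expansion distance d1: Asp76 CA to Glu87 CA (Angstrom)."""
    s = pair_distance(ensemble, *D1_SPEC)
    s.metric_name = "d1"
    return s


def distance_d2(ensemble: Ensemble) -> MetricSeries:
    """Glu87 side-chain orientation distance d2: Asn80 CA to Glu87 CD (Angstrom)."""
    s = pair_distance(ensemble, *D2_SPEC)
    s.metric_name = "d2"
    return s


# --------------------------------------------------------------------------
# Contact maps
# --------------------------------------------------------------------------

def contact_map(
    ensemble: Ensemble,
    model: int = 0,
    selection: str | np.ndarray | None = None,
    subdomain_map: SubdomainMap | None = None,
) -> ContactMatrix:
    """Minimum heavy-atom distance between every residue pair of a selection.

    Symmetric with a zero diagonal; hydrogens are excluded.
    """
    smap = subdomain_map or default_subdomain_map()
    idx, _ = _resolve_selection(ensemble, selection, "resnum -5 to 201", smap)
    heavy = idx[ensemble.elements[idx] != "H"]
    if heavy.size == 0:
        raise EmptyInputError("selection contains no heavy atoms")
    resnums = ensemble.residue_numbers[heavy]
    uniq = np.unique(resnums)
    if uniq.size < 2:
        raise EnsembleError("contact map requires at least 2 residues")
    xyz = ensemble.coords[model, heavy]
    groups = [xyz[resnums == r] for r in uniq]
    n = uniq.size
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(groups[i][:, None, :] - groups[j][None, :, :], axis=2)
            mat[i, j] = mat[j, i] = d.min()
    return ContactMatrix(residue_numbers=uniq, distances=mat)


def hydrophobic_contacts(
    ensemble: Ensemble,
    residues: "list[int] | np.ndarray",
    cutoff: float = 4.5,
    model: int = 0,
) -> list[tuple[int, int, float]]:
    """Residue pairs whose minimum heavy-atom distance is within ``cutoff`` (A).

    Returns ``(res_i, res_j, min_distance)`` with res_i < res_j, excluding
    sequence neighbours (|i-j| <= 1), sorted by residue pair.
    """
    residues = np.asarray(sorted(set(int(r) for r in residues)))
    mask = np.isin(ensemble.residue_numbers, residues)
    idx = np.nonzero(mask)[0]
    cm = contact_map(ensemble, model=model, selection=idx)
    out = []
    for i, ri in enumerate(cm.residue_numbers):
        for j in range(i + 1, cm.residue_numbers.size):
            rj = cm.residue_numbers[j]
            if rj - ri <= 1:
                continue
            if cm.distances[i, j] <= cutoff:
                out.append((int(ri), int(rj), float(cm.distances[i, j])))
    return out
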