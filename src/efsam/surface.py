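"""Solvent accessibility, exposure states, secondary structure, Ca2+ geometry.

SASA uses the Shrake-Rupley sphere-point rejection method with a
deterministic golden-section spiral point set (no randomness) and a pinned
Chothia-class van der Waals radius table. Exposure of the probe residue
(Phe108) is classified into three states by its whole-residue SASA:
buried (< 0.25 nm^2), surface adsorbed (0.25-1 nm^2, closed interval),
fully exposed (> 1 nm^2).

Secondary structure follows the DSSP convention: amide hydrogens are
reconstructed geometrically, backbone hydrogen bonds are scored with the
Kabsch-Sander electrostatic energy and accepted below -0.5 kcal/mol, and
alpha-helix (H) is assigned from consecutive i -> i+4 turns. Strand (E) is
detected minimally from isolated bridges and is not used by the folded-state
pipeline, whose reaction coordinate is alpha-helical content only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .ensembles import EmptyInputError, Ensemble, EnsembleError

__all__ = [
    "SASAProfile",
    "ExposureState",
    "SSAssignment",
    "CoordinationReport",
    "VDW_RADII",
    "sasa",
    "residue_sasa",
    "classify_exposure",
    "assign_ss",
    "helical_fraction",
    "ca_site_geometry",
]

# Chothia (1976)-class united-heavy-atom radii, Angstrom.
VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "Ca": 1.97,
}

_CHAIN_BREAK_CN = 2.5  # Angstrom; larger C(i)-N(i+1) distances split segments


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------

def _spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SASAProfile:
    """Per-atom and per-residue accessible area in nm^2."""

    atom_area: np.ndarray          # nm^2 per atom (topology order)
    residue_numbers: np.ndarray
    residue_area: np.ndarray       # nm^2 per residue (sum of its atoms)
    probe_radius: float            # Angstrom
    n_points: int

    def residue(self, residue_number: int) -> float:
        """Whole-residue SASA (nm^2)."""
        hits = np.nonzero(self.residue_numbers == residue_number)[0]
        if hits.size == 0:
            raise EnsembleError(f"residue {residue_number} not in SASA profile")
        return float(self.residue_area[hits[0]])


def _atom_areas(
    xyz: np.ndarray,
    ext: np.ndarray,
    n_points: int,
    subset: np.ndarray,
) -> np.ndarray:
    """Accessible area (A^2) of ``subset`` atoms given all occluders.

    ``ext`` are vdW + probe radii; the sphere-point set is deterministic.
    """
    sphere = _spiral_points(n_points)
    n = xyz.shape[0]
    out = np.zeros(subset.size)
    for k, i in enumerate(subset):
        delta = xyz - xyz[i]
        d2 = np.sum(delta**2, axis=1)
        cut = (ext[i] + ext) ** 2
        nb = np.nonzero((d2 < cut) & (np.arange(n) != i))[0]
        pts = xyz[i] + ext[i] * sphere
        if nb.size:
            dd = np.sum((pts[:, None, :] - xyz[nb][None, :, :]) ** 2, axis=2)
            exposed = np.all(dd >= (ext[nb] ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        out[k] = frac * 4.0 * np.pi * ext[i] ** 2
    return out


def _heavy_geometry(ensemble: Ensemble, model: int, probe_radius: float):
    heavy = np.nonzero(ensemble.elements != "H")[0]
    if heavy.size == 0:
        raise EmptyInputError("no heavy atoms for SASA")
    try:
        radii = np.array([VDW_RADII[e] for e in ensemble.elements[heavy]])
    except KeyError as exc:
        raise EnsembleError(f"no van der Waals radius for element {exc}") from exc
    return heavy, ensemble.coords[model, heavy], radii + probe_radius


def sasa(
    ensemble: Ensemble,
    model: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SASAProfile:
    """Shrake-Rupley solvent-accessible surface area of one model.

    Hydrogens are excluded from both the surface and the occluders. The
    point set is deterministic, so repeated calls are bit-identical.
    """
    heavy, xyz, ext = _heavy_geometry(ensemble, model, probe_radius)
    areas = np.zeros(ensemble.n_atoms)
    areas[heavy] = _atom_areas(xyz, ext, n_points, np.arange(heavy.size))
    areas /= 100.0  # A^2 -> nm^2
    uniq = np.unique(ensemble.residue_numbers)
    res_area = np.array(
        [areas[ensemble.residue_numbers == r].sum() for r in uniq]
    )
    return SASAProfile(
        atom_area=areas,
        residue_numbers=uniq,
        residue_area=res_area,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def residue_sasa(
    ensemble: Ensemble,
    residue_number: int,
    model: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Whole-residue SASA (nm^2) of one residue, occluded by the full model.

    Identical to ``sasa(...).residue(residue_number)`` but only the residue's
    own atoms are surfaced, which is much faster for per-frame probe tracking.
    """
    heavy, xyz, ext = _heavy_geometry(ensemble, model, probe_radius)
    subset = np.nonzero(ensemble.residue_numbers[heavy] == residue_number)[0]
    if subset.size == 0:
        raise EnsembleError(f"residue {residue_number} has no heavy atoms")
    return float(_atom_areas(xyz, ext, n_points, subset).sum() / 100.0)


class ExposureState(str, Enum):
    BURIED = "buried"
    SURFACE_ADSORBED = "surface_adsorbed"
    FULLY_EXPOSED = "fully_exposed"


def classify_exposure(residue_sasa: float) -> ExposureState:
    """Three-state exposure call from whole-residue SASA in nm^2.

    Partition: < 0.25 buried; [0.25, 1.0] surface adsorbed; > 1.0 fully
    exposed (both boundary values belong to the adsorbed state).
    """
    if residue_sasa < 0:
        raise ValueError("SASA must be non-negative")
    if residue_sasa < 0.25:
        return ExposureState.BURIED
    if residue_sasa <= 1.0:
        return ExposureState.SURFACE_ADSORBED
    return ExposureState.FULLY_EXPOSED


# --------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander convention)
# --------------------------------------------------------------------------

@dataclass
class SSAssignment:
    """Per-residue secondary-structure codes in {H, E, C}."""

    residue_numbers: np.ndarray
    codes: np.ndarray  # unicode '<U1'

    def code(self, residue_number: int) -> str:
        hits = np.nonzero(self.residue_numbers == residue_number)[0]
        if hits.size == 0:
            raise EnsembleError(f"residue {residue_number} not in assignment")
        return str(self.codes[hits[0]])


def _backbone_table(ensemble: Ensemble, model: int):
    """Backbone N/CA/C/O coordinates per residue, or None when incomplete."""
    resnums = np.unique(ensemble.residue_numbers)
    table = {}
    xyz = ensemble.coords[model]
    for r in resnums:
        sel = np.nonzero(ensemble.residue_numbers == r)[0]
        names = ensemble.atom_names[sel]
        entry = {}
        for nm in ("N", "CA", "C", "O"):
            hit = sel[names == nm]
            if hit.size:
                entry[nm] = xyz[hit[0]]
        table[int(r)] = entry if len(entry) == 4 else None
    return resnums, table


def assign_ss(ensemble: Ensemble, model: int = 0) -> SSAssignment:
    """DSSP-convention assignment (helix subset plus minimal bridge detection).

    Amide H is placed 1.01 A from N, anti-parallel to the carbonyl C=O of the
    preceding bonded residue; residues without a bonded predecessor donate no
    hydrogen bond. Chains are split wherever C(i)-N(i+1) exceeds 2.5 A.
    """
    resnums, bb = _backbone_table(ensemble, model)
    res = [int(r) for r in resnums if bb[int(r)] is not None]
    n = len(res)
    codes = {int(r): "C" for r in resnums}
    if n >= 2:
        pos = {r: i for i, r in enumerate(res)}
        N = np.array([bb[r]["N"] for r in res])
        CA = np.array([bb[r]["CA"] for r in res])
        C = np.array([bb[r]["C"] for r in res])
        O = np.array([bb[r]["O"] for r in res])
        # bonded predecessor from chain continuity in author numbering
        has_prev = np.zeros(n, dtype=bool)
        for i in range(1, n):
            if res[i] - res[i - 1] == 1 and np.linalg.norm(
                N[i] - C[i - 1]
            ) <= _CHAIN_BREAK_CN:
                has_prev[i] = True
        H = np.full((n, 3), np.nan)
        for i in np.nonzero(has_prev)[0]:
            co = C[i - 1] - O[i - 1]
            H[i] = N[i] + 1.01 * co / np.linalg.norm(co)

        # Kabsch-Sander energy matrix: CO of i accepts NH of j
        def dists(a, b):
            return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)

        with np.errstate(divide="ignore", invalid="ignore"):
            q = 0.084 * 332.0
            e = q * (1.0 / dists(O, N) + 1.0 / dists(C, H)
                     - 1.0 / dists(O, H) - 1.0 / dists(C, N))
        seq = np.array(res)
        invalid = (~has_prev)[None, :] | (np.abs(seq[:, None] - seq[None, :]) < 2)
        hb = np.where(invalid | ~np.isfinite(e), False, e < -0.5)

        # 4-turns require a contiguous i..i+4 stretch and hb(i, i+4)
        turn = {}
        for i, r in enumerate(res):
            j = pos.get(r + 4)
            ok = j is not None and all(
                pos.get(r + k + 1) is not None and has_prev[pos[r + k + 1]]
                for k in range(4)
            )
            turn[r] = bool(ok and hb[i, j])
        # minimal helix i..i+3 requires turns at i-1 and i
        for r in res:
            if turn.get(r - 1) and turn.get(r):
                for k in range(r, r + 4):
                    if k in pos:
                        codes[k] = "H"
        # minimal bridge (strand) detection; H has priority
        def hbr(a, b):
            ia, ib = pos.get(a), pos.get(b)
            return bool(ia is not None and ib is not None and hb[ia, ib])

        for i in res:
            for j in res:
                if j - i < 3 or codes[i] == "H" or codes[j] == "H":
                    continue
                para = (hbr(i - 1, j) and hbr(j, i + 1)) or (
                    hbr(j - 1, i) and hbr(i, j + 1)
                )
                anti = (hbr(i, j) and hbr(j, i)) or (
                    hbr(i - 1, j + 1) and hbr(j - 1, i + 1)
                )
                if para or anti:
                    codes[i], codes[j] = "E", "E"
    return SSAssignment(
        residue_numbers=resnums,
        codes=np.array([codes[int(r)] for r in resnums], dtype="<U1"),
    )


def helical_fraction(
    assignment: SSAssignment, residues: "np.ndarray | list[int] | None" = None
) -> float:
    """Fraction of selected residues assigned H (the reaction coordinate)."""
    if residues is None:
        mask = np.ones(assignment.residue_numbers.size, dtype=bool)
    else:
        mask = np.isin(assignment.residue_numbers, np.asarray(residues, dtype=int))
    if not mask.any():
        raise EmptyInputError("helical_fraction: empty residue selection")
    return float(np.mean(assignment.codes[mask] == "H"))


# --------------------------------------------------------------------------
# Ca2+ coordination geometry
# --------------------------------------------------------------------------

@dataclass
class CoordinationReport:
    """Ligand inventory and pentagonal-bipyramid verdict for a bound ion."""

    ligand_indices: np.ndarray
    ligand_distances: np.ndarray   # Angstrom
    n_ligands: int
    is_pentagonal_bipyramidal: bool
    axial_indices: tuple[int, int] | None
    equatorial_indices: np.ndarray | None


def ca_site_geometry(
    ensemble: Ensemble,
    model: int = 0,
    ion_element: str = "Ca",
    cutoff: float = 3.0,
    angle_tol_deg: float = 20.0,
) -> CoordinationReport:
    """Check the coordination shell of a bound ion for pentagonal-bipyramid
    geometry: exactly 7 O/N ligands within ``cutoff``, one axial pair at
    ~180 deg and five equatorial ligands with ~72 deg neighbour spacing.
    """
    ion_idx = np.nonzero(ensemble.elements == ion_element)[0]
    if ion_idx.size == 0:
        raise EnsembleError(f"no {ion_element} ion in the model")
    ion = ensemble.coords[model, ion_idx[0]]
    candidates = np.nonzero(
        np.isin(ensemble.elements, ["O", "N"])
    )[0]
    d = np.linalg.norm(ensemble.coords[model, candidates] - ion, axis=1)
    keep = d <= cutoff
    lig = candidates[keep]
    ligd = d[keep]
    verdict = False
    axial = None
    equatorial = None
    if lig.size == 7:
        vecs = ensemble.coords[model, lig] - ion
        unit = vecs / np.linalg.norm(vecs, axis=1)[:, None]

        def angle(i, j):
            return np.degrees(np.arccos(np.clip(unit[i] @ unit[j], -1.0, 1.0)))

        for a in range(7):
            for b in range(a + 1, 7):
                if abs(angle(a, b) - 180.0) > angle_tol_deg:
                    continue
                eq = [k for k in range(7) if k not in (a, b)]
                axis = unit[a] - unit[b]
                axis /= np.linalg.norm(axis)
                # project equatorial ligands onto the plane normal to the axis
                proj = unit[eq] - np.outer(unit[eq] @ axis, axis)
                norms = np.linalg.norm(proj, axis=1)
                if np.any(norms < 1e-6):
                    continue
                proj /= norms[:, None]
                ref = proj[0]
                ref2 = np.cross(axis, ref)
                az = np.degrees(np.arctan2(proj @ ref2, proj @ ref)) % 360.0
                order = np.argsort(az)
                gaps = np.diff(np.concatenate([az[order], [az[order][0] + 360.0]]))
                if np.all(np.abs(gaps - 72.0) <= angle_tol_deg):
                    verdict = True
                    axial = (int(lig[a]), int(lig[b]))
                    equatorial = lig[np.array(eq)[order]]
                    break
            if verdict:
                break
    return CoordinationReport(
        ligand_indices=lig,
        ligand_distances=ligd,
        n_ligands=int(lig.size),
        is_pentagonal_bipyramidal=verdict,
        axial_indices=axial,
        equatorial_indices=equatorial,
    )
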