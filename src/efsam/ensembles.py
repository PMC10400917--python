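"""Structural ensembles, subdomain map, selections and system-composition audits.

The central container is :class:`Ensemble`: an ordered stack of same-topology
coordinate sets (NMR models or MD snapshots) with author residue numbering
preserved, including the non-positive numbers of N-terminal expression tags.
Coordinates are stored in Angstrom; metrics that the literature reports in nm
convert at the reporting boundary.

Multi-model PDB reading/writing is delegated to biotite; everything layered on
top (selection mini-language, subdomain bookkeeping, ion electroneutrality
arithmetic) is local.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.constants import Avogadro

__all__ = [
    "Atom",
    "Ensemble",
    "SubdomainMap",
    "IonComposition",
    "EnsembleError",
    "TopologyMismatchError",
    "EmptyInputError",
    "SelectionError",
    "parse_ensemble",
    "write_ensemble",
    "select",
    "default_subdomain_map",
    "load_subdomain_map",
    "salt_pairs_for_box",
    "rebalance_anions",
]


class EnsembleError(ValueError):
    """Base class for structural-input errors."""


class TopologyMismatchError(EnsembleError):
    """Models in a multi-model file do not share one atom list."""


class EmptyInputError(EnsembleError):
    """A structure or selection that must be non-empty is empty."""


class SelectionError(EnsembleError):
    """Malformed selection expression or unknown segment name."""


# --------------------------------------------------------------------------
# Atom / Ensemble
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom of the shared topology (author numbering, element symbol)."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    hetero: bool = False


class Ensemble:
    """Ordered models over one shared topology.

    Parameters
    ----------
    atoms:
        Topology shared by every model.
    coords:
        Array of shape ``(n_models, n_atoms, 3)`` in Angstrom.
    times:
        Optional per-model time stamps in ps, strictly increasing.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        coords: np.ndarray,
        times: Sequence[float] | None = None,
    ):
        atoms = list(atoms)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if len(atoms) == 0 or coords.shape[1] == 0:
            raise EmptyInputError("ensemble must contain at least one atom")
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise EnsembleError(f"coords must be (n_models, n_atoms, 3), got {coords.shape}")
        if coords.shape[1] != len(atoms):
            raise TopologyMismatchError(
                f"{len(atoms)} atoms in topology but {coords.shape[1]} coordinate rows"
            )
        if coords.shape[0] < 1:
            raise EmptyInputError("ensemble must contain at least one model")
        if not np.all(np.isfinite(coords)):
            raise EnsembleError("coordinates must be finite")
        if times is not None:
            times = np.asarray(times, dtype=float)
            if times.shape != (coords.shape[0],):
                raise EnsembleError("times must have one entry per model")
            if np.any(np.diff(times) <= 0):
                raise EnsembleError("times must be strictly increasing")
        self.atoms: list[Atom] = atoms
        self.coords: np.ndarray = coords
        self.times = times
        # cached annotation arrays for vectorised selection
        self.atom_names = np.array([a.atom_name for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.residue_names = np.array([a.residue_name for a in atoms])
        self.residue_numbers = np.array([a.residue_number for a in atoms], dtype=int)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_ids(self) -> np.ndarray:
        """Sorted unique author residue numbers present."""
        return np.unique(self.residue_numbers)

    def model(self, index: int) -> np.ndarray:
        """Coordinates of one model, shape (n_atoms, 3), Angstrom."""
        return self.coords[index]

    def subset(self, indices: np.ndarray) -> "Ensemble":
        """New ensemble restricted to the given atom indices (order preserved)."""
        indices = np.asarray(indices, dtype=int)
        return Ensemble(
            [self.atoms[i] for i in indices],
            self.coords[:, indices, :],
            None if self.times is None else self.times,
        )

    def find_atom(self, residue_number: int, atom_name: str) -> int:
        """Index of a uniquely named atom; raises if absent."""
        hits = np.nonzero(
            (self.residue_numbers == residue_number) & (self.atom_names == atom_name)
        )[0]
        if hits.size == 0:
            raise EnsembleError(
                f"atom {atom_name} of residue {residue_number} is missing from the topology"
            )
        return int(hits[0])


# --------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# --------------------------------------------------------------------------

def parse_ensemble(path: str | Path) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    Author numbering is preserved (expression-tag residues -5..0 included);
    alternate locations are resolved to the highest occupancy; insertion
    codes are rejected.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    if not any(l.startswith(("ATOM", "HETATM")) for l in pdb.lines):
        raise EmptyInputError(f"no atoms in {path}")
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises on per-model atom-count mismatch
        raise TopologyMismatchError(
            f"models in {path} do not share one atom list: {exc}"
        ) from exc
    if stack.array_length() == 0:
        raise EmptyInputError(f"no atoms in {path}")
    ins = stack.ins_code
    if np.any(ins != ""):
        raise EnsembleError("insertion codes are not supported")
    atoms = [
        Atom(
            atom_name=str(stack.atom_name[i]),
            element=str(stack.element[i]).capitalize(),
            residue_name=str(stack.res_name[i]),
            residue_number=int(stack.res_id[i]),
            hetero=bool(stack.hetero[i]),
        )
        for i in range(stack.array_length())
    ]
    return Ensemble(atoms, np.asarray(stack.coord, dtype=float))


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an :class:`Ensemble` as a multi-model PDB (MODEL/ENDMDL records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = ensemble.n_atoms
    arrays = []
    for m in range(ensemble.n_models):
        arr = struc.AtomArray(n)
        arr.coord = ensemble.coords[m].astype(np.float32)
        arr.atom_name = ensemble.atom_names
        arr.element = np.char.upper(ensemble.elements)
        arr.res_name = ensemble.residue_names
        arr.res_id = ensemble.residue_numbers
        arr.chain_id = np.full(n, "A")
        arr.hetero = np.array([a.hetero for a in ensemble.atoms])
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# Subdomain map
# --------------------------------------------------------------------------

Interval = tuple[int, int]

# Published segment facts for this construct: the binding loop spans Leu74-Ser88, the
# delta regions are alpha1-alpha2 (73-88), alpha2-alpha4 (95-115) and the
# alpha9/alpha10 region (171-184), and the global fit range is Ser64-Leu199.
# Individual helix boundaries are not printed and are set to values
# consistent with those facts; they are fully overridable via config.
_DEFAULT_SEGMENTS: dict[str, list[Interval]] = {
    "alpha1": [(64, 73)],
    "alpha2": [(88, 96)],
    "alpha3": [(98, 107)],
    "alpha4": [(112, 124)],
    "alpha5": [(127, 131)],
    "alpha6": [(135, 147)],
    "alpha7": [(150, 157)],
    "alpha8": [(160, 168)],
    "alpha9": [(176, 180)],
    "alpha10": [(186, 200)],
    "cEF": [(64, 96)],
    "hEF": [(97, 128)],
    "SAM": [(132, 200)],
    "delta1": [(73, 88)],
    "delta2": [(95, 115)],
    "delta3": [(171, 184)],
    "binding_loop": [(74, 88)],
    "fit_global": [(64, 199)],
}

_DEFAULT_NAMED = {
    "probe": 108,                      # Phe108, the conserved hydrophobic probe
    "anchors": [192, 195, 199],        # Leu anchors on alpha10
    "chelators": [76, 78, 80, 82, 84, 87],  # Ca2+ binding-loop residues
}


@dataclass
class SubdomainMap:
    """Named residue segments of the EF-SAM construct (author numbering).

    The construct is the recombinant UniProt 58-201 span preceded by a
    six-residue expression tag numbered -5..0; tag residues are parsed but
    excluded from all default segments.
    """

    segments: dict[str, list[Interval]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_SEGMENTS.items()}
    )
    named_residues: dict = field(default_factory=lambda: dict(_DEFAULT_NAMED))
    uniprot_span: Interval = (58, 201)
    tag_span: Interval = (-5, 0)

    def __post_init__(self):
        lo, hi = self.tag_span[0], self.uniprot_span[1]
        for name, ivals in self.segments.items():
            for a, b in ivals:
                if a > b:
                    raise ValueError(f"segment {name}: empty interval ({a},{b})")
                if a < lo or b > hi:
                    raise ValueError(
                        f"segment {name}: interval ({a},{b}) outside construct range "
                        f"[{lo},{hi}]"
                    )
        d1 = self.segments.get("delta1")
        if d1 is not None:
            n = sum(b - a + 1 for a, b in d1)
            if n != 16:
                raise ValueError(f"delta1 must span 16 residues, got {n}")

    def residues(self, name: str) -> np.ndarray:
        """All residue numbers of a named segment."""
        if name not in self.segments:
            raise SelectionError(
                f"unknown segment {name!r}; available: {sorted(self.segments)}"
            )
        out: list[int] = []
        for a, b in self.segments[name]:
            out.extend(range(a, b + 1))
        return np.unique(np.array(out, dtype=int))

    def construct_length(self) -> int:
        """Residue count of the construct: UniProt span plus expression tag."""
        span = self.uniprot_span[1] - self.uniprot_span[0] + 1
        tag = self.tag_span[1] - self.tag_span[0] + 1
        return span + tag


def default_subdomain_map() -> SubdomainMap:
    return SubdomainMap()


def load_subdomain_map(path: str | Path) -> SubdomainMap:
    """Load a subdomain map from YAML, overriding defaults segment-wise.

    Format::

        segments:
          alpha3: [[99, 107]]
        named_residues:
          probe: 108
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    m = default_subdomain_map()
    for name, ivals in (cfg.get("segments") or {}).items():
        m.segments[name] = [tuple(int(x) for x in iv) for iv in ivals]
    m.named_residues.update(cfg.get("named_residues") or {})
    m.__post_init__()
    return m


# --------------------------------------------------------------------------
# Selection mini-language
# --------------------------------------------------------------------------
#
# Grammar:   expr    := term ("or" term)*
#            term    := factor ("and" factor)*
#            factor  := "(" expr ")" | primitive
#            primitive := "resnum" INT ["to" INT]
#                       | "resname" NAME | "name" NAME | "segment" NAME
#                       | "element" NAME

_TOKEN = re.compile(r"\(|\)|[A-Za-z_][\w']*|-?\d+")


class _Parser:
    def __init__(self, tokens: list[str], ens: Ensemble, smap: SubdomainMap | None):
        self.tokens = tokens
        self.pos = 0
        self.ens = ens
        self.smap = smap

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.take()
        if tok == "(":
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        ens = self.ens
        if tok == "resnum":
            a = int(self.take())
            if self.peek() == "to":
                self.take()
                b = int(self.take())
            else:
                b = a
            return (ens.residue_numbers >= a) & (ens.residue_numbers <= b)
        if tok == "resname":
            return ens.residue_names == self.take().upper()
        if tok == "name":
            return ens.atom_names == self.take().upper()
        if tok == "element":
            return ens.elements == self.take().capitalize()
        if tok == "segment":
            name = self.take()
            if self.smap is None:
                raise SelectionError("segment selection requires a SubdomainMap")
            resids = self.smap.residues(name)
            return np.isin(ens.residue_numbers, resids)
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(
    ensemble: Ensemble,
    expr: str,
    subdomain_map: SubdomainMap | None = None,
) -> np.ndarray:
    """Evaluate a selection expression to a sorted array of atom indices.

    Supports residue ranges (``resnum 74 to 88``), residue / atom / element
    names, named segments from a :class:`SubdomainMap`, parentheses, and
    ``and`` / ``or``. Deterministic and order-preserving; may be empty.
    """
    tokens = _TOKEN.findall(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    parser = _Parser(tokens, ensemble, subdomain_map)
    mask = parser.expr()
    if parser.peek() is not None:
        raise SelectionError(f"trailing tokens in selection: {parser.tokens[parser.pos:]}")
    return np.nonzero(mask)[0]


# --------------------------------------------------------------------------
# Ion electroneutrality arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IonComposition:
    """Counter-ion content of a simulation box.

    Electroneutrality: ``n_cation - n_anion + solute_formal_charge == 0``
    (monovalent K+ / Cl-).
    """

    n_cation: int
    n_anion: int
    box_edge_nm: float = 7.0
    target_concentration: float = 0.150
    solute_formal_charge: int | None = None

    def __post_init__(self):
        if self.n_cation < 0 or self.n_anion < 0:
            raise ValueError("ion counts must be non-negative")
        if self.solute_formal_charge is None:
            # infer the (unprinted) solute charge from the neutrality identity
            object.__setattr__(
                self, "solute_formal_charge", self.n_anion - self.n_cation
            )
        if self.n_cation - self.n_anion + self.solute_formal_charge != 0:
            raise ValueError(
                f"composition is not electroneutral: "
                f"{self.n_cation} - {self.n_anion} + {self.solute_formal_charge} != 0"
            )


def salt_pairs_for_box(concentration: float, box_edge: float) -> int:
    """Number of salt ion pairs for a cubic box at a target concentration.

    ``round(concentration [mol/L] * edge^3 [nm^3] * 1e-24 L/nm^3 * N_A)``
    with round-half-away-from-zero.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if box_edge <= 0:
        raise ValueError("box edge must be positive")
    pairs = concentration * box_edge**3 * 1e-24 * Avogadro
    return int(math.floor(pairs + 0.5))


def rebalance_anions(holo: IonComposition, solute_charge_change: int) -> IonComposition:
    """Adjust the anion count after a change of the solute's formal charge.

    Removing a bound Ca2+ (charge change -2) from an electroneutral system
    drops two Cl- from the solvent; the cation count never changes.
    """
    new_anion = holo.n_anion + solute_charge_change
    if new_anion < 0:
        raise ValueError(
            f"rebalancing would require {new_anion} anions (negative count)"
        )
    return IonComposition(
        n_cation=holo.n_cation,
        n_anion=new_anion,
        box_edge_nm=holo.box_edge_nm,
        target_concentration=holo.target_concentration,
        solute_formal_charge=holo.solute_formal_charge + solute_charge_change,
    )
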