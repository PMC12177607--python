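"""Read/write PDB coordinate files and the structure/ensemble data model.

The data model is deliberately minimal: an :class:`AtomRecord` per ATOM/HETATM
line, a :class:`StructureModel` per MODEL block, and an :class:`Ensemble`
holding models that share an identical atom topology (the stand-in for
trajectory frames).  Fixed-column PDB v3.x is the only on-disk format.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "PDBParseError",
    "TopologyError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "STANDARD_AMINO_ACIDS",
]

STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE""".split()
)

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: residue key: (chain id, residue sequence number, insertion code)
ResidueKey = Tuple[str, int, str]


class PDBParseError(ValueError):
    """Malformed fixed-column record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class TopologyError(ValueError):
    """MODEL blocks of an ensemble do not share the same atom-key sequence."""


class PDBFormatError(ValueError):
    """A value does not fit the fixed-column PDB field it must be written to."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    hetatm: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: xyz must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            warnings.warn(
                f"atom {self.serial} {self.name}: occupancy {self.occupancy} "
                "outside [0, 1], clamping"
            )
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)
        if not self.element:
            # element column is optional in older files; infer from the name
            self.element = _element_from_name(self.name)

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.resseq, self.icode)

    @property
    def atom_key(self) -> Tuple[str, int, str, str]:
        return (self.chain, self.resseq, self.icode, self.name)

    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def is_standard_aa(self) -> bool:
        return not self.hetatm and self.resname in STANDARD_AMINO_ACIDS

    def is_polymer(self) -> bool:
        """ATOM records always count; HETATM only for standard residues
        (modified residues deposited as HETATM), so ligands/ions stay out."""
        return not self.hetatm or self.resname in STANDARD_AMINO_ACIDS


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. 1HB, 2HG1
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("FE", "ZN", "MG", "MN", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class StructureModel:
    """One MODEL block: an ordered list of atoms plus residue bookkeeping."""

    model_id: int
    atoms: List[AtomRecord]
    residue_keys: List[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residue_keys:
            seen = set()
            for a in self.atoms:
                if a.residue_key not in seen:
                    seen.add(a.residue_key)
                    self.residue_keys.append(a.residue_key)
        keys = [a.atom_key for a in self.atoms]
        if len(keys) != len(set(keys)):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate atom keys after altloc resolution: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def topology_fingerprint(self) -> Tuple[Tuple[str, int, str, str], ...]:
        return tuple(a.atom_key for a in self.atoms)

    def coords(self) -> np.ndarray:
        """All coordinates as an (n_atoms, 3) array (a copy)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        """A copy of this model with every atom moved to the given coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, xyz=xyz[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(self.model_id, atoms)

    def atoms_by_residue(self) -> "dict[ResidueKey, dict[str, AtomRecord]]":
        out: dict = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, {})[a.name] = a
        return out


@dataclass
class Ensemble:
    """Ordered models sharing one topology; stands in for trajectory frames."""

    models: List[StructureModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble requires at least one model")
        ref = self.models[0].topology_fingerprint
        for m in self.models[1:]:
            if m.topology_fingerprint != ref:
                raise TopologyError(
                    f"model {m.model_id} atom-key sequence differs from model "
                    f"{self.models[0].model_id}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    @property
    def topology_fingerprint(self):
        return self.models[0].topology_fingerprint

    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_models, n_atoms, 3)."""
        return np.stack([m.coords() for m in self.models])


# ---------------------------------------------------------------------------
# parsing


def _parse_atom_line(line: str, lineno: int, hetatm: bool) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than coordinate fields", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"malformed fixed-column field ({exc})", lineno) from None
    return AtomRecord(
        serial=serial, name=name, altloc=altloc, resname=resname, chain=chain,
        resseq=resseq, icode=icode, xyz=xyz, occupancy=occ, bfactor=bfac,
        element=element, hetatm=hetatm,
    )


def _resolve_altlocs(atoms: Sequence[AtomRecord], policy: str) -> List[AtomRecord]:
    """Collapse alternate locations to one atom per (chain, resseq, icode, name).

    ``occupancy`` (default): highest occupancy wins, ties broken by the
    lexicographically smallest altloc (so blank/'A' beat 'B').  ``first``:
    the first record in file order wins.
    """
    if policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    chosen: dict = {}
    order: List[Tuple[str, int, str, str]] = []
    for a in atoms:
        key = a.atom_key
        if key not in chosen:
            chosen[key] = a
            order.append(key)
        elif policy == "occupancy":
            b = chosen[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                chosen[key] = a
    return [chosen[k] for k in order]


def _altloc_rank(altloc: str) -> int:
    # higher rank wins; blank sorts like 'A', later letters lose
    return -ord(altloc or "A")


def read_pdb(source, altloc_policy: str = "occupancy") -> Ensemble:
    """Parse PDB text (a path or a string of records) into an :class:`Ensemble`.

    One :class:`StructureModel` per MODEL block; a file without MODEL records
    yields a single model with ``model_id=1``.  Alternate locations are
    resolved per ``altloc_policy``; hydrogens are retained (downstream
    selectors exclude them where appropriate).
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)

    models: List[StructureModel] = []
    current: List[AtomRecord] = []
    current_id = 1
    in_model = False
    saw_model_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(StructureModel(current_id, _resolve_altlocs(current, altloc_policy)))
                current = []
            saw_model_record = True
            in_model = True
            try:
                current_id = int(line[6:].split()[0])
            except (IndexError, ValueError):
                raise PDBParseError("MODEL record without a serial number", lineno) from None
        elif rec == "ENDMDL":
            models.append(StructureModel(current_id, _resolve_altlocs(current, altloc_policy)))
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno, hetatm=rec == "HETATM"))
        # TER / END / headers are ignored

    if current:
        models.append(StructureModel(
            current_id if in_model or not saw_model_record else current_id + 1,
            _resolve_altlocs(current, altloc_policy),
        ))
    if not models:
        raise PDBParseError("no ATOM/HETATM records found", 0)
    return Ensemble(models)


# ---------------------------------------------------------------------------
# writing


def _format_atom(a: AtomRecord) -> str:
    for c in a.xyz:
        if not -999.999 <= c <= 9999.999:
            raise PDBFormatError(f"coordinate {c} does not fit the 8.3 PDB field")
    if not -9999 <= a.serial <= 99999:
        raise PDBFormatError(f"serial {a.serial} does not fit the PDB field")
    name = a.name if len(a.name) >= 4 or (a.element and len(a.element) == 2) else f" {a.name}"
    record = "HETATM" if a.hetatm else "ATOM  "
    return (
        f"{record}{a.serial:>5} {name:<4}{a.altloc or ' '}{a.resname:>3} "
        f"{a.chain:1}{a.resseq:>4}{a.icode or ' '}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2}"
    )


def write_pdb(ensemble: Ensemble) -> str:
    """Serialize an ensemble to PDB text (round-trip safe to 3 decimals)."""
    lines: List[str] = []
    multi = len(ensemble) > 1
    for model in ensemble.models:
        if multi:
            lines.append(f"MODEL     {model.model_id:>4}")
        lines.extend(_format_atom(a) for a in model.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# selections


def select_atoms(model: StructureModel, selector: str = "CA") -> List[AtomRecord]:
    """Select atoms by role: ``CA``, ``backbone``, ``heavy`` or ``all``.

    Protein selections (everything but ``all``) are restricted to standard
    amino-acid residues, so docking ligands and ions parsed from HETATM
    records do not leak into RMSD fits.  Residues without a CA are skipped
    from the CA selection (logged).
    """
    if selector == "all":
        return list(model.atoms)
    if selector == "heavy":
        return [a for a in model.atoms if a.is_polymer() and not a.is_hydrogen()]
    if selector == "backbone":
        return [a for a in model.atoms
                if a.is_polymer() and a.name in BACKBONE_NAMES]
    if selector == "CA":
        out = []
        seen = set()
        for a in model.atoms:
            if a.is_polymer() and a.name == "CA" and a.element.upper() != "CA" and a.residue_key not in seen:
                seen.add(a.residue_key)
                out.append(a)
        missing = [k for k in model.residue_keys if k not in seen
                   and any(x.residue_key == k and x.is_polymer() for x in model.atoms)]
        if missing:
            logger.info("select_atoms: %d residues lack a CA and were skipped", len(missing))
        return out
    raise ValueError(f"unknown selector {selector!r}")
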