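"""Coordinate data model and multi-model PDB input/output.

The unit of analysis throughout the package is the :class:`StructureEnsemble`:
an ordered list of models (cryo-EM depositions of one condition, or exported
trajectory frames) over a fixed atom topology.  All coordinates are in
angstroms and residues keep the author numbering of the source file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, TextIO

from .errors import (
    EmptyInputError,
    EmptySelectionError,
    FormatOverflowError,
    PDBParseError,
    ResidueLookupError,
    TopologyError,
    UnsupportedResidueError,
)

logger = logging.getLogger(__name__)

#: Side-chain terminal charged atoms per residue type.  These are the atoms
#: between which salt-bridge proxy distances are measured: the carboxylate
#: oxygens of Asp/Glu and the terminal amine/guanidinium/imidazole nitrogens
#: of Lys/Arg/His.
TERMINAL_CHARGED_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

ACIDIC_RESNAMES = frozenset({"ASP", "GLU"})
BASIC_RESNAMES = frozenset({"LYS", "ARG", "HIS"})

#: Alternate-location indicators that are kept; everything else is dropped
#: (deterministic approximation of the highest-occupancy convention).
KEPT_ALTLOCS = ("", "A")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model; coordinates in angstroms."""

    model_id: int
    chain_id: str
    resid: int
    icode: str
    resname: str
    atom_name: str
    element: str
    altloc: str
    xyz: tuple[float, float, float]
    is_hetero: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resid, self.icode)

    @property
    def topology_key(self) -> tuple[str, int, str, str, str]:
        return (self.chain_id, self.resid, self.icode, self.resname, self.atom_name)


@dataclass(frozen=True)
class ResidueRef:
    """Reference to a single residue by chain, author number and type."""

    chain_id: str
    resid: int
    resname: str
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A/GLU294"
        return f"{self.chain_id}/{self.resname}{self.resid}{self.icode}"


@dataclass
class StructureEnsemble:
    """Ordered models over a constant atom topology.

    ``source_label`` carries the experimental condition ("apo", "Ca2+/CaM",
    "NaCl", "CaCl2", ...) and is propagated into every statistic computed
    from the ensemble.
    """

    models: list[list[AtomRecord]]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.models or not self.models[0]:
            raise EmptyInputError("ensemble must contain at least one non-empty model")
        validate_topology(self.models)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0])


def validate_topology(models: list[list[AtomRecord]]) -> None:
    """Raise :class:`TopologyError` unless all models share the atom sequence."""
    ref = [a.topology_key for a in models[0]]
    for m, model in enumerate(models[1:], start=2):
        keys = [a.topology_key for a in model]
        if keys != ref:
            if len(keys) != len(ref):
                raise TopologyError(
                    f"model {m} has {len(keys)} atoms, model 1 has {len(ref)}"
                )
            first = next(i for i, (a, b) in enumerate(zip(keys, ref)) if a != b)
            raise TopologyError(
                f"model {m} atom {first + 1} is {keys[first]}, "
                f"model 1 has {ref[first]}"
            )


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_coordinate_line(line: str, lineno: int, model_id: int) -> AtomRecord:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate record: {exc}") from exc
    if not resname:
        raise PDBParseError(f"line {lineno}: empty residue name")
    if not element:
        # fall back on the leading letter of the atom name, PDB v2 style
        element = name.lstrip("0123456789")[:1].upper()
    return AtomRecord(
        model_id=model_id,
        chain_id=chain,
        resid=resid,
        icode=icode,
        resname=resname,
        atom_name=name,
        element=element,
        altloc=altloc,
        xyz=(x, y, z),
        is_hetero=line.startswith("HETATM"),
    )


def read_pdb(
    source: str | TextIO,
    *,
    keep_hetero: bool = False,
    source_label: str = "",
) -> StructureEnsemble:
    """Parse PDB-dialect text into a :class:`StructureEnsemble`.

    MODEL/ENDMDL blocks are optional; absent blocks mean a single model.
    Hydrogens are always dropped (all geometry here is heavy-atom), HETATM
    records only kept when ``keep_hetero`` is set, and alternate locations
    other than blank or 'A' are dropped with a logged count.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source

    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model_block = False
    dropped_altloc = 0
    model_id = 1

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model_block:
                raise PDBParseError(f"line {lineno}: nested MODEL record")
            in_model_block = True
            if current:
                models.append(current)
                current = []
                model_id += 1
        elif rec == "ENDMDL":
            if not in_model_block:
                raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
            in_model_block = False
            models.append(current)
            current = []
            model_id += 1
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_coordinate_line(line, lineno, model_id)
            if atom.is_hetero and not keep_hetero:
                continue
            if atom.element == "H":
                continue
            if atom.altloc not in KEPT_ALTLOCS:
                dropped_altloc += 1
                continue
            if not all(abs(c) < float("inf") for c in atom.xyz):
                raise PDBParseError(f"line {lineno}: non-finite coordinate")
            current.append(atom)

    if current:
        models.append(current)
    if dropped_altloc:
        logger.info("dropped %d alternate-location atoms", dropped_altloc)
    if not models or all(not m for m in models):
        raise EmptyInputError("no atoms parsed from input")
    models = [m for m in models if m]
    return StructureEnsemble(models=models, source_label=source_label)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # Standard PDB convention: single-letter elements start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_pdb(ensemble: StructureEnsemble) -> str:
    """Serialize an ensemble to fixed-column PDB text.

    MODEL/ENDMDL framing is emitted when the ensemble has more than one
    model; coordinates are written to three decimals (field width %8.3f).
    """
    lines: list[str] = []
    multi = ensemble.n_models > 1
    for i, model in enumerate(ensemble.models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for serial, atom in enumerate(model, start=1):
            x, y, z = atom.xyz
            if any(abs(c) >= 10000.0 for c in (x, y, z)):
                raise FormatOverflowError(
                    f"coordinate {atom.xyz} of {atom.topology_key} exceeds the "
                    "8-column PDB field"
                )
            rec = "HETATM" if atom.is_hetero else "ATOM  "
            lines.append(
                f"{rec}{min(serial, 99999):5d} "
                f"{_format_atom_name(atom.atom_name, atom.element)}"
                f"{atom.altloc or ' '}"
                f"{atom.resname:>3} "
                f"{atom.chain_id}"
                f"{atom.resid:4d}"
                f"{atom.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Residue resolution
# ---------------------------------------------------------------------------

def find_residue_atoms(model: Iterable[AtomRecord], ref: ResidueRef) -> list[AtomRecord]:
    """All atoms of the referenced residue, in file order.

    Raises :class:`ResidueLookupError` if the residue is absent or its type
    disagrees with the reference.
    """
    atoms = [
        a
        for a in model
        if a.chain_id == ref.chain_id and a.resid == ref.resid and a.icode == ref.icode
    ]
    if not atoms:
        raise ResidueLookupError(f"residue {ref} not found in model")
    resnames = {a.resname for a in atoms}
    if resnames != {ref.resname}:
        raise ResidueLookupError(
            f"residue {ref}: file has resname {sorted(resnames)}, expected {ref.resname}"
        )
    return atoms


def terminal_charged_atoms(
    model: Iterable[AtomRecord], ref: ResidueRef
) -> list[AtomRecord]:
    """Side-chain terminal charged atoms of a residue.

    Salt-bridge proxy distances are measured between the terminal charged
    oxygen(s) of an acidic residue and the terminal charged nitrogen(s) of a
    basic one; this returns the atoms of one side.  Atoms listed for the
    residue type but absent from the model are skipped with a logged warning.
    """
    if ref.resname not in TERMINAL_CHARGED_ATOMS:
        raise UnsupportedResidueError(
            f"{ref.resname} has no terminal-charged-atom entry "
            f"(supported: {sorted(TERMINAL_CHARGED_ATOMS)})"
        )
    atoms = find_residue_atoms(model, ref)
    wanted = TERMINAL_CHARGED_ATOMS[ref.resname]
    by_name = {a.atom_name: a for a in atoms}
    present = [by_name[n] for n in wanted if n in by_name]
    missing = [n for n in wanted if n not in by_name]
    if missing:
        logger.warning("residue %s is missing charged atoms %s", ref, missing)
    if not present:
        raise EmptySelectionError(f"residue {ref} has none of its charged atoms {wanted}")
    return present


def transform_ensemble(
    ensemble: StructureEnsemble,
    fn: Callable[[tuple[float, float, float]], tuple[float, float, float]],
) -> StructureEnsemble:
    """Apply a coordinate transform to every atom; topology is untouched."""
    models = [[replace(a, xyz=fn(a.xyz)) for a in model] for model in ensemble.models]
    return StructureEnsemble(models=models, source_label=ensemble.source_label)
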