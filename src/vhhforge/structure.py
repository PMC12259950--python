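"""Atomic structure model for a designed-chain/target-chain complex.

A :class:`StructureComplex` holds exactly two chains: the designed VHH
(nanobody) scaffold as chain A and the target receptor as chain B.  Residues
on the designed chain are addressed by Kabat-style labels (an integer plus an
optional insertion letter, e.g. ``52a``) and partitioned into framework (FR)
and complementarity-determining (CDR) regions by an explicit
:class:`RegionMap`.  Kabat renumbering is never computed from sequence: the
map is configuration, fixed by construction of the scaffold.

PDB reading and writing are delegated to :mod:`biotite`; this module only
adds the Kabat labelling, the frozen van der Waals radius table and the
two-chain validation that the rest of the pipeline relies on.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ELEMENT_VDW_RADII",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "REGION_TAGS",
    "CDR_TAGS",
    "FR_TAGS",
    "ResidueLabel",
    "Atom",
    "RegionMap",
    "StructureComplex",
    "EpitopeSpec",
    "StructureError",
    "PdbFormatError",
    "default_region_map",
    "annotate_regions",
    "chain_sequence",
    "read_pdb",
    "write_pdb",
]

# Frozen per-element van der Waals radii (Å).  Values are the conventional
# Bondi-style set; elements outside the table fall back to carbon.
ELEMENT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
_DEFAULT_VDW = 1.70

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

REGION_TAGS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
CDR_TAGS = frozenset({"CDR1", "CDR2", "CDR3"})
FR_TAGS = frozenset({"FR1", "FR2", "FR3", "FR4"})


class StructureError(ValueError):
    """Raised for invalid complexes, region maps or residue addressing."""


class PdbFormatError(StructureError):
    """Raised when a PDB file cannot be parsed."""


@functools.total_ordering
@dataclass(frozen=True)
class ResidueLabel:
    """Kabat-style residue label: integer number plus optional insertion letter.

    Labels order as ``(number, letter)`` with the bare number first, so
    ``52 < 52a < 53``.
    """

    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.insertion and (len(self.insertion) != 1 or not self.insertion.isalpha()):
            raise StructureError(f"invalid insertion code {self.insertion!r}")
        object.__setattr__(self, "insertion", self.insertion.lower())

    @classmethod
    def parse(cls, text: str | int | "ResidueLabel") -> "ResidueLabel":
        if isinstance(text, ResidueLabel):
            return text
        if isinstance(text, int):
            return cls(text)
        text = str(text).strip()
        if text and text[-1].isalpha():
            num, ins = text[:-1], text[-1]
        else:
            num, ins = text, ""
        try:
            return cls(int(num), ins)
        except ValueError as exc:
            raise StructureError(f"cannot parse residue label {text!r}") from exc

    def _key(self) -> tuple[int, str]:
        return (self.number, self.insertion)

    def __lt__(self, other: "ResidueLabel") -> bool:
        return self._key() < other._key()

    def __str__(self) -> str:
        return f"{self.number}{self.insertion}"


@dataclass(frozen=True)
class Atom:
    """A single (possibly pseudo) atom.

    ``name`` is the PDB atom name; the toy-world pseudo-residue model uses
    ``CA`` for the backbone sphere and ``SC`` for the side-chain sphere.
    """

    serial: int
    element: str
    coords: tuple[float, float, float]
    radius: float
    residue_label: ResidueLabel
    residue_name: str
    chain_id: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise StructureError(f"atom {self.serial}: radius must be positive")
        if not all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial}: non-finite coordinates")
        if not self.name:
            object.__setattr__(self, "name", self.element)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


def _labels(values: Iterable[str | int | ResidueLabel]) -> list[ResidueLabel]:
    return [ResidueLabel.parse(v) for v in values]


@dataclass(frozen=True)
class RegionMap:
    """Ordered FR/CDR segmentation of the designed chain by Kabat labels.

    ``segments`` lists ``(region_tag, labels)`` in chain order; segments are
    disjoint and together cover the designed chain.  ``fixed_labels`` are the
    positions held immutable during design and must lie inside FR segments.
    """

    segments: tuple[tuple[str, tuple[ResidueLabel, ...]], ...]
    fixed_labels: frozenset[ResidueLabel]

    @classmethod
    def from_segments(
        cls,
        segments: Sequence[tuple[str, Sequence[str | int | ResidueLabel]]],
        fixed_labels: Iterable[str | int | ResidueLabel] | None = None,
    ) -> "RegionMap":
        segs = tuple(
            (tag, tuple(_labels(labels))) for tag, labels in segments
        )
        if fixed_labels is None:
            fixed = frozenset(
                lab for tag, labs in segs if tag in FR_TAGS for lab in labs
            )
        else:
            fixed = frozenset(_labels(fixed_labels))
        rm = cls(segments=segs, fixed_labels=fixed)
        rm.validate()
        return rm

    def validate(self) -> None:
        seen: set[ResidueLabel] = set()
        fr_union: set[ResidueLabel] = set()
        for tag, labels in self.segments:
            if tag not in REGION_TAGS:
                raise StructureError(f"unknown region tag {tag!r}")
            if tag in CDR_TAGS and not labels:
                raise StructureError(f"CDR segment {tag} must be non-empty")
            if seen & set(labels):
                raise StructureError(f"segment {tag} overlaps a previous segment")
            seen.update(labels)
            if tag in FR_TAGS:
                fr_union.update(labels)
        present = {tag for tag, _ in self.segments}
        if not CDR_TAGS <= present:
            raise StructureError("region map must define CDR1, CDR2 and CDR3")
        if not self.fixed_labels <= fr_union:
            stray = sorted(str(l) for l in self.fixed_labels - fr_union)
            raise StructureError(f"fixed labels outside FR segments: {stray}")

    @property
    def labels(self) -> tuple[ResidueLabel, ...]:
        return tuple(lab for _, labs in self.segments for lab in labs)

    def tag_of(self, label: ResidueLabel) -> str:
        for tag, labels in self.segments:
            if label in labels:
                return tag
        raise StructureError(f"label {label} not in region map")

    def segment(self, tag: str) -> tuple[ResidueLabel, ...]:
        for t, labels in self.segments:
            if t == tag:
                return labels
        raise StructureError(f"region {tag!r} not in map")

    def cdr_lengths(self) -> dict[str, int]:
        return {tag: len(self.segment(tag)) for tag in ("CDR1", "CDR2", "CDR3")}


# Scaffold segmentation used throughout.  CDR1 spans Kabat 27-33 (7 positions)
# and CDR2 spans the 52a-57 block; that block names six bare labels for seven
# positions, so the default completes it with a second insertion (52a, 52b,
# 53-57).  CDR3 starts at 95 (FR3 therefore ends at 94) and takes a
# configurable 6-12 positions, extended past 99 with insertion codes.
def default_region_map(cdr3_length: int = 10) -> RegionMap:
    if not 6 <= cdr3_length <= 12:
        raise StructureError("CDR3 length must be between 6 and 12")
    cdr3: list[str] = [str(n) for n in range(95, 100)]
    cdr3 += [f"99{chr(ord('a') + i)}" for i in range(cdr3_length - 5)]
    return RegionMap.from_segments(
        [
            ("FR1", [str(n) for n in range(1, 27)]),
            ("CDR1", [str(n) for n in range(27, 34)]),
            ("FR2", [str(n) for n in range(34, 53)]),
            ("CDR2", ["52a", "52b"] + [str(n) for n in range(53, 58)]),
            ("FR3", [str(n) for n in range(58, 95)]),
            ("CDR3", cdr3),
            ("FR4", [str(n) for n in range(100, 114)]),
        ]
    )


@dataclass(frozen=True)
class EpitopeSpec:
    """A design epitope: exactly three residues on the target chain."""

    label: int
    residues: tuple[ResidueLabel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(_labels(self.residues)))
        if len(self.residues) != 3:
            raise StructureError("an epitope is defined by exactly three residues")


@dataclass(frozen=True)
class StructureComplex:
    """A two-chain complex: designed chain (A) plus target chain (B)."""

    designed_chain: tuple[Atom, ...]
    target_chain: tuple[Atom, ...]
    region_map: RegionMap | None = None

    def __post_init__(self) -> None:
        if not self.designed_chain or not self.target_chain:
            raise StructureError("complex requires two non-empty chains")
        serials = [a.serial for a in self.designed_chain + self.target_chain]
        if len(serials) != len(set(serials)):
            raise StructureError("atom serials must be unique within the complex")

    # -- residue-level views -------------------------------------------------

    def designed_residues(self) -> list[tuple[ResidueLabel, str, tuple[Atom, ...]]]:
        """Chain-A residues as (label, residue_name, atoms), in label order."""
        groups: dict[ResidueLabel, list[Atom]] = {}
        for atom in self.designed_chain:
            groups.setdefault(atom.residue_label, []).append(atom)
        out = []
        for label in sorted(groups):
            atoms = groups[label]
            names = {a.residue_name for a in atoms}
            if len(names) != 1:
                raise StructureError(f"residue {label}: inconsistent residue names {names}")
            out.append((label, atoms[0].residue_name, tuple(atoms)))
        return out

    def designed_labels(self) -> list[ResidueLabel]:
        return [label for label, _, _ in self.designed_residues()]

    @property
    def annotated(self) -> bool:
        return self.region_map is not None

    def tag_of(self, label: ResidueLabel) -> str:
        if self.region_map is None:
            raise StructureError("complex is not region-annotated")
        return self.region_map.tag_of(label)

    def all_atoms(self) -> tuple[Atom, ...]:
        return self.designed_chain + self.target_chain

    def n_atoms(self) -> int:
        return len(self.designed_chain) + len(self.target_chain)

    def translate_designed(self, shift: Sequence[float]) -> "StructureComplex":
        """Rigidly translate the designed chain by ``shift`` (Å)."""
        dx = np.asarray(shift, dtype=float)
        moved = tuple(
            replace(a, coords=tuple(a.xyz + dx)) for a in self.designed_chain
        )
        return replace(self, designed_chain=moved)


def annotate_regions(complex: StructureComplex, region_map: RegionMap) -> StructureComplex:
    """Attach ``region_map`` to the complex, validating full coverage.

    Every chain-A residue must receive exactly one region tag and every label
    in the map must exist on the chain.
    """
    region_map.validate()
    chain_labels = set(complex.designed_labels())
    map_labels = set(region_map.labels)
    missing = sorted(str(l) for l in map_labels - chain_labels)
    if missing:
        raise StructureError(f"region map labels absent from structure: {missing}")
    untagged = sorted(str(l) for l in chain_labels - map_labels)
    if untagged:
        raise StructureError(f"chain-A residues without a region tag: {untagged}")
    return replace(complex, region_map=region_map)


def chain_sequence(
    complex: StructureComplex, region_filter: set[str] | None = None
) -> str:
    """One-letter designed-chain sequence in Kabat label order.

    ``region_filter`` restricts output to the given region tags (an empty set
    yields the empty string); ``None`` returns the full chain.
    """
    if region_filter is not None and complex.region_map is None:
        raise StructureError("complex is not region-annotated")
    out = []
    for label, res_name, _ in complex.designed_residues():
        if region_filter is not None and complex.tag_of(label) not in region_filter:
            continue
        try:
            out.append(THREE_TO_ONE[res_name.upper()])
        except KeyError:
            raise StructureError(f"unknown residue name {res_name!r} at {label}") from None
    return "".join(out)


# -- PDB I/O (biotite-backed) ------------------------------------------------

def _validate_atom_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            int(line[6:11])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except (ValueError, IndexError):
            raise PdbFormatError(f"unparseable ATOM record at line {i}") from None


def read_pdb(path: str | Path, region_map: RegionMap | None = None) -> StructureComplex:
    """Read a two-chain complex from a PDB file.

    The first chain encountered is the designed chain, the second the target.
    Atoms receive element-derived van der Waals radii from the frozen table;
    insertion codes become part of the Kabat label.
    """
    from biotite.structure.io import pdb as pdbio

    path = Path(path)
    text = path.read_text()
    _validate_atom_lines(text)
    try:
        pdb_file = pdbio.PDBFile.read(io.StringIO(text))
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises various subclasses
        raise PdbFormatError(f"{path}: {exc}") from exc

    chains: dict[str, list[Atom]] = {}
    for i in range(arr.array_length()):
        element = str(arr.element[i]).upper() or "C"
        atom = Atom(
            serial=i + 1,
            element=element,
            coords=tuple(float(x) for x in arr.coord[i]),
            radius=ELEMENT_VDW_RADII.get(element, _DEFAULT_VDW),
            residue_label=ResidueLabel(int(arr.res_id[i]), str(arr.ins_code[i]).strip()),
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
            name=str(arr.atom_name[i]),
        )
        chains.setdefault(atom.chain_id, []).append(atom)

    if len(chains) < 2:
        raise StructureError("complex requires two chains")
    if len(chains) > 2:
        raise StructureError(f"expected exactly two chains, found {sorted(chains)}")
    (a_id, a_atoms), (b_id, b_atoms) = chains.items()
    cx = StructureComplex(tuple(a_atoms), tuple(b_atoms))
    if region_map is not None:
        cx = annotate_regions(cx, region_map)
    return cx


def write_pdb(complex: StructureComplex, path: str | Path) -> Path:
    """Write the complex as standard fixed-width PDB ATOM records."""
    from biotite.structure import AtomArray
    from biotite.structure.io import pdb as pdbio

    atoms = complex.all_atoms()
    n = len(atoms)
    arr = AtomArray(n)
    arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in atoms])
    arr.res_id = np.array([a.residue_label.number for a in atoms])
    arr.ins_code = np.array([a.residue_label.insertion.upper() for a in atoms])
    arr.res_name = np.array([a.residue_name for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.element = np.array([a.element for a in atoms])
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    path = Path(path)
    pdb_file.write(str(path))
    return path
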