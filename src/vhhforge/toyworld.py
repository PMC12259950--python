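"""Deterministic synthetic complexes so every pipeline stage runs offline.

The toy world replaces a real VHH/receptor complex with a pseudo-residue
model: the receptor (chain B) is a planar grid of uniform spheres and the
designed chain (chain A) is a scaffold of pseudo residues, each one backbone
sphere (``CA``) plus one side-chain sphere (``SC``) whose radius tracks the
amino-acid identity.  CDR side chains hang below the backbone, facing a
three-residue epitope on the grid; framework segments arc away from the
receptor so they never make contact.  The geometry is deliberately
non-physical — it exists so that SASA, contacts, scoring and the optimizer
have an exact, fast substrate (< 400 atoms) with a guaranteed admissible
starting pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backends import (
    AA_SIDECHAIN_RADII,
    SIDECHAIN_ATOM_NAME,
    ScoreRecord,
    Scorer,
    SurrogateScorer,
    surrogate_structure_update,
)
from .pipeline import CandidateDesign
from .sampler import DesignMode, graft_cdrs, sample_cdr_set
from .structure import (
    Atom,
    EpitopeSpec,
    RegionMap,
    ResidueLabel,
    StructureComplex,
    StructureError,
    annotate_regions,
    chain_sequence,
    default_region_map,
    ONE_TO_THREE,
)

__all__ = ["ToySpec", "make_toy_complex", "make_toy_roots", "SCAFFOLD_FR"]

# Frozen framework sequences of the synthetic scaffold (lengths match the
# default region map: FR1 26, FR2 19, FR3 37, FR4 14).  CDR placeholders are
# poly-serine and are replaced by sampling.
SCAFFOLD_FR = {
    "FR1": "EVQLLESGGGLVQPGGSLRLSCAASG",
    "FR2": "WFRQAPGKGREFVSAISGS",
    "FR3": "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYY",
    "FR4": "WGQGTLVTVSSGSA",
}

_BACKBONE_LIFT = 3.0   # CDR backbone sits this far above its side chain (Å)
_FR_BASE_HEIGHT = 9.2  # framework backbone height above the CDR side chains
_FR_SC_LIFT = 3.0
_FR_Y_OFFSET = -5.0    # frameworks run on the far side of the grid
_FR_Y_STEP = -3.0
_FR_X_STEP = 3.0
_CDR_ROWS = {"CDR1": 2, "CDR2": 4, "CDR3": 6}


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the synthetic complex.

    ``separation`` is the vertical gap (Å) between CDR side-chain centers and
    the receptor plane; the default 2.8 Å puts every CDR in contact under the
    4.0 Å rule without clashing (clash cutoff 2.5 Å).
    """

    receptor_grid: tuple[int, int, float] = (9, 12, 2.5)
    epitope_indices: tuple[int, int, int] | None = None
    cdr3_length: int = 10
    seed: int = 42
    separation: float = 2.8

    def region_map(self) -> RegionMap:
        return default_region_map(self.cdr3_length)

    def validate(self) -> None:
        rows, cols, spacing = self.receptor_grid
        if rows < 8 or cols < 12 or spacing <= 0:
            raise StructureError("toy receptor grid must be at least 8x12 with positive spacing")
        if self.separation <= 0:
            raise StructureError("separation must be positive")
        if self.epitope_indices is not None and len(self.epitope_indices) != 3:
            raise StructureError("an epitope is defined by exactly three residues")

    def default_epitope(self) -> EpitopeSpec:
        """Three receptor residues under the CDR1/CDR2/CDR3 centers."""
        rows, cols, _ = self.receptor_grid
        if self.epitope_indices is not None:
            idx = self.epitope_indices
        else:
            idx = tuple(_CDR_ROWS[t] * cols + cols // 2 - 1 for t in ("CDR1", "CDR2", "CDR3"))
        return EpitopeSpec(label=1, residues=tuple(ResidueLabel(i + 1) for i in idx))


def scaffold_sequence(region_map: RegionMap) -> str:
    parts = []
    for tag, seg in region_map.segments:
        if tag in SCAFFOLD_FR:
            fr = SCAFFOLD_FR[tag]
            if len(fr) != len(seg):
                raise StructureError(f"{tag}: scaffold length mismatch")
            parts.append(fr)
        else:
            parts.append("S" * len(seg))
    return "".join(parts)


def make_toy_complex(spec: ToySpec | None = None) -> StructureComplex:
    """Build the annotated synthetic complex (deterministic for a fixed spec)."""
    spec = spec or ToySpec()
    spec.validate()
    rows, cols, spacing = spec.receptor_grid
    region_map = spec.region_map()
    sequence = scaffold_sequence(region_map)

    serial = 0
    designed: list[Atom] = []
    seq_iter = iter(sequence)

    # per-region backbone/side-chain positions
    fr_index = 0
    for tag, seg in region_map.segments:
        if tag in _CDR_ROWS:
            row = _CDR_ROWS[tag]
            start_col = max(0, (cols - len(seg)) // 2)
            y = row * spacing
            for k, label in enumerate(seg):
                aa = next(seq_iter)
                x = (start_col + k) * spacing
                sc = np.array([x, y, spec.separation])
                bb = sc + np.array([0.0, 0.0, _BACKBONE_LIFT])
                serial += 1
                designed.append(Atom(serial, "C", tuple(bb), 1.70, label,
                                     ONE_TO_THREE[aa], "A", "CA"))
                serial += 1
                designed.append(Atom(serial, "C", tuple(sc),
                                     AA_SIDECHAIN_RADII[aa], label,
                                     ONE_TO_THREE[aa], "A", SIDECHAIN_ATOM_NAME))
        else:
            y = _FR_Y_OFFSET + _FR_Y_STEP * fr_index
            fr_index += 1
            z_bb = spec.separation + _FR_BASE_HEIGHT
            for k, label in enumerate(seg):
                aa = next(seq_iter)
                x = -20.0 + k * _FR_X_STEP
                bb = np.array([x, y, z_bb])
                sc = bb + np.array([0.0, 0.0, _FR_SC_LIFT])
                serial += 1
                designed.append(Atom(serial, "C", tuple(bb), 1.70, label,
                                     ONE_TO_THREE[aa], "A", "CA"))
                serial += 1
                designed.append(Atom(serial, "C", tuple(sc),
                                     AA_SIDECHAIN_RADII[aa], label,
                                     ONE_TO_THREE[aa], "A", SIDECHAIN_ATOM_NAME))

    target: list[Atom] = []
    res = 0
    for row in range(rows):
        for col in range(cols):
            res += 1
            serial += 1
            target.append(Atom(serial, "C",
                               (col * spacing, row * spacing, 0.0), 1.70,
                               ResidueLabel(res), "GLY", "B", "CA"))

    cx = StructureComplex(tuple(designed), tuple(target))
    return annotate_regions(cx, region_map)


def make_toy_roots(
    spec: ToySpec,
    n: int,
    mode: DesignMode,
    scorer: Scorer | None = None,
) -> list[CandidateDesign]:
    """``n`` scored root candidates with CDRs sampled under ``mode``.

    Roots share the scaffold geometry (all admissible by construction) and
    differ in CDR sequence, hence in side-chain radii and interface SA.
    Deterministic for a fixed ``spec.seed``.
    """
    if n < 1:
        raise ValueError("need at least one root")
    base = make_toy_complex(spec)
    region_map = base.region_map
    framework = chain_sequence(base)
    scorer = scorer or SurrogateScorer()

    roots = []
    for i in range(n):
        rng = np.random.default_rng([spec.seed, i])
        cdrs = sample_cdr_set(mode, region_map, rng)
        seq = graft_cdrs(framework, cdrs, region_map)
        structure = surrogate_structure_update(base, seq)
        scores = scorer.score(structure)
        root_id = f"root-{i:03d}"
        roots.append(CandidateDesign(
            id=root_id, ancestor_id=root_id, sequence=seq,
            structure=structure, scores=scores, generation=0,
        ))
    return roots
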