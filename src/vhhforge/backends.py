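"""Backend contracts and deterministic desk-scale surrogates.

The full design pipeline delegates four external stages to pluggable
backends: CDR sequence proposal (ProteinMPNN-class inverse folding),
structure update after a sequence change (Rosetta FastRelax-class
minimization), interaction scoring (Rosetta interface scoring) and folding
confidence (AlphaFold2 PAE of inter-chain pairs).  This module defines the
contracts and ships deterministic in-repo surrogates so the optimizer,
filters and reports are fully exercisable on one CPU.

The surrogates are intentionally simple and non-physical: they are pure
functions of the complex geometry, chosen so that the pipeline's control flow
and invariants (acceptance monotonicity, constraint filtering, budget
accounting) are exactly testable.

* interaction score = −1.0 per inter-chain atom pair within the contact
  cutoff (4.0 Å) plus +10.0 per pair inside the clash cutoff (2.5 Å);
  lower is better, like Rosetta energy units.
* PAE surrogate = clamp(30 − 2 × contacting residue pairs, 1, 30).
* structure update reassigns each CDR residue's pseudo side-chain sphere
  radius from a frozen per-amino-acid table (cube roots of standard mean
  residue volumes mapped linearly onto [1.0, 2.4] Å); the backbone and all
  framework side chains are untouched.

Command templates for the real external stages are documented in
``REAL_BACKEND_TEMPLATES`` and are never invoked here.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import sasa as sasa_mod
from .contacts import DEFAULT_CONTACT_CUTOFF, inter_chain_contacts
from .sampler import CdrSet, DesignMode, sample_cdr_set
from .sampler import graft_cdrs
from .structure import (
    CDR_TAGS,
    ONE_TO_THREE,
    RegionMap,
    StructureComplex,
    StructureError,
    chain_sequence,
)

__all__ = [
    "ScoreRecord",
    "SequenceProposer",
    "StructureUpdater",
    "Scorer",
    "AA_SIDECHAIN_RADII",
    "surrogate_interaction_score",
    "surrogate_pae",
    "surrogate_structure_update",
    "SurrogateProposer",
    "SurrogateScorer",
    "ReplayScorer",
    "SubprocessScorer",
    "REAL_BACKEND_TEMPLATES",
]

DEFAULT_CLASH_CUTOFF = 2.5  # Å
CONTACT_WEIGHT = -1.0       # per inter-chain pair within the contact cutoff
CLASH_WEIGHT = 10.0         # per inter-chain pair inside the clash cutoff
PAE_SLOPE = 2.0             # PAE drop per contacting residue pair
PAE_MIN, PAE_MAX = 1.0, 30.0

# Pseudo side-chain sphere radii (Å): cube roots of standard mean residue
# volumes (Zamyatnin), mapped linearly onto [1.0, 2.4] (Gly -> 1.0, Trp -> 2.4).
AA_SIDECHAIN_RADII: dict[str, float] = {
    "A": 1.346, "C": 1.545, "D": 1.569, "E": 1.803, "F": 2.170,
    "G": 1.000, "H": 1.916, "I": 2.014, "K": 2.027, "L": 2.014,
    "M": 1.987, "N": 1.596, "P": 1.584, "Q": 1.845, "R": 2.061,
    "S": 1.350, "T": 1.614, "V": 1.815, "W": 2.400, "Y": 2.194,
}

SIDECHAIN_ATOM_NAME = "SC"


@dataclass(frozen=True)
class ScoreRecord:
    """The three design metrics: REU-like score, interface SA (Å²), PAE."""

    interaction_score: float
    interface_sa: float
    pae_interaction: float

    def __post_init__(self) -> None:
        if self.interface_sa < -0.5:
            raise ValueError(f"interface SA {self.interface_sa:.3f} below tolerance")
        if not (0.0 <= self.pae_interaction <= 30.0):
            raise ValueError("PAE_interaction must lie in [0, 30]")


class SequenceProposer(Protocol):
    """Proposes a full designed-chain sequence for a candidate."""

    def propose(self, sequence: str, rng: np.random.Generator) -> str: ...


class StructureUpdater(Protocol):
    """Rebuilds/updates the complex after a designed-chain sequence change."""

    def update(self, complex: StructureComplex, new_sequence: str) -> StructureComplex: ...


class Scorer(Protocol):
    """Scores a complex, populating every ScoreRecord field."""

    def score(self, complex: StructureComplex) -> ScoreRecord: ...


# -- surrogate primitives -----------------------------------------------------

def _inter_chain_pair_counts(
    complex: StructureComplex, contact_cutoff: float, clash_cutoff: float
) -> tuple[int, int]:
    a = np.array([at.coords for at in complex.designed_chain])
    b = np.array([at.coords for at in complex.target_chain])
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    n_contact = tree_a.count_neighbors(tree_b, contact_cutoff)  # closed ball
    # strict inequality for clashes: subtract pairs at exactly the cutoff
    n_clash_closed = tree_a.count_neighbors(tree_b, clash_cutoff)
    hits = tree_a.query_ball_tree(tree_b, r=clash_cutoff)
    n_boundary = 0
    for i, js in enumerate(hits):
        for j in js:
            if abs(np.linalg.norm(a[i] - b[j]) - clash_cutoff) == 0.0:
                n_boundary += 1
    return int(n_contact), int(n_clash_closed - n_boundary)


def surrogate_interaction_score(
    complex: StructureComplex,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> float:
    """REU-like geometric score: favourable contacts minus clash penalty."""
    n_contact, n_clash = _inter_chain_pair_counts(complex, contact_cutoff, clash_cutoff)
    return CONTACT_WEIGHT * n_contact + CLASH_WEIGHT * n_clash


def surrogate_pae(
    complex: StructureComplex, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> float:
    """Confidence surrogate: more contacting residue pairs, lower PAE."""
    report = inter_chain_contacts(complex, contact_cutoff)
    raw = PAE_MAX - PAE_SLOPE * len(report.contact_pairs)
    return float(min(PAE_MAX, max(PAE_MIN, raw)))


def surrogate_structure_update(
    complex: StructureComplex, new_sequence: str
) -> StructureComplex:
    """Apply a sequence change under the pseudo-residue structure model.

    CDR residues take their new residue name and a side-chain sphere radius
    from :data:`AA_SIDECHAIN_RADII`; backbone coordinates are unchanged.
    Framework positions are immutable — a substitution there is an error.
    """
    if complex.region_map is None:
        raise StructureError("structure update requires a region-annotated complex")
    residues = complex.designed_residues()
    if len(new_sequence) != len(residues):
        raise StructureError(
            f"sequence length {len(new_sequence)} != designed-chain residues {len(residues)}"
        )
    old_sequence = chain_sequence(complex)
    new_by_label: dict = {}
    for (label, _, _), old_aa, new_aa in zip(residues, old_sequence, new_sequence):
        tag = complex.tag_of(label)
        if tag not in CDR_TAGS and new_aa != old_aa:
            raise StructureError(
                f"framework position {label} is immutable ({old_aa} -> {new_aa})"
            )
        new_by_label[label] = (tag, new_aa)

    new_atoms = []
    for atom in complex.designed_chain:
        tag, new_aa = new_by_label[atom.residue_label]
        if tag in CDR_TAGS:
            kwargs = {"residue_name": ONE_TO_THREE[new_aa]}
            if atom.name == SIDECHAIN_ATOM_NAME:
                kwargs["radius"] = AA_SIDECHAIN_RADII[new_aa]
            atom = replace(atom, **kwargs)
        new_atoms.append(atom)
    return replace(complex, designed_chain=tuple(new_atoms))


# -- backend implementations ---------------------------------------------------

@dataclass
class SurrogateProposer:
    """Resamples all three CDRs from a design mode and grafts them."""

    mode: DesignMode
    region_map: RegionMap

    def propose(self, sequence: str, rng: np.random.Generator) -> str:
        cdrs = sample_cdr_set(self.mode, self.region_map, rng)
        return graft_cdrs(sequence, cdrs, self.region_map)


class SurrogateUpdater:
    """StructureUpdater backed by :func:`surrogate_structure_update`."""

    def update(self, complex: StructureComplex, new_sequence: str) -> StructureComplex:
        return surrogate_structure_update(complex, new_sequence)


@dataclass
class SurrogateScorer:
    """Scorer combining the geometric surrogates with the real SASA objective.

    The target chain never moves during optimization, so its standalone SASA
    is cached after the first call (keyed on the target atoms' identity).
    """

    probe_radius: float = sasa_mod.DEFAULT_PROBE_RADIUS
    n_points: int = sasa_mod.DEFAULT_N_POINTS
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF
    _target_cache: tuple[int, float] | None = None

    def score(self, complex: StructureComplex) -> ScoreRecord:
        key = id(complex.target_chain)
        sa_target = None
        if self._target_cache is not None and self._target_cache[0] == key:
            sa_target = self._target_cache[1]
        area = sasa_mod.interface_sa(
            complex, self.probe_radius, self.n_points, sa_target=sa_target
        )
        self._target_cache = (key, area.sa_target)
        return ScoreRecord(
            interaction_score=surrogate_interaction_score(
                complex, self.contact_cutoff, self.clash_cutoff
            ),
            interface_sa=area.sa_interface,
            pae_interaction=surrogate_pae(complex, self.contact_cutoff),
        )


@dataclass
class ReplayScorer:
    """Scorer that replays a recorded sequence of ScoreRecords.

    Stands in for any external backend honouring the Scorer contract; used to
    verify that pipeline semantics do not depend on which backend produced
    the records.
    """

    records: Sequence[ScoreRecord]
    _cursor: int = 0

    def score(self, complex: StructureComplex) -> ScoreRecord:
        if self._cursor >= len(self.records):
            raise RuntimeError("replay scorer exhausted")
        rec = self.records[self._cursor]
        self._cursor += 1
        return rec


@dataclass
class SubprocessScorer:
    """Scorer that shells out to an external command.

    Exchange schema (JSON on stdin/stdout):

    request  — ``{"stage": "scorer", "pdb_path": str,
                  "designed_chain": str, "target_chain": str}``
    response — ``{"interaction_score": float, "interface_sa": float,
                  "pae_interaction": float}``

    The complex is written as a PDB file under ``workdir`` before each call.
    """

    command: Sequence[str]
    workdir: Path

    def score(self, complex: StructureComplex) -> ScoreRecord:
        from .structure import write_pdb

        self.workdir.mkdir(parents=True, exist_ok=True)
        pdb_path = self.workdir / "request.pdb"
        write_pdb(complex, pdb_path)
        request = {
            "stage": "scorer",
            "pdb_path": str(pdb_path),
            "designed_chain": complex.designed_chain[0].chain_id,
            "target_chain": complex.target_chain[0].chain_id,
        }
        proc = subprocess.run(
            list(self.command),
            input=json.dumps(request),
            capture_output=True,
            text=True,
            check=True,
        )
        payload = json.loads(proc.stdout)
        return ScoreRecord(
            interaction_score=float(payload["interaction_score"]),
            interface_sa=float(payload["interface_sa"]),
            pae_interaction=float(payload["pae_interaction"]),
        )


# Documented command templates for the real external stages.  These mirror the
# settings used in the original design campaign and are shipped for users with
# access to the GPU/Rosetta stack; they are never invoked by this package.
REAL_BACKEND_TEMPLATES: dict[str, dict] = {
    "rfdiffusion": {
        "kind": "structure_proposer",
        "invocation": "subprocess",
        "command": (
            "run_inference.py inference.input_pdb={input_pdb} "
            "inference.output_prefix={out_prefix} "
            "contigmap.contigs=[{fixed_contigs}] "
            "ppi.hotspot_res=[{epitope_residues}] "
            "diffuser.partial_T=50 inference.num_designs={n_backbones} "
            "inference.ckpt_override_path=Complex_base_ckpt.pt"
        ),
        "notes": "partial diffusion, 50 steps, default diffuser parameters; "
                 "typically 200 backbones per design attempt",
    },
    "proteinmpnn": {
        "kind": "sequence_proposer",
        "invocation": "subprocess",
        "command": (
            "protein_mpnn_run.py --pdb_path {input_pdb} "
            "--fixed_positions_jsonl {fixed_positions} "
            "--bias_AA_jsonl {composition_bias} --num_seq_per_target {n_seqs}"
        ),
        "notes": "fixed framework positions; per-region composition bias "
                 "mirroring the design-mode tables",
    },
    "alphafold2": {
        "kind": "confidence",
        "invocation": "subprocess",
        "command": "predict.py --pdb {input_pdb} --out {out_json}",
        "notes": "complex prediction; report PAE restricted to inter-chain "
                 "residue pairs (PAE_interaction)",
    },
    "rosetta": {
        "kind": "scorer",
        "invocation": "subprocess",
        "command": (
            "rosetta_scripts -s {input_pdb} -parser:protocol relax_score.xml "
            "-parser:script_vars constrain_backbone={constrain_backbone}"
        ),
        "notes": "FastRelax then interface scoring; constrain_backbone is "
                 "exposed as a flag with no default (protocols differ on it)",
    },
}
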