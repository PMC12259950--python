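"""Step-1 gating, the stack-sorted iterative optimizer, and final selection.

The design campaign runs in two steps.  Step 1 produces scored root
candidates (externally, via backbone diffusion + inverse folding; in-repo,
via the toy-world generator) which are gated on folding confidence and
interaction score (PAE_interaction < 10 and score < −20 REU, both strict).

Step 2 optimizes each surviving root independently.  Candidates live on a
stack sorted by interface surface area (descending).  Each cycle takes the
top-ranked candidate and makes a fixed number of improvement attempts
(default 16): resample the CDRs, rebuild the structure, rescore, and re-check
the contact constraints.  A proposal is pushed onto the stack iff its
interface SA strictly exceeds its predecessor's and the pose is admissible;
the predecessor always remains on the stack.  The cycle repeats up to 50
times per root.

Final selection keeps candidates scoring below −40 REU and fills the quota
round-robin across Step-1 ancestors (each ancestor's best remaining
candidate, ancestors ordered by their best score) so the selection descends
from as many distinct roots as possible.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .backends import ScoreRecord, Scorer, SequenceProposer, StructureUpdater
from .contacts import check_constraints, inter_chain_contacts
from .structure import StructureComplex

__all__ = [
    "CandidateDesign",
    "OptimizerState",
    "PipelineConfig",
    "step1_filter",
    "optimize_candidate",
    "run_step2",
    "final_select",
    "export_report",
]

logger = logging.getLogger("vhhforge.pipeline")


@dataclass(frozen=True)
class CandidateDesign:
    """A sequence/structure variant with lineage bookkeeping."""

    id: str
    ancestor_id: str
    sequence: str
    structure: StructureComplex
    scores: ScoreRecord | None
    generation: int = 0
    parent_id: str | None = None

    def scored(self) -> "CandidateDesign":
        if self.scores is None:
            raise ValueError(f"candidate {self.id} is unscored")
        return self


@dataclass
class OptimizerState:
    """The SA-sorted candidate stack plus cycle/attempt counters."""

    stack: list[CandidateDesign] = field(default_factory=list)
    cycle_count: int = 0
    attempts_per_cycle: int = 16
    max_cycles: int = 50

    def push(self, candidate: CandidateDesign) -> None:
        """Insert keeping non-increasing interface_sa order (stable on ties)."""
        keys = [-c.scores.interface_sa for c in self.stack]
        idx = bisect.bisect_right(keys, -candidate.scores.interface_sa)
        self.stack.insert(idx, candidate)

    @property
    def top(self) -> CandidateDesign:
        return self.stack[0]


@dataclass(frozen=True)
class PipelineConfig:
    """Gates, budgets and geometry parameters of the two-step pipeline."""

    pae_gate: float = 10.0
    score_gate: float = -20.0
    final_score_gate: float = -40.0
    max_cycles: int = 50
    attempts_per_cycle: int = 16
    contact_cutoff: float = 4.0
    max_fr_contacts: int = 5
    min_cdrs: int = 2
    cdr3_required: bool = True
    selection_quota: int = 80
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_quota <= 0 or self.max_cycles <= 0 or self.attempts_per_cycle <= 0:
            raise ValueError("quotas and budgets must be positive")
        for gate in (self.pae_gate, self.score_gate, self.final_score_gate):
            if not np.isfinite(gate):
                raise ValueError("gates must be finite")


def step1_filter(
    candidates: Sequence[CandidateDesign], config: PipelineConfig
) -> list[CandidateDesign]:
    """Strict Step-1 gate: keep PAE < pae_gate AND score < score_gate.

    Boundary values (PAE exactly at the gate, score exactly at the gate) are
    rejected.  Order is preserved.
    """
    kept = []
    for cand in candidates:
        cand.scored()
        if (cand.scores.pae_interaction < config.pae_gate
                and cand.scores.interaction_score < config.score_gate):
            kept.append(cand)
    return kept


def _attempt_rng(seed: int, root_index: int, cycle: int, attempt: int) -> np.random.Generator:
    # one stream per (root, cycle, attempt): serial and parallel runs agree
    return np.random.default_rng([seed, root_index, cycle, attempt])


def _admissible(complex: StructureComplex, config: PipelineConfig) -> bool:
    report = inter_chain_contacts(complex, config.contact_cutoff)
    verdict = check_constraints(
        report,
        max_fr_contacts=config.max_fr_contacts,
        min_cdrs=config.min_cdrs,
        cdr3_required=config.cdr3_required,
    )
    return verdict.passed


def optimize_candidate(
    root: CandidateDesign,
    proposer: SequenceProposer,
    updater: StructureUpdater,
    scorer: Scorer,
    config: PipelineConfig,
    root_index: int = 0,
) -> tuple[list[CandidateDesign], OptimizerState]:
    """Hill-climb one Step-1 root on the SA-sorted stack.

    Returns the lineage (root first, then every accepted variant in
    acceptance order) and the final optimizer state.  Scorer invocations are
    bounded by ``max_cycles × attempts_per_cycle``.
    """
    root.scored()
    state = OptimizerState(
        attempts_per_cycle=config.attempts_per_cycle, max_cycles=config.max_cycles
    )
    state.push(root)
    lineage = [root]
    n_accepted = 0

    for cycle in range(1, config.max_cycles + 1):
        state.cycle_count = cycle
        predecessor = state.top
        for attempt in range(config.attempts_per_cycle):
            rng = _attempt_rng(config.rng_seed, root_index, cycle, attempt)
            try:
                new_seq = proposer.propose(predecessor.sequence, rng)
                new_structure = updater.update(predecessor.structure, new_seq)
                scores = scorer.score(new_structure)
            except Exception as exc:
                raise RuntimeError(
                    f"backend failure at root={root.id} cycle={cycle} "
                    f"attempt={attempt}: {exc}"
                ) from exc
            if scores.interface_sa <= predecessor.scores.interface_sa:
                continue
            if not _admissible(new_structure, config):
                continue
            n_accepted += 1
            child = CandidateDesign(
                id=f"{root.id}-g{predecessor.generation + 1}-c{cycle:02d}a{attempt:02d}",
                ancestor_id=root.ancestor_id,
                sequence=new_seq,
                structure=new_structure,
                scores=scores,
                generation=predecessor.generation + 1,
                parent_id=predecessor.id,
            )
            state.push(child)
            lineage.append(child)
        logger.debug(
            "root=%s cycle=%d stack=%d best_sa=%.2f",
            root.id, cycle, len(state.stack), state.top.scores.interface_sa,
        )
    return lineage, state


def run_step2(
    roots: Sequence[CandidateDesign],
    proposer: SequenceProposer,
    updater: StructureUpdater,
    scorer: Scorer,
    config: PipelineConfig,
) -> list[CandidateDesign]:
    """Optimize every root; pool the admissible members of all lineages."""
    if not roots:
        warnings.warn("run_step2 called with no roots; returning empty pool")
        return []
    pool: list[CandidateDesign] = []
    for index, root in enumerate(roots):
        lineage, _ = optimize_candidate(
            root, proposer, updater, scorer, config, root_index=index
        )
        pool.extend(c for c in lineage if _admissible(c.structure, config))
    return pool


def final_select(
    pool: Sequence[CandidateDesign], config: PipelineConfig
) -> list[CandidateDesign]:
    """Threshold on interaction score, then round-robin across ancestors.

    Candidates scoring at or above ``final_score_gate`` are dropped (strict
    bound).  Ancestors are ordered by their best (lowest) candidate score;
    the selection repeatedly takes each ancestor's best remaining candidate
    until the quota is filled.  Ties break on higher interface SA, then id.
    """
    def rank_key(c: CandidateDesign):
        return (c.scores.interaction_score, -c.scores.interface_sa, c.id)

    eligible = [c for c in pool if c.scores.interaction_score < config.final_score_gate]
    by_ancestor: dict[str, list[CandidateDesign]] = {}
    for cand in eligible:
        by_ancestor.setdefault(cand.ancestor_id, []).append(cand)
    for cands in by_ancestor.values():
        cands.sort(key=rank_key)
    ancestors = sorted(by_ancestor, key=lambda a: rank_key(by_ancestor[a][0]))

    selection: list[CandidateDesign] = []
    cursor = {a: 0 for a in ancestors}
    while len(selection) < config.selection_quota:
        progressed = False
        for anc in ancestors:
            if len(selection) >= config.selection_quota:
                break
            i = cursor[anc]
            if i < len(by_ancestor[anc]):
                selection.append(by_ancestor[anc][i])
                cursor[anc] = i + 1
                progressed = True
        if not progressed:
            break
    return selection


def export_report(
    selection: Sequence[CandidateDesign],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Write FASTA + TSV + run log for a ranked selection.

    The TSV carries id, ancestor, the three scores (3 decimals) and the
    constraint verdict recomputed from the stored structure.
    """
    import pandas as pd
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "selection.fasta"
    tsv_path = out_dir / "selection.tsv"
    log_path = out_dir / "run.log"

    records = [
        SeqRecord(Seq(c.sequence), id=c.id,
                  description=f"ancestor={c.ancestor_id} generation={c.generation}")
        for c in selection
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")

    rows = []
    for c in selection:
        report = inter_chain_contacts(c.structure, config.contact_cutoff)
        verdict = check_constraints(
            report,
            max_fr_contacts=config.max_fr_contacts,
            min_cdrs=config.min_cdrs,
            cdr3_required=config.cdr3_required,
        )
        rows.append({
            "id": c.id,
            "ancestor_id": c.ancestor_id,
            "generation": c.generation,
            "interaction_score": round(c.scores.interaction_score, 3),
            "interface_sa": round(c.scores.interface_sa, 3),
            "pae_interaction": round(c.scores.pae_interaction, 3),
            "verdict": "PASS" if verdict.passed else ";".join(verdict.violations),
        })
    frame = pd.DataFrame(
        rows,
        columns=["id", "ancestor_id", "generation", "interaction_score",
                 "interface_sa", "pae_interaction", "verdict"],
    )
    frame.to_csv(tsv_path, sep="\t", index=False)

    with open(log_path, "w") as fh:
        fh.write(f"selected {len(selection)} candidates\n")
        for c in selection:
            fh.write(
                f"{c.id}\tancestor={c.ancestor_id}\t"
                f"score={c.scores.interaction_score:.3f}\t"
                f"sa={c.scores.interface_sa:.3f}\tpae={c.scores.pae_interaction:.3f}\n"
            )
    return {"fasta": fasta_path, "tsv": tsv_path, "log": log_path}
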