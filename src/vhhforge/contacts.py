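"""Inter-chain contact detection and pose admissibility constraints.

A designed-chain residue is in contact with the target if any of its atoms
lies within the cutoff (default 4.0 Å, inclusive) of any target atom.  A pose
is admissible when

* at most ``max_fr_contacts`` framework residues touch the target (default 5
  — strictly more than five is discarded),
* at least ``min_cdrs`` distinct CDRs touch the target (default 2), and
* CDR3 contact is mandatory (read as: at least one CDR3 residue in contact).

All atoms participate — backbone, side chain, and hydrogens when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import CDR_TAGS, FR_TAGS, ResidueLabel, StructureComplex, StructureError

__all__ = [
    "ContactReport",
    "ConstraintVerdict",
    "DEFAULT_CONTACT_CUTOFF",
    "inter_chain_contacts",
    "check_constraints",
]

DEFAULT_CONTACT_CUTOFF = 4.0  # Å

FR_EXCESS = "FR_EXCESS"
TOO_FEW_CDRS = "TOO_FEW_CDRS"
CDR3_NOT_IN_CONTACT = "CDR3_NOT_IN_CONTACT"


@dataclass(frozen=True)
class ContactReport:
    """Residue-level inter-chain contact map plus derived counts."""

    contact_pairs: frozenset[tuple[ResidueLabel, ResidueLabel]]
    fr_contact_count: int
    contacting_cdrs: frozenset[str]
    cutoff: float


@dataclass(frozen=True)
class ConstraintVerdict:
    passed: bool
    violations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (not self.violations)


def inter_chain_contacts(
    complex: StructureComplex, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> ContactReport:
    """All residue pairs (chain A label, chain B label) within ``cutoff``.

    The bound is inclusive: a minimum inter-atomic distance of exactly the
    cutoff counts as a contact.
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    if complex.region_map is None:
        raise StructureError("contacts require a region-annotated designed chain")

    a_atoms = complex.designed_chain
    b_atoms = complex.target_chain
    a_coords = np.array([a.coords for a in a_atoms])
    b_coords = np.array([b.coords for b in b_atoms])
    tree_b = cKDTree(b_coords)
    # query_ball_point is a closed ball: distance <= cutoff.
    hits = cKDTree(a_coords).query_ball_tree(tree_b, r=cutoff)

    pairs: set[tuple[ResidueLabel, ResidueLabel]] = set()
    for i, js in enumerate(hits):
        for j in js:
            pairs.add((a_atoms[i].residue_label, b_atoms[j].residue_label))

    a_contact_labels = {p[0] for p in pairs}
    fr_count = sum(1 for lab in a_contact_labels if complex.tag_of(lab) in FR_TAGS)
    cdrs = frozenset(
        complex.tag_of(lab) for lab in a_contact_labels
        if complex.tag_of(lab) in CDR_TAGS
    )
    return ContactReport(
        contact_pairs=frozenset(pairs),
        fr_contact_count=fr_count,
        contacting_cdrs=cdrs,
        cutoff=cutoff,
    )


def check_constraints(
    report: ContactReport,
    max_fr_contacts: int = 5,
    min_cdrs: int = 2,
    cdr3_required: bool = True,
) -> ConstraintVerdict:
    """Admissibility verdict for a contact report."""
    violations: list[str] = []
    if report.fr_contact_count > max_fr_contacts:
        violations.append(FR_EXCESS)
    if len(report.contacting_cdrs) < min_cdrs:
        violations.append(TOO_FEW_CDRS)
    if cdr3_required and "CDR3" not in report.contacting_cdrs:
        violations.append(CDR3_NOT_IN_CONTACT)
    return ConstraintVerdict(passed=not violations, violations=tuple(violations))


def report_to_frame(report: ContactReport):
    """Contact pairs as a two-column DataFrame for TSV export."""
    import pandas as pd

    rows = sorted(
        ((str(a), str(b)) for a, b in report.contact_pairs),
        key=lambda t: (len(t[0]), t[0], len(t[1]), t[1]),
    )
    return pd.DataFrame(rows, columns=["designed_residue", "target_residue"])
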