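"""Built-in 4-1BB design epitopes.

Five epitopes on the human 4-1BB receptor, each defined by three surface
residues (UniProt Q07011 numbering), chosen to avoid the 4-1BBL binding
site, the C121 dimerization residue and the N138/N149 glycosylation sites.
They parameterize backbone generation against the real target and are
carried here as configuration data only.
"""

from __future__ import annotations

from .structure import EpitopeSpec

__all__ = ["FORTY_ONE_BB_EPITOPES"]

FORTY_ONE_BB_EPITOPES: tuple[EpitopeSpec, ...] = (
    EpitopeSpec(label=1, residues=("128", "129", "130")),  # Q128, K129, R130
    EpitopeSpec(label=2, residues=("80", "81", "82")),     # S80, T81, S82
    EpitopeSpec(label=3, residues=("155", "156", "157")),  # D155, V156, V157
    EpitopeSpec(label=4, residues=("107", "108", "153")),  # K107, Q108, E153
    EpitopeSpec(label=5, residues=("73", "90", "107")),    # R73, P90, K107
)
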