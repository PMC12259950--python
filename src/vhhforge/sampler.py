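"""Composition-biased CDR sequence sampling, grafting, and CDR identity.

Minimalist synthetic-library design restricts the CDR alphabet to a few
residues with fixed aggregate composition.  Two built-in design modes are
provided:

* ``cdr123-min`` — CDR1/CDR2 from {Tyr 50%, Ser 50%}; CDR3 from
  {Tyr 50%, Ser 25%, Gly 25%}.
* ``cdr12-min-3-germ`` — CDR1/CDR2 as above; CDR3 from Tyr 20%, Ser 15%,
  Gly 15% and the fifteen remaining residues (cysteine and methionine
  prohibited) sharing the remaining 50% equally (≈3.33% each).

Positions are drawn i.i.d. from the per-region table; the design gives only
aggregate composition, so no positional profile is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import CDR_TAGS, FR_TAGS, RegionMap, StructureError

__all__ = [
    "AMINO_ACIDS",
    "DesignMode",
    "CdrSet",
    "builtin_modes",
    "get_mode",
    "sample_cdr",
    "sample_cdr_set",
    "graft_cdrs",
    "extract_cdrs",
    "cdr_identity",
    "mode_from_config",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DesignMode:
    """Per-region amino-acid composition tables with prohibited sets."""

    name: str
    cdr12_table: dict[str, float]
    cdr3_table: dict[str, float]
    prohibited_cdr12: frozenset[str]
    prohibited_cdr3: frozenset[str]

    def __post_init__(self) -> None:
        for region, table, prohibited in (
            ("CDR1-2", self.cdr12_table, self.prohibited_cdr12),
            ("CDR3", self.cdr3_table, self.prohibited_cdr3),
        ):
            if any(p < 0 for p in table.values()):
                raise ValueError(f"{self.name}/{region}: negative probability")
            if abs(sum(table.values()) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}/{region}: table must sum to 1")
            if any(table.get(aa, 0.0) != 0.0 for aa in prohibited):
                raise ValueError(f"{self.name}/{region}: prohibited residue has mass")

    def table_for(self, region: str) -> dict[str, float]:
        if region in ("CDR1", "CDR2"):
            return self.cdr12_table
        if region == "CDR3":
            return self.cdr3_table
        raise ValueError(f"no composition table for region {region!r}")


@dataclass(frozen=True)
class CdrSet:
    """The three CDR sequences of one design."""

    cdr1: str
    cdr2: str
    cdr3: str

    def get(self, region: str) -> str:
        return {"CDR1": self.cdr1, "CDR2": self.cdr2, "CDR3": self.cdr3}[region]


def _mode_minimal() -> DesignMode:
    cdr12 = {"Y": 0.50, "S": 0.50}
    cdr3 = {"Y": 0.50, "S": 0.25, "G": 0.25}
    return DesignMode(
        name="cdr123-min",
        cdr12_table=cdr12,
        cdr3_table=cdr3,
        prohibited_cdr12=frozenset(set(AMINO_ACIDS) - set(cdr12)),
        prohibited_cdr3=frozenset(set(AMINO_ACIDS) - set(cdr3)),
    )


def _mode_germ() -> DesignMode:
    cdr12 = {"Y": 0.50, "S": 0.50}
    others = sorted(set(AMINO_ACIDS) - set("YSGCM"))  # 15 residues
    share = (1.0 - 0.50) / len(others)
    cdr3 = {"Y": 0.20, "S": 0.15, "G": 0.15, **{aa: share for aa in others}}
    return DesignMode(
        name="cdr12-min-3-germ",
        cdr12_table=cdr12,
        cdr3_table=cdr3,
        prohibited_cdr12=frozenset(set(AMINO_ACIDS) - set(cdr12)),
        prohibited_cdr3=frozenset("CM"),
    )


def builtin_modes() -> list[DesignMode]:
    """The two built-in composition modes."""
    return [_mode_minimal(), _mode_germ()]


def get_mode(name: str) -> DesignMode:
    for mode in builtin_modes():
        if mode.name == name:
            return mode
    raise KeyError(f"unknown design mode {name!r}")


def mode_from_config(config: dict) -> DesignMode:
    """Build a DesignMode from a config mapping (region -> residue -> percent).

    Percentages are normalized; residues absent from a region's table are
    prohibited in that region.
    """
    def table(region_cfg: dict[str, float]) -> dict[str, float]:
        total = float(sum(region_cfg.values()))
        if total <= 0:
            raise ValueError("composition table has no mass")
        return {aa: float(p) / total for aa, p in region_cfg.items()}

    cdr12 = table(config["cdr12"])
    cdr3 = table(config["cdr3"])
    return DesignMode(
        name=str(config.get("name", "custom")),
        cdr12_table=cdr12,
        cdr3_table=cdr3,
        prohibited_cdr12=frozenset(set(AMINO_ACIDS) - set(cdr12)),
        prohibited_cdr3=frozenset(set(AMINO_ACIDS) - set(cdr3)),
    )


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_cdr(mode: DesignMode, region: str, length: int, rng_seed) -> str:
    """Sample a CDR sequence of ``length`` i.i.d. positions for ``region``.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``;
    a fixed integer seed reproduces the same string.
    """
    if region not in CDR_TAGS:
        raise ValueError(f"sampling is defined for CDR regions only, got {region!r}")
    if length < 1:
        raise ValueError("length must be at least 1")
    table = mode.table_for(region)
    letters = sorted(table)
    probs = np.array([table[aa] for aa in letters])
    rng = _as_rng(rng_seed)
    draws = rng.choice(len(letters), size=length, p=probs)
    return "".join(letters[i] for i in draws)


def sample_cdr_set(
    mode: DesignMode, region_map: RegionMap, rng_seed, cdr3_length: int | None = None
) -> CdrSet:
    """Sample all three CDRs with lengths taken from the region map.

    The map fixes all lengths; ``cdr3_length`` may override CDR3 only when it
    matches the map (kept as an explicit argument for custom maps).
    """
    rng = _as_rng(rng_seed)
    lengths = region_map.cdr_lengths()
    n3 = cdr3_length if cdr3_length is not None else lengths["CDR3"]
    return CdrSet(
        cdr1=sample_cdr(mode, "CDR1", lengths["CDR1"], rng),
        cdr2=sample_cdr(mode, "CDR2", lengths["CDR2"], rng),
        cdr3=sample_cdr(mode, "CDR3", n3, rng),
    )


def graft_cdrs(framework: str, cdrs: CdrSet, region_map: RegionMap) -> str:
    """Replace CDR positions of a full annotated sequence, keeping FRs fixed.

    ``framework`` is the full designed-chain sequence in region-map order.
    Framework positions in the output are byte-identical to the input.
    """
    labels = region_map.labels
    if len(framework) != len(labels):
        raise StructureError(
            f"framework length {len(framework)} != region map length {len(labels)}"
        )
    for tag in ("CDR1", "CDR2", "CDR3"):
        seg = region_map.segment(tag)
        if len(cdrs.get(tag)) != len(seg):
            raise StructureError(
                f"{tag}: sequence length {len(cdrs.get(tag))} != segment length {len(seg)}"
            )
    out = list(framework)
    pos = 0
    for tag, seg in region_map.segments:
        if tag in CDR_TAGS:
            out[pos:pos + len(seg)] = cdrs.get(tag)
        pos += len(seg)
    return "".join(out)


def extract_cdrs(sequence: str, region_map: RegionMap) -> CdrSet:
    """Slice the three CDR substrings out of a full annotated sequence."""
    labels = region_map.labels
    if len(sequence) != len(labels):
        raise StructureError(
            f"sequence length {len(sequence)} != region map length {len(labels)}"
        )
    parts: dict[str, str] = {}
    pos = 0
    for tag, seg in region_map.segments:
        if tag in CDR_TAGS:
            parts[tag] = sequence[pos:pos + len(seg)]
        pos += len(seg)
    return CdrSet(cdr1=parts["CDR1"], cdr2=parts["CDR2"], cdr3=parts["CDR3"])


def cdr_identity(a: CdrSet, b: CdrSet) -> float:
    """Mean ungapped positional CDR identity, in percent.

    Per CDR: matching positions / max(len_a, len_b); averaged over the three
    CDRs and scaled to a percentage.
    """
    fractions = []
    for region in ("CDR1", "CDR2", "CDR3"):
        sa, sb = a.get(region), b.get(region)
        denom = max(len(sa), len(sb))
        if denom == 0:
            fractions.append(1.0)
            continue
        matches = sum(1 for x, y in zip(sa, sb) if x == y)
        fractions.append(matches / denom)
    return 100.0 * sum(fractions) / 3.0
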