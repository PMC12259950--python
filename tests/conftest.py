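import numpy as np
import pytest
from hypothesis import settings

from vhhforge.structure import (
    Atom,
    RegionMap,
    ResidueLabel,
    StructureComplex,
    annotate_regions,
)
from vhhforge.toyworld import ToySpec, make_toy_complex

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_atom(serial, coords, radius=1.7, label="1", chain="A",
              res_name="GLY", name="CA", element="C"):
    return Atom(
        serial=serial,
        element=element,
        coords=tuple(float(x) for x in coords),
        radius=radius,
        residue_label=ResidueLabel.parse(label),
        residue_name=res_name,
        chain_id=chain,
        name=name,
    )


def make_mini_complex(a_residues, b_coords, b_radius=1.7):
    """Small annotated two-chain complex for geometry tests.

    ``a_residues``: iterable of (label, region_tag, coords[, radius]); tags
    must appear grouped (consecutive residues with the same tag form one
    segment) and must include all three CDRs.
    ``b_coords``: iterable of target-atom coordinates, one residue per atom.
    """
    atoms_a, segments = [], []
    serial = 0
    for entry in a_residues:
        label, tag, coords = entry[0], entry[1], entry[2]
        radius = entry[3] if len(entry) > 3 else 1.7
        serial += 1
        atoms_a.append(make_atom(serial, coords, radius=radius, label=label))
        if segments and segments[-1][0] == tag:
            segments[-1][1].append(label)
        else:
            segments.append((tag, [label]))
    atoms_b = []
    for i, coords in enumerate(b_coords, start=1):
        serial += 1
        atoms_b.append(make_atom(serial, coords, radius=b_radius,
                                 label=str(i), chain="B"))
    region_map = RegionMap.from_segments(segments)
    cx = StructureComplex(tuple(atoms_a), tuple(atoms_b))
    return annotate_regions(cx, region_map)


# a_residues template covering all seven regions with one residue each,
# placed far from any target atom unless a test overrides coordinates
def far_template():
    return [
        ("1", "FR1", (0.0, 100.0, 0.0)),
        ("2", "CDR1", (5.0, 100.0, 0.0)),
        ("3", "FR2", (10.0, 100.0, 0.0)),
        ("4", "CDR2", (15.0, 100.0, 0.0)),
        ("5", "FR3", (20.0, 100.0, 0.0)),
        ("6", "CDR3", (25.0, 100.0, 0.0)),
        ("7", "FR4", (30.0, 100.0, 0.0)),
    ]


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec()


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    return make_toy_complex(toy_spec)
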