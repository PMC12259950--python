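"""Surrogate backends: scoring formulas, structure model, contracts."""

import json
import sys
from dataclasses import replace

import numpy as np
import pytest

from vhhforge.backends import (
    AA_SIDECHAIN_RADII,
    SIDECHAIN_ATOM_NAME,
    ReplayScorer,
    ScoreRecord,
    SubprocessScorer,
    SurrogateProposer,
    SurrogateScorer,
    SurrogateUpdater,
    surrogate_interaction_score,
    surrogate_pae,
    surrogate_structure_update,
)
from vhhforge.sasa import interface_sa
from vhhforge.structure import StructureComplex, StructureError, chain_sequence

from conftest import far_template, make_mini_complex


def complex_with_cdr3_contacts(n):
    """Mini complex with exactly n CDR3 residues 3.0 A above n target atoms."""
    template = far_template()
    extra = [(f"6{chr(ord('a') + i)}", "CDR3", (30.0 + 8.0 * i, 0.0, 3.0))
             for i in range(n)]
    out = template[:6] + extra + template[6:]
    b = [(30.0 + 8.0 * i, 0.0, 0.0) for i in range(n)]
    return make_mini_complex(out, b or [(0.0, 0.0, 0.0)])


class TestInteractionScore:
    def test_no_pairs_scores_zero(self):
        cx = make_mini_complex(far_template(), [(0.0, 0.0, 0.0)])
        assert surrogate_interaction_score(cx) == 0.0

    def test_three_contacts_no_clash(self):
        cx = complex_with_cdr3_contacts(3)
        assert surrogate_interaction_score(cx) == -3.0

    def test_clash_penalty_dominates(self):
        template = far_template()
        template[5] = ("6", "CDR3", (0.0, 0.0, 2.0))
        cx = make_mini_complex(template, [(0.0, 0.0, 0.0)])
        assert surrogate_interaction_score(cx) == pytest.approx(-1.0 + 10.0)

    def test_clash_cutoff_is_strict(self):
        template = far_template()
        template[5] = ("6", "CDR3", (0.0, 0.0, 2.5))
        cx = make_mini_complex(template, [(0.0, 0.0, 0.0)])
        assert surrogate_interaction_score(cx) == -1.0

    def test_permutation_of_atom_order_is_irrelevant(self, toy_complex):
        rng = np.random.default_rng(3)
        perm_a = tuple(np.array(toy_complex.designed_chain, dtype=object)[
            rng.permutation(len(toy_complex.designed_chain))])
        perm_b = tuple(np.array(toy_complex.target_chain, dtype=object)[
            rng.permutation(len(toy_complex.target_chain))])
        shuffled = StructureComplex(perm_a, perm_b, toy_complex.region_map)
        assert surrogate_interaction_score(shuffled) == surrogate_interaction_score(toy_complex)
        assert surrogate_pae(shuffled) == surrogate_pae(toy_complex)


class TestPae:
    def test_no_contacts_gives_max(self):
        cx = make_mini_complex(far_template(), [(0.0, 0.0, 0.0)])
        assert surrogate_pae(cx) == 30.0

    def test_ten_pairs(self):
        assert surrogate_pae(complex_with_cdr3_contacts(10)) == 10.0

    def test_fifteen_pairs_clamps_to_one(self):
        assert surrogate_pae(complex_with_cdr3_contacts(15)) == 1.0


class TestStructureUpdate:
    def test_same_sequence_is_identity(self, toy_complex):
        seq = chain_sequence(toy_complex)
        updated = surrogate_structure_update(toy_complex, seq)
        assert updated.designed_chain == toy_complex.designed_chain

    def test_growing_residue_increases_sidechain_radius(self, toy_complex):
        seq = chain_sequence(toy_complex)
        labels = toy_complex.designed_labels()
        pos = next(i for i, lab in enumerate(labels)
                   if toy_complex.tag_of(lab) == "CDR3")
        small = seq[:pos] + "G" + seq[pos + 1:]
        big = seq[:pos] + "W" + seq[pos + 1:]
        cx_small = surrogate_structure_update(toy_complex, small)
        cx_big = surrogate_structure_update(toy_complex, big)
        label = labels[pos]

        def sc_radius(cx):
            return next(a.radius for a in cx.designed_chain
                        if a.residue_label == label and a.name == SIDECHAIN_ATOM_NAME)

        assert sc_radius(cx_big) > sc_radius(cx_small)
        assert sc_radius(cx_big) == AA_SIDECHAIN_RADII["W"]
        # backbone untouched
        assert all(a.coords == b.coords for a, b in
                   zip(cx_big.designed_chain, toy_complex.designed_chain))

    def test_framework_substitution_rejected(self, toy_complex):
        seq = chain_sequence(toy_complex)
        mutated = ("W" if seq[0] != "W" else "A") + seq[1:]
        with pytest.raises(StructureError, match="immutable"):
            surrogate_structure_update(toy_complex, mutated)

    def test_length_mismatch_rejected(self, toy_complex):
        with pytest.raises(StructureError, match="length"):
            surrogate_structure_update(toy_complex, "ACD")

    @pytest.mark.parametrize("tag", ["CDR1", "CDR2", "CDR3"])
    def test_growing_contact_facing_radius_never_shrinks_interface(self, toy_complex, tag):
        seq = chain_sequence(toy_complex)
        labels = toy_complex.designed_labels()
        pos = next(i for i, lab in enumerate(labels) if toy_complex.tag_of(lab) == tag)
        small = surrogate_structure_update(toy_complex, seq[:pos] + "S" + seq[pos + 1:])
        big = surrogate_structure_update(toy_complex, seq[:pos] + "Y" + seq[pos + 1:])
        sa_small = interface_sa(small, n_points=240).sa_interface
        sa_big = interface_sa(big, n_points=240).sa_interface
        assert sa_big >= sa_small


class TestScoreRecord:
    def test_pae_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ScoreRecord(interaction_score=0.0, interface_sa=0.0, pae_interaction=31.0)

    def test_interface_sa_below_tolerance_rejected(self):
        with pytest.raises(ValueError):
            ScoreRecord(interaction_score=0.0, interface_sa=-1.0, pae_interaction=10.0)


class TestBackendContracts:
    def test_replay_scorer_returns_recorded_records(self, toy_complex):
        records = [
            ScoreRecord(-5.0, 100.0, 8.0),
            ScoreRecord(-6.0, 110.0, 7.0),
        ]
        scorer = ReplayScorer(records)
        assert scorer.score(toy_complex) == records[0]
        assert scorer.score(toy_complex) == records[1]
        with pytest.raises(RuntimeError):
            scorer.score(toy_complex)

    def test_subprocess_scorer_exchange_schema(self, toy_complex, tmp_path):
        script = (
            "import json,sys;"
            "req=json.load(sys.stdin);"
            "assert req['stage']=='scorer' and req['pdb_path'];"
            "print(json.dumps({'interaction_score':-42.0,"
            "'interface_sa':1234.5,'pae_interaction':3.0}))"
        )
        scorer = SubprocessScorer(command=[sys.executable, "-c", script],
                                  workdir=tmp_path)
        rec = scorer.score(toy_complex)
        assert rec == ScoreRecord(-42.0, 1234.5, 3.0)
        assert (tmp_path / "request.pdb").exists()

    def test_surrogate_proposer_keeps_framework(self, toy_complex):
        from vhhforge.sampler import get_mode

        proposer = SurrogateProposer(get_mode("cdr123-min"), toy_complex.region_map)
        seq = chain_sequence(toy_complex)
        proposed = proposer.propose(seq, np.random.default_rng(0))
        rm = toy_complex.region_map
        pos = 0
        for tag, seg in rm.segments:
            if tag.startswith("FR"):
                assert proposed[pos:pos + len(seg)] == seq[pos:pos + len(seg)]
            pos += len(seg)

    def test_surrogate_scorer_caches_target_term(self, toy_complex):
        scorer = SurrogateScorer(n_points=240)
        first = scorer.score(toy_complex)
        again = scorer.score(toy_complex)
        assert first == again
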