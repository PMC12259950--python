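# vhhforge

Desk-scale framework for two-step generative design of nanobody (VHH) CDR
loops against a target receptor: composition-biased CDR sequence sampling, a
buried-interface-area objective computed with a from-scratch Shrake–Rupley
SASA, contact-based admissibility constraints, and a stack-sorted iterative
hill-climbing optimizer.

## The problem

De novo binder design pipelines couple generative backbone models
(RFdiffusion), inverse folding (ProteinMPNN), structure prediction
(AlphaFold2) and physics-based scoring (Rosetta) into a campaign that
proposes CDR loops on a fixed VHH framework, filters weak binders, and
iteratively refines the survivors. Those external stages need GPUs and
licensed toolchains; the *control logic* around them — what to sample, what
to keep, what "better" means, when to stop — is where most of the design
decisions live. `vhhforge` implements that control logic as a reusable,
fully tested library, with the external stages abstracted behind backend
contracts and replaced by deterministic in-repo surrogates so every stage
runs and is testable on one CPU with no downloads.

The designed chain is a VHH scaffold (chain A) whose framework regions
(FR1–FR4, Kabat numbering) are immutable; only the three CDR loops are
designed (CDR1 = Kabat 27–33, 7 positions; CDR2 = the 52a–57 block,
7 positions; CDR3 = 95–99 plus insertions, 6–12 positions). The target
(chain B) is a receptor with a chosen three-residue epitope.

## The method

**Sampling.** CDR positions are drawn i.i.d. from per-region amino-acid
composition tables. Two built-in modes:

| mode | CDR1/2 | CDR3 |
|---|---|---|
| `cdr123-min` | Tyr 50%, Ser 50% | Tyr 50%, Ser 25%, Gly 25% |
| `cdr12-min-3-germ` | Tyr 50%, Ser 50% | Tyr 20%, Ser 15%, Gly 15%, 15 others ≈3.33% each (no Cys/Met) |

**Objective.** The buried interface area

```
SA_interface = SA_VHH + SA_target − SA_complex
```

with each term a Shrake–Rupley solvent-accessible surface area (probe
1.4 Å, 960 lattice points per atom). Areas are evaluated in a canonical
molecular frame, so they are exactly invariant under rigid motion, and the
interface of two non-interacting chains is exactly zero.

**Constraints.** A residue contacts the other chain if any of its atoms is
within 4.0 Å (inclusive) of any atom of that chain. A pose is admissible iff
at most 5 framework residues contact the target, at least 2 CDRs contact the
target, and CDR3 contact is mandatory.

**Optimization (Step 2).** Per Step-1 root, candidates sit on a stack sorted
by SA_interface (descending). Each of up to 50 cycles takes the top-ranked
candidate and makes 16 attempts: resample the CDRs, rebuild the structure,
rescore. A proposal is pushed onto the stack iff its SA_interface strictly
exceeds its predecessor's and the pose is admissible; the predecessor stays
on the stack.

**Gates.** Step 1 → Step 2: PAE_interaction < 10 and interaction score
< −20 REU (strict). Final selection: score < −40 REU, then a round-robin
across Step-1 ancestors so the selection descends from as many distinct
roots as possible.

## Worked example

```python
import numpy as np
from vhhforge import (
    ToySpec, make_toy_complex, make_toy_roots, get_mode,
    PipelineConfig, step1_filter, run_step2, final_select,
    SurrogateProposer, SurrogateScorer, interface_sa, inter_chain_contacts,
)
from vhhforge.backends import SurrogateUpdater

spec = ToySpec()                      # deterministic synthetic complex, seed 42
cx = make_toy_complex(spec)
print(round(interface_sa(cx).sa_interface, 1))   # 904.2  (Å², scaffold pose)

rep = inter_chain_contacts(cx)
print(len(rep.contact_pairs), rep.fr_contact_count, sorted(rep.contacting_cdrs))
# 120 0 ['CDR1', 'CDR2', 'CDR3']     -> admissible starting pose

mode = get_mode("cdr123-min")
roots = make_toy_roots(spec, 2, mode)
config = PipelineConfig(max_cycles=5, attempts_per_cycle=8, rng_seed=42)
kept = step1_filter(roots, config)               # both roots pass the gates
pool = run_step2(kept, SurrogateProposer(mode, cx.region_map),
                 SurrogateUpdater(), SurrogateScorer(), config)
print(len(pool))                                  # 7
print(round(np.median([r.scores.interface_sa for r in roots]), 1))  # 1008.9
print(round(np.median([c.scores.interface_sa for c in pool]), 1))   # 1031.5
```

The optimizer accepted five variants across the two roots; the pool's median
buried interface grew from 1008.9 to 1031.5 Å². `final_select` then ranks
the pool (here all surrogate scores are −120.0 REU, well below the −40 REU
gate, so ties break on interface area) and `export_report` writes FASTA,
TSV and a run log.

The same workflow is available from the shell:

```bash
vhhforge toy --out run/ --n-roots 4 --seed 42
vhhforge filter run/roots.tsv --complex run/complex.pdb --out run/kept.tsv
vhhforge optimize run/kept.tsv --complex run/complex.pdb --out run/pool.tsv --seed 42
vhhforge select run/pool.tsv --complex run/complex.pdb --out run/selection.tsv
vhhforge report run/selection.tsv --complex run/complex.pdb --out run/report/
```

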