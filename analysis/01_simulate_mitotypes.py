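#!/usr/bin/env python
"""Simulate a six-mitotype panel with a known evolutionary history.

Emulates the proposed formation mechanism for a clade of plant
mitochondrial genomes: all six circles descend from one ancestral master
circle; one pair stays near-identical (inheritance with a handful of
substitutions), one genome carries a large segmental duplication, and the
rest diverge through rearrangement, indels and mutation.  The panel
(FASTA), the per-branch truth logs (JSON) and the generating topology
(newick) go to results/simulated/.
"""

import json
from pathlib import Path

from mitocmp import simulate_clade, write_fasta

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 11

TOPOLOGY = ((("m1", "m2"), "m3"), ("m4", ("m5", "m6")))

BRANCH_EVENTS = {
    # near-identical pair: inheritance with a few substitutions
    "m1": [],
    "m2": [{"kind": "substitution_batch", "params": {"count": 8}}],
    # moderately diverged relative with a deletion
    "m3": [
        {"kind": "substitution_batch", "params": {"count": 120}},
        {"kind": "deletion", "params": {"length": 900}},
    ],
    # a large duplication (multipartite-relevant large direct repeat)
    "m4": [
        {"kind": "duplication", "params": {"length": 6000}},
        {"kind": "substitution_batch", "params": {"count": 150}},
    ],
    # rearranged + compacted genomes
    "m5": [
        {"kind": "inversion", "params": {"length": 8000}},
        {"kind": "substitution_batch", "params": {"count": 250}},
    ],
    "m6": [
        {"kind": "translocation", "params": {"length": 5000}},
        {"kind": "deletion", "params": {"length": 1500}},
        {"kind": "insertion", "params": {"length": 2000}},
        {"kind": "substitution_batch", "params": {"count": 300}},
    ],
}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    leaves, newick, logs = simulate_clade(
        TOPOLOGY,
        branch_events=BRANCH_EVENTS,
        seed=SEED,
        root_kwargs={
            "length": 60000,
            "n_genes": 12,
            "repeat_spec": [(2400, 2, "direct"), (100, 2, "direct")],
            "orf_codon_counts": [110, 130, 160],
            "seed": SEED,
        },
    )
    write_fasta(leaves, OUT / "panel.fasta")
    (OUT / "truth_tree.nwk").write_text(newick + "\n")
    (OUT / "truth_logs.json").write_text(
        json.dumps({k: json.loads(v.to_json()) for k, v in logs.items()}, indent=1)
    )
    print(f"panel: {[g.id for g in leaves]} -> {OUT / 'panel.fasta'}")
    print(f"truth topology: {newick}")
    print("lengths:", {g.id: g.length for g in leaves})


if __name__ == "__main__":
    main()
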