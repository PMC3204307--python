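"""Multipartite-structure prediction from large repeat pairs.

Reversible homologous recombination across a *direct* repeat pair splits
the master circle into two subgenomic circles, each carrying one repeat
copy and one inter-repeat arc: with arcs a1, a2 and repeat length r,

    s1 = a1 + r,  s2 = a2 + r,  s1 + s2 = master length.

An inverted pair cannot resolve the circle into subcircles — recombination
across it only flips the intervening arc, yielding an isomeric master
circle — so such predictions are reported infeasible.  Genomes with more
than one direct pair admit many coexisting forms; they are flagged
combinatorially complex and no joint prediction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import CircularGenome
from .repeats import RepeatPair

__all__ = ["SubgenomeStructure", "StructureSet", "predict_subgenomes", "enumerate_structures"]


@dataclass(frozen=True)
class SubgenomeStructure:
    master_length: int
    repeat: RepeatPair
    subcircle_lengths: tuple[int, int]
    feasible: bool


@dataclass(frozen=True)
class StructureSet:
    structures: tuple[SubgenomeStructure, ...]
    combinatorially_complex: bool


def predict_subgenomes(g: CircularGenome, pair: RepeatPair) -> SubgenomeStructure:
    """Subgenomic circle sizes implied by one repeat pair on the master.

    For a near-identical pair the crossover is taken at the midpoint of
    each occurrence; the resulting sizes do not depend on the crossover
    position within the repeat.  Overlapping occurrences are an error.
    """
    L = g.length
    (s1, l1, _), (s2, l2, _) = pair.occ1, pair.occ2
    off = (s2 - s1) % L
    if off < l1 or (L - off) < l2:
        raise ValueError("repeat occurrences overlap; no subcircle geometry")
    if pair.orientation != "direct":
        return SubgenomeStructure(L, pair, (0, 0), feasible=False)
    r = (l1 + l2) // 2  # midpoint crossover for near-identical copies
    arc1 = (s2 - (s1 + l1)) % L
    arc2 = (s1 - (s2 + l2)) % L
    sub1 = arc1 + r
    sub2 = arc2 + r
    # rounding guard: conserve total length exactly
    sub2 = L - sub1
    return SubgenomeStructure(L, pair, (sub1, sub2), feasible=True)


def enumerate_structures(g: CircularGenome, pairs) -> StructureSet:
    """One independent prediction per direct pair.

    With more than one direct pair the genome's multipartite structure is
    combinatorially complex and no joint prediction is made (the per-pair
    predictions are still listed).
    """
    structures = tuple(
        predict_subgenomes(g, p) for p in pairs if p.orientation == "direct"
    )
    return StructureSet(
        structures=structures, combinatorially_complex=len(structures) > 1
    )
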