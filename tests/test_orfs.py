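"""ORF finding, grouping, and evolutionary classification."""

import dataclasses

import numpy as np
import pytest

from mitocmp import (
    CircularGenome,
    apply_events,
    classify_mutation_sites,
    classify_polymorphic_orfs,
    extract_indels,
    find_orfs,
    find_synteny_blocks,
    group_orfs,
    generate_ancestor,
)
from oracles import brute_orfs, hamming_identity


class TestFindOrfs:
    def test_no_atg_background_empty(self):
        g = CircularGenome("x", "AAC" * 134)
        assert find_orfs(g) == []

    def test_implanted_orf_found_with_exact_codon_count(self):
        g = generate_ancestor(8000, orf_codon_counts=[100], seed=2)
        orfs = find_orfs(g, min_codons=100)
        assert len(orfs) == 1
        (o,) = orfs
        assert o.n_codons == 100
        assert o.nt_seq.startswith("ATG")
        stop = g.fetch(o.start, o.end, o.strand)[-3:]
        assert stop in ("TAA", "TAG", "TGA")

    def test_min_codons_threshold(self):
        g = generate_ancestor(8000, orf_codon_counts=[100], seed=2)
        assert find_orfs(g, min_codons=101) == []

    def test_origin_spanning_orf_reported_once(self):
        g = generate_ancestor(8000, orf_codon_counts=[100], seed=2)
        (o,) = find_orfs(g)
        rot = g.rotated((o.start + 150) % g.length)
        orfs_r = find_orfs(rot)
        assert len(orfs_r) == 1
        assert orfs_r[0].end > rot.length  # wraps the origin
        assert orfs_r[0].nt_seq == o.nt_seq

    @pytest.mark.parametrize("seed", [41, 42, 43])
    def test_six_frame_oracle_equivalence(self, seed):
        g = generate_ancestor(1500, orf_codon_counts=[25, 30], seed=seed)
        mine = {
            (o.start % g.length, o.length, o.strand)
            for o in find_orfs(g, min_codons=20)
        }
        assert mine == brute_orfs(g.seq, min_codons=20)

    def test_rotation_equivariance(self):
        g = generate_ancestor(3000, orf_codon_counts=[30], seed=44)
        base = find_orfs(g, min_codons=20)
        off = 1234
        rot = find_orfs(g.rotated(off), min_codons=20)
        remapped = {((o.start + off) % g.length, o.length, o.strand) for o in rot}
        assert {(o.start % g.length, o.length, o.strand) for o in base} == remapped


class TestGroupOrfs:
    def _two_genomes_same_orf(self):
        # seed chosen so the implant is the only >=100-codon ORF
        g1 = generate_ancestor(6000, orf_codon_counts=[110], seed=1)
        g2 = CircularGenome("g2", g1.seq)
        c2 = [dataclasses.replace(o, genome_id="g2") for o in find_orfs(g2)]
        return find_orfs(g1), c2

    def test_identical_orf_one_group(self):
        c1, c2 = self._two_genomes_same_orf()
        groups = group_orfs([c1, c2])
        assert len(groups) == 1
        assert len(groups[0].shared_by) == 2

    def test_sixty_percent_identity_two_groups(self):
        c1, _ = self._two_genomes_same_orf()
        (o,) = c1
        rng = np.random.default_rng(0)
        nt = list(o.nt_seq)
        # mutate 40% of positions (keeping ATG start, no new stops needed:
        # grouping is nucleotide-level on the stored sequences)
        idx = rng.choice(np.arange(3, len(nt)), size=int(0.4 * len(nt)), replace=False)
        for i in idx:
            nt[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[nt[i]]
        mutated = dataclasses.replace(o, genome_id="g2", nt_seq="".join(nt))
        assert hamming_identity(o.nt_seq, mutated.nt_seq) < 0.65
        groups = group_orfs([[o], [mutated]])
        assert len(groups) == 2

    def test_shared_group_count_matches_implants(self):
        genomes = []
        base = generate_ancestor(12000, orf_codon_counts=[100, 120, 140], seed=1)
        for i in range(6):
            genomes.append(CircularGenome(f"m{i}", base.seq))
        cats = [
            [dataclasses.replace(o, genome_id=g.id) for o in find_orfs(g)]
            for g in genomes
        ]
        groups = group_orfs(cats)
        shared = [g for g in groups if len(g.shared_by) == 6]
        assert len(shared) == 3

    def test_group_ids_deterministic(self):
        c1, c2 = self._two_genomes_same_orf()
        g1 = group_orfs([c1, c2])
        g2 = group_orfs([c1, c2])
        assert [g.group_id for g in g1] == [g.group_id for g in g2]


def _panel_with_event(event, seed, orf_codons=(120,), length=20000):
    """Parent with implanted ORF(s) + child modified by one event."""
    parent = generate_ancestor(length, orf_codon_counts=list(orf_codons), seed=seed)
    child, log = apply_events(parent, [event], seed=seed + 1, child_id="child")
    return parent, child, log


def _classify(parent, child):
    cats = [find_orfs(parent), find_orfs(child)]
    groups = group_orfs(cats)
    blocks = find_synteny_blocks(parent, child)
    indels = extract_indels(parent, child, blocks)
    pair = (parent.id, child.id)
    calls = classify_polymorphic_orfs(
        groups,
        {pair: blocks},
        {pair: indels},
        [parent.id, child.id],
        {parent.id: parent.length, child.id: child.length},
    )
    return groups, calls


class TestClassifyPolymorphic:
    def test_untouched_orf_is_shared(self):
        parent, child, _ = _panel_with_event(
            {"kind": "substitution_batch", "params": {"count": 0}}, seed=102
        )
        groups, calls = _classify(parent, child)
        assert {c.cls for c in calls} == {"SHARED"}

    def test_inversion_breakpoint_inside_orf_is_GR(self):
        parent = generate_ancestor(20000, orf_codon_counts=[120], seed=102)
        s, e, _ = parent.annotations[0].intervals[0]
        mid = (s + e) // 2
        child, _ = apply_events(
            parent,
            [{"kind": "inversion", "params": {"start": mid, "length": 4000}}],
            seed=9,
            child_id="child",
        )
        groups, calls = _classify(parent, child)
        poly = [c for c in calls if c.cls != "SHARED"]
        # the break both destroys the parental ORF and generates a novel
        # chimeric ORF in the child; both trace to the rearrangement
        assert poly and all(c.cls == "GR" for c in poly)
        assert all(c.evidence for c in poly)

    def test_deletion_covering_orf_is_ID(self):
        parent = generate_ancestor(20000, orf_codon_counts=[150], seed=102)
        s, e, _ = parent.annotations[0].intervals[0]
        child, _ = apply_events(
            parent,
            [{"kind": "deletion", "params": {"start": s - 50, "length": (e - s) + 100}}],
            seed=11,
            child_id="child",
        )
        groups, calls = _classify(parent, child)
        poly = [c for c in calls if c.cls != "SHARED"]
        assert len(poly) == 1 and poly[0].cls == "ID"

    def test_internal_stop_substitution_is_M(self):
        parent = generate_ancestor(20000, orf_codon_counts=[150], seed=102)
        (o,) = find_orfs(parent)
        # find a position whose substitution creates an in-frame stop
        pos_alt = None
        for ci in range(2, o.n_codons - 2):
            codon = o.nt_seq[3 * ci : 3 * ci + 3]
            for alt, stop in (("T", "TAA"), ("T", "TAG"), ("T", "TGA")):
                if codon[1:] == stop[1:] and codon[0] != stop[0]:
                    pos_alt = (3 * ci, stop[0])
                    break
            if pos_alt:
                break
        assert pos_alt is not None
        off, alt = pos_alt
        gpos = (o.start + off) % parent.length if o.strand == "+" else None
        assert o.strand == "+" or gpos is not None
        child, _ = apply_events(
            parent,
            [
                {
                    "kind": "substitution_batch",
                    "params": {"positions": [gpos], "count": 1, "to": [alt]},
                }
            ],
            seed=13,
            child_id="child",
        )
        groups, calls = _classify(parent, child)
        poly = [c for c in calls if c.cls != "SHARED"]
        assert len(poly) == 1 and poly[0].cls == "M"

    def test_unknown_genome_errors(self):
        parent, child, _ = _panel_with_event(
            {"kind": "substitution_batch", "params": {"count": 0}}, seed=102
        )
        groups = group_orfs([find_orfs(parent)])
        with pytest.raises(ValueError):
            classify_polymorphic_orfs(groups, {}, {}, ["nobody"], {"nobody": 1})


class TestMutationSites:
    def _group_with_member(self, mutate):
        g = generate_ancestor(6000, orf_codon_counts=[110], seed=1)
        (o,) = find_orfs(g)
        m = dataclasses.replace(o, genome_id="g2", nt_seq=mutate(o.nt_seq))
        return group_orfs([[o], [m]])[0]

    def test_inframe_6bp_insertion_is_triplet_indel(self):
        grp = self._group_with_member(lambda nt: nt[:150] + "GCTGCT" + nt[150:])
        sites = classify_mutation_sites(grp)
        assert [(s.kind, s.indel_length) for s in sites] == [("triplet_indel", 6)]

    def test_2bp_deletion_is_non_triplet(self):
        grp = self._group_with_member(lambda nt: nt[:100] + nt[102:])
        sites = classify_mutation_sites(grp)
        assert [(s.kind, s.indel_length) for s in sites] == [("non_triplet_indel", 2)]

    def test_large_inframe_indel_outside_typology(self):
        grp = self._group_with_member(lambda nt: nt[:99] + nt[99 + 60 :])
        sites = classify_mutation_sites(grp)
        assert [(s.kind, s.indel_length) for s in sites] == [("large_indel", 60)]

    def test_substitution_to_stop_is_premature(self):
        def mutate(nt):
            # hunt a codon one substitution away from TAA
            for ci in range(2, len(nt) // 3 - 2):
                c = nt[3 * ci : 3 * ci + 3]
                if c[1:] == "AA" and c[0] != "T":
                    return nt[: 3 * ci] + "T" + nt[3 * ci + 1 :]
            raise AssertionError("no candidate codon")

        grp = self._group_with_member(mutate)
        sites = classify_mutation_sites(grp)
        assert [s.kind for s in sites] == ["premature_stop"]

    def test_plain_substitution_is_frame_preserving(self):
        def mutate(nt):
            for ci in range(2, len(nt) // 3 - 2):
                c = nt[3 * ci : 3 * ci + 3]
                alt = "C" if c[0] != "C" else "G"
                cand = alt + c[1:]
                if cand not in ("TAA", "TAG", "TGA"):
                    return nt[: 3 * ci] + cand + nt[3 * ci + 3 :]
            raise AssertionError

        grp = self._group_with_member(mutate)
        sites = classify_mutation_sites(grp)
        assert [s.kind for s in sites] == ["frame_preserving"]

    def test_single_member_group_errors(self):
        g = generate_ancestor(6000, orf_codon_counts=[110], seed=1)
        grp = group_orfs([find_orfs(g)])[0]
        with pytest.raises(ValueError):
            classify_mutation_sites(grp)
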