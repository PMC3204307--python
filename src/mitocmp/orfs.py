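"""ORF prediction, cross-genome grouping and evolutionary classification.

ORF convention: per strand and frame, each stop-to-stop segment contributes
the ORF running from its first ATG to the stop; nested ATGs are not
reported.  ``n_codons`` counts the start codon and excludes the stop, and
only ORFs of at least ``min_codons`` (default 100) are kept.  Circularity:
the scan runs on the doubled sequence, so origin-spanning ORFs are found
once, with a wrapped interval.

Grouping follows the homology convention used for unknown-function ORF
inventories: two ORFs belong together when their nucleotide identity is at
least 70% over at least 80% of the shorter ORF (single linkage).  A group
present in complete form in every genome is SHARED; otherwise its
polymorphism is attributed, in order of precedence, to genome rearrangement
(a synteny-block boundary inside the locus), to an indel covering or
disrupting the locus, or to nucleotide mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .core import CircularGenome, revcomp

__all__ = [
    "OrfRecord",
    "OrfGroup",
    "PolymorphicOrfCall",
    "MutationSite",
    "find_orfs",
    "group_orfs",
    "classify_polymorphic_orfs",
    "classify_mutation_sites",
]

STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfRecord:
    genome_id: str
    start: int  # 0-based on the genome's linearization
    end: int  # half-open; may exceed genome length when wrapping the origin
    strand: str
    n_codons: int
    nt_seq: str
    aa_seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrfGroup:
    group_id: str
    members: list[OrfRecord]
    representative: OrfRecord

    @property
    def shared_by(self) -> frozenset:
        return frozenset(m.genome_id for m in self.members)


@dataclass(frozen=True)
class PolymorphicOrfCall:
    group_id: str
    cls: str  # GR | ID | M | SHARED
    evidence: tuple = ()


@dataclass(frozen=True)
class MutationSite:
    group_id: str
    position: int  # in representative ORF coordinates
    kind: str  # frame_preserving | premature_stop | triplet_indel | non_triplet_indel | large_indel
    indel_length: int = 0


def find_orfs(g: CircularGenome, min_codons: int = 100) -> list[OrfRecord]:
    """Six-frame circular ORF scan; first-ATG per stop-to-stop segment."""
    L = g.length
    if L < 3:
        return []
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        seq = g.seq if strand == "+" else revcomp(g.seq)
        s2 = seq + seq
        for frame in range(3):
            prev_stop_end = frame  # scan start of current stop-to-stop segment
            first_atg = None
            for i in range(frame, len(s2) - 2, 3):
                codon = s2[i : i + 3]
                if codon == "ATG" and first_atg is None:
                    first_atg = i
                if codon in STOPS:
                    if first_atg is not None and first_atg < L:
                        out.append(
                            _make_orf(g, strand, first_atg, i, L, min_codons)
                        )
                    first_atg = None
                    prev_stop_end = i + 3
                if i >= 2 * L and first_atg is None:
                    break
    records = [o for o in out if o is not None]
    # Per stop-to-stop segment only the first ATG counts.  A segment that
    # wraps the origin is scanned twice (once from the linearization start
    # without its upstream context, once in the doubled region), which can
    # emit a shorter suffix ORF sharing the stop of the true ORF: keep only
    # the longest ORF per (stop position, strand).
    best: dict[tuple, OrfRecord] = {}
    for o in records:
        stop_pos = (o.start + o.length - 3) % g.length if o.strand == "+" else o.start % g.length
        key = (stop_pos, o.strand)
        if key not in best or o.n_codons > best[key].n_codons:
            best[key] = o
    return sorted(best.values(), key=lambda r: (r.start % g.length, r.strand))


def _make_orf(g, strand, atg, stop_start, L, min_codons):
    n_codons = (stop_start - atg) // 3
    if n_codons < min_codons or (stop_start + 3 - atg) > L:
        return None
    seq = g.seq if strand == "+" else revcomp(g.seq)
    s2 = seq + seq
    nt = s2[atg:stop_start]
    aa = str(Seq(nt).translate())
    if strand == "+":
        start, end = atg, stop_start + 3
    else:
        # map [atg, stop_start+3) on the reverse strand back to forward coords
        end_f = 2 * L - atg
        start_f = 2 * L - (stop_start + 3)
        start, end = start_f % L, start_f % L + (end_f - start_f)
    return OrfRecord(
        genome_id=g.id,
        start=start % L,
        end=start % L + (end - start),
        strand=strand,
        n_codons=n_codons,
        nt_seq=nt,
        aa_seq=aa,
    )


# ---------------------------------------------------------------------------
# grouping

_aligner = PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -4
_aligner.extend_gap_score = -1


def _identity_cov(a: str, b: str) -> tuple[float, float]:
    """(identity over aligned columns, aligned coverage of the shorter)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    aln = _aligner.align(short, long_)[0]
    s_aln, l_aln = aln[0], aln[1]
    cols = len(s_aln)
    if cols == 0:
        return 0.0, 0.0
    matches = sum(1 for x, y in zip(s_aln, l_aln) if x == y and x != "-")
    covered = sum(1 for x in s_aln if x != "-")
    return matches / cols, covered / len(short)


def _homologous(a: OrfRecord, b: OrfRecord, min_identity, min_cov) -> bool:
    for bseq in (b.nt_seq, revcomp(b.nt_seq)):
        short, long_ = (
            (a.nt_seq, bseq) if len(a.nt_seq) <= len(bseq) else (bseq, a.nt_seq)
        )
        # cheap screen: best infix edit distance of the shorter in the longer
        ed = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
        est = 1 - ed / len(short)
        if est >= 0.90:
            return True
        if est < 0.30:
            continue
        ident, cov = _identity_cov(a.nt_seq, bseq)
        if ident >= min_identity and cov >= min_cov:
            return True
    return False


def group_orfs(
    catalogues, min_identity: float = 0.70, min_cov: float = 0.80
) -> list[OrfGroup]:
    """Single-linkage grouping of ORFs across genome catalogues.

    Group ids are deterministic, ordered by the representative's (genome,
    start); the representative is the longest member (ties by coordinates).
    """
    if not catalogues:
        raise ValueError("need >= 1 catalogue")
    records = [o for cat in catalogues for o in cat]
    n = len(records)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    # bucket by length band to skip hopeless pairs (coverage on the shorter
    # cannot reach 80% identity x coverage if lengths are wildly different
    # ... but a short ORF may sit inside a long one, so compare all pairs)
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _homologous(records[i], records[j], min_identity, min_cov):
                union(i, j)

    clusters: dict[int, list[OrfRecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(records[i])
    groups = []
    for members in clusters.values():
        rep = max(members, key=lambda m: (m.length, m.genome_id, -m.start))
        groups.append((rep, sorted(members, key=lambda m: (m.genome_id, m.start))))
    groups.sort(key=lambda t: (t[0].genome_id, t[0].start % 10**9, t[0].strand))
    return [
        OrfGroup(group_id=f"G{idx+1:03d}", members=m, representative=rep)
        for idx, (rep, m) in enumerate(groups)
    ]


# ---------------------------------------------------------------------------
# classification


def _complete_member(group: OrfGroup, genome_id: str) -> bool:
    """Does this genome carry the group's ORF in complete form?

    Complete means near-full-length and near-identical to the
    representative; a truncated or chimeric remnant that still met the
    70%/80% grouping threshold is partial, not complete.
    """
    rep = group.representative
    for m in group.members:
        if m.genome_id != genome_id:
            continue
        if m is rep or m.nt_seq == rep.nt_seq:
            return True
        short, long_ = sorted((m.nt_seq, rep.nt_seq), key=len)
        if len(short) < 0.9 * len(long_):
            continue
        ed = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
        if ed <= 0.1 * len(short):
            return True
    return False


def _locus_on(genome_id: str, group: OrfGroup):
    for m in group.members:
        if m.genome_id == genome_id:
            return m
    return None


def _interval_contains(iv, pos, L):
    s, e = iv
    return (pos - s) % L < (e - s)


def _overlaps(iv1, iv2, L):
    s1, e1 = iv1
    s2, e2 = iv2
    return _interval_contains(iv1, s2 % L, L) or _interval_contains(iv2, s1 % L, L)


def classify_polymorphic_orfs(
    groups,
    blocks_by_pair: dict,
    indels_by_pair: dict,
    genome_ids,
    genome_lengths: dict,
) -> list[PolymorphicOrfCall]:
    """Assign each ORF group a class: SHARED, GR, ID or M.

    A group complete in every genome is SHARED; a member counts as
    complete when its sequence matches the representative near-full-length
    (length within 10% and edit distance within 10% of the shorter — a
    truncated or chimeric remnant is "partial").  Otherwise, for each
    affected genome (where the group is absent or partial), the
    representative locus is inspected in the pairwise comparison between
    the representative's genome and the affected genome:

    * GR — a synteny-block boundary falls strictly inside the locus
      (a DNA break within the ORF);
    * ID — the locus lies inside, or is disrupted by, an indel record;
    * M  — otherwise (nucleotide-level changes).

    GR takes precedence over ID, and ID over M.
    """
    genome_ids = list(genome_ids)
    calls = []
    for grp in groups:
        unknown = grp.shared_by - set(genome_ids)
        if unknown:
            raise ValueError(f"group {grp.group_id} references unknown genome {unknown}")
        missing = [
            gid
            for gid in genome_ids
            if gid not in grp.shared_by or not _complete_member(grp, gid)
        ]
        if not missing:
            calls.append(PolymorphicOrfCall(grp.group_id, "SHARED"))
            continue
        rep = grp.representative
        rg = rep.genome_id
        L = genome_lengths[rg]
        locus = (rep.start, rep.end)
        cls, evidence = "M", []
        for gid in missing:
            pair = (rg, gid) if (rg, gid) in blocks_by_pair else (gid, rg)
            blocks = blocks_by_pair.get(pair, [])
            which = 0 if pair[0] == rg else 1
            hit_bp = None
            for blk in blocks:
                iv = blk.a_interval if which == 0 else blk.b_interval
                for bp in iv:
                    # boundary strictly inside the locus
                    off = (bp % L - locus[0]) % L
                    if 0 < off < (locus[1] - locus[0]):
                        hit_bp = (gid, blk.index, bp % L)
            if hit_bp:
                cls = "GR"
                evidence.append(("block_boundary",) + hit_bp)
                break
            for rec in indels_by_pair.get(pair, []):
                if rec.carrier_genome != rg:
                    continue
                if _overlaps(rec.interval, locus, L):
                    cls = "ID"
                    evidence.append(("indel", gid, rec.interval))
        if cls == "M":
            evidence = [("mutation", gid) for gid in missing]
        calls.append(PolymorphicOrfCall(grp.group_id, cls, tuple(evidence)))
    return calls


# ---------------------------------------------------------------------------
# mutation-site typology

_global = PairwiseAligner()
_global.mode = "global"
_global.match_score = 1
_global.mismatch_score = -1
_global.open_gap_score = -4
_global.extend_gap_score = -1

TRIPLET_MAX = 52  # in-frame indels below this length form their own class


def classify_mutation_sites(group: OrfGroup) -> list[MutationSite]:
    """Per-site typology of the differences between members and the
    representative.

    Substitution columns are frame-preserving unless they create an
    in-frame stop before the annotated stop (premature_stop); gap runs are
    typed by length: multiples of 3 below 52 nt are triplet indels,
    non-multiples of 3 are non-triplet indels, and in-frame indels of at
    least 52 nt are reported as large_indel (outside the four classes).
    One site is one substitution column or one contiguous gap run; sites
    are positioned on the representative sequence.
    """
    if len(group.members) < 2:
        raise ValueError("group has < 2 members")
    rep = group.representative
    sites: set[MutationSite] = set()
    for m in group.members:
        if m is rep or m.nt_seq == rep.nt_seq:
            continue
        aln = _global.align(rep.nt_seq, m.nt_seq)[0]
        r_aln, m_aln = aln[0], aln[1]
        if all(c == "-" for c in r_aln) or all(c == "-" for c in m_aln):
            raise ValueError("members with zero alignable overlap")
        rpos = 0
        i = 0
        ncols = len(r_aln)
        while i < ncols:
            rc, mc = r_aln[i], m_aln[i]
            if rc != "-" and mc != "-":
                if rc != mc:
                    kind = "frame_preserving"
                    # does the variant create an in-frame stop on either
                    # side (one member's intact codon vs the other's stop)?
                    frame = rpos % 3
                    cstart = i - frame
                    m_codon = "".join(
                        m_aln[cstart + t] if cstart + t < ncols else ""
                        for t in range(3)
                    )
                    r_codon = "".join(
                        r_aln[cstart + t] if cstart + t < ncols else ""
                        for t in range(3)
                    )
                    created_stop = (m_codon in STOPS) != (r_codon in STOPS)
                    if created_stop and rpos < len(rep.nt_seq) - 3:
                        kind = "premature_stop"
                    sites.add(MutationSite(group.group_id, rpos, kind, 0))
                rpos += 1
                i += 1
            else:
                j = i
                glen = 0
                while j < ncols and (r_aln[j] == "-" or m_aln[j] == "-"):
                    glen += 1
                    j += 1
                if glen % 3 == 0:
                    kind = "triplet_indel" if glen < TRIPLET_MAX else "large_indel"
                else:
                    kind = "non_triplet_indel"
                sites.add(MutationSite(group.group_id, rpos, kind, glen))
                rpos += sum(1 for t in range(i, j) if r_aln[t] != "-")
                i = j
    return sorted(sites, key=lambda s: (s.position, s.kind))
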