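"""Pairwise genome comparison: syntenic blocks, SNPs, indels, rearrangement
bounds and repeat-breakpoint association.

The block finder chains co-diagonal k-mer anchors into candidate homologous
segments (both strands), scores them by matched length, and resolves
overlapping candidates to the highest-scoring tiling on both genomes.
Within-block base-level work (SNP counting, identity) runs on the edit-
distance alignment of the paired segments (edlib), so blocks tolerate both
substitutions and small internal indels.

The operational definitions implemented here: a homologous
segment must exceed ``min_block`` (400 bp) at >= ``min_identity`` (0.87);
an indel is a sequence present in one genome and absent in the other, kept
above ``min_indel`` (400 bp); SNPs are substitution columns inside blocks.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, replace as dc_replace
from math import ceil

import edlib

from .core import CircularGenome, circular_distance, revcomp
from .repeats import ShortRepeat, _seed_positions, _maximal_pairs

__all__ = [
    "SyntenyBlock",
    "IndelRecord",
    "SnpCount",
    "BreakpointAssociation",
    "find_synteny_blocks",
    "count_snps",
    "extract_indels",
    "classify_insertions",
    "breakpoint_lower_bound",
    "associate_repeats_with_breakpoints",
    "coverage_bookkeeping",
]


@dataclass(frozen=True)
class SyntenyBlock:
    """One homologous segment shared by genomes A and B.

    Intervals are 0-based half-open on each genome's linearization; ``end``
    may exceed the genome length for an origin-wrapping block.  ``index``
    numbers blocks by order of appearance on genome A.
    """

    index: int
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    orientation: str  # "same" | "inverted"
    identity: float

    @property
    def a_len(self) -> int:
        return self.a_interval[1] - self.a_interval[0]

    @property
    def b_len(self) -> int:
        return self.b_interval[1] - self.b_interval[0]


@dataclass(frozen=True)
class IndelRecord:
    carrier_genome: str
    interval: tuple[int, int]
    length: int
    flanking_blocks: tuple[int, int]
    counterpart_gap: int
    match_status: str = "unclassified"  # matched | unmatched | unclassified


@dataclass(frozen=True)
class SnpCount:
    pair: tuple[str, str]
    n_snp: int


@dataclass(frozen=True)
class BreakpointAssociation:
    breakpoint: int
    repeat: ShortRepeat
    occurrence: tuple[int, str]
    distance: int


# ---------------------------------------------------------------------------
# anchors and chaining


def _anchors(a: CircularGenome, b: CircularGenome, k: int):
    """Maximal exact matches between a and b, both strands of b.

    Yields (a0, b0, length, strand) in linear coordinates of a and b
    (b coords on the forward strand even for inverted matches).
    """
    sa, sb = a.seq, b.seq
    La, Lb = len(sa), len(sb)
    seeds_a = _seed_positions(sa, La - k + 1, k)
    seeds_bf = _seed_positions(sb, Lb - k + 1, k)
    out = []
    for a0, b0, ln in _maximal_pairs(sa, sb, La, k, seeds_a, seeds_bf):
        out.append((a0, b0, ln, "+"))
    rb = revcomp(sb)
    seeds_br = _seed_positions(rb, Lb - k + 1, k)
    for a0, p0, ln in _maximal_pairs(sa, rb, La, k, seeds_a, seeds_br):
        out.append((a0, Lb - (p0 + ln), ln, "-"))
    return out


def _chain(anchors, max_gap: int, max_drift: int):
    """Greedy co-diagonal chaining of anchors into candidate segments.

    Anchors on the same strand whose diagonals differ by <= max_drift and
    whose gap along A is <= max_gap join one chain.  Returns candidate
    tuples (a_start, a_end, b_start, b_end, strand, matched).
    """
    chains = []
    by_strand = defaultdict(list)
    for a0, b0, ln, st in anchors:
        diag = (b0 + a0) if st == "-" else (b0 - a0)
        by_strand[st].append((a0, b0, ln, diag))
    for st, lst in by_strand.items():
        lst.sort()
        open_chains = []  # [a_end, b_lo, b_hi, diag, matched, a_start]
        for a0, b0, ln, diag in lst:
            best = None
            for c in open_chains:
                if abs(diag - c[3]) <= max_drift and 0 <= a0 - c[0] <= max_gap:
                    if best is None or c[0] > best[0]:
                        best = c
            if best is not None:
                best[0] = max(best[0], a0 + ln)
                best[1] = min(best[1], b0)
                best[2] = max(best[2], b0 + ln)
                best[4] += ln
            else:
                open_chains.append([a0 + ln, b0, b0 + ln, diag, ln, a0])
        for a_end, b_lo, b_hi, diag, matched, a_start in open_chains:
            chains.append((a_start, a_end, b_lo, b_hi, st, matched))
    return chains


def _block_identity(a_seg: str, b_seg: str) -> float:
    if a_seg == b_seg:
        return 1.0
    r = edlib.align(a_seg, b_seg, task="distance")
    aln = max(len(a_seg), len(b_seg))
    return max(0.0, 1.0 - r["editDistance"] / aln)


def find_synteny_blocks(
    a: CircularGenome,
    b: CircularGenome,
    min_block: int = 400,
    min_identity: float = 0.87,
    k: int = 31,
    max_gap: int = 1000,
    max_drift: int = 200,
) -> list[SyntenyBlock]:
    """Unique homologous segments > ``min_block`` between two circles.

    Candidates come from co-diagonal anchor chains; overlap conflicts are
    resolved to the highest-scoring tiling on both genomes (greedy by
    matched length, overlaps trimmed).  Blocks adjacent across the origin
    of both genomes merge into one wrapped block, and blocks are numbered
    along genome A.
    """
    if a.length == 0 or b.length == 0:
        raise ValueError("empty genome")
    cands = _chain(_anchors(a, b, k), max_gap, max_drift)
    cands.sort(key=lambda c: -c[5])
    taken_a: list[tuple[int, int]] = []
    taken_b: list[tuple[int, int]] = []
    chosen = []
    for a0, a1, b0, b1, st, matched in cands:
        # trim against already-claimed regions; cuts on one genome are
        # mirrored on the other to keep the segments in correspondence
        for _ in range(2):
            na0, na1 = _trim(a0, a1, taken_a)
            lcut, rcut = na0 - a0, a1 - na1
            a0, a1 = na0, na1
            if st == "+":
                b0, b1 = b0 + lcut, b1 - rcut
            else:
                b0, b1 = b0 + rcut, b1 - lcut
            nb0, nb1 = _trim(b0, b1, taken_b)
            lcut, rcut = nb0 - b0, b1 - nb1
            b0, b1 = nb0, nb1
            if st == "+":
                a0, a1 = a0 + lcut, a1 - rcut
            else:
                a0, a1 = a0 + rcut, a1 - lcut
        # keep sub-min_block fragments for now: a fragment stranded at the
        # origin may complete a circular block after the wrap merge
        if a1 - a0 < k or b1 - b0 < k:
            continue
        a_seg = a.seq[a0:a1]
        b_seg = b.seq[b0:b1] if st == "+" else revcomp(b.seq[b0:b1])
        ident = _block_identity(a_seg, b_seg)
        if ident < min_identity:
            continue
        taken_a.append((a0, a1))
        taken_b.append((b0, b1))
        chosen.append((a0, a1, b0, b1, st, ident))

    chosen = _polish_boundaries(chosen, a, b, min_identity)
    chosen = _merge_wrapped(chosen, a.length, b.length)
    chosen = [
        c for c in chosen if min(c[1] - c[0], c[3] - c[2]) >= min_block
    ]
    chosen.sort(key=lambda c: c[0] % a.length)
    return [
        SyntenyBlock(
            index=i + 1,
            a_interval=(c[0], c[1]),
            b_interval=(c[2], c[3]),
            orientation="same" if c[4] == "+" else "inverted",
            identity=round(c[5], 4),
        )
        for i, c in enumerate(chosen)
    ]


def _trim(lo, hi, taken):
    """Clip [lo, hi) against already-claimed intervals; keep largest piece."""
    for t0, t1 in sorted(taken):
        if hi <= t0 or lo >= t1:
            continue
        left = (lo, min(hi, t0))
        right = (max(lo, t1), hi)
        lo, hi = max((left, right), key=lambda iv: iv[1] - iv[0])
        if hi <= lo:
            return lo, lo
    return lo, hi


def _polish_boundaries(chosen, a, b, min_identity, chunk: int = 64):
    """Extend block boundaries into unclaimed sequence on both genomes.

    Exact-anchor chains stop at the last exact match, stranding terminal
    substitutions just outside the block; absorb flanking chunks while the
    added chunk still aligns at a usable identity (ungapped comparison).
    Extension never crosses another block's claim or the sequence ends.
    """
    out = list(chosen)
    for idx in range(len(out)):
        a0, a1, b0, b1, st, ident = out[idx]
        others_a = [(c[0], c[1]) for i, c in enumerate(out) if i != idx]
        others_b = [(c[2], c[3]) for i, c in enumerate(out) if i != idx]

        def room(pos, direction, claims, limit):
            """Free bp from pos toward direction before a claim or limit."""
            if direction > 0:
                edge = min([s for s, e in claims if s >= pos] + [limit])
                return edge - pos
            edge = max([e for s, e in claims if e <= pos] + [0])
            return pos - edge

        changed = True
        while changed:
            changed = False
            # right end of A
            ra = room(a1, +1, others_a, a.length)
            rb = room(b1, +1, others_b, b.length) if st == "+" else room(
                b0, -1, others_b, b.length
            )
            t = min(ra, rb, chunk)
            if t > 0:
                ca = a.seq[a1 : a1 + t]
                cb = (
                    b.seq[b1 : b1 + t]
                    if st == "+"
                    else revcomp(b.seq[b0 - t : b0])
                )
                if _absorbable(ca, cb, min_identity):
                    a1 += t
                    if st == "+":
                        b1 += t
                    else:
                        b0 -= t
                    changed = True
            # left end of A
            la = room(a0, -1, others_a, a.length)
            lb = room(b0, -1, others_b, b.length) if st == "+" else room(
                b1, +1, others_b, b.length
            )
            t = min(la, lb, chunk)
            if t > 0:
                ca = a.seq[a0 - t : a0]
                cb = (
                    b.seq[b0 - t : b0]
                    if st == "+"
                    else revcomp(b.seq[b1 : b1 + t])
                )
                if _absorbable(ca, cb, min_identity):
                    a0 -= t
                    if st == "+":
                        b0 -= t
                    else:
                        b1 += t
                    changed = True
        a_seg = a.seq[a0:a1]
        b_seg = b.seq[b0:b1] if st == "+" else revcomp(b.seq[b0:b1])
        out[idx] = (a0, a1, b0, b1, st, _block_identity(a_seg, b_seg))
    return out


def _absorbable(x: str, y: str, min_identity: float) -> bool:
    """Can a flanking chunk join the block?  Short chunks tolerate a couple
    of mismatches (a terminal SNP must not strand itself outside the
    block); longer chunks must meet the identity floor."""
    if len(x) != len(y) or not x:
        return False
    mism = sum(1 for p, q in zip(x, y) if p != q)
    return mism <= max(2, int((1 - min_identity) * len(x)))


def _merge_wrapped(chosen, La, Lb):
    """Merge blocks that are contiguous on both circles.

    Two same-orientation blocks adjacent on A (modulo La) whose B
    intervals are also adjacent (modulo Lb) describe one circular block
    that the linear tiling split — at either genome's origin.  Iterate to
    a fixpoint; merged intervals may have end > length (wrapped).
    """

    def try_merge(c1, c2):
        # c1 followed by c2 along A
        if c1[4] != c2[4]:
            return None
        a_len = (c1[1] - c1[0]) + (c2[1] - c2[0])
        if a_len > La or c1[1] % La != c2[0] % La:
            return None
        if c1[4] == "+":
            if c1[3] % Lb != c2[2] % Lb:
                return None
            b0, b1 = c1[2], c1[2] + (c1[3] - c1[2]) + (c2[3] - c2[2])
        else:
            if c2[3] % Lb != c1[2] % Lb:
                return None
            b0, b1 = c2[2], c2[2] + (c1[3] - c1[2]) + (c2[3] - c2[2])
        ident = (
            c1[5] * (c1[1] - c1[0]) + c2[5] * (c2[1] - c2[0])
        ) / a_len
        return (c1[0], c1[0] + a_len, b0, b1, c1[4], ident)

    merged = True
    chosen = list(chosen)
    while merged and len(chosen) > 1:
        merged = False
        n = len(chosen)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                m = try_merge(chosen[i], chosen[j])
                if m is not None:
                    chosen = [
                        c for k, c in enumerate(chosen) if k not in (i, j)
                    ] + [m]
                    merged = True
                    break
            if merged:
                break
    return chosen


# ---------------------------------------------------------------------------
# SNPs


def _block_segments(a, b, blk):
    a_seg = a.fetch(blk.a_interval[0], blk.a_interval[1])
    b_seg = b.fetch(blk.b_interval[0], blk.b_interval[1])
    if blk.orientation == "inverted":
        b_seg = revcomp(b_seg)
    return a_seg, b_seg


def _cigar_walk(cigar):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def count_snps(a: CircularGenome, b: CircularGenome, blocks) -> SnpCount:
    """Single-nucleotide substitutions summed over all syntenic blocks.

    Every substitution column of the per-block alignment counts one SNP
    (mismatch runs count per position); gap positions never count.  An
    adjacent insertion/deletion pair of equal span — an edit-path artifact
    equivalent to substitutions — is normalized back to substitution
    columns before counting.
    """
    if not blocks:
        warnings.warn(f"count_snps({a.id},{b.id}): no blocks; n_snp=0")
        return SnpCount(pair=(a.id, b.id), n_snp=0)
    total = 0
    for blk in blocks:
        a_seg, b_seg = _block_segments(a, b, blk)
        if a_seg == b_seg:
            continue
        if len(a_seg) == len(b_seg):
            # tie-break: when a substitution-only alignment is optimal,
            # prefer it over an equal-cost path using indels
            ham = sum(1 for x, y in zip(a_seg, b_seg) if x != y)
            if ham == edlib.align(a_seg, b_seg, task="distance")["editDistance"]:
                total += ham
                continue
        r = edlib.align(a_seg, b_seg, task="path")
        ops = list(_cigar_walk(r["cigar"]))
        i = 0
        while i < len(ops):
            ln, op = ops[i]
            if op == "X":
                total += ln
            elif (
                op in "ID"
                and i + 1 < len(ops)
                and ops[i + 1][1] in "ID"
                and ops[i + 1][1] != op
            ):
                total += min(ln, ops[i + 1][0])
                i += 1
            i += 1
    return SnpCount(pair=(a.id, b.id), n_snp=total)


# ---------------------------------------------------------------------------
# indels


def _uncovered(intervals, L):
    """Complement of a set of (possibly wrapped) intervals on the circle."""
    if not intervals:
        return [(0, L)]
    norm = sorted((s % L, (s % L) + (e - s)) for s, e in intervals)
    # unwrap any interval spilling past L into a leading segment
    spill = 0
    for s, e in norm:
        if e > L:
            spill = max(spill, e - L)
    gaps = []
    prev_end = spill
    for s, e in norm:
        if s > prev_end:
            gaps.append((prev_end, s))
        prev_end = max(prev_end, min(e, L + spill))
    if prev_end < L:
        gaps.append((prev_end, L))
    return [(s, e) for s, e in gaps if e > s]


def extract_indels(
    a: CircularGenome, b: CircularGenome, blocks, min_indel: int = 400
) -> list[IndelRecord]:
    """Sequences present in one genome and absent in the other.

    Every segment of a genome not covered by a syntenic block, longer than
    ``min_indel``, becomes an IndelRecord of that carrier (the counterpart
    gap between the flanking blocks on the other genome is recorded; a
    replacement region therefore yields one record on each side).
    """
    out = []
    for g, other, key, other_key in (
        (a, b, "a_interval", "b_interval"),
        (b, a, "b_interval", "a_interval"),
    ):
        ivs = [getattr(blk, key) for blk in blocks]
        for gap_start, gap_end in _uncovered(ivs, g.length):
            if gap_end - gap_start <= min_indel:
                continue
            left = right = -1
            cgap = -1
            for i, (s, e) in enumerate(ivs):
                if e % g.length == gap_start or e == gap_start:
                    left = blocks[i].index
                if s % g.length == gap_end % g.length:
                    right = blocks[i].index
            if left > 0 and right > 0:
                lb = next(b_ for b_ in blocks if b_.index == left)
                rb = next(b_ for b_ in blocks if b_.index == right)
                lo = getattr(lb, other_key)
                ro = getattr(rb, other_key)
                cgap = min(
                    (ro[0] - lo[1]) % other.length, (lo[0] - ro[1]) % other.length
                )
            out.append(
                IndelRecord(
                    carrier_genome=g.id,
                    interval=(gap_start, gap_end),
                    length=gap_end - gap_start,
                    flanking_blocks=(left, right),
                    counterpart_gap=cgap,
                )
            )
    return out


def merge_carrier_indels(records) -> list[IndelRecord]:
    """Collapse per-pair indel records to one record per carrier locus.

    The same insertion surfaces once per pairwise comparison of a panel;
    overlapping intervals on one carrier merge to their union, so the
    result counts physical insertions, not pairwise observations.
    """
    by_carrier: dict[str, list[IndelRecord]] = {}
    for r in records:
        by_carrier.setdefault(r.carrier_genome, []).append(r)
    out = []
    for carrier, recs in sorted(by_carrier.items()):
        recs.sort(key=lambda r: r.interval)
        cur = None
        for r in recs:
            if cur is not None and r.interval[0] <= cur.interval[1]:
                s = cur.interval[0]
                e = max(cur.interval[1], r.interval[1])
                cur = dc_replace(cur, interval=(s, e), length=e - s)
            else:
                if cur is not None:
                    out.append(cur)
                cur = r
        if cur is not None:
            out.append(cur)
    return out


def classify_insertions(
    panel,
    records,
    min_identity: float = 0.70,
    min_cov: float = 0.80,
) -> list[IndelRecord]:
    """Mark each insertion matched/unmatched against all non-carrier genomes.

    An insertion is matched when some other genome of the panel carries a
    homologous stretch at >= ``min_identity`` identity over >=
    ``min_cov`` of the insertion (screened by best infix edit-distance
    alignment against the doubled target).
    """
    if len(panel) < 3:
        raise ValueError("classify_insertions needs a panel of >= 3 genomes")
    by_id = {g.id: g for g in panel}
    out = []
    for rec in records:
        carrier = by_id[rec.carrier_genome]
        q = carrier.fetch(rec.interval[0], rec.interval[1])
        core = q[
            int(len(q) * (1 - min_cov) / 2) : int(len(q) * (1 + min_cov) / 2)
        ]
        matched = False
        for g in panel:
            if g.id == rec.carrier_genome:
                continue
            t = g.doubled()
            lim_full = int(len(q) * (1 - min_identity))
            if edlib.align(q, t, mode="HW", task="distance", k=lim_full)["editDistance"] >= 0:
                matched = True
                break
            lim_core = int(len(core) * (1 - min_identity))
            if edlib.align(core, t, mode="HW", task="distance", k=lim_core)["editDistance"] >= 0:
                matched = True
                break
        out.append(dc_replace(rec, match_status="matched" if matched else "unmatched"))
    return out


# ---------------------------------------------------------------------------
# rearrangement bound and repeat association


def breakpoint_lower_bound(blocks) -> int:
    """ceil(breakpoints / 2) on the signed circular block permutation.

    Blocks are taken in A order as the signed identity 1..n and read off in
    B order with orientation signs; an adjacency (x, y) in B matches the
    identity when y = x+1 (signed, circular, with (x, y) === (-y, -x)).
    This is a lower bound on the number of reversal/recombination events,
    not a distance.
    """
    n = len(blocks)
    if n <= 1:
        return 0
    in_b = sorted(blocks, key=lambda blk: blk.b_interval[0])
    signed = [
        blk.index if blk.orientation == "same" else -blk.index for blk in in_b
    ]
    identity_adj = {(i, i + 1) for i in range(1, n)} | {(n, 1)}
    identity_adj |= {(-y, -x) for x, y in identity_adj}
    breakpoints = 0
    for i in range(n):
        x, y = signed[i], signed[(i + 1) % n]
        if (x, y) not in identity_adj:
            breakpoints += 1
    return ceil(breakpoints / 2)


def associate_repeats_with_breakpoints(
    short_repeats,
    blocks,
    genome_length: int,
    window: int = 200,
    which: str = "a",
) -> list[BreakpointAssociation]:
    """Short-repeat occurrences within ``window`` bp of a block boundary.

    Boundaries are the interval endpoints of each block on the chosen
    genome (``which`` = "a" or "b"); distance is the circular distance from
    the boundary to the nearer end of the occurrence.
    """
    out = []
    key = "a_interval" if which == "a" else "b_interval"
    bps = set()
    for blk in blocks:
        s, e = getattr(blk, key)
        bps.add(s % genome_length)
        bps.add(e % genome_length)
    for rep in short_repeats:
        for start, strand in rep.occurrences:
            ends = (start, (start + rep.length) % genome_length)
            for bp in sorted(bps):
                d = min(
                    circular_distance(bp, ends[0], genome_length),
                    circular_distance(bp, ends[1], genome_length),
                )
                # inside the occurrence counts as distance 0
                off = (bp - start) % genome_length
                if off < rep.length:
                    d = 0
                if d <= window:
                    out.append(
                        BreakpointAssociation(
                            breakpoint=bp,
                            repeat=rep,
                            occurrence=(start, strand),
                            distance=d,
                        )
                    )
    return out


def coverage_bookkeeping(g: CircularGenome, blocks, indels, which: str):
    """(block bp, indel bp, residue bp) on one genome; they sum to length.

    ``which`` selects the genome's role in the pair ("a" or "b").
    """
    key = "a_interval" if which == "a" else "b_interval"
    block_bp = sum(getattr(blk, key)[1] - getattr(blk, key)[0] for blk in blocks)
    indel_bp = sum(r.length for r in indels if r.carrier_genome == g.id)
    residue = g.length - block_bp - indel_bp
    return block_bp, indel_bp, residue
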