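"""Repeat detection on circular genomes.

Three detectors share one engine: k-mer seeding on the doubled sequence
(circularity = scan ``S+S``, keep matches whose start lies in the first
copy) with maximal ungapped extension along the diagonal.

* :func:`find_large_repeats` — repeat pairs above a length threshold, both
  strands, identity possibly < 1 (mismatch-tolerant merging of co-diagonal
  exact runs, identity re-scored by gapped alignment when below 1).
* :func:`find_short_repeats` — exact repeat families in a length window
  (default 30-500 bp); homopolymers and tandem arrays are excluded and left
  to the tandem detector.
* :func:`find_tandem_repeats` — maximal arrays of >= 2 adjacent copies of a
  period-p unit, exact matching, smallest (primitive) period reported.

:func:`ks_uniformity` tests positional uniformity of repeat starts with a
one-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CircularGenome, revcomp

__all__ = [
    "RepeatPair",
    "ShortRepeat",
    "TandemRepeat",
    "KsResult",
    "find_large_repeats",
    "find_short_repeats",
    "find_tandem_repeats",
    "ks_uniformity",
]


@dataclass(frozen=True)
class RepeatPair:
    """Two occurrences of a repeated segment on the circle.

    Occurrences are ``(start, length, strand)`` with start in ``[0, L)``;
    an occurrence may wrap across the origin.  ``orientation`` is ``direct``
    when both copies read the same strand, ``inverted`` otherwise.
    """

    occ1: tuple[int, int, str]
    occ2: tuple[int, int, str]
    identity: float
    orientation: str
    label: str | None = None

    @property
    def length(self) -> int:
        return self.occ1[1]


@dataclass(frozen=True)
class ShortRepeat:
    """A family of >= 2 exact occurrences of one short repeated sequence."""

    occurrences: tuple[tuple[int, str], ...]
    length: int
    consensus: str

    @property
    def copy_count(self) -> int:
        return len(self.occurrences)


@dataclass(frozen=True)
class TandemRepeat:
    start: int
    period: int
    copy_number: float
    consensus: str

    @property
    def span(self) -> int:
        return round(self.period * self.copy_number)


@dataclass(frozen=True)
class KsResult:
    D: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# seeding engine


def _seed_positions(s2: str, L: int, k: int, max_occ: int = 500):
    """k-mer -> sorted start positions in [0, L) on the doubled sequence.

    k-mers occurring more than ``max_occ`` times (extreme low-complexity)
    are dropped from seeding; their repeats surface via the tandem finder.
    """
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(L):
        idx[s2[i : i + k]].append(i)
    return {km: ps for km, ps in idx.items() if len(ps) <= max_occ}


def _extend_exact(s2a: str, s2b: str, i: int, j: int, k: int, cap: int):
    """Maximal exact extension of a seed match s2a[i:i+k] == s2b[j:j+k].

    Returns (i0, j0, length) of the maximal run, capped at ``cap`` bp.
    """
    lo = 0
    while i - lo - 1 >= 0 and j - lo - 1 >= 0 and s2a[i - lo - 1] == s2b[j - lo - 1]:
        lo += 1
    hi = k
    na, nb = len(s2a), len(s2b)
    while i + hi < na and j + hi < nb and s2a[i + hi] == s2b[j + hi]:
        hi += 1
    length = min(lo + hi, cap)
    return i - lo, j - lo, length


def _maximal_pairs(s2a: str, s2b: str, L: int, k: int, seeds_a, seeds_b=None):
    """All maximal exact co-diagonal matches between s2a and s2b.

    Yields (i0, j0, length) with i0 in [0, L).  When ``seeds_b`` is None the
    comparison is self-vs-self (trivial diagonals 0 and L excluded).
    """
    self_mode = seeds_b is None
    seen: set[tuple[int, int]] = set()
    out = []
    for km, pa in seeds_a.items():
        pb = pa if self_mode else seeds_b.get(km)
        if not pb:
            continue
        for i in pa:
            for j in pb:
                if self_mode and (j <= i or (j - i) % L == 0):
                    continue
                d = j - i
                key0 = (i, d)
                if key0 in seen:
                    continue
                i0, j0, length = _extend_exact(s2a, s2b, i, j, k, cap=L)
                # mark every seed start inside the run as visited
                seen.update((i0 + t, j0 - i0) for t in range(length - k + 1))
                seen.add((i0, j0 - i0))
                out.append((i0, j0, length))
    # dedup identical runs
    return sorted(set(out))


def _merge_codiagonal(runs, min_identity: float, max_gap: int = 200):
    """Merge exact runs on one diagonal across short mismatch gaps.

    ``runs`` is [(i0, length)] on a single diagonal, sorted.  Gaps count as
    mismatches (ungapped model); a merge is kept while overall identity
    stays >= min_identity.
    """
    if not runs:
        return []
    merged = [list(runs[0]) + [runs[0][1]]]  # [start, span, matched]
    for i0, ln in runs[1:]:
        start, span, matched = merged[-1]
        gap = i0 - (start + span)
        if 0 <= gap <= max_gap:
            new_span = (i0 + ln) - start
            new_matched = matched + ln
            if new_matched / new_span >= min_identity:
                merged[-1] = [start, new_span, new_matched]
                continue
        if gap < 0:  # overlapping runs: keep the longer
            if i0 + ln <= start + span:
                continue
            merged[-1] = [start, i0 + ln - start, matched + ln - (start + span - i0)]
            continue
        merged.append([i0, ln, ln])
    return [(s, sp, m / sp) for s, sp, m in merged]


def _contains(occ_a, occ_b, L):
    """True if circular interval occ_a contains occ_b (same strand)."""
    sa, la, sta = occ_a
    sb, lb, stb = occ_b
    if sta != stb or lb > la:
        return False
    off = (sb - sa) % L
    return off + lb <= la


def find_large_repeats(
    g: CircularGenome,
    min_len: int = 2000,
    min_identity: float = 0.99,
    k: int = 31,
) -> list[RepeatPair]:
    """Maximal repeat pairs of length >= ``min_len`` on both strands.

    Matches may span the origin.  Nested/contained duplicates of a maximal
    pair are suppressed; pairs are sorted by length descending.  Returns an
    empty list when ``min_len`` exceeds the genome length.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    L = g.length
    if min_len > L:
        return []
    k = min(k, min_len)
    s2 = g.doubled()
    seeds = _seed_positions(s2, L, k)
    pairs: list[RepeatPair] = []

    # the merge step sees only seeded exact runs; stretches between close
    # substitutions are shorter than k and never seed, so merged identity
    # underestimates — merge with a relaxed floor, then re-score exactly
    merge_floor = max(0.5, min_identity - 0.05)

    def exact_ident(x: str, y: str) -> float:
        return sum(1 for p, q in zip(x, y) if p == q) / len(x)

    def candidates(runs):
        # exact matching asked for: maximal exact runs ARE the candidates
        if min_identity >= 1.0:
            return [(s, ln, 1.0) for s, ln in runs]
        return _merge_codiagonal(runs, merge_floor)

    # direct: self vs self on the doubled forward strand
    by_diag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for i0, j0, ln in _maximal_pairs(s2, s2, L, k, seeds):
        by_diag[j0 - i0].append((i0, ln))
    for d, runs in by_diag.items():
        for start, span, _ in candidates(sorted(set(runs))):
            if span < min_len:
                continue
            ident = exact_ident(s2[start : start + span], s2[start + d : start + d + span])
            if ident >= min_identity:
                pairs.append(
                    RepeatPair(
                        occ1=(start % L, span, "+"),
                        occ2=((start + d) % L, span, "+"),
                        identity=round(ident, 4),
                        orientation="direct",
                    )
                )

    # inverted: forward doubled vs reverse-complement doubled
    r2 = revcomp(s2)
    seeds_r = _seed_positions(r2, L, k)
    by_diag.clear()
    for i0, j0, ln in _maximal_pairs(s2, r2, L, k, seeds, seeds_r):
        by_diag[j0 - i0].append((i0, ln))
    seen_inv: set[frozenset] = set()
    for d, runs in by_diag.items():
        for start, span, _ in candidates(sorted(set(runs))):
            if span < min_len:
                continue
            ident = exact_ident(s2[start : start + span], r2[start + d : start + d + span])
            if ident < min_identity:
                continue
            p = start + d  # start in r2 coordinates
            fwd_start = (2 * L - (p + span)) % L
            o1 = (start % L, span, "+")
            o2 = (fwd_start, span, "-")
            if o1[0] == o2[0]:  # palindromic self-match
                continue
            if o1[0] > o2[0]:
                # canonical representation: '+' on the smaller start
                o1, o2 = (o2[0], span, "+"), (o1[0], span, "-")
            key = frozenset([(o1[0], span), (o2[0], span)])
            if key in seen_inv:
                continue
            seen_inv.add(key)
            pairs.append(
                RepeatPair(
                    occ1=o1, occ2=o2, identity=round(ident, 4), orientation="inverted"
                )
            )

    pairs.sort(key=lambda p: (-p.length, p.occ1[0]))
    return _suppress_contained(pairs, L)


def _suppress_contained(pairs: list[RepeatPair], L: int) -> list[RepeatPair]:
    kept: list[RepeatPair] = []
    for p in pairs:
        redundant = False
        for q in kept:
            if q.orientation != p.orientation:
                continue
            if (_contains(q.occ1, p.occ1, L) and _contains(q.occ2, p.occ2, L)) or (
                _contains(q.occ1, p.occ2, L) and _contains(q.occ2, p.occ1, L)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(p)
    return kept


def _is_homopolymer(s: str) -> bool:
    return len(set(s)) == 1


def _overlap_circular(s1, l1, s2, l2, L) -> bool:
    off = (s2 - s1) % L
    return off < l1 or (L - off) < l2


def find_short_repeats(
    g: CircularGenome, min_len: int = 30, max_len: int = 500, k: int | None = None
) -> list[ShortRepeat]:
    """Exact short-repeat families with >= 2 occurrences, both strands.

    A family is one repeated sequence with all its occurrences; maximal
    exact matches whose length falls outside ``[min_len, max_len]`` are not
    short repeats.  Homopolymer sequences and overlapping (tandem-style)
    occurrence pairs are excluded — those belong to the tandem detector.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    L = g.length
    k = k or min(21, min_len)
    s2 = g.doubled()
    seeds = _seed_positions(s2, L, k)
    fams: dict[str, set[tuple[int, str]]] = defaultdict(set)
    lens: dict[str, int] = {}

    for i0, j0, ln in _maximal_pairs(s2, s2, L, k, seeds):
        if not (min_len <= ln <= max_len):
            continue
        if _overlap_circular(i0 % L, ln, j0 % L, ln, L):
            continue  # tandem-style overlapping pair
        seq = s2[i0 : i0 + ln]
        if _is_homopolymer(seq):
            continue
        canon = min(seq, revcomp(seq))
        strand = "+" if canon == seq else "-"
        fams[canon].update([(i0 % L, strand), (j0 % L, strand)])
        lens[canon] = ln

    r2 = revcomp(s2)
    seeds_r = _seed_positions(r2, L, k)
    for i0, j0, ln in _maximal_pairs(s2, r2, L, k, seeds, seeds_r):
        if not (min_len <= ln <= max_len):
            continue
        seq = s2[i0 : i0 + ln]
        if _is_homopolymer(seq):
            continue
        fwd2 = (2 * L - (j0 + ln)) % L
        if (i0 % L) == fwd2:
            continue  # palindrome self-match
        if _overlap_circular(i0 % L, ln, fwd2, ln, L):
            continue
        canon = min(seq, revcomp(seq))
        if canon == seq:
            for s, st in [(i0 % L, "+"), (fwd2, "-")]:
                fams[canon].add((s, st))
        else:
            for s, st in [(i0 % L, "-"), (fwd2, "+")]:
                fams[canon].add((s, st))
        lens[canon] = ln

    out = []
    for canon, occs in fams.items():
        if len(occs) >= 2:
            out.append(
                ShortRepeat(
                    occurrences=tuple(sorted(occs)),
                    length=lens[canon],
                    consensus=canon,
                )
            )
    out.sort(key=lambda f: (-f.length, f.occurrences))
    return out


def find_tandem_repeats(
    g: CircularGenome, min_period: int = 2, min_copies: float = 2, max_period: int = 100
) -> list[TandemRepeat]:
    """Maximal exact tandem arrays, circle-aware, primitive period reported.

    Scans every period ``p`` in [min_period, max_period] on the doubled
    sequence; an array is a maximal run where position i matches i+p, kept
    when its copy number (possibly fractional) reaches ``min_copies``.
    """
    L = g.length
    s2 = np.frombuffer(g.doubled().encode(), dtype="S1")
    out = []
    for p in range(min_period, min(max_period, L) + 1):
        eq = s2[:-p] == s2[p:]
        # run-length encode
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for a, b in zip(idx[::2], idx[1::2]):
            run = b - a
            span = min(run + p, L)
            copies = span / p
            if copies < min_copies or a >= L:
                continue
            unit = g.doubled()[a : a + p]
            if _primitive_period(unit) != p:
                continue
            out.append(
                TandemRepeat(
                    start=int(a), period=p, copy_number=round(float(copies), 2), consensus=unit
                )
            )
    out.sort(key=lambda t: (t.start, t.period))
    return _dedup_tandem(out, L)


def _primitive_period(unit: str) -> int:
    n = len(unit)
    for q in range(1, n):
        if n % q == 0 and unit == unit[:q] * (n // q):
            return q
    return n


def _dedup_tandem(arrays: list[TandemRepeat], L: int) -> list[TandemRepeat]:
    """Drop an array wholly covered by another array with the same period."""
    kept: list[TandemRepeat] = []
    for t in arrays:
        shadowed = False
        for u in arrays:
            if u is t or u.period != t.period:
                continue
            off = (t.start - u.start) % L
            if off + t.span <= u.span and u.span > t.span:
                shadowed = True
                break
        if not shadowed:
            kept.append(t)
    return kept


def ks_uniformity(
    positions, genome_length: int, rotation_max: bool = False
) -> KsResult:
    """One-sample KS test of positions against Uniform(0, genome_length).

    Positions are linearized at the record origin; ``rotation_max=True``
    evaluates the statistic with the origin placed at each observed position
    and reports the maximum D (conservative circular variant).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("ks_uniformity: empty position list")
    if np.any((pos < 0) | (pos >= genome_length)):
        raise ValueError("positions must lie in [0, genome_length)")
    if rotation_max:
        best = None
        for origin in pos:
            rot = np.sort((pos - origin) % genome_length) / genome_length
            r = stats.kstest(rot, "uniform")
            if best is None or r.statistic > best.statistic:
                best = r
        res = best
    else:
        res = stats.kstest(pos / genome_length, "uniform")
    return KsResult(D=float(res.statistic), p_value=float(res.pvalue), n=int(pos.size))
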