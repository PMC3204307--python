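"""Independent brute-force oracles for the repeat and ORF detectors.

Everything here recomputes results from first principles (quadratic
diagonal scans, six-frame rotation scans) without touching the package's
seeding/chaining machinery, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def _runs(mask: np.ndarray):
    """(start, length) of each maximal run of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b - a)) for a, b in zip(idx[::2], idx[1::2])]


def brute_repeat_pairs(seq: str, min_len: int, max_len: int | None = None):
    """All maximal exact repeat pairs on a circle, both strands.

    Returns a set of canonical descriptors
    ``frozenset({(start, strand), (start, strand)}), length, orientation``
    with starts mod L.  Contained duplicates of a maximal pair (both
    occurrences inside both occurrences of a longer same-orientation pair)
    are suppressed, as are palindromic self-matches.
    """
    L = len(seq)
    s2 = seq + seq
    a = np.frombuffer(s2.encode(), dtype="S1")
    cand = []
    # direct: diagonal shift d in (0, L)
    for d in range(1, L):
        eq = a[: 2 * L - d] == a[d:]
        for start, run in _runs(eq):
            if start >= L:
                continue
            ln = min(run, L)
            if ln < min_len or (max_len and ln > max_len):
                continue
            occ = frozenset({((start % L), "+", 0), ((start + d) % L, "+", 1)})
            cand.append((occ, ln, "direct", start % L, d))
    # inverted: compare s2 with rc(s2)
    r2 = rc(s2)
    b = np.frombuffer(r2.encode(), dtype="S1")
    for d in range(-2 * L + 1, 2 * L):
        lo = max(0, -d)
        hi = min(2 * L, 2 * L - d)
        if hi - lo < min_len:
            continue
        eq = a[lo:hi] == b[lo + d : hi + d]
        for start, run in _runs(eq):
            i0 = lo + start
            if i0 >= L:
                continue
            ln = min(run, L)
            if ln < min_len or (max_len and ln > max_len):
                continue
            p0 = i0 + d
            fwd = (2 * L - (p0 + ln)) % L
            if fwd == i0 % L:
                continue  # palindromic self-match
            lo_s, hi_s = sorted((i0 % L, fwd))
            occ = frozenset({(lo_s, "+", 0), (hi_s, "-", 1)})
            cand.append((occ, ln, "inverted", i0 % L, d))

    # dedup identical occurrence sets (each inverted pair found twice)
    seen = {}
    for occ, ln, ori, _, _ in cand:
        key = (frozenset((s, st) for s, st, _ in occ), ori)
        seen[key] = max(seen.get(key, 0), ln)
    out = {(k[0], ln, k[1]) for k, ln in seen.items()}
    return _suppress_contained_oracle(out, L)


def _suppress_contained_oracle(pairs, L):
    def contains(big, small, big_len, small_len):
        (s1, t1), (s2, t2) = sorted(big), sorted(small)
        # try both occurrence matchings
        for (bs, bstr), (ss, sstr) in zip(sorted(big), sorted(small)):
            pass
        ok = False
        bigs = sorted(big)
        smalls = sorted(small)
        for perm in (smalls, smalls[::-1]):
            good = True
            for (bs, bstr), (ss, sstr) in zip(bigs, perm):
                if bstr != sstr or (ss - bs) % L + small_len > big_len:
                    good = False
                    break
            if good:
                ok = True
        return ok

    kept = set()
    plist = sorted(pairs, key=lambda p: -p[1])
    for occ, ln, ori in plist:
        redundant = any(
            ori == o2 and ln <= l2 and contains(occ2, occ, l2, ln)
            for occ2, l2, o2 in kept
        )
        if not redundant:
            kept.add((occ, ln, ori))
    return kept


def brute_tandem(seq: str, min_period: int, max_period: int, min_copies: float = 2):
    """Maximal exact tandem arrays on the circle, primitive period only.

    Returns set of (start, period, span).
    """
    L = len(seq)
    s2 = seq + seq
    a = np.frombuffer(s2.encode(), dtype="S1")
    out = set()
    for p in range(min_period, min(max_period, L) + 1):
        eq = a[:-p] == a[p:]
        for start, run in _runs(eq):
            span = min(run + p, L)
            if span / p < min_copies or start >= L:
                continue
            unit = s2[start : start + p]
            if _primitive(unit) != p:
                continue
            out.add((start, p, span))
    # drop arrays covered by a longer array of the same period
    kept = set()
    for start, p, span in out:
        if not any(
            p == p2 and span2 > span and (start - s2_) % L + span <= span2
            for s2_, p2, span2 in out
        ):
            kept.add((start, p, span))
    return kept


def _primitive(unit: str) -> int:
    n = len(unit)
    for q in range(1, n):
        if n % q == 0 and unit == unit[:q] * (n // q):
            return q
    return n


STOPS = {"TAA", "TAG", "TGA"}


def brute_orfs(seq: str, min_codons: int):
    """Six-frame circular ORF scan by explicit rotation.

    For every rotation placing a candidate ATG at position 0, walk codons
    forward until a stop; keep first-ATG-per-segment ORFs of >= min_codons.
    Returns set of (start mod L, nt_length_with_stop, strand).
    """
    L = len(seq)
    found = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        for atg in range(L):
            if s[atg % L] != "A" or s[(atg + 1) % L] != "T" or s[(atg + 2) % L] != "G":
                continue
            # walk forward to stop
            n = 0
            pos = atg
            stopped = False
            while n * 3 < L:
                codon = "".join(s[(pos + t) % L] for t in range(3))
                if codon in STOPS and n > 0:
                    stopped = True
                    break
                pos += 3
                n += 1
            if not stopped or n < min_codons:
                continue
            # first-ATG rule: no earlier in-frame ATG in the same
            # stop-to-stop segment
            first = True
            back = atg - 3
            steps = 0
            while steps * 3 < L:
                codon = "".join(s[(back + t) % L] for t in range(3))
                if codon in STOPS:
                    break
                if codon == "ATG":
                    first = False
                    break
                back -= 3
                steps += 1
            if not first:
                continue
            nt_len = n * 3 + 3
            if nt_len > L:
                continue
            if strand == "+":
                start = atg % L
            else:
                start = (L - (atg + nt_len)) % L
            found.add((start, nt_len, strand))
    return found


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length co-linear sequences."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)
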