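"""Core data model: circular DNA genomes and annotated features.

All coordinates are 0-based, half-open, on a linearization anchored at the
record origin.  Interval arithmetic is modulo the genome length; an interval
whose ``end`` exceeds the length wraps across the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")

FEATURE_KEYS = frozenset({"gene", "CDS", "exon", "intron", "rRNA", "tRNA", "ORF"})


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """An annotated feature: one or more stranded intervals on the circle.

    ``intervals`` is an ordered list of ``(start, end, strand)`` with
    0-based half-open coordinates; ``end`` may exceed the genome length to
    denote wrapping across the origin (e.g. a gene spanning position 0).
    """

    key: str
    name: str
    intervals: tuple[tuple[int, int, str], ...]
    product_group: str | None = None

    def __post_init__(self):
        if self.key not in FEATURE_KEYS:
            raise ValueError(f"unknown feature key {self.key!r}")
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if not self.intervals:
            raise ValueError("feature must have at least one interval")
        for s, e, strand in self.intervals:
            if e <= s:
                raise ValueError(f"empty/inverted interval ({s}, {e})")
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)


@dataclass
class CircularGenome:
    """One circular DNA molecule with optional annotations.

    The sequence is stored linearized at the deposited/record origin; all
    queries that cross position 0 use modular arithmetic (see
    :meth:`fetch`).
    """

    id: str
    seq: str
    annotations: list[Feature] = field(default_factory=list)
    origin_note: str = ""

    def __post_init__(self):
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            sym = sorted(bad)[0]
            pos = self.seq.index(sym)
            raise ValueError(
                f"genome {self.id!r}: non-IUPAC symbol {sym!r} at position {pos}"
            )
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        for f in self.annotations:
            for s, e, _ in f.intervals:
                if not (0 <= s % self.length < self.length):
                    raise ValueError(f"feature {f.name}: start out of range")
                if e - s > self.length:
                    raise ValueError(
                        f"feature {f.name}: interval longer than genome"
                    )

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on the circle; wraps across origin.

        ``end - start`` must not exceed the genome length.
        """
        L = self.length
        if end - start > L:
            raise ValueError("interval longer than genome")
        start %= L
        span = end - start if end > start else (end % L) - start
        if span <= 0:
            span += L
        end = start + span
        s = self.seq[start:end] if end <= L else self.seq[start:] + self.seq[: end - L]
        return s if strand == "+" else revcomp(s)

    def rotated(self, offset: int) -> "CircularGenome":
        """The same circle linearized ``offset`` bp downstream of the origin."""
        L = self.length
        offset %= L
        seq = self.seq[offset:] + self.seq[:offset]
        feats = []
        for f in self.annotations:
            ivs = tuple(
                ((s - offset) % L, (s - offset) % L + (e - s), strand)
                for s, e, strand in f.intervals
            )
            feats.append(replace(f, intervals=ivs))
        return CircularGenome(self.id, seq, feats, self.origin_note)

    def doubled(self) -> str:
        """The sequence concatenated with itself (circle-aware scanning)."""
        return self.seq + self.seq


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest distance between two positions on a circle of given length."""
    d = abs(a - b) % length
    return min(d, length - d)
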