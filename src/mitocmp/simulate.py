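"""Synthetic circular-genome evolution with ground-truth event logs.

Generates an ancestor genome (random background + implanted repeat copies +
gene-like features), evolves children through duplication, inversion,
translocation, insertion, deletion and batched point substitution, and
records every realized event so a child can be replayed byte-for-byte from
its parent.  This emulates the formation mechanism proposed for plant
mitotypes — inheritance of a parental circle modified by a small number of
structural events plus background mutation — and underlies every
parameter-recovery test in the suite.

All randomness flows from one ``numpy.random.default_rng(seed)`` per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import CircularGenome, Feature, revcomp

__all__ = [
    "EvolEvent",
    "EventLog",
    "generate_ancestor",
    "apply_events",
    "replay",
    "simulate_clade",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

EVENT_KINDS = {
    "duplication",
    "inversion",
    "translocation",
    "insertion",
    "deletion",
    "substitution_batch",
}


@dataclass
class EvolEvent:
    """One evolutionary event.  ``params`` may leave coordinates unset
    (None) to be drawn at application time; the realized event stored in the
    log always carries concrete coordinates."""

    kind: str
    params: dict = field(default_factory=dict)
    applied_at: int | None = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventLog:
    parent_id: str
    child_id: str
    events: list[EvolEvent]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "parent_id": self.parent_id,
                "child_id": self.child_id,
                "seed": self.seed,
                "events": [asdict(e) for e in self.events],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        d = json.loads(text)
        return cls(
            parent_id=d["parent_id"],
            child_id=d["child_id"],
            seed=d["seed"],
            events=[EvolEvent(**e) for e in d["events"]],
        )


def _random_seq(rng, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _random_orf(rng, n_codons: int) -> str:
    """ATG + (n_codons-1) sense codons + TAA."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in stops and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def generate_ancestor(
    length: int,
    n_genes: int = 0,
    repeat_spec=(),
    seed: int = 0,
    orf_codon_counts=(),
) -> CircularGenome:
    """Random circular genome with implanted repeats, genes and ORFs.

    ``repeat_spec`` is a list of ``(repeat_length, copies, orientation)``
    with orientation "direct" or "inverted"; all copies of one spec entry
    are identical and placed at non-overlapping random positions.
    ``orf_codon_counts`` implants real ORFs (ATG + sense codons + stop) as
    annotated features.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    implants: list[tuple[str, str, str]] = []  # (seq, kind, name)
    for idx, (rlen, copies, orientation) in enumerate(repeat_spec):
        unit = _random_seq(rng, rlen)
        for c in range(copies):
            s = unit if (orientation == "direct" or c == 0) else revcomp(unit)
            implants.append((s, "repeat", f"rep{idx}_{c}"))
    for idx, nc in enumerate(orf_codon_counts):
        implants.append((_random_orf(rng, nc), "ORF", f"orf{idx}"))

    total = sum(len(s) for s, _, _ in implants)
    if total > length:
        raise ValueError("genome length too small for requested implants")

    seq = list(_random_seq(rng, length))
    placed: list[tuple[int, int]] = []
    features: list[Feature] = []
    for s, kind, name in implants:
        for _ in range(200):
            start = int(rng.integers(0, length - len(s)))
            if all(
                start + len(s) <= a or start >= a + ln for a, ln in placed
            ):
                placed.append((start, len(s)))
                seq[start : start + len(s)] = list(s)
                if kind == "ORF":
                    features.append(
                        Feature("ORF", name, ((start, start + len(s), "+"),))
                    )
                break
        else:
            raise ValueError("could not place implants without overlap")

    for gi in range(n_genes):
        glen = int(rng.integers(300, 2000))
        start = int(rng.integers(0, length))
        features.append(
            Feature(
                "gene",
                f"gene{gi}",
                ((start, start + min(glen, length - 1), "+"),),
            )
        )
    return CircularGenome(f"anc_s{seed}", "".join(seq), features)


# ---------------------------------------------------------------------------
# event application


def _realize(ev: EvolEvent, L: int, rng) -> EvolEvent:
    """Fill in any unset coordinates for the current genome length."""
    p = dict(ev.params)
    kind = ev.kind
    if kind in ("duplication", "inversion", "translocation", "deletion"):
        ln = int(p["length"])
        if ln >= L and kind == "deletion":
            raise ValueError("deletion longer than genome")
        if ln > L:
            raise ValueError(f"{kind} longer than genome")
        if p.get("start") is None:
            p["start"] = int(rng.integers(0, L - ln)) if ln < L else 0
        if kind in ("duplication", "translocation") and p.get("dest") is None:
            # insertion point outside the source segment, so the two copies
            # of a duplication stay contiguous
            s = p["start"]
            free = L - ln
            if free <= 0:
                p["dest"] = 0
            else:
                off = int(rng.integers(0, free + 1))
                p["dest"] = (s + ln + off) % L
    elif kind == "insertion":
        if "seq" not in p or p["seq"] is None:
            p["seq"] = _random_seq(rng, int(p["length"]))
        p["length"] = len(p["seq"])
        if p.get("pos") is None:
            p["pos"] = int(rng.integers(0, L))
    elif kind == "substitution_batch":
        count = int(p.get("count", 0))
        if count > L:
            raise ValueError("more substitutions than positions")
        if p.get("positions") is None:
            p["positions"] = sorted(
                int(x) for x in rng.choice(L, size=count, replace=False)
            )
        if p.get("to") is None:
            kappa = float(p.get("ts_tv_ratio", 1.0))
            p["to"] = None  # drawn during application (needs current bases)
            p["ts_tv_ratio"] = kappa
    return EvolEvent(kind, p, ev.applied_at)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _apply_one(seq: str, ev: EvolEvent, rng) -> tuple[str, EvolEvent]:
    L = len(seq)
    p = dict(ev.params)
    kind = ev.kind
    if kind == "deletion":
        s, ln = p["start"] % L, p["length"]
        e = s + ln
        seq = seq[:s] + seq[e:] if e <= L else seq[e - L : s]
    elif kind == "insertion":
        pos = p["pos"] % L
        seq = seq[:pos] + p["seq"] + seq[pos:]
    elif kind == "duplication":
        s, ln, dest = p["start"] % L, p["length"], p["dest"]
        e = s + ln
        segment = seq[s:e] if e <= L else seq[s:] + seq[: e - L]
        dest %= L
        seq = seq[:dest] + segment + seq[dest:]
        p["dest"] = dest
    elif kind == "inversion":
        s, ln = p["start"] % L, p["length"]
        e = s + ln
        if e <= L:
            seq = seq[:s] + revcomp(seq[s:e]) + seq[e:]
        else:
            seg = revcomp(seq[s:] + seq[: e - L])
            seq = seg[L - s :] + seq[e - L : s] + seg[: L - s]
    elif kind == "translocation":
        s, ln, dest = p["start"] % L, p["length"], p["dest"] % L
        e = s + ln
        if e > L:
            raise ValueError("translocation segment may not wrap")
        segment = seq[s:e]
        rest = seq[:s] + seq[e:]
        # dest is a position on the *original* circle, remapped to the
        # excised circle so the realized event is replayable
        dest_adj = dest - ln if dest >= e else dest
        dest_adj %= len(rest)
        seq = rest[:dest_adj] + segment + rest[dest_adj:]
        p["dest_realized"] = dest_adj
    elif kind == "substitution_batch":
        arr = list(seq)
        to = p.get("to")
        realized_to = []
        kappa = float(p.get("ts_tv_ratio", 1.0))
        for i, pos in enumerate(p["positions"]):
            ref = arr[pos]
            if to is not None:
                alt = to[i]
            else:
                tv = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
                w = np.array([kappa, 1.0, 1.0])
                w = w / w.sum()
                alt = str(rng.choice([_TRANSITION[ref]] + tv, p=w))
            arr[pos] = alt
            realized_to.append(alt)
        p["to"] = realized_to
        seq = "".join(arr)
    return seq, EvolEvent(kind, p, ev.applied_at)


def _remap_features(feats, ev: EvolEvent, old_len: int):
    """Shift/truncate features through a structural event (best effort).

    Features whose interval is hit by a breakpoint are renamed with a
    ``~trunc`` suffix and clipped; substitutions leave features unchanged.
    """
    kind, p = ev.kind, ev.params
    if kind == "substitution_batch":
        return list(feats)
    out = []
    for f in feats:
        new_ivs = []
        truncated = False
        for s, e, st in f.intervals:
            if kind == "deletion":
                ds, dl = p["start"], p["length"]
                de = ds + dl
                if e <= ds:
                    new_ivs.append((s, e, st))
                elif s >= de:
                    new_ivs.append((s - dl, e - dl, st))
                else:
                    truncated = True
            elif kind == "insertion":
                pos, il = p["pos"], p["length"]
                if e <= pos:
                    new_ivs.append((s, e, st))
                elif s >= pos:
                    new_ivs.append((s + il, e + il, st))
                else:
                    truncated = True
            elif kind == "duplication":
                dest, dl = p["dest"], p["length"]
                if e <= dest:
                    new_ivs.append((s, e, st))
                elif s >= dest:
                    new_ivs.append((s + dl, e + dl, st))
                else:
                    truncated = True
            elif kind == "inversion":
                vs, vl = p["start"], p["length"]
                ve = vs + vl
                if e <= vs or s >= ve:
                    new_ivs.append((s, e, st))
                elif s >= vs and e <= ve:  # wholly inside: flipped
                    ns = vs + (ve - e)
                    new_ivs.append((ns, ns + (e - s), "-" if st == "+" else "+"))
                else:
                    truncated = True
            elif kind == "translocation":
                ts, tl = p["start"], p["length"]
                te = ts + tl
                if e <= ts:
                    new_ivs.append((s, e, st))
                elif s >= te:
                    new_ivs.append((s - tl, e - tl, st))
                elif s >= ts and e <= te:
                    # rides along with the segment
                    dest = p.get("dest_realized", 0)
                    new_ivs.append((dest + (s - ts), dest + (e - ts), st))
                else:
                    truncated = True
        if new_ivs:
            name = f.name + "~trunc" if truncated else f.name
            out.append(Feature(f.key, name, tuple(new_ivs), f.product_group))
        elif f.intervals:
            out.append(
                Feature(f.key, f.name + "~trunc", f.intervals, f.product_group)
            )
    return out


def apply_events(
    parent: CircularGenome, events, seed: int = 0, child_id: str | None = None
) -> tuple[CircularGenome, EventLog]:
    """Apply events in order to a parent genome, returning child + log.

    The log stores realized coordinates; :func:`replay` on (parent, log)
    reproduces the child exactly.
    """
    rng = np.random.default_rng(seed)
    seq = parent.seq
    feats = list(parent.annotations)
    realized: list[EvolEvent] = []
    for order, ev in enumerate(events):
        if isinstance(ev, dict):
            ev = EvolEvent(ev["kind"], dict(ev.get("params", {})))
        ev = _realize(ev, len(seq), rng)
        old_len = len(seq)
        seq, done = _apply_one(seq, ev, rng)
        done.applied_at = order
        feats = _remap_features(feats, done, old_len)
        realized.append(done)
    cid = child_id or f"{parent.id}_c{seed}"
    child = CircularGenome(cid, seq, feats)
    return child, EventLog(parent.id, cid, realized, seed)


def replay(parent: CircularGenome, log: EventLog) -> CircularGenome:
    """Re-apply a realized event log; byte-identical to the logged child."""
    rng = np.random.default_rng(log.seed)
    seq = parent.seq
    for ev in log.events:
        if ev.kind == "substitution_batch" and ev.params.get("to") is None:
            raise ValueError("log not realized")
        seq, _ = _apply_one(seq, ev, rng)
    return CircularGenome(log.child_id, seq)


# ---------------------------------------------------------------------------
# clade simulation


def _parse_topology(t):
    """Nested tuples/lists of leaf labels -> internal representation."""
    if isinstance(t, str):
        return t
    return tuple(_parse_topology(x) for x in t)


def _leaves(t):
    if isinstance(t, str):
        return [t]
    out = []
    for c in t:
        out.extend(_leaves(c))
    return out


def simulate_clade(
    topology,
    branch_events: dict | None = None,
    default_events: list | None = None,
    seed: int = 0,
    root: CircularGenome | None = None,
    root_kwargs: dict | None = None,
):
    """Evolve genomes down a clade topology, recording the truth tree.

    ``topology`` is nested tuples of leaf labels, e.g. ``(("A","B"),"C")``.
    ``branch_events`` maps a leaf label or a clade (frozenset of its leaves)
    to the event list for the branch leading to it; branches not listed use
    ``default_events`` (may be empty).  Events are specified as dicts, e.g.
    ``{"kind": "substitution_batch", "params": {"count": 50}}``.

    Returns ``(leaf genomes, truth newick string, logs by child label)``.
    """
    topo = _parse_topology(topology)
    leaves = _leaves(topo)
    if len(leaves) < 2:
        raise ValueError("need >= 2 leaves")
    branch_events = branch_events or {}
    default_events = default_events if default_events is not None else []
    rng = np.random.default_rng(seed)
    if root is None:
        kw = dict(length=20000, seed=int(rng.integers(2**31)))
        kw.update(root_kwargs or {})
        root = generate_ancestor(**kw)
    if root.length == 0:
        raise ValueError("zero-length root genome")

    genomes: dict[str, CircularGenome] = {}
    logs: dict[str, EventLog] = {}

    def events_for(node):
        key = node if isinstance(node, str) else frozenset(_leaves(node))
        if key in branch_events:
            return branch_events[key]
        return default_events

    def walk(node, genome):
        label = node if isinstance(node, str) else "+".join(_leaves(node))
        child, log = apply_events(
            genome,
            events_for(node),
            seed=int(rng.integers(2**31)),
            child_id=label,
        )
        logs[label] = log
        if isinstance(node, str):
            genomes[node] = child
            return node
        parts = [walk(c, child) for c in node]
        return "(" + ",".join(parts) + ")"

    newick = "(" + ",".join(walk(c, root) for c in topo) + ");"
    return [genomes[l] for l in leaves], newick, logs
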