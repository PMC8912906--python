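"""Quadripartite partition, GC content and dispersed-repeat discovery.

A typical plastome is a circle of four blocks — large single copy (LSC),
inverted repeat b (IRb), small single copy (SSC), inverted repeat a (IRa) —
where IRa is the reverse complement of IRb.  ``detect_quadripartite`` finds
the maximal pair of disjoint reverse-complement-identical segments on the
circle by exact k-mer seeding (k = 25 by default) with gap-free merging of
near-identical runs, and labels the two intervening single-copy arcs by
length (the longer one is the LSC).

``find_repeats`` reports dispersed repeats of the four REPuter kinds
(forward, palindrome, reverse, complement) above a length and identity
cutoff, using exact 8-mer seeds extended/merged along diagonals without
gaps.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from plastomarker.errors import StructureNotFound
from plastomarker.plastome_io import PlastomeRecord
from plastomarker.sequtils import complement, gc_fraction, revcomp

REPEAT_KINDS = ("forward", "palindrome", "reverse", "complement")


@dataclass
class QuadripartiteStructure:
    """Coordinates (0-based half-open; end may exceed length_bp when a region
    wraps the deposited origin) and lengths of the four plastome blocks."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    length_bp: int

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    def region_of(self, pos: int) -> str:
        """Return LSC/IR/SSC for a forward-strand position."""
        n = self.length_bp
        for name, (s, e) in (("LSC", self.lsc), ("IR", self.irb),
                             ("SSC", self.ssc), ("IR", self.ira)):
            if s <= pos < e or s <= pos + n < e:
                return name
        raise ValueError(f"position {pos} outside [0, {n})")


@dataclass
class RepeatHit:
    kind: str
    pos1: int
    pos2: int
    length: int
    identity: float


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence; N bases are excluded from the denominator."""
    return gc_fraction(sequence.upper())


# ---------------------------------------------------------------------------
# seed-and-merge machinery (shared by IR detection and repeat finding)
# ---------------------------------------------------------------------------

def _exact_diagonal_runs(query: str, target: str, k: int,
                         skip_diag: int | None = None):
    """Maximal exact match runs between query and target via k-mer seeds.

    Yields (qstart, tstart, length) for every maximal run of consecutive
    matching k-mers along a diagonal.  ``skip_diag`` drops one diagonal
    (used to suppress the trivial self-match of a sequence against itself).
    """
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(target) - k + 1):
        index[target[j:j + k]].append(j)
    by_diag: dict[int, list[int]] = defaultdict(list)
    for i in range(len(query) - k + 1):
        for j in index.get(query[i:i + k], ()):
            d = i - j
            if skip_diag is not None and d == skip_diag:
                continue
            by_diag[d].append(i)
    for d, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i == prev + 1:
                prev = i
                continue
            yield run_start, run_start - d, prev - run_start + k
            run_start = prev = i
        yield run_start, run_start - d, prev - run_start + k


def _merge_runs(runs, min_identity: float):
    """Greedily merge same-diagonal runs whose combined ungapped identity
    stays >= min_identity; returns (qstart, tstart, length, identity)."""
    by_diag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for q, t, ln in runs:
        by_diag[q - t].append((q, ln))
    out = []
    for d, items in by_diag.items():
        items.sort()
        cq, cl = items[0]
        matches = cl
        for q, ln in items[1:]:
            gap = q - (cq + cl)
            new_len = q + ln - cq
            new_matches = matches + ln
            if gap >= 0 and new_matches / new_len >= min_identity:
                cl, matches = new_len, new_matches
            else:
                out.append((cq, cq - d, cl, matches / cl))
                cq, cl, matches = q, ln, ln
        out.append((cq, cq - d, cl, matches / cl))
    return out


# ---------------------------------------------------------------------------
# quadripartite detection
# ---------------------------------------------------------------------------

def detect_quadripartite(record: PlastomeRecord | str,
                         min_ir_len: int = 10000,
                         seed_k: int = 25,
                         min_copy_identity: float = 0.995) -> QuadripartiteStructure:
    """Locate LSC/IRb/SSC/IRa on a circular plastome.

    The sequence is doubled so an inverted-repeat copy spanning the deposited
    origin is still found; candidate copy pairs are maximal (merged) exact
    inverted matches, the winner is the longest pair whose two copies are
    disjoint on the circle.  Raises :class:`StructureNotFound` when no
    inverted duplication of at least ``min_ir_len`` exists.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_ir_len:
        raise StructureNotFound(
            f"sequence of {n} bp cannot hold two IR copies of {min_ir_len} bp")
    doubled = seq + seq
    rc = revcomp(doubled)
    runs = _exact_diagonal_runs(doubled, rc, k=seed_k)
    merged = _merge_runs(runs, min_copy_identity)

    best = None
    seen = set()
    for q, t, ln, ident in merged:
        if ln < min_ir_len or ln > n // 2:
            continue
        # target coords are on revcomp(doubled): map back to doubled coords
        p = len(doubled) - t - ln
        a, b = sorted((q % n, p % n))
        key = (a, b, ln)
        if key in seen:
            continue
        seen.add(key)
        # disjoint on the circle?
        if _circular_overlap(a, ln, b, ln, n):
            continue
        if best is None or ln > best[2] or (ln == best[2] and (a, b) < best[:2]):
            best = (a, b, ln, ident)
    if best is None:
        raise StructureNotFound(
            f"no inverted repeat >= {min_ir_len} bp found")
    s1, s2, ir_len, _ = best
    gap12 = (s2 - (s1 + ir_len)) % n      # arc after copy1 (clockwise to copy2)
    gap21 = (s1 - (s2 + ir_len)) % n      # arc after copy2
    assert 2 * ir_len + gap12 + gap21 == n
    # the copy followed (clockwise) by the shorter arc is IRb (LSC-IRb-SSC-IRa)
    if gap12 <= gap21:
        irb, ira = (s1, s1 + ir_len), (s2, s2 + ir_len)
        ssc = (s1 + ir_len, s1 + ir_len + gap12)
        lsc = (s2 + ir_len, s2 + ir_len + gap21)
    else:
        irb, ira = (s2, s2 + ir_len), (s1, s1 + ir_len)
        ssc = (s2 + ir_len, s2 + ir_len + gap21)
        lsc = (s1 + ir_len, s1 + ir_len + gap12)
    norm = tuple((s % n, s % n + (e - s)) for s, e in (lsc, irb, ssc, ira))
    return QuadripartiteStructure(lsc=norm[0], irb=norm[1], ssc=norm[2],
                                  ira=norm[3], length_bp=n)


def _circular_overlap(a: int, la: int, b: int, lb: int, n: int) -> bool:
    """Do circular intervals [a, a+la) and [b, b+lb) overlap modulo n?"""
    for shift in (-n, 0, n):
        if a < b + lb + shift and b + shift < a + la:
            return True
    return False


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------

def find_repeats(sequence: str, min_len: int = 30,
                 min_identity: float = 0.90,
                 seed_k: int = 8) -> list[RepeatHit]:
    """All maximal dispersed repeat pairs of the four kinds.

    Kinds follow the REPuter taxonomy: *forward* (segment copied as-is),
    *palindrome* (copied as reverse complement), *reverse* (copied reversed),
    *complement* (copied complemented, unreversed).  Identity is
    matches/columns of the ungapped pairing.  Self-trivial pairs
    (pos1 == pos2) are dropped and hits wholly contained in a longer hit of
    the same kind are suppressed.
    """
    if min_len < 8:
        raise ValueError("min_len below 8 not supported by the seed scheme")
    seq = sequence.upper()
    n = len(seq)
    if n < min_len:
        raise ValueError("sequence shorter than min_len")
    k = min(seed_k, min_len)

    transforms = {
        "forward": seq,
        "palindrome": revcomp(seq),
        "reverse": seq[::-1],
        "complement": complement(seq),
    }
    hits: list[RepeatHit] = []
    for kind, target in transforms.items():
        skip = 0 if kind == "forward" else None
        runs = _exact_diagonal_runs(seq, target, k=k, skip_diag=skip)
        for q, t, ln, ident in _merge_runs(runs, min_identity):
            if ln < min_len or ident < min_identity:
                continue
            if kind in ("palindrome", "reverse"):
                pos2 = n - t - ln
            else:
                pos2 = t
            p1, p2 = min(q, pos2), max(q, pos2)
            if p1 == p2:
                continue
            hits.append(RepeatHit(kind=kind, pos1=p1, pos2=p2,
                                  length=ln, identity=ident))
    # dedupe symmetric discoveries, then suppress contained hits per kind
    uniq = {(h.kind, h.pos1, h.pos2, h.length): h for h in hits}
    hits = sorted(uniq.values(), key=lambda h: (-h.length, h.kind, h.pos1, h.pos2))
    kept: list[RepeatHit] = []
    for h in hits:
        contained = any(
            o.kind == h.kind and o.length > h.length
            and o.pos1 <= h.pos1 and h.pos1 + h.length <= o.pos1 + o.length
            and o.pos2 <= h.pos2 and h.pos2 + h.length <= o.pos2 + o.length
            for o in kept)
        if not contained:
            kept.append(h)
    return kept
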