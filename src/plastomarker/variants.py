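"""Pairwise plastome alignment, normalized SNP/InDel calling and the
pairwise variant-count matrix.

Two collinear plastomes are aligned end-to-end by chaining unique shared
31-mers (longest-increasing-subsequence chaining) and closing the
inter-anchor gaps with an affine-gap global alignment (match +1, mismatch
-2, gap open -5, gap extend -1).  Each mismatch column of the resulting
alignment is one SNP; each maximal run of gap columns is one InDel event
regardless of its length — counting events, not bases, is what makes a
43-event InDel list compatible with a 271 bp length difference.  InDels are
left-normalized against the first genome so calls are independent of the
aligner's gap-placement dialect.

The panel-level :func:`variant_matrix` assembles all pairwise counts into
the familiar two-triangle table (InDel events above the diagonal, SNP counts
below, with the SNP count as a percentage of the mean genome length in
brackets).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from plastomarker.errors import CollinearityError, CoordinateError
from plastomarker.plastome_io import PlastomeRecord
from plastomarker.sequtils import revcomp
from plastomarker.structure import QuadripartiteStructure
from plastomarker.util import round_half_up

ANCHOR_K = 31


@dataclass
class Variant:
    kind: str                    # 'SNP' | 'InDel'
    ref_pos: int                 # 0-based on genome A
    ref_allele: str
    alt_allele: str
    region: str | None = None    # LSC | IR | SSC
    context: str | None = None   # genic-exon | genic-intron | intergenic
    gene: str | None = None

    @property
    def delta(self) -> int:
        """Signed length change alt - ref (insertions positive)."""
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class PairwiseAlignment:
    """End-to-end gapped alignment of two plastomes (rows over {A,C,G,T,N,-})."""

    label_a: str
    label_b: str
    aligned_a: str
    aligned_b: str
    b_flipped: bool = False
    seq_a: str = field(default="", repr=False)
    seq_b: str = field(default="", repr=False)

    def identity(self) -> float:
        m = sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                if x == y and x != "-")
        return m / len(self.aligned_a)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -1
    return al


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _chain_anchors(a_pos: dict[str, int], b_pos: dict[str, int]):
    """Collinear chain (LIS in b-coordinates) of shared unique k-mer matches."""
    matches = sorted((pa, b_pos[km]) for km, pa in a_pos.items() if km in b_pos)
    tails: list[int] = []          # tails[i] = min pb ending an LIS of length i+1
    back: list[int] = []
    chain_idx: list[int] = []
    for idx, (_, pb) in enumerate(matches):
        j = bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            chain_idx.append(idx)
        else:
            tails[j] = pb
            chain_idx[j] = idx
        back.append(chain_idx[j - 1] if j > 0 else -1)
    chain = []
    cur = chain_idx[-1] if chain_idx else -1
    while cur != -1:
        chain.append(matches[cur])
        cur = back[cur]
    chain.reverse()
    return chain


def _anchor_blocks(chain, k: int):
    """Merge chained anchors into maximal co-diagonal exact blocks."""
    blocks = []
    for pa, pb in chain:
        if blocks and pa - blocks[-1][0] == pb - blocks[-1][1] \
                and pa <= blocks[-1][0] + blocks[-1][2]:
            blocks[-1][2] = pa + k - blocks[-1][0]
        else:
            blocks.append([pa, pb, k])
    # trim block heads so consecutive blocks never overlap on either genome
    # (repeat-context indels make shifted diagonals overlap by a few bases)
    out = []
    for pa, pb, ln in blocks:
        if out:
            t = max(out[-1][0] + out[-1][2] - pa,
                    out[-1][1] + out[-1][2] - pb, 0)
            if t >= ln:
                continue
            pa, pb, ln = pa + t, pb + t, ln - t
        out.append([pa, pb, ln])
    return out


def align_plastomes(a: PlastomeRecord, b: PlastomeRecord,
                    k: int = ANCHOR_K,
                    min_coverage: float = 0.90) -> PairwiseAlignment:
    """Globally align two collinear plastomes.

    Orientation of ``b`` is harmonized first: if its reverse complement
    shares more unique anchors with ``a`` than the forward sequence, it is
    flipped.  Raises :class:`CollinearityError` when the anchor chain covers
    less than ``min_coverage`` of either genome.
    """
    seq_a, seq_b = a.sequence, b.sequence
    ka = _unique_kmers(seq_a, k)
    kb_f = _unique_kmers(seq_b, k)
    shared_f = len(ka.keys() & kb_f.keys())
    seq_b_rc = revcomp(seq_b)
    kb_r = _unique_kmers(seq_b_rc, k)
    shared_r = len(ka.keys() & kb_r.keys())
    flipped = shared_r > shared_f
    if flipped:
        seq_b, kb = seq_b_rc, kb_r
    else:
        kb = kb_f

    chain = _chain_anchors(ka, kb)
    blocks = _anchor_blocks(chain, k)
    covered = sum(ln for _, _, ln in blocks)
    if covered < min_coverage * max(len(seq_a), len(seq_b)):
        raise CollinearityError(
            f"anchor chain covers {covered} bp "
            f"(< {min_coverage:.0%} of {a.individual_label} / "
            f"{b.individual_label}); input likely rearranged")

    al = _aligner()
    rows_a, rows_b = [], []
    prev_a = prev_b = 0
    for pa, pb, ln in blocks + [[len(seq_a), len(seq_b), 0]]:
        ga, gb = seq_a[prev_a:pa], seq_b[prev_b:pb]
        if ga or gb:
            if not ga:
                rows_a.append("-" * len(gb))
                rows_b.append(gb)
            elif not gb:
                rows_a.append(ga)
                rows_b.append("-" * len(ga))
            elif ga == gb:
                rows_a.append(ga)
                rows_b.append(gb)
            else:
                sub = al.align(ga, gb)[0]
                rows_a.append(str(sub[0]))
                rows_b.append(str(sub[1]))
        rows_a.append(seq_a[pa:pa + ln])
        rows_b.append(seq_b[pb:pb + ln])
        prev_a, prev_b = pa + ln, pb + ln
    return PairwiseAlignment(
        label_a=a.individual_label, label_b=b.individual_label,
        aligned_a="".join(rows_a), aligned_b="".join(rows_b),
        b_flipped=flipped, seq_a=seq_a, seq_b=seq_b)


def _left_normalize(pos: int, allele: str, seq: str) -> tuple[int, str]:
    """Shift a pure insertion/deletion leftward through repeat context."""
    while pos > 0 and allele and seq[pos - 1] == allele[-1]:
        allele = seq[pos - 1] + allele[:-1]
        pos -= 1
    return pos, allele


def call_variants(alignment: PairwiseAlignment) -> list[Variant]:
    """SNP and InDel events from an end-to-end alignment.

    One maximal run of gap columns = one InDel event; each mismatch column =
    one SNP.  InDels are left-normalized against genome A.
    """
    ga, gb = alignment.aligned_a, alignment.aligned_b
    seq_a = alignment.seq_a or ga.replace("-", "")
    variants: list[Variant] = []
    ref_pos = 0
    i, n = 0, len(ga)
    while i < n:
        x, y = ga[i], gb[i]
        if x != "-" and y != "-":
            if x != y:
                variants.append(Variant("SNP", ref_pos, x, y))
            ref_pos += 1
            i += 1
        elif x == "-":                      # insertion in B
            j = i
            ins = []
            while j < n and ga[j] == "-":
                ins.append(gb[j])
                j += 1
            pos, allele = _left_normalize(ref_pos, "".join(ins), seq_a)
            variants.append(Variant("InDel", pos, "", allele))
            i = j
        else:                               # deletion from A
            j = i
            dele = []
            while j < n and gb[j] == "-":
                dele.append(ga[j])
                j += 1
            pos, allele = _left_normalize(ref_pos, "".join(dele), seq_a)
            variants.append(Variant("InDel", pos, allele, ""))
            ref_pos += j - i
            i = j
    return sorted(variants, key=lambda v: (v.ref_pos, v.kind))


def classify_variants(variants: list[Variant], record: PlastomeRecord,
                      structure: QuadripartiteStructure) -> list[Variant]:
    """Fill region (LSC/IR/SSC) and genic context for variants on genome A."""
    for v in variants:
        if not 0 <= v.ref_pos < record.length_bp:
            raise CoordinateError(f"variant position {v.ref_pos} outside genome")
        v.region = structure.region_of(v.ref_pos)
        v.context, v.gene = "intergenic", None
        for g in record.genes:
            s, e = g.span
            if s <= v.ref_pos < e:
                in_exon = any(es <= v.ref_pos < ee for es, ee in g.exons)
                v.context = "genic-exon" if in_exon else "genic-intron"
                v.gene = g.name
                break
    return variants


@dataclass
class VariantMatrix:
    """Pairwise SNP (lower triangle) and InDel (upper triangle) counts."""

    labels: list[str]
    snp_counts: np.ndarray       # symmetric
    indel_counts: np.ndarray     # symmetric
    snp_pct: np.ndarray          # symmetric, 2 dp of 100*snp/mean length

    def to_table(self) -> pd.DataFrame:
        """Two-triangle table: InDels above the diagonal, 'SNPs (pct)' below."""
        m = len(self.labels)
        out = pd.DataFrame("", index=self.labels, columns=self.labels)
        for i in range(m):
            for j in range(m):
                if i < j:
                    out.iloc[i, j] = str(int(self.indel_counts[i, j]))
                elif i > j:
                    out.iloc[i, j] = (f"{int(self.snp_counts[i, j])} "
                                      f"({self.snp_pct[i, j]:.2f})")
        return out


def variant_matrix(records: list[PlastomeRecord]) -> VariantMatrix:
    """All pairwise alignments of a panel assembled into a variant matrix."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    m = len(records)
    snp = np.zeros((m, m), dtype=int)
    indel = np.zeros((m, m), dtype=int)
    pct = np.zeros((m, m), dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                aln = align_plastomes(records[i], records[j])
            except CollinearityError as exc:
                raise CollinearityError(
                    f"pair ({records[i].individual_label}, "
                    f"{records[j].individual_label}): {exc}") from exc
            vs = call_variants(aln)
            ns = sum(1 for v in vs if v.kind == "SNP")
            ni = sum(1 for v in vs if v.kind == "InDel")
            mean_len = (records[i].length_bp + records[j].length_bp) / 2
            p = round_half_up(100.0 * ns / mean_len, 2)
            snp[i, j] = snp[j, i] = ns
            indel[i, j] = indel[j, i] = ni
            pct[i, j] = pct[j, i] = p
    return VariantMatrix([r.individual_label for r in records], snp, indel, pct)
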