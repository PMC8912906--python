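"""Shared-CDS neighbor-joining phylogeny with bootstrap supports.

The workflow mirrors the classic plastome pipeline: extract the protein
coding genes present in every genome of the panel, align each gene, glue the
gene blocks into one concatenated matrix, compute pairwise distances
(Kimura 2-parameter by default, p-distance as a fallback) under pairwise
deletion of gap/N sites, and run Saitou-Nei neighbor joining.  Supports come
from column bootstrap: resample alignment columns with replacement, rebuild
the tree, and report the percentage of replicates containing each internal
bipartition of the full-data tree.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from plastomarker.plastome_io import PlastomeRecord
from plastomarker.sequtils import revcomp

# ---------------------------------------------------------------------------
# shared CDS extraction
# ---------------------------------------------------------------------------


def extract_shared_cds(records: list[PlastomeRecord]) -> dict[str, dict[str, str]]:
    """Genes (CDS) present in every record, spliced to one sequence per taxon.

    Gene names are matched case-insensitively; when a gene is duplicated
    (e.g. inside the inverted repeat) the first annotated copy is used.
    Multi-exon genes are spliced in annotation order and reverse-complemented
    for minus-strand genes.  Raises ``ValueError`` when no gene is shared.
    """
    per_record: list[dict[str, str]] = []
    display: dict[str, str] = {}
    for rec in records:
        genes: dict[str, str] = {}
        for g in rec.genes:
            if g.kind != "CDS":
                continue
            key = g.name.lower()
            if key in genes:
                continue                      # first copy wins (IR duplicate)
            spliced = "".join(rec.sequence[s:e] for s, e in g.exons)
            if g.strand == "-":
                spliced = revcomp(spliced)
            genes[key] = spliced
            display.setdefault(key, g.name)
        per_record.append(genes)
    shared = set(per_record[0])
    for genes in per_record[1:]:
        shared &= set(genes)
    if not shared:
        raise ValueError("no protein-coding gene shared by all records")
    return {
        display[key]: {rec.individual_label: genes[key]
                       for rec, genes in zip(records, per_record)}
        for key in sorted(shared)
    }


# ---------------------------------------------------------------------------
# per-gene alignment and concatenation
# ---------------------------------------------------------------------------

@dataclass
class ConcatenatedAlignment:
    taxa: list[str]
    rows: dict[str, str]                       # taxon -> gapped sequence
    partitions: dict[str, tuple[int, int]]     # gene -> column range

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_matrix(self) -> np.ndarray:
        """(n_taxa, width) array of single-character bytes, taxon order = taxa."""
        return np.array([list(self.rows[t]) for t in self.taxa])


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -1
    return al


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _align_gene(seqs: dict[str, str]) -> dict[str, str] | None:
    """Star-progressive multiple alignment of one gene.

    The most central sequence (highest average 8-mer Jaccard similarity to
    the rest) is the merge reference; every other sequence is aligned to it
    pairwise and insertion columns are merged by taking, at each reference
    position, the longest insertion seen in any taxon.  Returns None when
    some sequence falls below 70% pairwise identity to the reference.
    """
    taxa = sorted(seqs)
    uniq = set(seqs.values())
    if len(uniq) == 1:
        return dict(seqs)
    ksets = {t: _kmer_set(seqs[t]) for t in taxa}

    def centrality(t):
        sims = [len(ksets[t] & ksets[u]) / max(1, len(ksets[t] | ksets[u]))
                for u in taxa if u != t]
        return sum(sims) / len(sims)

    ref = max(taxa, key=lambda t: (centrality(t), t))
    al = _aligner()
    R = len(seqs[ref])
    # per taxon: char at each ref position; insertions keyed by ref position
    chars: dict[str, list[str]] = {}
    inserts: dict[str, dict[int, str]] = {}
    for t in taxa:
        if t == ref:
            chars[t] = list(seqs[ref])
            inserts[t] = {}
            continue
        sub = al.align(seqs[ref], seqs[t])[0]
        gr, gt = str(sub[0]), str(sub[1])
        matches = sum(1 for a, b in zip(gr, gt) if a == b and a != "-")
        if matches / len(gr) < 0.70:
            return None
        col = [""] * R
        ins: dict[int, str] = {}
        rpos = -1
        for a, b in zip(gr, gt):
            if a == "-":
                ins[rpos] = ins.get(rpos, "") + b
            else:
                rpos += 1
                col[rpos] = b
        chars[t] = col
        inserts[t] = ins
    ins_width = {p: max(len(inserts[t].get(p, "")) for t in taxa)
                 for p in range(-1, R)}
    rows = {}
    for t in taxa:
        parts = []
        for p in range(-1, R):
            w = ins_width[p]
            if w:
                s = inserts[t].get(p, "")
                parts.append(s + "-" * (w - len(s)))
            if p >= 0:
                parts.append(chars[t][p] if chars[t][p] else "-")
        rows[t] = "".join(parts)
    return rows


def align_and_concatenate(gene_sets: dict[str, dict[str, str]]
                          ) -> ConcatenatedAlignment:
    """Align each gene, concatenate blocks, record gene -> column partitions.

    Genes whose sequences drop below the 70% identity regime are dropped
    with a warning rather than poisoning the concatenation.
    """
    taxa = sorted({t for seqs in gene_sets.values() for t in seqs})
    blocks: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    offset = 0
    for gene in sorted(gene_sets):
        aligned = _align_gene(gene_sets[gene])
        if aligned is None:
            warnings.warn(f"gene {gene} below identity threshold: dropped")
            continue
        width = len(next(iter(aligned.values())))
        for t in taxa:
            rows[t].append(aligned[t])
        blocks[gene] = (offset, offset + width)
        offset += width
    if not blocks:
        raise ValueError("no gene survived the identity filter")
    return ConcatenatedAlignment(
        taxa=taxa, rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=blocks)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}

# per-column pair classes: 0 excluded, 1 identical, 2 transition, 3 transversion
def _pair_classes(row_i: np.ndarray, row_j: np.ndarray) -> np.ndarray:
    valid = np.isin(row_i, list("ACGT")) & np.isin(row_j, list("ACGT"))
    cls = np.zeros(len(row_i), dtype=np.uint8)
    same = row_i == row_j
    puri = np.isin(row_i, list(_PURINES))
    purj = np.isin(row_j, list(_PURINES))
    cls[valid & same] = 1
    cls[valid & ~same & (puri == purj)] = 2
    cls[valid & ~same & (puri != purj)] = 3
    return cls


def _distance_from_counts(n_match: int, n_ts: int, n_tv: int,
                          model: str) -> float:
    total = n_match + n_ts + n_tv
    if total == 0:
        raise ValueError("no comparable sites between a pair (all gaps/N)")
    if model == "p-distance":
        return (n_ts + n_tv) / total
    if model == "k2p":
        P, Q = n_ts / total, n_tv / total
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            raise ValueError(
                "K2P distance undefined (saturation); try model='p-distance'")
        return -0.5 * math.log(w1 * math.sqrt(w2))
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(alignment: ConcatenatedAlignment,
                    model: str = "k2p") -> pd.DataFrame:
    """Pairwise distances under pairwise deletion of gap/N sites."""
    mat = alignment.to_matrix()
    taxa = alignment.taxa
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, j in itertools.combinations(range(len(taxa)), 2):
        cls = _pair_classes(mat[i], mat[j])
        counts = np.bincount(cls, minlength=4)
        d = _distance_from_counts(counts[1], counts[2], counts[3], model)
        D.iloc[i, j] = D.iloc[j, i] = d
    return D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node), branch lengths, supports."""

    root: TreeNode
    taxa: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal splits: the side not containing the first taxon."""
        ref = min(self.taxa)
        all_taxa = set(self.taxa)
        splits = set()

        def walk(node):
            for child, _ in node.children:
                leaves = set(child.leaves())
                side = leaves if ref not in leaves else all_taxa - leaves
                if 2 <= len(side) <= len(all_taxa) - 2:
                    splits.add(frozenset(side))
                walk(child)

        walk(self.root)
        return splits

    def are_siblings(self, a: str, b: str) -> bool:
        return frozenset(_canon({a, b}, set(self.taxa))) in self.bipartitions()

    def newick(self) -> str:
        def fmt(node, length):
            if not node.children:
                return f"{node.name}:{length:.6f}"
            inner = ",".join(fmt(c, bl) for c, bl in node.children)
            label = ""
            if self.supports:
                side = _canon(set(node.leaves()), set(self.taxa))
                if frozenset(side) in self.supports:
                    label = str(int(round(self.supports[frozenset(side)])))
            return f"({inner}){label}:{length:.6f}"

        inner = ",".join(fmt(c, bl) for c, bl in self.root.children)
        return f"({inner});"


def _canon(side: set, all_taxa: set) -> set:
    ref = min(all_taxa)
    return side if ref not in side else all_taxa - side


def neighbor_joining(dist: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the pair whose smallest
    member label sorts first.  Negative branch lengths are clamped to zero.
    """
    taxa = list(dist.index)
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in taxa}
    D: dict[str, dict[str, float]] = {
        a: {b: float(dist.loc[a, b]) for b in taxa if b != a} for a in taxa}
    # each active cluster is keyed by its smallest leaf label
    active = sorted(taxa)

    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[a].values()) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * D[a][b] - r[a] - r[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best:
                best = key
        _, a, b = best
        d_ab = D[a][b]
        la = d_ab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = d_ab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        key_new = min(a, b)
        newD = {}
        for c in active:
            if c in (a, b):
                continue
            newD[c] = (D[a][c] + D[b][c] - d_ab) / 2
            del D[c][a], D[c][b]
            D[c][key_new] = newD[c]
        D[key_new] = newD
        nodes[key_new] = new
        active = sorted(set(active) - {a, b} | {key_new})

    a, b, c = active
    la = max((D[a][b] + D[a][c] - D[b][c]) / 2, 0.0)
    lb = max((D[a][b] + D[b][c] - D[a][c]) / 2, 0.0)
    lc = max((D[a][c] + D[b][c] - D[a][b]) / 2, 0.0)
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root, taxa=sorted(taxa))


def nj_tree(alignment: ConcatenatedAlignment, model: str = "k2p") -> PhyloTree:
    """Neighbor-joining tree from a concatenated alignment."""
    return neighbor_joining(distance_matrix(alignment, model=model))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(alignment: ConcatenatedAlignment, n: int = 1000,
                      seed: int = 0, model: str = "k2p") -> PhyloTree:
    """Column bootstrap supports on the full-data NJ tree.

    ``n`` whole-column resamples with replacement; support of an internal
    bipartition is the percentage of replicate trees containing it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tree = nj_tree(alignment, model=model)
    taxa = alignment.taxa
    mat = alignment.to_matrix()
    width = mat.shape[1]
    pair_cls = {
        (i, j): _pair_classes(mat[i], mat[j])
        for i, j in itertools.combinations(range(len(taxa)), 2)}
    rng = np.random.default_rng(seed)
    counts = {split: 0 for split in tree.bipartitions()}
    for _ in range(n):
        idx = rng.integers(0, width, size=width)
        D = pd.DataFrame(0.0, index=taxa, columns=taxa)
        try:
            for (i, j), cls in pair_cls.items():
                cnt = np.bincount(cls[idx], minlength=4)
                d = _distance_from_counts(cnt[1], cnt[2], cnt[3], model)
                D.iloc[i, j] = D.iloc[j, i] = d
            rep = neighbor_joining(D)
        except ValueError:
            continue                      # saturated / degenerate resample
        splits = rep.bipartitions()
        for split in counts:
            if split in splits:
                counts[split] += 1
    tree.supports = {s: 100.0 * c / n for s, c in counts.items()}
    return tree
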