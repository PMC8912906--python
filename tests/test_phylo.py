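"""Shared-CDS extraction, concatenated alignment, NJ and bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from plastomarker.phylo import (ConcatenatedAlignment, align_and_concatenate,
                                bootstrap_support, distance_matrix,
                                extract_shared_cds, neighbor_joining, nj_tree)
from plastomarker.plastome_io import GeneAnnotation, PlastomeRecord
from plastomarker.sequtils import random_dna, revcomp


def _rec(label, seq, genes):
    return PlastomeRecord(f"SYN_{label}", "sp", label, seq, genes)


# ---------------------------------------------------------------------------
# shared CDS
# ---------------------------------------------------------------------------

def test_shared_cds_is_the_intersection_of_gene_sets():
    rng = np.random.default_rng(0)
    seq = random_dna(rng, 1000)
    g = lambda name, s, e: GeneAnnotation(name, "+", [(s, e)], "CDS")
    r1 = _rec("t1", seq, [g("g1", 0, 90), g("g2", 100, 190), g("g3", 200, 290)])
    r2 = _rec("t2", seq, [g("G1", 0, 90), g("g2", 100, 190), g("g3", 200, 290)])
    r3 = _rec("t3", seq, [g("g1", 0, 90), g("g2", 100, 190)])
    shared = extract_shared_cds([r1, r2, r3])
    assert set(shared) == {"g1", "g2"}          # case-insensitive match
    assert set(shared["g1"]) == {"t1", "t2", "t3"}


def test_minus_strand_two_exon_gene_splices_to_reverse_complement():
    rng = np.random.default_rng(1)
    seq = random_dna(rng, 500)
    gene = GeneAnnotation("gx", "-", [(50, 110), (150, 210)], "CDS")
    shared = extract_shared_cds([_rec("t1", seq, [gene])])
    assert shared["gx"]["t1"] == revcomp(seq[50:110] + seq[150:210])


def test_ir_duplicated_gene_contributes_one_sequence():
    rng = np.random.default_rng(2)
    seq = random_dna(rng, 600)
    dup = [GeneAnnotation("rrn1", "+", [(10, 100)], "CDS"),
           GeneAnnotation("rrn1", "-", [(400, 490)], "CDS")]
    shared = extract_shared_cds([_rec("t1", seq, dup)])
    assert list(shared["rrn1"].values()) == [seq[10:100]]


def test_zero_shared_genes_raises():
    rng = np.random.default_rng(3)
    seq = random_dna(rng, 300)
    r1 = _rec("t1", seq, [GeneAnnotation("a", "+", [(0, 90)], "CDS")])
    r2 = _rec("t2", seq, [GeneAnnotation("b", "+", [(0, 90)], "CDS")])
    with pytest.raises(ValueError):
        extract_shared_cds([r1, r2])


# ---------------------------------------------------------------------------
# alignment + concatenation
# ---------------------------------------------------------------------------

def test_identical_gene_sets_concatenate_without_gaps():
    rng = np.random.default_rng(4)
    genes = {f"g{i}": {t: random_dna(np.random.default_rng(i), 120)
                       for t in ("t1", "t2", "t3")} for i in range(3)}
    for gs in genes.values():                     # make taxa identical
        ref = gs["t1"]
        for t in gs:
            gs[t] = ref
    aln = align_and_concatenate(genes)
    assert aln.width == 360
    assert all("-" not in row for row in aln.rows.values())
    assert sum(e - s for s, e in aln.partitions.values()) == aln.width


def test_planted_deletion_produces_one_gap_block_inside_its_partition():
    rng = np.random.default_rng(5)
    g1 = random_dna(rng, 150)
    g2 = random_dna(rng, 180)
    genes = {"g1": {"t1": g1, "t2": g1, "t3": g1},
             "g2": {"t1": g2, "t2": g2[:90] + g2[93:], "t3": g2}}
    aln = align_and_concatenate(genes)
    row = aln.rows["t2"]
    s, e = aln.partitions["g2"]
    gap_cols = [i for i, c in enumerate(row) if c == "-"]
    assert len(gap_cols) == 3
    assert all(s <= i < e for i in gap_cols)
    assert gap_cols[2] - gap_cols[0] == 2         # one contiguous block
    # partitions stay contiguous and covering
    spans = sorted(aln.partitions.values())
    assert spans[0][0] == 0 and spans[-1][1] == aln.width
    assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))


def test_divergent_gene_dropped_with_warning():
    rng = np.random.default_rng(6)
    good = random_dna(rng, 150)
    genes = {"ok": {"t1": good, "t2": good},
             "bad": {"t1": random_dna(rng, 150), "t2": random_dna(rng, 150)}}
    with pytest.warns(UserWarning, match="bad"):
        aln = align_and_concatenate(genes)
    assert set(aln.partitions) == {"ok"}


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxon_closed_form_branch_lengths():
    D = pd.DataFrame([[0, .2, .3], [.2, 0, .4], [.3, .4, 0]],
                     index=list("ABC"), columns=list("ABC"))
    tree = neighbor_joining(D)
    lengths = {c.name: bl for c, bl in tree.root.children}
    assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})


def _additive_distances(branch_of, inner, taxa):
    """Distances on a tree ((A,B),(C,D),...) with named leaf branches plus an
    internal branch ``inner`` between the two cherries."""
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    left = set(taxa[:2])
    for x, y in itertools.combinations(taxa, 2):
        d = branch_of[x] + branch_of[y]
        if (x in left) != (y in left):
            d += inner
        D.loc[x, y] = D.loc[y, x] = d
    return D


def test_nj_recovers_additive_four_taxon_tree_exactly():
    taxa = list("ABCD")
    bl = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}
    D = _additive_distances(bl, 3.0, taxa)
    tree = neighbor_joining(D)
    assert tree.are_siblings("A", "B") and tree.are_siblings("C", "D")
    # edge lengths recovered to numerical precision
    def edges(node, acc):
        for c, l in node.children:
            if c.name:
                acc[c.name] = l
            edges(c, acc)
        return acc
    leaf_lengths = edges(tree.root, {})
    for t in taxa:
        assert leaf_lengths[t] == pytest.approx(bl[t], abs=1e-9)


def _enumerate_unrooted(taxa):
    """All unrooted binary topologies as edge lists (brute-force oracle)."""
    trees = [{("i0", taxa[0]), ("i0", taxa[1]), ("i0", taxa[2])}]
    for k, leaf in enumerate(taxa[3:], start=1):
        new_trees = []
        for edges in trees:
            for edge in sorted(edges):
                inner = f"i{k}"
                rest = edges - {edge}
                new_trees.append(rest | {(edge[0], inner), (inner, edge[1]),
                                         (inner, leaf)})
        trees = new_trees
    return trees


def _tree_splits(edges, taxa):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def side(u, v):
        seen, stack = {u}, [v]
        leaves = set()
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x in taxa:
                leaves.add(x)
            else:
                stack.extend(adj[x])
        return leaves

    ref = min(taxa)
    splits = set()
    for a, b in edges:
        for u, v in ((a, b), (b, a)):
            leaves = side(u, v)
            s = leaves if ref not in leaves else set(taxa) - leaves
            if 2 <= len(s) <= len(taxa) - 2:
                splits.add(frozenset(s))
    return splits


def test_nj_topology_matches_least_squares_search_over_all_topologies():
    """On an additive 5-taxon matrix, NJ picks the same topology as a
    brute-force least-squares fit over all 15 unrooted trees."""
    taxa = list("ABCDE")
    rng = np.random.default_rng(8)
    # additive matrix from a fixed tree: ((A,B),C,(D,E)) with random lengths
    true_edges = {("x", "A"), ("x", "B"), ("x", "y"), ("y", "C"), ("y", "z"),
                  ("z", "D"), ("z", "E")}
    lengths = {tuple(sorted(e)): float(rng.uniform(0.05, 0.5))
               for e in true_edges}
    adj = {}
    for a, b in true_edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def path_len(a, b):
        stack = [(a, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == b:
                return dist
            for nxt in adj[node]:
                if nxt != prev:
                    stack.append((nxt, dist + lengths[tuple(sorted((node, nxt)))],
                                  node))
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for x, y in itertools.combinations(taxa, 2):
        D.loc[x, y] = D.loc[y, x] = path_len(x, y)

    best_sse, best_splits = None, None
    for edges in _enumerate_unrooted(taxa):
        edge_list = sorted(tuple(sorted(e)) for e in edges)
        eadj = {}
        for a, b in edge_list:
            eadj.setdefault(a, []).append(b)
            eadj.setdefault(b, []).append(a)

        def on_path(a, b):
            stack = [(a, [], None)]
            while stack:
                node, path, prev = stack.pop()
                if node == b:
                    return path
                for nxt in eadj[node]:
                    if nxt != prev:
                        stack.append((nxt, path +
                                      [tuple(sorted((node, nxt)))], node))
        pairs = list(itertools.combinations(taxa, 2))
        A = np.zeros((len(pairs), len(edge_list)))
        y = np.zeros(len(pairs))
        for r, (x1, x2) in enumerate(pairs):
            for e in on_path(x1, x2):
                A[r, edge_list.index(e)] = 1.0
            y[r] = D.loc[x1, x2]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(((A @ coef - y) ** 2).sum())
        if best_sse is None or sse < best_sse:
            best_sse = sse
            best_splits = _tree_splits(edges, set(taxa))
    tree = neighbor_joining(D)
    assert tree.bipartitions() == best_splits
    assert best_sse == pytest.approx(0.0, abs=1e-16)


def test_k2p_saturation_raises_with_hint():
    rows = {"t1": "A" * 200, "t2": "G" * 200, "t3": "C" * 200}
    aln = ConcatenatedAlignment(taxa=list(rows), rows=rows,
                                partitions={"g": (0, 200)})
    with pytest.raises(ValueError, match="p-distance"):
        distance_matrix(aln, model="k2p")
    # p-distance remains defined
    D = distance_matrix(aln, model="p-distance")
    assert D.loc["t1", "t2"] == 1.0


def test_conspecific_individuals_cluster_as_siblings(phylo_panel):
    records, _ = phylo_panel
    aln = align_and_concatenate(extract_shared_cds(records))
    tree = nj_tree(aln)
    assert tree.are_siblings("SpA-1", "SpA-2")
    assert tree.are_siblings("SpB-1", "SpB-2")


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_unanimous_split_gets_support_100(phylo_panel):
    records, _ = phylo_panel
    aln = align_and_concatenate(extract_shared_cds(records))
    tree = bootstrap_support(aln, n=50, seed=11)
    assert tree.supports
    key = frozenset({"SpA-1", "SpA-2"})
    assert tree.supports[key] == 100.0


def test_bootstrap_is_deterministic_for_a_seed(phylo_panel):
    records, _ = phylo_panel
    aln = align_and_concatenate(extract_shared_cds(records))
    t1 = bootstrap_support(aln, n=30, seed=42)
    t2 = bootstrap_support(aln, n=30, seed=42)
    assert t1.supports == t2.supports
    assert t1.newick() == t2.newick()


def test_supports_invariant_to_taxon_input_order(phylo_panel):
    records, _ = phylo_panel
    aln1 = align_and_concatenate(extract_shared_cds(records))
    aln2 = align_and_concatenate(extract_shared_cds(records[::-1]))
    t1 = bootstrap_support(aln1, n=30, seed=9)
    t2 = bootstrap_support(aln2, n=30, seed=9)
    assert t1.supports == t2.supports


def _weak_edge_alignment(n_major=70, n_minor=50):
    """5-taxon matrix where columns conflict over the placement of C."""
    taxa = ["A", "B", "C", "D", "E"]
    cols = []
    for _ in range(n_major):                      # supports ((A,B),C | D,E)
        cols.append({"A": "A", "B": "A", "C": "A", "D": "G", "E": "G"})
    for _ in range(n_minor):                      # supports (A,B | (C,D),E)
        cols.append({"A": "T", "B": "T", "C": "C", "D": "C", "E": "T"})
    for i in range(200):                          # neutral noise columns
        base = "ACGT"[i % 4]
        cols.append({t: base for t in taxa})
    rows = {t: "".join(c[t] for c in cols) for t in taxa}
    return ConcatenatedAlignment(taxa=taxa, rows=rows,
                                 partitions={"g": (0, len(cols))})


def test_weakly_supported_edge_is_intermediate_and_seed_stable():
    aln = _weak_edge_alignment()
    supports = []
    for seed in (1, 2):
        tree = bootstrap_support(aln, n=1000, seed=seed, model="p-distance")
        key = frozenset({"D", "E"})               # side opposite the A,B cherry
        # pick the contested split's support (whichever representation exists)
        vals = [v for k, v in tree.supports.items() if 0 < v < 100]
        assert vals, f"no intermediate support found: {tree.supports}"
        supports.append(sorted(tree.supports.items(), key=str))
    for (k1, v1), (k2, v2) in zip(*supports):
        assert k1 == k2
        assert abs(v1 - v2) <= 5.0


def test_bootstrap_rejects_nonpositive_replicates(phylo_panel):
    records, _ = phylo_panel
    aln = align_and_concatenate(extract_shared_cds(records))
    with pytest.raises(ValueError):
        bootstrap_support(aln, n=0, seed=1)
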