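"""Ledgered synthetic inputs: plastome panels and LC-MS feature tables.

The plastome generator draws a random circular ancestor with a planted
quadripartite structure and evenly spaced genes, then evolves it down a
star-shaped species tree (one stem branch per species, one terminal branch
per individual) by planting SNP and InDel events at positions at least
62 bp apart — twice the 31-mer anchor size, the regime in which the
alignment-based caller recovers planted events exactly.  Every planted
event goes into a :class:`VariantLedger` from which pairwise truth counts,
expected diagnostic loci and coordinate mappings can be derived.

Defaults are calibrated to the real study system: ~151 kb plastomes with a
~25 kb IR, interspecific divergence of a few hundred SNPs and ~100 InDel
events per pair, intraspecific divergence an order of magnitude lower, and
a 1,763-feature LC-MS table with triplicate injections per plant and a
spiked internal standard.

By default events are planted only in the single-copy regions, keeping the
two IR copies identical across the whole panel; with ``events_in_ir=True``
an IR event is mirrored into both copies (preserving the quadripartite
invariant), in which case an alignment-based caller sees it twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plastomarker.chem import FeatureTable
from plastomarker.plastome_io import GeneAnnotation, PlastomeRecord
from plastomarker.sequtils import random_dna, revcomp

# ---------------------------------------------------------------------------
# plastome panel simulation
# ---------------------------------------------------------------------------


@dataclass
class SpeciesSpec:
    """One species of the panel: individuals and per-branch event counts."""

    name: str
    n_individuals: int = 1
    stem_snps: int = 0        # events shared by all individuals of the species
    stem_indels: int = 0
    ind_snps: int = 0         # events private to each individual
    ind_indels: int = 0


@dataclass
class PlastomeSimConfig:
    seed: int = 0
    lsc_len: int = 83000
    ir_len: int = 25000
    ssc_len: int = 18300
    n_genes: int = 60
    species: list[SpeciesSpec] = field(default_factory=lambda: [
        SpeciesSpec("SpA", 2, stem_snps=200, stem_indels=50,
                    ind_snps=50, ind_indels=20),
        SpeciesSpec("SpB", 2, stem_snps=200, stem_indels=50,
                    ind_snps=15, ind_indels=5),
        SpeciesSpec("SpC", 1, stem_snps=250, stem_indels=55),
    ])
    indel_geom_p: float = 0.25
    indel_max_len: int = 50
    min_spacing: int = 62
    boundary_margin: int = 100
    events_in_ir: bool = False

    @property
    def length_bp(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass
class PlantedEvent:
    branch: str          # "stem:<species>" or "ind:<leaf label>"
    kind: str            # SNP | InDel
    position: int        # 0-based on the ancestor
    ref: str
    alt: str
    region: str          # LSC | SSC | IR
    context: str         # genic-exon | genic-intron | intergenic
    gene: str | None

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class VariantLedger:
    """Planted-event bookkeeping for a simulated panel."""

    events: list[PlantedEvent]
    leaves: list[str]
    species_of: dict[str, str]

    def branches_of(self, leaf: str) -> set[str]:
        return {f"stem:{self.species_of[leaf]}", f"ind:{leaf}"}

    def events_on_path(self, x: str, y: str) -> list[PlantedEvent]:
        """Events on the tree path between two leaves (symmetric difference)."""
        bx, by = self.branches_of(x), self.branches_of(y)
        path = bx ^ by
        return [e for e in self.events if e.branch in path]

    def pair_counts(self, x: str, y: str) -> tuple[int, int]:
        path = self.events_on_path(x, y)
        return (sum(1 for e in path if e.kind == "SNP"),
                sum(1 for e in path if e.kind == "InDel"))

    def truth_matrix(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        m = len(self.leaves)
        snp = np.zeros((m, m), dtype=int)
        indel = np.zeros((m, m), dtype=int)
        for i in range(m):
            for j in range(i + 1, m):
                s, d = self.pair_counts(self.leaves[i], self.leaves[j])
                snp[i, j] = snp[j, i] = s
                indel[i, j] = indel[j, i] = d
        return self.leaves, snp, indel

    def map_to_leaf(self, leaf: str, anc_pos: int) -> int:
        """Map an ancestor coordinate onto a leaf genome."""
        shift = 0
        for e in self.events:
            if e.branch not in self.branches_of(leaf) or e.kind != "InDel":
                continue
            if e.position < anc_pos:
                if e.delta < 0 and anc_pos < e.position - e.delta:
                    return e.position + shift          # inside a deletion
                shift += e.delta
        return anc_pos + shift

    def expected_diagnostic(self, reference: str,
                            min_len: int = 5) -> list[tuple[int, int]]:
        """Diagnostic InDel loci as (reference-leaf position, |length diff|).

        A planted InDel is species-diagnostic when it is fixed within its
        species (stem events always; individual-branch events only for
        single-individual species) and its length is >= min_len.
        """
        n_by_species: dict[str, int] = {}
        for leaf, sp in self.species_of.items():
            n_by_species[sp] = n_by_species.get(sp, 0) + 1
        out = []
        for e in self.events:
            if e.kind != "InDel" or abs(e.delta) < min_len:
                continue
            btype, name = e.branch.split(":", 1)
            if btype == "ind" and n_by_species[self.species_of[name]] > 1:
                continue
            out.append((self.map_to_leaf(reference, e.position), abs(e.delta)))
        return sorted(out)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "leaves": self.leaves,
                "species_of": self.species_of,
                "events": [vars(e) for e in self.events],
            }, fh, indent=1)


def _place_genes(cfg: PlastomeSimConfig, rng: np.random.Generator
                 ) -> list[GeneAnnotation]:
    """Evenly spaced CDS genes in the single-copy regions; the second gene of
    the LSC gets an intron so multi-exon splicing is exercised."""
    genes: list[GeneAnnotation] = []
    regions = [("LSC", 0, cfg.lsc_len),
               ("SSC", cfg.lsc_len + cfg.ir_len,
                cfg.lsc_len + cfg.ir_len + cfg.ssc_len)]
    total_sc = cfg.lsc_len + cfg.ssc_len
    idx = 0
    for _, start, end in regions:
        n_here = max(1, round(cfg.n_genes * (end - start) / total_sc))
        slot = (end - start) // n_here
        glen = max(120, min(900, int(slot * 0.5)))
        for i in range(n_here):
            idx += 1
            s = start + i * slot + slot // 4
            e = min(s + glen, end - 1)
            if e - s < 60:
                continue
            strand = "+" if idx % 2 else "-"
            if idx == 2 and e - s > 300:      # one intron-bearing gene
                third = (e - s) // 3
                exons = [(s, s + third), (e - third, e)]
            else:
                exons = [(s, e)]
            genes.append(GeneAnnotation(name=f"g{idx:02d}", strand=strand,
                                        exons=exons, kind="CDS"))
    return genes


def _truth_classify(pos: int, cfg: PlastomeSimConfig,
                    genes: list[GeneAnnotation]) -> tuple[str, str, str | None]:
    if pos < cfg.lsc_len:
        region = "LSC"
    elif pos < cfg.lsc_len + cfg.ir_len:
        region = "IR"
    elif pos < cfg.lsc_len + cfg.ir_len + cfg.ssc_len:
        region = "SSC"
    else:
        region = "IR"
    for g in genes:
        s, e = g.span
        if s <= pos < e:
            in_exon = any(es <= pos < ee for es, ee in g.exons)
            return region, ("genic-exon" if in_exon else "genic-intron"), g.name
    return region, "intergenic", None


def _sample_positions(cfg: PlastomeSimConfig, rng: np.random.Generator,
                      n: int) -> list[int]:
    m = cfg.boundary_margin
    segments = [(m, cfg.lsc_len - m),
                (cfg.lsc_len + cfg.ir_len + m,
                 cfg.lsc_len + cfg.ir_len + cfg.ssc_len - m)]
    if cfg.events_in_ir:
        segments.append((cfg.lsc_len + m, cfg.lsc_len + cfg.ir_len - m))
    weights = np.array([e - s for s, e in segments], dtype=float)
    weights /= weights.sum()
    available = sum(e - s for s, e in segments)
    if n * cfg.min_spacing > 0.7 * available:
        raise ValueError(
            f"{n} events at spacing {cfg.min_spacing} too dense for "
            f"{available} bp of plantable sequence")
    chosen: list[int] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise ValueError("could not satisfy the event-spacing constraint")
        seg = segments[rng.choice(len(segments), p=weights)]
        pos = int(rng.integers(seg[0], seg[1]))
        if all(abs(pos - p) >= cfg.min_spacing for p in chosen):
            chosen.append(pos)
    return chosen


def _indel_len(cfg: PlastomeSimConfig, rng: np.random.Generator) -> int:
    while True:
        ln = int(rng.geometric(cfg.indel_geom_p))
        if 1 <= ln <= cfg.indel_max_len:
            return ln


def _map_pos(pos: int, events: list[PlantedEvent]) -> int:
    """Ancestor coordinate -> leaf coordinate through a leaf's sorted events."""
    shift = 0
    for e in events:
        if e.kind != "InDel" or e.position >= pos:
            continue
        if e.delta < 0 and pos < e.position - e.delta:
            return e.position + shift
        shift += e.delta
    return pos + shift


def simulate_plastome_panel(config: PlastomeSimConfig | None = None
                            ) -> tuple[list[PlastomeRecord], VariantLedger]:
    """Generate a plastome panel plus its planted-variant ledger."""
    cfg = config or PlastomeSimConfig()
    rng = np.random.default_rng(cfg.seed)
    lsc = random_dna(rng, cfg.lsc_len)
    irb = random_dna(rng, cfg.ir_len)
    ssc = random_dna(rng, cfg.ssc_len)
    # pin the single-copy edge bases so the planted IR cannot extend by a
    # chance reverse-complement match at a boundary ('A' never pairs with 'A')
    lsc = "A" + lsc[1:-1] + "A"
    ssc = "A" + ssc[1:-1] + "A"
    ancestor = lsc + irb + ssc + revcomp(irb)
    genes = _place_genes(cfg, rng)

    branches: list[tuple[str, int, int]] = []    # (branch id, snps, indels)
    leaves: list[str] = []
    species_of: dict[str, str] = {}
    for sp in cfg.species:
        if sp.n_individuals < 1:
            raise ValueError(f"species {sp.name} has no individuals")
        branches.append((f"stem:{sp.name}", sp.stem_snps, sp.stem_indels))
        for i in range(1, sp.n_individuals + 1):
            label = f"{sp.name}-{i}"
            leaves.append(label)
            species_of[label] = sp.name
            branches.append((f"ind:{label}", sp.ind_snps, sp.ind_indels))

    total = sum(s + d for _, s, d in branches)
    positions = _sample_positions(cfg, rng, total)
    rng.shuffle(positions)

    events: list[PlantedEvent] = []
    cursor = 0
    bases = "ACGT"
    for branch, n_snp, n_indel in branches:
        for _ in range(n_snp):
            pos = positions[cursor]
            cursor += 1
            ref = ancestor[pos]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            region, context, gene = _truth_classify(pos, cfg, genes)
            events.append(PlantedEvent(branch, "SNP", pos, ref, alt,
                                       region, context, gene))
        for _ in range(n_indel):
            pos = positions[cursor]
            cursor += 1
            ln = _indel_len(cfg, rng)
            if rng.random() < 0.5:
                ref, alt = "", random_dna(rng, ln)     # insertion
            else:
                ref, alt = ancestor[pos:pos + ln], ""  # deletion
            region, context, gene = _truth_classify(pos, cfg, genes)
            events.append(PlantedEvent(branch, "InDel", pos, ref, alt,
                                       region, context, gene))
    events.sort(key=lambda e: e.position)
    ledger = VariantLedger(events=events, leaves=leaves, species_of=species_of)

    records: list[PlastomeRecord] = []
    for label in leaves:
        path = ledger.branches_of(label)
        mine = [e for e in events if e.branch in path]
        seq = ancestor
        for e in sorted(mine, key=lambda e: -e.position):
            if e.kind == "SNP":
                seq = seq[:e.position] + e.alt + seq[e.position + 1:]
            elif e.ref:                                # deletion
                seq = seq[:e.position] + seq[e.position + len(e.ref):]
            else:                                      # insertion
                seq = seq[:e.position] + e.alt + seq[e.position:]
        leaf_genes = [
            GeneAnnotation(
                name=g.name, strand=g.strand, kind=g.kind,
                exons=[(_map_pos(s, mine), _map_pos(e_, mine))
                       for s, e_ in g.exons])
            for g in genes]
        records.append(PlastomeRecord(
            accession=f"SYN_{label}", species=species_of[label],
            individual_label=label, sequence=seq, genes=leaf_genes))
    return records, ledger


# ---------------------------------------------------------------------------
# LC-MS feature-table simulation
# ---------------------------------------------------------------------------

@dataclass
class FeatureSimConfig:
    seed: int = 0
    n_features: int = 1763
    #: species group -> number of samples (plants x triplicate injections)
    groups: dict[str, int] = field(default_factory=lambda: {
        "Ag": 6, "Ac": 6, "Af": 3})
    n_marker_features: int = 5
    fold_change: float = 100.0
    noise_cv: float = 0.10
    is_intensity: float = 1e4    # spiked at a level comparable to the median analyte
    sample_scale_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")


def simulate_feature_table(config: FeatureSimConfig | None = None
                           ) -> tuple[FeatureTable, dict[str, list[str]]]:
    """Grouped LC-MS feature table with planted species markers.

    Baseline feature intensities are log-normal; each group gets a disjoint
    set of marker features whose intensity is multiplied by ``fold_change``
    in that group's samples.  A constant internal standard is spiked before
    a per-sample log-normal scale jitter is applied to every row, so IS
    normalization exactly cancels the jitter.  Returns the table and the
    truth map of planted markers per group.
    """
    cfg = config or FeatureSimConfig()
    rng = np.random.default_rng(cfg.seed)
    feat_ids = [f"F{i + 1:04d}" for i in range(cfg.n_features)]
    samples, group_of = [], {}
    for g, n in cfg.groups.items():
        for i in range(1, n + 1):
            name = f"{g}_{i}"
            samples.append(name)
            group_of[name] = g

    baseline = 10.0 ** rng.normal(4.0, 1.0, size=cfg.n_features)
    X = np.tile(baseline[:, None], (1, len(samples)))

    marker_pool = rng.permutation(cfg.n_features)
    truth: dict[str, list[str]] = {}
    k = cfg.n_marker_features
    for gi, g in enumerate(cfg.groups):
        idx = marker_pool[gi * k:(gi + 1) * k]
        cols = [j for j, s in enumerate(samples) if group_of[s] == g]
        X[np.ix_(idx, cols)] *= cfg.fold_change
        truth[g] = [feat_ids[i] for i in sorted(idx)]

    sigma = np.sqrt(np.log(1.0 + cfg.noise_cv ** 2))
    X *= np.exp(rng.normal(0.0, sigma, size=X.shape))

    inten = pd.DataFrame(X, index=feat_ids, columns=samples)
    inten.loc["IS"] = cfg.is_intensity
    scale = np.exp(rng.normal(0.0, cfg.sample_scale_sigma, size=len(samples)))
    inten = inten * scale

    features = pd.DataFrame({
        "id": feat_ids + ["IS"],
        "mz": np.round(rng.uniform(100, 900, size=cfg.n_features + 1), 4),
        "rt": np.round(rng.uniform(0.5, 20.0, size=cfg.n_features + 1), 2),
    })
    meta = pd.DataFrame({
        "sample": samples,
        "group": [group_of[s] for s in samples],
        "replicate": [int(s.split("_")[1]) for s in samples],
    }).set_index("sample")
    table = FeatureTable(features=features, intensities=inten,
                         sample_meta=meta, is_feature_id="IS")
    return table, truth
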