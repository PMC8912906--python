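"""Diagnostic InDel barcode markers: selection, primer design, in-silico PCR
and gel/capillary genotype simulation.

A diagnostic InDel locus is one where every individual of a species carries
the same allele but at least two species differ, with a length difference
large enough to resolve on the chosen readout (an agarose gel resolves
roughly max(10 bp, 5% of the product); a capillary fragment analyzer
resolves ~3 bp).  Primers are picked from flanks that are strictly conserved
across the panel, using a closed-form GC-based melting temperature
``Tm = 64.9 + 41*(gc_count - 16.4)/N`` and simple composition rules (length
18-27, GC 40-60%, no homopolymer of 5, G/C clamp at the 3' end).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plastomarker.errors import DesignFailure
from plastomarker.plastome_io import PlastomeRecord
from plastomarker.sequtils import revcomp
from plastomarker.variants import Variant

GEL = "gel"
CAPILLARY = "capillary"


def resolvability_threshold(mode: str, smaller_product: int) -> int:
    """Minimum resolvable size difference (bp) for a readout mode."""
    if mode == GEL:
        return max(10, int(round(0.05 * smaller_product)))
    if mode == CAPILLARY:
        return 3
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# diagnostic locus selection
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticLocus:
    """An InDel locus fixed within species but polymorphic between them.

    ``delta_by_species`` holds the net length change relative to the
    reference genome (0 = reference allele); ``max_diff`` is the largest
    between-species length difference.
    """

    ref_pos: int
    alleles_by_species: dict[str, tuple[str, str]]   # species -> (ref, alt)
    delta_by_species: dict[str, int]
    max_diff: int


def select_diagnostic_indels(
        variants_by_individual: dict[str, list[Variant]],
        species_map: dict[str, str],
        min_len: int = 5) -> list[DiagnosticLocus]:
    """Select InDel loci that separate species without intraspecific noise.

    ``variants_by_individual`` maps each individual label to its variants
    called against one shared reference individual (the reference itself maps
    to an empty list).  A locus qualifies when (i) all individuals of every
    species carry the same allele there, (ii) at least two species differ,
    and (iii) the largest between-species length difference is >= min_len.
    Returned loci are sorted by that difference, descending.
    """
    species = {}
    for ind, sp in species_map.items():
        species.setdefault(sp, []).append(ind)
    if any(len(inds) == 0 for inds in species.values()):
        raise ValueError("every species needs at least one individual")
    missing = set(species_map) - set(variants_by_individual)
    if missing:
        raise ValueError(f"no variant calls for individuals: {sorted(missing)}")

    # allele of each individual at each InDel start position (None = reference)
    loci: dict[int, dict[str, tuple[str, str]]] = {}
    for ind, vs in variants_by_individual.items():
        for v in vs:
            if v.kind != "InDel":
                continue
            loci.setdefault(v.ref_pos, {})[ind] = (v.ref_allele, v.alt_allele)

    out: list[DiagnosticLocus] = []
    for pos, carriers in loci.items():
        allele_by_sp: dict[str, tuple[str, str]] = {}
        ok = True
        for sp, inds in species.items():
            alleles = {carriers.get(ind, ("", "")) for ind in inds}
            if len(alleles) != 1:
                ok = False            # intraspecific diversity: reject
                break
            allele_by_sp[sp] = next(iter(alleles))
        if not ok or len(set(allele_by_sp.values())) < 2:
            continue
        deltas = {sp: len(alt) - len(ref)
                  for sp, (ref, alt) in allele_by_sp.items()}
        diffs = [abs(deltas[a] - deltas[b])
                 for a, b in itertools.combinations(deltas, 2)]
        if max(diffs) < min_len:
            continue
        out.append(DiagnosticLocus(pos, allele_by_sp, deltas, max(diffs)))
    return sorted(out, key=lambda d: (-d.max_diff, d.ref_pos))


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------

@dataclass
class PrimerConfig:
    min_len: int = 18
    max_len: int = 27
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 54.0
    tm_max: float = 62.0
    max_tm_diff: float = 3.0
    flank_span: int = 200     # how far from the locus to search for primers
    min_gap: int = 10         # keep primers clear of the variable locus


@dataclass
class PrimerPair:
    fwd_seq: str
    rev_seq: str               # 5'->3' on the minus strand
    fwd_pos: int               # template start of forward primer
    rev_pos: int               # template start of the reverse-primer site
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float


def primer_tm(primer: str) -> float:
    """Closed-form GC-count melting temperature (degrees C)."""
    gc = primer.count("G") + primer.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def _primer_ok(primer: str, cfg: PrimerConfig) -> bool:
    n = len(primer)
    gc = (primer.count("G") + primer.count("C")) / n
    if not cfg.gc_min <= gc <= cfg.gc_max:
        return False
    if not cfg.tm_min <= primer_tm(primer) <= cfg.tm_max:
        return False
    if primer[-1] not in "GC":
        return False
    if any(b * 5 in primer for b in "ACGT"):
        return False
    return True


def _candidate_windows(template: str, lo: int, hi: int, cfg: PrimerConfig,
                       panel_seqs: list[str] | None):
    """All (start, length) windows in [lo, hi) passing composition rules and,
    when a panel is given, occurring exactly once in every panel genome."""
    for start in range(max(0, lo), hi):
        for ln in range(cfg.min_len, cfg.max_len + 1):
            if start + ln > hi:
                break
            w = template[start:start + ln]
            if panel_seqs is not None and any(
                    s.count(w) + s.count(revcomp(w)) != 1 for s in panel_seqs):
                continue
            yield start, ln, w


def design_primers(locus: tuple[int, int], template: PlastomeRecord | str,
                   panel: list[PlastomeRecord] | None = None,
                   config: PrimerConfig | None = None) -> PrimerPair:
    """Design a flanking primer pair for a diagnostic locus.

    Forward candidates come from the window upstream of ``locus``, reverse
    candidates (reverse-complemented) from downstream; both must pass the
    composition rules and, when ``panel`` is given, occur exactly once in
    every panel genome so the assay amplifies cleanly panel-wide.  Among
    feasible pairs the one minimizing \\|Tm_fwd - Tm_rev\\| then product
    length wins.  Raises :class:`DesignFailure` when no pair exists.
    """
    cfg = config or PrimerConfig()
    seq = template.sequence if isinstance(template, PlastomeRecord) else template
    panel_seqs = [p.sequence for p in panel] if panel else None
    ls, le = locus
    fwd_hi = max(0, ls - cfg.min_gap)
    fwd_lo = fwd_hi - cfg.flank_span
    rev_lo = min(len(seq), le + cfg.min_gap)
    rev_hi = min(len(seq), rev_lo + cfg.flank_span)

    fwd_cands = [(s, ln, w) for s, ln, w in
                 _candidate_windows(seq, fwd_lo, fwd_hi, cfg, panel_seqs)
                 if _primer_ok(w, cfg)]
    rev_cands = [(s, ln, revcomp(w)) for s, ln, w in
                 _candidate_windows(seq, rev_lo, rev_hi, cfg, panel_seqs)
                 if _primer_ok(revcomp(w), cfg)]
    if not fwd_cands or not rev_cands:
        raise DesignFailure(
            f"no conserved primer window flanking locus [{ls}, {le})")

    best = None
    for (fs, fl, fw), (rs, rl, rw) in itertools.product(fwd_cands, rev_cands):
        tmf, tmr = primer_tm(fw), primer_tm(rw)
        if abs(tmf - tmr) > cfg.max_tm_diff:
            continue
        product = rs + rl - fs
        key = (abs(tmf - tmr), product, fs, rs)
        if best is None or key < best[0]:
            best = (key, PrimerPair(
                fwd_seq=fw, rev_seq=rw, fwd_pos=fs, rev_pos=rs,
                tm_fwd=tmf, tm_rev=tmr,
                gc_fwd=(fw.count("G") + fw.count("C")) / fl,
                gc_rev=(rw.count("G") + rw.count("C")) / rl))
    if best is None:
        raise DesignFailure(
            f"no primer pair within {cfg.max_tm_diff} C Tm difference "
            f"for locus [{ls}, {le})")
    return best[1]


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def _binding_sites(primer: str, seq: str, max_mismatch: int) -> list[int]:
    """Plus-strand start positions where primer binds with <= max_mismatch
    mismatches and an exact-match 3'-terminal 3-mer."""
    n, m = len(seq), len(primer)
    if m == 0 or n < m:
        return []
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p).sum(axis=1)
    tail_exact = (windows[:, -3:] == p[-3:]).all(axis=1)
    return list(np.nonzero((mism <= max_mismatch) & tail_exact)[0])


@dataclass
class AmpliconProfile:
    marker: str
    genome: str
    amplicons: list[tuple[int, int, int]]   # (start, end, length) half-open
    band_call: str = field(init=False)

    def __post_init__(self) -> None:
        self.band_call = ("none" if not self.amplicons
                          else "single" if len(self.amplicons) == 1
                          else "multiple")

    @property
    def size(self) -> int | None:
        return self.amplicons[0][2] if self.band_call == "single" else None


def insilico_pcr(primers: PrimerPair, genome: PlastomeRecord | str,
                 max_mismatch: int = 2, max_product: int = 3000,
                 marker: str = "", label: str | None = None) -> AmpliconProfile:
    """Predict PCR products of a primer pair on a genome.

    Binding sites on both strands are found with at most ``max_mismatch``
    mismatches and an exact 3'-terminal 3-mer; every convergent pair of sites
    at most ``max_product`` apart yields an amplicon whose length runs from
    the outer edge of one primer to the outer edge of the other.
    """
    if not primers.fwd_seq or not primers.rev_seq:
        raise ValueError("primers must be non-empty")
    seq = genome.sequence if isinstance(genome, PlastomeRecord) else genome
    name = label or (genome.individual_label
                     if isinstance(genome, PlastomeRecord) else "template")
    amplicons = set()
    for left, right in ((primers.fwd_seq, primers.rev_seq),
                        (primers.rev_seq, primers.fwd_seq)):
        plus = _binding_sites(left, seq, max_mismatch)
        minus = _binding_sites(revcomp(right), seq, max_mismatch)
        for s1 in plus:
            for s2 in minus:
                end = s2 + len(right)
                length = end - s1
                if s1 + len(left) <= end and 0 < length <= max_product:
                    amplicons.add((int(s1), int(end), int(length)))
    return AmpliconProfile(marker=marker, genome=name,
                           amplicons=sorted(amplicons))


# ---------------------------------------------------------------------------
# marker candidates and panel genotyping
# ---------------------------------------------------------------------------

@dataclass
class MarkerCandidate:
    name: str
    locus: tuple[int, int]
    flanking_features: tuple[str, str] | None
    primers: PrimerPair
    diagnostic_indels: list[Variant] = field(default_factory=list)
    expected_sizes: dict[str, int] = field(default_factory=dict)


def build_markers(loci: list[DiagnosticLocus], reference: PlastomeRecord,
                  panel: list[PlastomeRecord],
                  config: PrimerConfig | None = None,
                  max_mismatch: int = 2) -> list[MarkerCandidate]:
    """Design primers and expected sizes for each diagnostic locus.

    Loci where primer design or in-silico PCR fails on any panel genome are
    skipped.  Expected sizes are always taken from in-silico PCR per genome,
    never from summing ledger events, so nested InDels inside a candidate
    window are sized the way a gel would see them.  Marker names are ``ar`` +
    zero-padded ordinal by genomic position on the reference.
    """
    designed = []
    for loc in loci:
        span = max(1, -min(0, min(loc.delta_by_species.values())))
        locus_iv = (loc.ref_pos, loc.ref_pos + span)
        try:
            primers = design_primers(locus_iv, reference, panel, config)
        except DesignFailure:
            continue
        designed.append((loc, locus_iv, primers))
    designed.sort(key=lambda t: t[1][0])

    markers = []
    for ordinal, (loc, locus_iv, primers) in enumerate(designed, start=1):
        sizes = {}
        ok = True
        for g in panel:
            prof = insilico_pcr(primers, g, max_mismatch=max_mismatch)
            if prof.band_call != "single":
                ok = False
                break
            sizes[g.individual_label] = prof.amplicons[0][2]
        if not ok:
            continue
        markers.append(MarkerCandidate(
            name=f"ar{ordinal:02d}", locus=locus_iv,
            flanking_features=_flanking_genes(reference, locus_iv),
            primers=primers, expected_sizes=sizes))
    return markers


def _flanking_genes(record: PlastomeRecord, locus: tuple[int, int]):
    left = [g for g in record.genes if g.span[1] <= locus[0]]
    right = [g for g in record.genes if g.span[0] >= locus[1]]
    lname = max(left, key=lambda g: g.span[1]).name if left else ""
    rname = min(right, key=lambda g: g.span[0]).name if right else ""
    return (lname, rname) if (lname or rname) else None


@dataclass
class GenotypeTable:
    """Predicted band sizes per (marker, genome) plus the discrimination
    summary: which species pairs each marker separates and the panel verdict."""

    sizes: pd.DataFrame                       # markers x genomes (NaN = failed)
    flagged: list[tuple[str, str]]            # (marker, genome) PCR failures
    separations: dict[str, set[frozenset]]    # marker -> separated species pairs
    distinguishable: bool


def genotype_panel(markers: list[MarkerCandidate],
                   genomes: list[PlastomeRecord],
                   species_map: dict[str, str],
                   mode: str = GEL,
                   max_mismatch: int = 2) -> GenotypeTable:
    """In-silico genotype a panel and score species discrimination.

    A marker separates a species pair when every individual of both species
    yields a single band and every cross-species size difference meets the
    readout's resolvability threshold.  The panel distinguishes all species
    iff every species pair is separated by at least one marker.
    """
    if not markers or len(genomes) < 2:
        raise ValueError("need at least one marker and two genomes")
    labels = [g.individual_label for g in genomes]
    sizes = pd.DataFrame(np.nan, index=[m.name for m in markers], columns=labels)
    flagged = []
    for m in markers:
        for g in genomes:
            prof = insilico_pcr(m.primers, g, max_mismatch=max_mismatch,
                                marker=m.name)
            if prof.band_call == "single":
                sizes.loc[m.name, g.individual_label] = prof.amplicons[0][2]
            else:
                flagged.append((m.name, g.individual_label))

    by_species: dict[str, list[str]] = {}
    for lab in labels:
        by_species.setdefault(species_map[lab], []).append(lab)
    pairs = [frozenset(p) for p in itertools.combinations(by_species, 2)]

    separations: dict[str, set[frozenset]] = {}
    for m in markers:
        sep = set()
        row = sizes.loc[m.name]
        for pair in pairs:
            sp1, sp2 = tuple(pair)
            v1 = row[by_species[sp1]]
            v2 = row[by_species[sp2]]
            if v1.isna().any() or v2.isna().any():
                continue
            diffs = [abs(a - b) for a in v1 for b in v2]
            thr = resolvability_threshold(
                mode, int(min(v1.min(), v2.min())))
            if all(d >= thr for d in diffs):
                sep.add(pair)
        separations[m.name] = sep
    covered = set().union(*separations.values()) if separations else set()
    return GenotypeTable(
        sizes=sizes, flagged=flagged, separations=separations,
        distinguishable=all(p in covered for p in pairs))
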