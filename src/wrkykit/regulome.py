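"""Promoter extraction, degenerate-motif scanning and target-gene calling.

Promoters are the up-to-1-kb windows immediately 5' of the translation start
(ATG), reported in gene orientation.  Motif hits carry a negative offset:
the position of the hit window's 5'-most base in gene orientation, where -1
is the base immediately upstream of the A of ATG.  Scanning covers both
strands (the reverse-strand scan matches the pattern's reverse complement on
the promoter string); overlapping matches are all reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GeneModel, reverse_complement

logger = logging.getLogger(__name__)

WBOX_ELEMENT_ID = "WBOX"
WBOX_PATTERN = "YTGACY"
DEFAULT_PROMOTER_WINDOW = 1000
DEFAULT_MIN_SITES = 3

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


class PatternError(ValueError):
    """Raised for a pattern containing a non-IUPAC nucleotide code."""


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    sequence: str  # gene orientation, 5'->3' toward ATG
    truncated: bool
    contig: str
    strand: str
    interval: tuple[int, int]  # genomic, 0-based half-open

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    element_id: str
    pattern: str
    strand: str  # + / - relative to gene orientation
    offset: int  # negative; 5'-most base of the hit window, ATG-relative


@dataclass(frozen=True)
class TargetGeneCall:
    gene_id: str
    wbox_count: int
    positions: tuple[int, ...]

    @property
    def tier1(self) -> bool:
        return self.wbox_count >= 1

    @property
    def tier2(self) -> bool:
        return self.wbox_count >= 2

    @property
    def tier3(self) -> bool:
        return self.wbox_count >= 3


@dataclass
class CisElementCatalog:
    entries: list[tuple[str, str, str]]  # (element_id, IUPAC pattern, category)

    def __post_init__(self) -> None:
        for eid, pattern, _ in self.entries:
            validate_pattern(pattern, eid)


@dataclass(frozen=True)
class GeneStructure:
    gene_id: str
    n_exons: int

    @property
    def n_introns(self) -> int:
        return self.n_exons - 1


def validate_pattern(pattern: str, element_id: str = "") -> None:
    if not pattern:
        raise PatternError(f"empty pattern for element {element_id!r}")
    for ch in pattern:
        if ch not in IUPAC_DNA:
            raise PatternError(
                f"non-IUPAC character {ch!r} in pattern {pattern!r}"
            )


def reverse_complement_pattern(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[ch] for ch in reversed(pattern))


def _iupac_match(seq: str, pattern: str, start: int) -> bool:
    return all(
        seq[start + k] in IUPAC_DNA[pch] for k, pch in enumerate(pattern)
    )


def extract_promoters(
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[PromoterRegion]:
    """Up-to-``window``-nt regions upstream of each gene's translation start.

    Plus strand: ``contig[max(0, s - window) .. s)`` where ``s`` is the
    5'-most CDS coordinate.  Minus strand: the reverse complement of
    ``contig[e .. e + window)`` where ``e`` is the CDS genomic end.  Regions
    shorter than ``window`` are flagged truncated.  Genes without CDS are
    skipped with a log notice.
    """
    regions: list[PromoterRegion] = []
    for gene in genes:
        if gene.contig not in genome:
            raise KeyError(f"gene {gene.gene_id}: contig {gene.contig!r} not in genome")
        contig_seq = genome[gene.contig]
        span = gene.cds_span()
        if span is None:
            logger.info("gene %s has no CDS; skipped", gene.gene_id)
            continue
        cds_start, cds_end = span
        if cds_end > len(contig_seq):
            raise ValueError(f"gene {gene.gene_id}: CDS outside contig")
        if gene.strand == "+":
            lo, hi = max(0, cds_start - window), cds_start
            seq = contig_seq[lo:hi]
        else:
            lo = cds_end
            hi = min(len(contig_seq), cds_end + window)
            seq = reverse_complement(contig_seq[lo:hi])
        regions.append(
            PromoterRegion(
                gene.gene_id,
                seq,
                truncated=len(seq) < window,
                contig=gene.contig,
                strand=gene.strand,
                interval=(lo, hi),
            )
        )
    return regions


def scan_motif(
    region: PromoterRegion,
    pattern: str,
    element_id: str = WBOX_ELEMENT_ID,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All matches of an IUPAC pattern in a promoter, on one or both strands.

    A reverse-strand hit is a match of the pattern's reverse complement on
    the promoter string; its offset is still the window's 5'-most base in
    gene orientation, so the subsequence at ``[offset, offset + len)``
    matches the stated strand's pattern.
    """
    validate_pattern(pattern, element_id)
    seq = region.sequence
    L = len(seq)
    m = len(pattern)
    hits: list[MotifHit] = []
    strands = [("+", pattern)]
    if both_strands:
        strands.append(("-", reverse_complement_pattern(pattern)))
    for strand, pat in strands:
        for i in range(L - m + 1):
            if _iupac_match(seq, pat, i):
                hits.append(MotifHit(region.gene_id, element_id, pattern, strand, i - L))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_wbox(regions: Iterable[PromoterRegion]) -> dict[str, list[MotifHit]]:
    """W-box (YTGACY) hits for every region, keyed by gene id."""
    return {r.gene_id: scan_motif(r, WBOX_PATTERN, WBOX_ELEMENT_ID) for r in regions}


def call_targets(
    hits_by_gene: dict[str, list[MotifHit]],
    min_sites: int = DEFAULT_MIN_SITES,
) -> tuple[list[TargetGeneCall], list[TargetGeneCall]]:
    """Per-gene W-box counts and the target list (count >= min_sites).

    Returns (all calls, target calls); genes with zero hits are included in
    the first list with count 0.  Offsets are emitted sorted ascending.
    """
    calls = []
    for gene_id in sorted(hits_by_gene):
        positions = tuple(sorted(h.offset for h in hits_by_gene[gene_id]))
        calls.append(TargetGeneCall(gene_id, len(positions), positions))
    targets = [c for c in calls if c.wbox_count >= min_sites]
    return calls, targets


def scan_catalog(
    regions: Sequence[PromoterRegion],
    catalog: CisElementCatalog,
) -> tuple[list[tuple[str, str, str, MotifHit]], dict[str, dict[str, int]]]:
    """Scan every catalog element over every region.

    Returns (flat hit list of (gene, element, category, hit), per-gene
    per-category counts).  A category's count is the sum of its elements'
    hit counts.
    """
    if not catalog.entries:
        return [], {}
    flat: list[tuple[str, str, str, MotifHit]] = []
    counts: dict[str, dict[str, int]] = {}
    for region in regions:
        per_cat = counts.setdefault(region.gene_id, {})
        for element_id, pattern, category in catalog.entries:
            found = scan_motif(region, pattern, element_id)
            per_cat[category] = per_cat.get(category, 0) + len(found)
            flat.extend((region.gene_id, element_id, category, h) for h in found)
    return flat, counts


def gene_structure(genes: Sequence[GeneModel]) -> list[GeneStructure]:
    """Exon/intron counts from the longest transcript of each gene.

    The longest transcript is the one with the greatest summed exon length;
    genes without exon features are skipped with a log notice.
    """
    out: list[GeneStructure] = []
    for gene in genes:
        with_exons = [t for t in gene.transcripts if t.exons]
        if not with_exons:
            logger.info("gene %s has no exon features; skipped", gene.gene_id)
            continue
        longest = max(
            with_exons,
            key=lambda t: (sum(e - s for s, e in t.exons), t.transcript_id),
        )
        out.append(GeneStructure(gene.gene_id, len(longest.exons)))
    return out
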