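"""Promoter extraction, IUPAC scanning, target tiers, gene structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrkykit import simulate
from wrkykit.io import GeneModel, Transcript, reverse_complement
from wrkykit.regulome import (
    WBOX_PATTERN,
    CisElementCatalog,
    PatternError,
    PromoterRegion,
    call_targets,
    extract_promoters,
    gene_structure,
    reverse_complement_pattern,
    scan_catalog,
    scan_motif,
    scan_wbox,
)


def _region(seq, gene_id="g"):
    return PromoterRegion(gene_id, seq, len(seq) < 1000, "ctg", "+", (0, len(seq)))


def _gene(gene_id, contig, strand, cds_intervals):
    t = Transcript(f"{gene_id}.t1", exons=list(cds_intervals), cds=list(cds_intervals))
    start = min(s for s, _ in cds_intervals)
    end = max(e for _, e in cds_intervals)
    return GeneModel(gene_id, contig, strand, start, end, [t])


# ---------------------------------------------------------------------------
# extract_promoters
# ---------------------------------------------------------------------------


def test_plus_strand_window():
    contig = "".join(np.random.default_rng(0).choice(list("ACGT"), size=2000))
    genes = [_gene("g1", "c1", "+", [(1500, 1800)])]
    (r,) = extract_promoters({"c1": contig}, genes)
    assert r.length == 1000 and not r.truncated
    assert r.sequence == contig[500:1500]
    assert r.interval == (500, 1500)


def test_minus_strand_is_reverse_complement():
    # hand-built 60-nt toy contig; gene CDS at [10, 40) on minus strand
    contig = "ACGTACGTTTGACGTACGTACGGCCTTAAGGCCAATTCCGGAAGCTTGGATCCAAGGTT"
    genes = [_gene("g1", "c1", "-", [(10, 40)])]
    (r,) = extract_promoters({"c1": contig}, genes, window=15)
    assert r.sequence == reverse_complement(contig[40:55])
    assert not r.truncated and r.interval == (40, 55)


def test_short_promoter_truncated():
    contig = "A" * 700
    genes = [_gene("g1", "c1", "+", [(300, 600)])]
    (r,) = extract_promoters({"c1": contig}, genes)
    assert r.length == 300 and r.truncated


def test_contig_edge_empty_region():
    contig = "A" * 100
    genes = [_gene("g1", "c1", "+", [(0, 90)])]
    (r,) = extract_promoters({"c1": contig}, genes)
    assert r.length == 0 and r.truncated


def test_gene_without_cds_skipped(caplog):
    g = GeneModel("g1", "c1", "+", 10, 50, [Transcript("t1", exons=[(10, 50)])])
    assert extract_promoters({"c1": "A" * 100}, [g]) == []


def test_missing_contig_raises():
    with pytest.raises(KeyError):
        extract_promoters({}, [_gene("g1", "c1", "+", [(10, 20)])])


# ---------------------------------------------------------------------------
# scan_motif
# ---------------------------------------------------------------------------


def iupac_oracle(seq, pattern):
    """Naive per-window IUPAC check, forward orientation only."""
    from wrkykit.regulome import IUPAC_DNA

    m = len(pattern)
    return [
        i
        for i in range(len(seq) - m + 1)
        if all(seq[i + k] in IUPAC_DNA[p] for k, p in enumerate(pattern))
    ]


def test_single_wbox_at_minus_106():
    L = 1000
    seq = ["A"] * L
    seq[L - 106 : L - 100] = "CTGACC"
    (hit,) = scan_motif(_region("".join(seq)), WBOX_PATTERN)
    assert (hit.strand, hit.offset) == ("+", -106)


def test_poly_a_region_no_hits():
    assert scan_motif(_region("A" * 1000), WBOX_PATTERN) == []


def test_overlapping_hits_both_reported():
    seq = "A" * 500 + "CTGACTTGACC" + "A" * 489
    hits = scan_motif(_region(seq), WBOX_PATTERN)
    assert len(hits) == 2
    offsets = sorted(h.offset for h in hits)
    assert offsets[1] - offsets[0] == 5


def test_offsets_satisfy_interval_invariant():
    rng = np.random.default_rng(21)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    region = _region(seq)
    for pattern in (WBOX_PATTERN, "CCGAC", "ACGTG"):
        for h in scan_motif(region, pattern):
            assert h.offset + len(pattern) <= 0
            assert -len(seq) <= h.offset
            window = seq[h.offset + len(seq) : h.offset + len(seq) + len(pattern)]
            pat = pattern if h.strand == "+" else reverse_complement_pattern(pattern)
            assert iupac_oracle(window, pat) == [0]


def test_forward_hits_match_oracle():
    rng = np.random.default_rng(22)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    region = _region(seq)
    fwd = [h for h in scan_motif(region, WBOX_PATTERN) if h.strand == "+"]
    assert [h.offset + len(seq) for h in fwd] == iupac_oracle(seq, WBOX_PATTERN)


@given(st.text(alphabet="ACGT", min_size=10, max_size=200))
@settings(max_examples=60, deadline=None)
def test_strand_symmetry(seq):
    """Hits of a region and its reverse complement map onto each other with
    strands swapped and offsets reflected."""
    L = len(seq)
    m = len(WBOX_PATTERN)
    fwd = scan_motif(_region(seq), WBOX_PATTERN)
    rev = scan_motif(_region(reverse_complement(seq)), WBOX_PATTERN)
    mapped = {(("-" if h.strand == "+" else "+"), -(h.offset + L) - m + L - L) for h in rev}
    expected = {(h.strand, h.offset) for h in fwd}
    got = {(s, o) for s, o in mapped}
    assert got == expected


def test_non_iupac_pattern_rejected():
    with pytest.raises(PatternError):
        scan_motif(_region("ACGT" * 10), "ACQT")


# ---------------------------------------------------------------------------
# call_targets / scan_catalog
# ---------------------------------------------------------------------------


def test_three_sites_is_target():
    specs = [
        simulate.GeneSpec(
            "gA", "+", [("WBOX", WBOX_PATTERN, o) for o in (-106, -33, -127)]
        ),
        simulate.GeneSpec("gB", "+", [("WBOX", WBOX_PATTERN, o) for o in (-50, -80)]),
        simulate.GeneSpec("gC", "+", []),
    ]
    genome, genes, _ = simulate.gen_genome(specs, seed=10)
    regions = extract_promoters(genome, genes)
    calls, targets = call_targets(scan_wbox(regions))
    by_id = {c.gene_id: c for c in calls}
    assert by_id["gA"].wbox_count == 3 and by_id["gA"].tier3
    assert by_id["gA"].positions == (-127, -106, -33)
    assert by_id["gB"].tier2 and not by_id["gB"].tier3
    assert by_id["gC"].wbox_count == 0
    assert [t.gene_id for t in targets] == ["gA"]


def test_tier_monotonicity():
    rng = np.random.default_rng(30)
    specs = []
    for i in range(12):
        k = int(rng.integers(0, 5))
        offsets = (-900 + 40 * np.arange(k)).tolist()
        specs.append(
            simulate.GeneSpec(f"g{i:02d}", "+", [("WBOX", WBOX_PATTERN, int(o)) for o in offsets])
        )
    genome, genes, truth = simulate.gen_genome(specs, seed=31)
    hits = scan_wbox(extract_promoters(genome, genes))
    previous = None
    for min_sites in (1, 2, 3, 4, 5):
        _, targets = call_targets(hits, min_sites)
        ids = {t.gene_id for t in targets}
        if previous is not None:
            assert ids <= previous
        previous = ids
    # tier sizes equal planted tallies
    calls, _ = call_targets(hits)
    for c in calls:
        assert c.wbox_count == len(truth["genes"][c.gene_id]["planted"])


def test_scan_catalog_counts_and_conservation():
    catalog = CisElementCatalog(
        [
            ("LTRECORE", "CCGAC", "low temperature-responsive"),
            ("LTRE1", "CCGAAA", "low temperature-responsive"),
            ("ABRE", "ACGTG", "ABA-responsive"),
        ]
    )
    planted = [("LTRECORE", "CCGAC", int(o)) for o in range(-950, -500, 50)]
    assert len(planted) == 9
    specs = [simulate.GeneSpec("gL", "+", planted + [("ABRE", "ACGTG", -100)])]
    genome, genes, _ = simulate.gen_genome(specs, seed=12)
    regions = extract_promoters(genome, genes)
    flat, counts = scan_catalog(regions, catalog)
    assert counts["gL"]["low temperature-responsive"] == 9
    assert counts["gL"]["ABA-responsive"] == 1
    by_cat = {}
    for gene, element, category, hit in flat:
        by_cat[category] = by_cat.get(category, 0) + 1
    assert by_cat == {k: v for k, v in counts["gL"].items() if v}


def test_empty_catalog_empty_report():
    specs = [simulate.GeneSpec("g1", "+", [])]
    genome, genes, _ = simulate.gen_genome(specs, seed=13)
    flat, counts = scan_catalog(extract_promoters(genome, genes), CisElementCatalog([]))
    assert flat == [] and counts == {}


# ---------------------------------------------------------------------------
# gene structure
# ---------------------------------------------------------------------------


def test_gene_structure_counts():
    one = _gene("g1", "c", "+", [(100, 400)])
    three = GeneModel(
        "g3", "c", "+", 100, 700,
        [Transcript("g3.t1", exons=[(100, 200), (300, 450), (600, 700)])],
    )
    out = {s.gene_id: s for s in gene_structure([one, three])}
    assert (out["g1"].n_exons, out["g1"].n_introns) == (1, 0)
    assert (out["g3"].n_exons, out["g3"].n_introns) == (3, 2)


def test_gene_structure_longest_transcript_wins():
    g = GeneModel(
        "g", "c", "+", 0, 1000,
        [
            Transcript("t.short", exons=[(0, 50)]),
            Transcript("t.long", exons=[(0, 300), (400, 700), (800, 1000)]),
        ],
    )
    (s,) = gene_structure([g])
    assert s.n_exons == 3


def test_gene_structure_from_generator():
    specs = [
        simulate.GeneSpec("gX", "+", [], n_exons=3),
        simulate.GeneSpec("gY", "-", [], n_exons=5, cds_len=600),
        simulate.GeneSpec("gZ", "+", [], n_exons=1),
    ]
    _, genes, _ = simulate.gen_genome(specs, seed=14)
    out = {s.gene_id: s.n_exons for s in gene_structure(genes)}
    assert out == {"gX": 3, "gY": 5, "gZ": 1}
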