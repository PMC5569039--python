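"""Seeded generators for every input the pipeline consumes.

Each generator returns its dataset together with a ground-truth dictionary
(JSON-serializable) sufficient to predict pipeline output exactly (domain
and motif planting) or within stated tolerance (expression).  Protein
backgrounds use an alphabet free of W/C/H/Y so no spurious heptapeptide or
finger match can arise; genomic promoter backgrounds stay ACGT and are
certified motif-free by rejection sampling before planting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .domains import CANONICAL_HEPTAPEPTIDE
from .io import GeneModel, Transcript, reverse_complement
from .regulome import (
    PromoterRegion,
    reverse_complement_pattern,
    scan_motif,
    validate_pattern,
)

#: 20-letter amino-acid alphabet minus W, C, H and Y.
SAFE_AA = "ADEFGIKLMNPQRSTV"

#: (spacer1, spacer2, terminal) finger templates per subgroup; group I lists
#: the N- and C-domain templates.
GROUP_FINGERS: dict[str, list[tuple[int, int, str]]] = {
    "I": [(4, 22, "H"), (4, 23, "H")],
    "IIa": [(5, 22, "H")],
    "IIb": [(5, 23, "H")],
    "IIc": [(4, 23, "H")],
    "IId": [(5, 23, "H")],
    "IIe": [(5, 23, "H")],
    "III": [(7, 23, "C")],
}
#: finger used for non-group decoys (valid spacing, absent from the panel)
NG_FINGER = (6, 14, "H")
#: variant heptapeptides used for non-group decoys
NG_HEPTAPEPTIDES = ("WRKYGKK", "WNKYGQK", "WTKYGQK", "WRKYGRD")

_PANEL_SEED = 291746


def _rand_safe(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(SAFE_AA), size=length))


def _domain_block(
    rng: np.random.Generator,
    spacers: tuple[int, int, str],
    linker_len: int = 8,
    hepta: str = CANONICAL_HEPTAPEPTIDE,
) -> tuple[str, list[int]]:
    """A heptapeptide+finger block and its protected (anchor) positions."""
    s1, s2, term = spacers
    linker = _rand_safe(rng, linker_len)
    block = (
        hepta
        + linker
        + "C"
        + _rand_safe(rng, s1)
        + "C"
        + _rand_safe(rng, s2)
        + "H"
        + _rand_safe(rng, 1)
        + term
    )
    fstart = 7 + linker_len
    protected = [0, 2, 3]  # heptapeptide anchors W, K, Y
    protected += [fstart, fstart + 1 + s1, fstart + s1 + s2 + 2, fstart + s1 + s2 + 4]
    return block, protected


def panel_blocks() -> dict[str, list[tuple[str, list[int]]]]:
    """Deterministic subgroup template blocks (the default panel's source)."""
    rng = np.random.default_rng(_PANEL_SEED)
    return {
        subgroup: [_domain_block(rng, spacers) for spacers in templates]
        for subgroup, templates in GROUP_FINGERS.items()
    }


def write_default_panel(path: str | Path) -> None:
    """Write the deterministic default reference panel as labelled FASTA."""
    from .io import write_fasta

    records = []
    for subgroup, blocks in panel_blocks().items():
        for i, (block, _) in enumerate(blocks, start=1):
            records.append((f"REF_{subgroup}_{i}|{subgroup}", block))
    write_fasta(path, records)


def _mutate_block(
    rng: np.random.Generator,
    block: str,
    protected: Sequence[int],
    rate: float,
) -> str:
    out = list(block)
    protected_set = set(protected)
    for i, ch in enumerate(out):
        if i in protected_set or rate <= 0:
            continue
        if rng.random() < rate:
            choices = [c for c in SAFE_AA if c != ch]
            out[i] = str(rng.choice(choices))
    return "".join(out)


def gen_proteome(
    n_per_group: dict[str, int],
    mutation_rate: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Synthetic proteome with planted WRKY domains and full ground truth.

    Groups I/IIa–e/III are built from the default panel templates (so the
    nearest-reference classifier can recover them); "NG" proteins carry a
    valid domain whose flanks and spacing match no panel entry.
    """
    if not 0.0 <= mutation_rate <= 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    templates = panel_blocks()
    records: list[tuple[str, str]] = []
    truth: dict = {"seed": seed, "mutation_rate": mutation_rate, "proteins": {}}
    for group in sorted(n_per_group):
        if group != "NG" and group not in templates:
            raise ValueError(f"unknown group {group!r}")
        for i in range(n_per_group[group]):
            pid = f"SYN_{group}_{i + 1}"
            if group == "NG":
                hepta = NG_HEPTAPEPTIDES[int(rng.integers(len(NG_HEPTAPEPTIDES)))]
                blocks = [_domain_block(rng, NG_FINGER, linker_len=20, hepta=hepta)]
            else:
                blocks = templates[group]
            segments = [_rand_safe(rng, int(rng.integers(15, 41)))]
            starts, motifs, signatures = [], [], []
            for block, protected in blocks:
                mutated = _mutate_block(rng, block, protected, mutation_rate)
                starts.append(sum(len(s) for s in segments))
                motifs.append(mutated[:7])
                segments.append(mutated)
                segments.append(_rand_safe(rng, int(rng.integers(15, 41))))
            seq = "".join(segments)
            records.append((pid, seq))
            truth["proteins"][pid] = {
                "group": group,
                "n_domains": len(blocks),
                "domain_starts": starts,
                "motifs": motifs,
            }
    return records, truth


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------


@dataclass
class GeneSpec:
    """Recipe for one synthetic gene with planted promoter elements."""

    gene_id: str
    strand: str = "+"
    planted: list[tuple[str, str, int]] = field(default_factory=list)
    # (element_id, IUPAC pattern, ATG-relative offset)
    promoter_len: int = 1000
    n_exons: int = 3
    cds_len: int = 300


class PlantingError(ValueError):
    """Raised when requested planted offsets are infeasible."""


def _plant_constraints(spec: GeneSpec) -> dict[int, set[str]]:
    """Per-column allowed-base sets implied by all planted windows.

    Overlapping windows are legal when their IUPAC constraints intersect on
    every shared column (the fixture tables contain genuinely overlapping
    W-boxes); an empty intersection is an infeasible (overlap) request.
    """
    from .regulome import IUPAC_DNA

    constraints: dict[int, set[str]] = {}
    for element_id, pattern, offset in spec.planted:
        validate_pattern(pattern, element_id)
        m = len(pattern)
        if offset + m > 0 or offset < -spec.promoter_len:
            raise PlantingError(
                f"gene {spec.gene_id}: offset {offset} outside promoter bounds"
            )
        for k, pch in enumerate(pattern):
            col = spec.promoter_len + offset + k
            allowed = constraints.get(col, set("ACGT")) & set(IUPAC_DNA[pch])
            if not allowed:
                raise PlantingError(
                    f"gene {spec.gene_id}: incompatible overlap of planted "
                    f"windows at promoter offset {offset + k - spec.promoter_len}"
                )
            constraints[col] = allowed
    return constraints


def _certified_background(
    rng: np.random.Generator,
    gene_id: str,
    length: int,
    patterns: Sequence[tuple[str, str]],
    max_rounds: int = 200,
) -> Optional[str]:
    """Random ACGT background certified hit-free for every pattern.

    Rejection sampling is targeted: any window still matching a pattern is
    re-randomized and the sequence rescanned, which converges even when the
    certification set is large.
    """
    seq = list(rng.choice(list("ACGT"), size=length))
    for _ in range(max_rounds):
        probe = PromoterRegion(gene_id, "".join(seq), False, "", "+", (0, length))
        hits = [h for _, pat in patterns for h in scan_motif(probe, pat)]
        if not hits:
            return "".join(seq)
        for h in hits:
            lo = length + h.offset
            for k in range(lo, lo + len(h.pattern)):
                seq[k] = str(rng.choice(list("ACGT")))
    return None


def _motif_free_promoter(
    rng: np.random.Generator,
    spec: GeneSpec,
    all_patterns: Sequence[tuple[str, str]] = (),
    max_tries: int = 200,
) -> str:
    """Promoter with planted elements and a certified motif-free background.

    The background is certified against every pattern planted anywhere in
    the dataset (``all_patterns``), so unplanted genes scan clean too.
    """
    patterns = sorted({(eid, pat) for eid, pat, _ in spec.planted} | set(all_patterns))
    constraints = _plant_constraints(spec)
    L = spec.promoter_len
    for _ in range(max_tries):
        bg = _certified_background(rng, spec.gene_id, L, patterns)
        if bg is None:
            continue
        seq = list(bg)
        for col, allowed in constraints.items():
            seq[col] = str(rng.choice(sorted(allowed)))
        planted_seq = "".join(seq)
        region = PromoterRegion(spec.gene_id, planted_seq, False, "", "+", (0, L))
        ok = True
        for eid, pat in patterns:
            # sets, not multisets: a self-reverse-complementary realization
            # legitimately hits both strands at one planted window
            want = {o for e, p, o in spec.planted if (e, p) == (eid, pat)}
            got = {h.offset for h in scan_motif(region, pat, eid)}
            if want != got:
                ok = False
                break
        if ok:
            return planted_seq
    raise PlantingError(f"gene {spec.gene_id}: could not realize planted offsets")


def gen_genome(
    gene_specs: Sequence[GeneSpec],
    seed: Optional[int] = None,
    window: int = 1000,
    certify_patterns: Sequence[tuple[str, str]] = (("WBOX", "YTGACY"),),
) -> tuple[dict[str, str], list[GeneModel], dict]:
    """Genome FASTA dict + gene models + ground truth for planted elements.

    Each gene gets its own contig.  A promoter shorter than ``window`` is
    placed flush against the contig start so extraction reports truncation.
    Genes may sit on either strand; planted offsets are always expressed in
    gene orientation.  Promoter backgrounds are certified free of every
    pattern planted anywhere in the dataset plus ``certify_patterns`` (the
    W-box by default), so unplanted genes scan clean.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth: dict = {"seed": seed, "window": window, "genes": {}}
    all_patterns = sorted(
        {(eid, pat) for spec in gene_specs for eid, pat, _ in spec.planted}
        | set(certify_patterns)
    )
    for spec in gene_specs:
        if spec.strand not in "+-":
            raise ValueError(f"gene {spec.gene_id}: bad strand {spec.strand!r}")
        if spec.cds_len % 3 or spec.cds_len < 3 * spec.n_exons:
            raise ValueError(f"gene {spec.gene_id}: invalid cds_len")
        promoter = _motif_free_promoter(rng, spec, all_patterns)
        cds = "ATG" + "".join(rng.choice(list("ACGT"), size=spec.cds_len - 6)) + "TAA"
        # split CDS across exons with fixed-length introns
        bounds = np.linspace(0, spec.cds_len, spec.n_exons + 1).astype(int)
        pieces = [cds[bounds[k] : bounds[k + 1]] for k in range(spec.n_exons)]
        intron_len = 40
        body = ""
        exon_local: list[tuple[int, int]] = []
        for k, piece in enumerate(pieces):
            if k:
                body += "".join(rng.choice(list("ACGT"), size=intron_len))
            start = len(body)
            body += piece
            exon_local.append((start, len(body)))
        left_pad = 0 if spec.promoter_len < window else int(rng.integers(0, 30))
        right_pad = int(rng.integers(10, 30))
        cassette = (
            "".join(rng.choice(list("ACGT"), size=left_pad))
            + promoter
            + body
            + "".join(rng.choice(list("ACGT"), size=right_pad))
        )
        body_off = left_pad + spec.promoter_len
        gene_local = (body_off, body_off + len(body))
        exons_cas = [(body_off + s, body_off + e) for s, e in exon_local]
        Lc = len(cassette)
        if spec.strand == "+":
            contig_seq = cassette
            gene_iv = gene_local
            exons = exons_cas
        else:
            contig_seq = reverse_complement(cassette)
            gene_iv = (Lc - gene_local[1], Lc - gene_local[0])
            exons = sorted((Lc - e, Lc - s) for s, e in exons_cas)
        contig = f"ctg_{spec.gene_id}"
        genome[contig] = contig_seq
        t = Transcript(f"{spec.gene_id}.t1", exons=list(exons), cds=list(exons))
        genes.append(
            GeneModel(spec.gene_id, contig, spec.strand, gene_iv[0], gene_iv[1], [t])
        )
        truth["genes"][spec.gene_id] = {
            "strand": spec.strand,
            "promoter_len": spec.promoter_len,
            "truncated": spec.promoter_len < window,
            "n_exons": spec.n_exons,
            "planted": [
                {"element": eid, "pattern": pat, "offset": off}
                for eid, pat, off in spec.planted
            ],
        }
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def gen_ct_table(
    fold_changes: dict[str, dict[str, float]],
    sigma: float = 0.1,
    replicates: int = 3,
    seed: Optional[int] = None,
    control_condition: str = "0h",
    reference_gene: str = "ACT",
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
):
    """Ct table with specified per-condition true fold changes.

    ``fold_changes[gene][condition]`` is the true expression ratio against
    the control; the target's Ct is shifted by -log2(fold).  The reference
    gene is constant up to noise.  Returns (DataFrame, ground truth).
    """
    import pandas as pd

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    conditions = sorted({c for folds in fold_changes.values() for c in folds} | {control_condition})
    rows = []
    for condition in conditions:
        for rep in range(1, replicates + 1):
            rows.append((reference_gene, condition, rep, reference_ct + sigma * rng.standard_normal()))
    for gene in sorted(fold_changes):
        folds = fold_changes[gene]
        for condition in conditions:
            fold = 1.0 if condition == control_condition else folds.get(condition, 1.0)
            for rep in range(1, replicates + 1):
                ct = base_ct - math.log2(fold) + sigma * rng.standard_normal()
                rows.append((gene, condition, rep, ct))
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    truth = {
        "seed": seed,
        "sigma": sigma,
        "replicates": replicates,
        "control_condition": control_condition,
        "reference_gene": reference_gene,
        "fold_changes": fold_changes,
    }
    return table, truth


def gen_counts(
    fold_changes: dict[str, float],
    n_replicates: int = 3,
    dispersion: float = 0.1,
    seed: Optional[int] = None,
    base_mean: Optional[dict[str, float]] = None,
    lengths: Optional[dict[str, int]] = None,
):
    """Negative-binomial count table with library-size factors.

    Control samples C1..Cn draw from each gene's base mean; treated samples
    T1..Tn from base mean times the gene's true fold change.  Returns
    (DataFrame with columns gene/sample/count/length, ground truth).
    """
    import pandas as pd

    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    genes = sorted(fold_changes)
    if base_mean is None:
        base_mean = {g: float(rng.uniform(100, 2000)) for g in genes}
    if lengths is None:
        lengths = {g: int(rng.integers(500, 3000)) for g in genes}
    samples = [f"C{i+1}" for i in range(n_replicates)] + [
        f"T{i+1}" for i in range(n_replicates)
    ]
    lib = {s: float(rng.uniform(0.7, 1.3)) for s in samples}
    r = 1.0 / dispersion
    rows = []
    for g in genes:
        for s in samples:
            mu = base_mean[g] * (fold_changes[g] if s.startswith("T") else 1.0)
            m = mu * lib[s]
            count = int(rng.negative_binomial(r, r / (r + m))) if m > 0 else 0
            rows.append((g, s, count, lengths[g]))
    table = pd.DataFrame(rows, columns=["gene", "sample", "count", "length"])
    truth = {
        "seed": seed,
        "dispersion": dispersion,
        "fold_changes": fold_changes,
        "base_mean": base_mean,
        "lengths": lengths,
        "library_factors": lib,
        "control_samples": samples[:n_replicates],
        "treated_samples": samples[n_replicates:],
    }
    return table, truth


def save_ground_truth(truth: dict, path: str | Path) -> None:
    from .io import atomic_open

    with atomic_open(path) as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
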