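"""Readers and writers for the formats the pipeline consumes and emits.

FASTA via Biopython; GFF3 through a small tolerant reader (1-based closed
coordinates are converted to 0-based half-open at this boundary; a gene with
CDS children but no mRNA is treated as a single-transcript gene).  Report
TSVs carry a commented header naming columns and the tool version.  All
writers go through write-to-temp-then-rename so failures leave no partial
output behind.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class GFF3Error(ValueError):
    """Raised for a malformed GFF3 line; message carries the line number."""


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def cds_span(self) -> tuple[int, int] | None:
        """Genomic min/max over all CDS intervals, or None without CDS."""
        intervals = [iv for t in self.transcripts for iv in t.cds]
        if not intervals:
            return None
        return min(s for s, _ in intervals), max(e for _, e in intervals)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], wrap: int = 60) -> None:
    with atomic_open(path) as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _attributes(field9: str, lineno: int) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GFF3Error(f"GFF3 line {lineno}: malformed attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModels.

    Raises :class:`GFF3Error` naming the line number on malformed records.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    transcript_gene: dict[str, str] = {}
    pending: list[tuple[str, str, int, int, int]] = []  # type, parent, start, end, line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3Error(
                    f"GFF3 line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            contig, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GFF3Error(f"GFF3 line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise GFF3Error(f"GFF3 line {lineno}: invalid interval {start}..{end}")
            start0, end0 = start - 1, end  # to 0-based half-open
            attrs = _attributes(attrs_s, lineno)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise GFF3Error(f"GFF3 line {lineno}: gene without ID")
                genes[gid] = GeneModel(gid, contig, strand, start0, end0)
            elif ftype == "mRNA":
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise GFF3Error(f"GFF3 line {lineno}: mRNA needs ID and Parent")
                transcripts[tid] = Transcript(tid)
                transcript_gene[tid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise GFF3Error(f"GFF3 line {lineno}: {ftype} without Parent")
                pending.append((ftype, parent, start0, end0, lineno))
    for ftype, parent, start0, end0, lineno in pending:
        if parent in transcripts:
            t = transcripts[parent]
        elif parent in genes:
            # gene without mRNA children: treat gene+CDS as one transcript
            t = transcripts.setdefault(parent, Transcript(parent))
            transcript_gene.setdefault(parent, parent)
        else:
            raise GFF3Error(f"GFF3 line {lineno}: unknown Parent {parent!r}")
        (t.exons if ftype == "exon" else t.cds).append((start0, end0))
    for tid, t in transcripts.items():
        t.exons.sort()
        t.cds.sort()
        gid = transcript_gene[tid]
        if gid in genes:
            genes[gid].transcripts.append(t)
    return list(genes.values())


def write_gff3(
    path: str | Path,
    genes: Sequence[GeneModel],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    with atomic_open(path) as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.contig}\twrkykit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.contig}\twrkykit\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.contig}\twrkykit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for s, e in t.cds:
                    fh.write(
                        f"{g.contig}\twrkykit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


@contextmanager
def atomic_open(path: str | Path):
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_report_tsv(path: str | Path, df: pd.DataFrame, columns: Sequence[str] | None = None) -> None:
    """Write a report TSV with a commented header naming columns and version."""
    from . import __version__

    if columns is not None:
        df = df[list(columns)]
    with atomic_open(path) as fh:
        fh.write(f"# wrkykit {__version__}\n")
        fh.write("# columns: " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_catalog_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """3-column catalog TSV (element_id, IUPAC pattern, category); '#' comments."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"catalog line {lineno}: expected 3 tab-separated columns"
                )
            rows.append((parts[0], parts[1], parts[2]))
    return rows


def read_panel_fasta(path: str | Path):
    """Reference panel FASTA with '>id|subgroup' headers."""
    from .classify import PanelEntry, ReferencePanel

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"panel header {rec.id!r} lacks '|subgroup' suffix")
        rid, subgroup = rec.id.rsplit("|", 1)
        entries.append(PanelEntry(rid, subgroup, str(rec.seq)))
    return ReferencePanel(entries)
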