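"""Readers and writers for the interchange formats used between stages:
plain FASTA, 12-column BLAST tabular ("outfmt 6") hit tables, and GFF3 gene
models.  Trees travel as newick via :mod:`skbio`."""

from __future__ import annotations

import csv
from pathlib import Path
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .recovery import OpenReadingFrame, RecoveredGene
from .search import LocalAlignmentHit

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_hits_tsv(hits: list[LocalAlignmentHit], path: str | Path) -> None:
    """Write hits in BLAST outfmt-6 column order.

    The strand convention follows BLAST: on minus-strand hits the subject
    coordinates are swapped (sstart > send) while query coordinates stay
    ascending.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            s_start, s_end = (h.s_start, h.s_end) if h.strand == "+" else (h.s_end, h.s_start)
            w.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity_pct:.3f}",
                    h.align_len,
                    h.mismatches,
                    h.gap_opens,
                    h.q_start,
                    h.q_end,
                    s_start,
                    s_end,
                    f"{h.evalue:.3g}",
                    f"{h.bit_score:.1f}",
                ]
            )


def read_hits_tsv(path: str | Path) -> list[LocalAlignmentHit]:
    hits: list[LocalAlignmentHit] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            s_start, s_end = int(row[8]), int(row[9])
            strand = "+" if s_start <= s_end else "-"
            if strand == "-":
                s_start, s_end = s_end, s_start
            hits.append(
                LocalAlignmentHit(
                    query_id=row[0],
                    subject_id=row[1],
                    identity_pct=float(row[2]),
                    align_len=int(row[3]),
                    mismatches=int(row[4]),
                    gap_opens=int(row[5]),
                    q_start=int(row[6]),
                    q_end=int(row[7]),
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                    raw_score=0,
                    bit_score=float(row[11]),
                    evalue=float(row[10]),
                )
            )
    return hits


def write_genes_gff3(genes: list[RecoveredGene], path: str | Path) -> None:
    """Recovered genes as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            o = g.orf
            attrs = (
                f"ID={quote(g.gene_id)};best_subject={quote(g.best_subject)};"
                f"identity={g.best_identity_pct:.2f};overlap_frac={g.overlap_frac:.3f};"
                f"group={g.group.value}"
            )
            fh.write(
                "\t".join(
                    [
                        o.contig_id,
                        "copatrace",
                        "gene",
                        str(o.start + 1),
                        str(o.end),
                        f"{g.best_identity_pct:.2f}",
                        o.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_orfs_gff3(orfs: list[OpenReadingFrame], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(
                "\t".join(
                    [
                        o.contig_id,
                        "copatrace",
                        "ORF",
                        str(o.start + 1),
                        str(o.end),
                        ".",
                        o.strand,
                        "0",
                        f"ID={quote(o.contig_id)}_{o.start}_{o.end}",
                    ]
                )
                + "\n"
            )


def read_gff3_intervals(path: str | Path) -> list[tuple[str, int, int, str, dict]]:
    """GFF3 -> list of (seqid, start, end, strand, attributes) with 0-based
    half-open coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            for kv in f[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = unquote(v)
            out.append((f[0], int(f[3]) - 1, int(f[4]), f[6], attrs))
    return out
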