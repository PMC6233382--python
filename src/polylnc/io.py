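"""Readers and writers for the standard text formats the pipeline touches.

GTF/GFF3 annotation, BED6 intervals (TE and read features), FASTA genomes,
7-column per-cytosine methylation reports, 12-column tabular homology hits
and tab-delimited count matrices.  Coordinates are converted between the
external conventions (1-based closed for GTF/GFF3 and the methylation
report; 0-based half-open for BED) and the internal 0-based half-open
model at this boundary only.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CountMatrix,
    CytosineRecord,
    GenomicInterval,
    HomologyHit,
    PolylncError,
    TEFeature,
    TranscriptModel,
    group_loci,
)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _parse_attributes(field: str, fmt: str) -> dict[str, str]:
    pat = _GTF_ATTR if fmt == "GTF" else _GFF3_ATTR
    return dict(pat.findall(field))


def read_annotation(path, format: str = "GTF") -> list[TranscriptModel]:
    """Read transcript models from a GTF or GFF3 annotation.

    Exon features must carry ``transcript_id``/``gene_id`` (GTF) or
    ``Parent`` plus a transcript feature with ``ID``/``Parent`` (GFF3).
    1-based closed coordinates are converted to 0-based half-open.
    Transcripts without a gene/locus identifier are grouped into loci by
    same-strand exonic overlap.
    """

    fmt = format.upper()
    if fmt not in ("GTF", "GFF3"):
        raise PolylncError(f"unknown annotation format {format!r}")
    exons: dict[str, list[GenomicInterval]] = {}
    tx_locus: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    tx_span: dict[str, GenomicInterval] = {}
    gff3_parent: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise PolylncError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise PolylncError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-"):
                raise PolylncError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_s, fmt)
            try:
                iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            except PolylncError as exc:
                raise PolylncError(f"{path}:{lineno}: {exc}") from None

            if fmt == "GTF":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise PolylncError(f"{path}:{lineno}: missing transcript_id")
                if ftype == "exon":
                    exons.setdefault(tid, []).append(iv)
                    tx_locus.setdefault(tid, attrs.get("gene_id", ""))
                    if "biotype" in attrs:
                        tx_biotype[tid] = attrs["biotype"]
                elif ftype == "transcript":
                    tx_span[tid] = iv
                    tx_locus[tid] = attrs.get("gene_id", "")
                    if "biotype" in attrs:
                        tx_biotype[tid] = attrs["biotype"]
            else:  # GFF3
                if ftype == "exon":
                    tid = attrs.get("Parent")
                    if tid is None:
                        raise PolylncError(f"{path}:{lineno}: exon without Parent")
                    exons.setdefault(tid, []).append(iv)
                elif ftype in ("mRNA", "transcript", "lnc_RNA", "ncRNA"):
                    tid = attrs.get("ID")
                    if tid is None:
                        raise PolylncError(
                            f"{path}:{lineno}: transcript feature without ID"
                        )
                    tx_span[tid] = iv
                    gff3_parent[tid] = attrs.get("Parent", "")
                    if "biotype" in attrs:
                        tx_biotype[tid] = attrs["biotype"]

    models: list[TranscriptModel] = []
    for tid, exs in sorted(exons.items()):
        exs = sorted(exs, key=lambda e: e.start)
        span = GenomicInterval(
            exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand
        )
        if tid in tx_span:
            declared = tx_span[tid]
            if not declared.contains(span):
                raise PolylncError(
                    f"transcript {tid}: exons outside declared span"
                )
            span = declared
        locus = tx_locus.get(tid) or gff3_parent.get(tid, "")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                locus_id=locus,
                interval=span,
                exons=exs,
                biotype=tx_biotype.get(tid, "lncRNA_candidate"),
            )
        )
    return group_loci(models)


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as GTF (1-based closed coordinates)."""

    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.locus_id}"; transcript_id "{t.transcript_id}"; '
                f'biotype "{t.biotype}";'
            )
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tpolylnc\ttranscript\t{iv.start + 1}\t{iv.end}\t."
                f"\t{iv.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\tpolylnc\texon\t{e.start + 1}\t{e.end}\t."
                    f"\t{e.strand}\t.\t{attrs}\n"
                )


def read_te_bed(path) -> list[TEFeature]:
    """Read TE features from BED6; column 4 is ``family:te_id``.

    Strand ``.`` is permitted (repeat annotations often omit it).
    """

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PolylncError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                iv = GenomicInterval(chrom, int(start_s), int(end_s), strand)
            except (ValueError, PolylncError) as exc:
                raise PolylncError(f"{path}:{lineno}: {exc}") from None
            family, _, te_id = name.partition(":")
            out.append(TEFeature(iv, family, te_id or name))
    return out


def write_te_bed(tes: Iterable[TEFeature], path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.family}:{te.te_id}"
                f"\t0\t{iv.strand}\n"
            )


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read plain intervals (e.g. sRNA reads, occupancy) from BED."""

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PolylncError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, PolylncError) as exc:
                raise PolylncError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_cx_report(path) -> list[CytosineRecord]:
    """Read a 7-column per-cytosine report.

    Columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context (CG/CHG/CHH), trinucleotide.  The
    position is converted to 0-based; ``n_total = meth + unmeth``.
    """

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PolylncError(f"{path}:{lineno}: expected >= 6 columns")
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            try:
                pos1, n_meth, n_unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError:
                raise PolylncError(f"{path}:{lineno}: non-integer field") from None
            if n_meth < 0 or n_unmeth < 0:
                raise PolylncError(f"{path}:{lineno}: negative counts")
            try:
                out.append(
                    CytosineRecord(chrom, pos1 - 1, strand, context,
                                   n_meth, n_meth + n_unmeth)
                )
            except PolylncError as exc:
                raise PolylncError(f"{path}:{lineno}: {exc}") from None
    return out


def write_cx_report(records: Iterable[CytosineRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.n_meth}"
                f"\t{r.n_total - r.n_meth}\t{r.context}\t{r.context}N\n"
            )


def write_cx_frame(frame: pd.DataFrame, path) -> None:
    """Write a columnar per-cytosine table (chrom, pos, strand, context,
    n_meth, n_total) as a 7-column report; vectorised for large frames."""

    out = pd.DataFrame({
        "chrom": frame["chrom"],
        "pos": frame["pos"] + 1,
        "strand": frame["strand"],
        "meth": frame["n_meth"],
        "unmeth": frame["n_total"] - frame["n_meth"],
        "context": frame["context"],
        "tricontext": frame["context"] + "N",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def cx_records_to_frame(records: Sequence[CytosineRecord]) -> pd.DataFrame:
    """Columnar view of cytosine records for vectorised aggregation."""

    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": np.fromiter((r.pos for r in records), dtype=np.int64,
                               count=len(records)),
            "strand": [r.strand for r in records],
            "context": [r.context for r in records],
            "n_meth": np.fromiter((r.n_meth for r in records), dtype=np.int64,
                                  count=len(records)),
            "n_total": np.fromiter((r.n_total for r in records), dtype=np.int64,
                                   count=len(records)),
        }
    )


def read_hits_tabular(path) -> list[HomologyHit]:
    """Read 12-column tabular local-alignment hits.

    Query/subject coordinates are 1-based closed; subject coordinates
    with ``sstart > send`` denote a minus-strand hit and are normalised
    to ``start < end`` with strand ``-``.
    """

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise PolylncError(f"{path}:{lineno}: expected 12 columns")
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                pident = float(fields[2])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise PolylncError(
                    f"{path}:{lineno}: non-numeric coordinate or score"
                ) from None
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            try:
                out.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        query_interval=GenomicInterval(
                            fields[0], qstart - 1, qend, "+"
                        ),
                        subject_interval=GenomicInterval(
                            fields[1], sstart - 1, send, strand
                        ),
                        percent_identity=pident,
                        evalue=evalue,
                        bitscore=bitscore,
                    )
                )
            except PolylncError as exc:
                raise PolylncError(f"{path}:{lineno}: {exc}") from None
    return out


def write_hits_tabular(hits: Iterable[HomologyHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            q, s = h.query_interval, h.subject_interval
            sstart, send = s.start + 1, s.end
            if s.strand == "-":
                sstart, send = send, sstart
            n = len(q)
            mism = int(round(n * (1 - h.percent_identity / 100)))
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t{n}"
                f"\t{mism}\t0\t{q.start + 1}\t{q.end}\t{sstart}\t{send}"
                f"\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def read_count_matrix(path) -> CountMatrix:
    """Read a tab-delimited count table (loci x samples).

    An optional first row ``#library_sizes`` carries total mapped reads
    per sample; otherwise column sums are used.
    """

    library_sizes = None
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#library_sizes"):
            library_sizes = [int(x) for x in first.split("\t")[1:]]
            table = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            table = pd.read_csv(fh, sep="\t", index_col=0)
    if library_sizes is None:
        sizes = table.sum(axis=0)
    else:
        if len(library_sizes) != table.shape[1]:
            raise PolylncError(f"{path}: library_sizes width mismatch")
        sizes = pd.Series(library_sizes, index=table.columns)
    return CountMatrix(table, sizes)


def write_count_matrix(cm: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#library_sizes\t" + "\t".join(str(int(x)) for x in cm.library_sizes) + "\n")
        cm.counts.to_csv(fh, sep="\t", index_label="locus_id")


def best_hit_per_query(hits: Sequence[HomologyHit]) -> dict[str, HomologyHit]:
    """Best hit per query by bitscore (ties: lowest E, then subject id)."""

    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.bitscore > cur.bitscore
            or (h.bitscore == cur.bitscore and (h.evalue, h.subject_id)
                < (cur.evalue, cur.subject_id))
        ):
            best[h.query_id] = h
    return best
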