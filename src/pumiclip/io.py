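"""Readers and writers for the plain-text formats used by the pipeline.

BED6 carries reads (UMI in the name field as ``readid|UMI``) and
clusters; bedGraph carries depth-normalized coverage; FASTA carries
transcript sequences; gene models and count matrices travel as TSV.
All emitted coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CoverageTrack, GeneModel, GenomicInterval, ReadRecord

GENE_TABLE_COLUMNS = [
    "gene_id", "chrom", "strand",
    "span_start", "span_end", "utr3_start", "utr3_end", "tx_length",
]


# ---------------------------------------------------------------------------
# BED6 reads
# ---------------------------------------------------------------------------

def write_reads_bed(reads: Iterable[ReadRecord], path) -> None:
    """Write reads as BED6; name field is ``readid|UMI``, score is 0."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{i}|{r.umi}\t0\t{iv.strand}\n"
            )


def read_reads_bed(path, sample_id: str) -> list[ReadRecord]:
    """Read BED6 reads written by :func:`write_reads_bed`."""
    reads = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected BED6, got {len(parts)} fields")
            chrom, start, end, name, _score, strand = parts[:6]
            if "|" not in name:
                raise ValueError(f"{path}:{ln}: name field lacks '|UMI' suffix")
            umi = name.rsplit("|", 1)[1]
            reads.append(
                ReadRecord(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    sample_id=sample_id,
                    umi=umi,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, total_usable: int, path) -> None:
    """Write depth-normalized coverage as bedGraph.

    Values are ``coverage * 1e6 / total_usable`` (reads per million
    usable reads); adjacent equal-value runs are collapsed and zero
    runs are omitted.
    """
    if total_usable <= 0:
        raise ValueError("no usable reads: total_usable must be > 0")
    scale = 1e6 / total_usable
    vals = track.values
    with open(path, "w") as fh:
        if len(vals) == 0:
            return
        # run-length encode
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vals)]))
        for s, e in zip(starts, ends):
            v = vals[s]
            if v == 0:
                continue
            fh.write(
                f"{track.chrom}\t{track.span_start + s}\t{track.span_start + e}\t"
                f"{v * scale:.6g}\n"
            )


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((chrom, int(start), int(end), float(value)))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genes: Sequence[GeneModel], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
        for g in genes
        if g.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Map sequence id -> uppercase sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Gene-model table
# ---------------------------------------------------------------------------

def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.span.chrom,
            "strand": g.span.strand,
            "span_start": g.span.start,
            "span_end": g.span.end,
            "utr3_start": g.utr3.start,
            "utr3_end": g.utr3.end,
            "tx_length": g.tx_length,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path, sequences: dict[str, str] | None = None) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} lacks columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        seq = sequences.get(row.gene_id) if sequences else None
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                span=GenomicInterval(row.chrom, int(row.span_start), int(row.span_end), row.strand),
                utr3=GenomicInterval(row.chrom, int(row.utr3_start), int(row.utr3_end), row.strand),
                tx_length=int(row.tx_length),
                sequence=seq,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Count matrices / sample sheets / ground truth
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genotype", "kind", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet {path} must carry columns {sorted(required)}")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
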