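"""File I/O: FASTA, GFF3, SAM and TSV alignment tables.

Genomes are handled in memory as ``dict[str, str]`` (contig id -> sequence);
alignment tables as pandas DataFrames with columns
``read_id, ref_id, start, end, identity`` (0-based half-open intervals).
"""
from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

ALIGNMENT_COLUMNS = ["read_id", "ref_id", "start", "end", "identity"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}
    if not genome:
        raise ValueError(f"no sequences in FASTA file: {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | os.PathLike, wrap: int = 80) -> None:
    """Write contigs to FASTA, wrapped at ``wrap`` columns."""
    records = (SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.items())
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(features: Iterable[dict], path: str | os.PathLike) -> None:
    """Write GFF3 features.

    Each feature dict carries ``seqid, source, type, start, end`` (0-based
    half-open; converted here to 1-based closed), optional ``score, strand,
    phase`` and an ``attributes`` mapping (ID/Name/Parent/...).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            row = [
                f["seqid"],
                f.get("source", "evekit"),
                f["type"],
                str(int(f["start"]) + 1),
                str(int(f["end"])),
                str(f.get("score", ".")),
                f.get("strand", "."),
                str(f.get("phase", ".")),
                attrs or ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_gff3_features(path: str | os.PathLike) -> list[dict]:
    """Read GFF3 features back into the same dict form (0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.all_features():
        out.append(
            {
                "seqid": feat.seqid,
                "source": feat.source,
                "type": feat.featuretype,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
                "attributes": {k: v[0] for k, v in feat.attributes.items()},
            }
        )
    return out


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str | os.PathLike) -> pd.DataFrame:
    """Read an alignment table from SAM or 5-column TSV.

    SAM: primary, mapped records only (secondary/supplementary dropped),
    matching CoverM-style recruitment semantics. Dialect is chosen by file
    extension (``.sam`` vs anything else = TSV).
    """
    path = os.fspath(path)
    if path.endswith(".sam"):
        rows = []
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                ident = 1.0
                if rec.has_tag("NM") and rec.query_alignment_length:
                    ident = 1.0 - rec.get_tag("NM") / rec.query_alignment_length
                rows.append(
                    (rec.query_name, rec.reference_name, rec.reference_start,
                     rec.reference_end, ident)
                )
        return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    return df[ALIGNMENT_COLUMNS]


def write_alignments_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_alignments_sam(
    df: pd.DataFrame, ref_lengths: dict[str, int], path: str | os.PathLike
) -> None:
    """Write the alignment table as a minimal SAM file (with @SQ headers).

    Sequence/quality fields are omitted (``*``); the CIGAR is a single match
    run of the interval length. Intended for interoperability checks, not as
    a read simulator.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = str(row.read_id)
            a.reference_name = str(row.ref_id)
            a.reference_start = int(row.start)
            a.mapping_quality = 60
            a.flag = 0
            length = int(row.end) - int(row.start)
            a.cigartuples = [(0, length)]
            a.set_tag("NM", int(round((1.0 - float(row.identity)) * length)))
            out.write(a)
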