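"""Readers and writers for the on-disk formats the pipeline consumes.

All interval files are BED dialect (0-based half-open); tables are plain
tab-separated text with a header.  BAM handling goes through pysam.
"""

from __future__ import annotations

import os

import pandas as pd
import pysam

BED_COLS = ["chrom", "start", "end"]


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    path = os.fspath(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(os.fspath(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(df: pd.DataFrame, path: str | os.PathLike, extra_cols: list[str] | None = None) -> None:
    cols = BED_COLS + (extra_cols or [])
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed(path: str | os.PathLike, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = BED_COLS + (extra_cols or [])
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bam(
    reads: pd.DataFrame,
    substitutions: pd.DataFrame,
    sequences: dict[str, str],
    path: str | os.PathLike,
    mapq: int = 60,
) -> None:
    """Write simulated reads as a coordinate-sorted, indexed BAM.

    ``reads`` needs columns read_id, chrom, start, end, is_reverse;
    ``substitutions`` columns read_id, base_pos, to_base give the damage
    edits relative to the reference.  Reads are stored in reference-forward
    orientation (reverse-strand molecules get flag 16), with a full-match
    CIGAR and NM set to the number of edits.
    """
    path = os.fspath(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in sequences.items()],
    }
    subs_by_read: dict[object, list[tuple[int, str]]] = {}
    if len(substitutions):
        for rid, bpos, base in zip(
            substitutions["read_id"], substitutions["base_pos"], substitutions["to_base"]
        ):
            subs_by_read.setdefault(rid, []).append((int(bpos), base))
    tmp = path + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        order = reads.sort_values(["chrom", "start"], kind="stable")
        for rid, chrom, start, end, rev in zip(
            order["read_id"], order["chrom"], order["start"], order["end"], order["is_reverse"]
        ):
            start, end = int(start), int(end)
            seq = list(sequences[chrom][start:end])
            edits = subs_by_read.get(rid, [])
            for bpos, base in edits:
                seq[bpos - start] = base
            a = pysam.AlignedSegment()
            a.query_name = str(rid)
            a.flag = 16 if rev else 0
            a.reference_id = list(sequences).index(chrom)
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = f"{end - start}M"
            a.query_sequence = "".join(seq)
            a.query_qualities = pysam.qualitystring_to_array("I" * (end - start))
            a.set_tag("NM", len(edits))
            bam.write(a)
    pysam.sort("-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)
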