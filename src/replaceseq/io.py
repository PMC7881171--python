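"""Format readers and writers: FASTA, FASTQ, BED, TSV, JSON.

FASTA/FASTQ go through Bio.SeqIO with a validation layer (reads with
non-ACGTN bases are rejected naming the offending record). BED is the
3+-column, 0-based half-open dialect; converting from 1-based inputs is the
caller's job. All writers produce content that the matching reader restores
exactly (round-trip fidelity), so every intermediate table is a re-loadable
pipeline input.
"""

from __future__ import annotations

import json

import pandas as pd
from Bio import SeqIO

from .dna import is_dna
from .simulate import ReadRecord


class FormatError(ValueError):
    """Malformed input file."""


def read_fasta(path) -> dict:
    """FASTA -> {name: sequence} (upper-cased, ACGTN enforced)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not is_dna(seq, allow_n=True):
            raise FormatError(f"record {rec.id!r}: non-ACGTN base in sequence")
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record id {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path, umi_from: str | None = "header", umi_len: int = 0) -> list:
    """FASTQ -> list[ReadRecord].

    UMIs are recovered either from a ``umi=XXX`` key in the read header
    (``umi_from='header'``, absent keys give umi=None) or from the first
    ``umi_len`` bases of the read (``umi_from='prefix'``; the bases are
    stripped from the sequence).
    """
    reads = []
    try:
        records = list(SeqIO.parse(str(path), "fastq"))
    except ValueError as e:
        raise FormatError(f"malformed FASTQ {path}: {e}") from e
    for rec in records:
        seq = str(rec.seq).upper()
        if not is_dna(seq, allow_n=True):
            raise FormatError(f"read {rec.id!r}: non-ACGTN base in sequence")
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        umi = None
        if umi_from == "header":
            for token in rec.description.split():
                if token.startswith("umi="):
                    umi = token[4:]
        elif umi_from == "prefix" and umi_len:
            umi, seq, qual = seq[:umi_len], seq[umi_len:], qual[umi_len:]
        reads.append(ReadRecord(id=rec.id, sequence=seq, qualities=qual, umi=umi))
    return reads


def write_fastq(reads, path) -> None:
    """list[ReadRecord] -> FASTQ; UMIs stored as a ``umi=`` header key."""
    with open(path, "w") as fh:
        for r in reads:
            header = r.id if r.umi is None else f"{r.id} umi={r.umi}"
            fh.write(f"@{header}\n{r.sequence}\n+\n{r.qualities}\n")


def read_bed(path) -> list:
    """BED (>= 3 columns, 0-based half-open) -> [(chrom, start, end, name), ...]."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer interval") from e
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} <= start {start}"
                )
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            name = fields[3] if len(fields) > 3 else ""
            out.append((chrom, start, end, name))
    return out


def write_bed(intervals, path) -> None:
    """[(chrom, start, end[, name]), ...] -> BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 and iv[3] else None
            row = f"{chrom}\t{start}\t{end}"
            fh.write(row + (f"\t{name}\n" if name is not None else "\n"))


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def json_dumps(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True)
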