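"""Small readers/writers for the plain-text formats the pipeline exchanges.

All intervals are 0-based half-open in memory. GFF3 output converts to
1-based closed coordinates; BED stays 0-based half-open. FASTQ is written
gzipped with a zeroed mtime so identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out[rec.name] = rec.sequence.upper()
    return out


def write_bed6(path: str | Path, rows: Iterable[tuple[str, int, int, str, int | float, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5]))
    return rows


def write_fastq_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    pairs: Iterable[tuple[str, str]],
    name_prefix: str = "read",
    quality_char: str = "I",
) -> None:
    """Write (seq1, seq2) pairs as a gzipped FASTQ pair with constant quality."""
    f1 = gzip.GzipFile(filename="", mode="wb", fileobj=open(r1_path, "wb"), mtime=0)
    f2 = gzip.GzipFile(filename="", mode="wb", fileobj=open(r2_path, "wb"), mtime=0)
    try:
        for i, (s1, s2) in enumerate(pairs):
            name = f"{name_prefix}.{i}"
            f1.write(f"@{name}/1\n{s1}\n+\n{quality_char * len(s1)}\n".encode())
            f2.write(f"@{name}/2\n{s2}\n+\n{quality_char * len(s2)}\n".encode())
    finally:
        f1.close()
        f2.close()


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for a, b in zip(f1, f2):
            pairs.append((a.sequence.upper(), b.sequence.upper()))
    return pairs
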