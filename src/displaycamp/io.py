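"""File I/O conventions: sequence files, tables, and count frames.

Sequence files stream; tables are pandas frames (TSV/CSV by extension,
UTF-8, '.' decimal).  Gzipped FASTQ/FASTA are detected by the .gz suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .amplicon import VariantKey
from .enrichment import SampleCounts
from .synthetic import FastqRecord

__all__ = [
    "ParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "read_table",
    "write_table",
    "counts_to_frame",
    "counts_from_frame",
]


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        suffix = f" (around line {line})" if line is not None else ""
        super().__init__(message + suffix)
        self.line = line


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream 4-line FASTQ records; malformed input raises ParseError with
    the approximate line number."""
    n = 0
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                yield FastqRecord(title.split()[0], seq, qual)
        except ValueError as exc:
            raise ParseError(str(exc), line=4 * n + 1) from exc


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from a FASTA file."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with _open_text(path) as handle:
        n = 0
        try:
            for title, seq in SimpleFastaParser(handle):
                n += 1
                yield title.split()[0], seq
        except ValueError as exc:
            raise ParseError(str(exc), line=2 * n + 1) from exc


def read_table(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a TSV/CSV by extension and validate required columns."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    sep = "\t" if name.endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    missing = set(required) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}", line=1)
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, encoding="utf-8")


def counts_to_frame(samples: Iterable[SampleCounts]) -> pd.DataFrame:
    frames = [s.to_frame() for s in samples]
    return pd.concat(frames, ignore_index=True)


def counts_from_frame(frame: pd.DataFrame) -> dict[str, SampleCounts]:
    """Rebuild per-sample counts from a long count table
    (sample_id, vh_pair, vl_pair[, dna_key], reads)."""
    required = {"sample_id", "vh_pair", "vl_pair", "reads"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"count table missing columns {sorted(missing)}")
    out: dict[str, SampleCounts] = {}
    has_dna = "dna_key" in frame.columns
    for row in frame.itertuples(index=False):
        dna = getattr(row, "dna_key", "") if has_dna else ""
        dna = dna if isinstance(dna, str) and dna else None
        key = VariantKey(vl_pair=row.vl_pair, vh_pair=row.vh_pair, dna_key=dna)
        sample = out.setdefault(row.sample_id, SampleCounts(sample_id=row.sample_id))
        sample.counts[key] = sample.counts.get(key, 0) + int(row.reads)
    return out
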