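"""Read quality filtering and collapsing to unique sequences.

A raw small-RNA read is *qualified* when every base among the first 25
nucleotides from its 5' end (or all bases, for shorter reads) has a Phred
quality of 30 or higher. Qualified reads longer than 18 nt are collapsed to
unique sequences with exact multiplicities; those counts drive every
downstream stage. Reads are assumed adapter-trimmed; no quality trimming is
performed — a read is kept whole or discarded.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DEFAULT_Q_MIN = 30
DEFAULT_WINDOW = 25
DEFAULT_MIN_LEN = 19  # "more than 18 nucleotides"


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores, already +33-decoded

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise PreprocessError(
                f"read {self.id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass(frozen=True)
class UniqueRead:
    sequence: str
    count: int
    sample_id: str = ""


@dataclass
class QCStats:
    sample_id: str = ""
    raw: int = 0
    qualified: int = 0
    long_enough: int = 0  # qualified and >= min_len
    unique: int = 0


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a (possibly gzipped) Phred+33 FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(
                id=title.split()[0],
                sequence=seq.upper().replace("U", "T"),
                qualities=tuple(ord(c) - 33 for c in qual),
            )


def qualify_reads(
    reads: Iterable[RawRead],
    q_min: int = DEFAULT_Q_MIN,
    window: int = DEFAULT_WINDOW,
    stats: QCStats | None = None,
) -> Iterator[RawRead]:
    """Yield reads whose first ``min(window, len)`` bases all have Q >= q_min."""
    for read in reads:
        if stats is not None:
            stats.raw += 1
        span = min(window, len(read.qualities))
        if all(q >= q_min for q in read.qualities[:span]):
            if stats is not None:
                stats.qualified += 1
            yield read


def collapse_unique(
    reads: Iterable[RawRead],
    min_len: int = DEFAULT_MIN_LEN,
    sample_id: str = "",
    stats: QCStats | None = None,
) -> list[UniqueRead]:
    """Collapse qualified reads to unique sequences with multiplicities.

    Sequences shorter than ``min_len`` are dropped. Output is sorted by
    descending count, then lexicographically by sequence.
    """
    counts: dict[str, int] = {}
    n = 0
    for read in reads:
        if len(read.sequence) < min_len:
            continue
        n += 1
        counts[read.sequence] = counts.get(read.sequence, 0) + 1
    if n == 0:
        logger.warning("collapse_unique: no reads of length >= %d (%s)", min_len, sample_id)
    out = [
        UniqueRead(sequence=s, count=c, sample_id=sample_id)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    if stats is not None:
        stats.long_enough = n
        stats.unique = len(out)
    return out


def preprocess_fastq(
    path: str | Path,
    sample_id: str | None = None,
    q_min: int = DEFAULT_Q_MIN,
    window: int = DEFAULT_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[list[UniqueRead], QCStats]:
    """FASTQ file -> (collapsed unique reads, QC summary)."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".fastq").removesuffix(".fq")
    stats = QCStats(sample_id=sample_id)
    qualified = qualify_reads(read_fastq(path), q_min=q_min, window=window, stats=stats)
    unique = collapse_unique(qualified, min_len=min_len, sample_id=sample_id, stats=stats)
    return unique, stats


def write_collapsed_fasta(unique: Iterable[UniqueRead], path: str | Path) -> None:
    """Interchange format: one record per unique sequence, ``>seq<i>_x<count>``."""
    with open(path, "w") as fh:
        for i, u in enumerate(unique, 1):
            fh.write(f">seq{i}_x{u.count}\n{u.sequence}\n")


def read_collapsed_fasta(path: str | Path, sample_id: str = "") -> list[UniqueRead]:
    out: list[UniqueRead] = []
    name = None
    seq_parts: list[str] = []

    def flush() -> None:
        if name is None:
            return
        try:
            count = int(name.rsplit("_x", 1)[1])
        except (IndexError, ValueError):
            raise PreprocessError(f"collapsed-FASTA header {name!r} lacks _x<count>")
        out.append(
            UniqueRead(sequence="".join(seq_parts), count=count, sample_id=sample_id)
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                seq_parts = []
            elif line:
                seq_parts.append(line.upper().replace("U", "T"))
        flush()
    return out


def write_qc_summary(stats_list: Iterable[QCStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\traw\tqualified\tlong_enough\tunique\n")
        for s in stats_list:
            fh.write(f"{s.sample_id}\t{s.raw}\t{s.qualified}\t{s.long_enough}\t{s.unique}\n")
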