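"""Alignment of unique reads to pre-miRNA hairpins.

Each read is decomposed, at every admissible start offset on a precursor,
into a *templated body* (at most one internal mismatch) followed by a short
*non-templated 3' tail* (at most three bases) that either mismatches the
precursor continuation at its first base or overhangs the precursor 3' end.
Among decompositions at one offset the longest body wins, so templated
explanations always beat tail explanations.

Reads mapping to several loci are down-weighted by an iterative
expression-proportional reallocation: a read's weight at a locus is the
locus's weighted expression divided by the summed expression of all the
read's loci, iterated to a fixed point. This is a simplified stand-in for
published cross-mapping correction schemes and is labeled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .preprocess import UniqueRead
from .reference_io import PreMiRNA

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 1
DEFAULT_MAX_TAIL = 3
_SEED_LEN = 8  # pigeonhole: body >= 16 nt with <= 1 mismatch -> one exact 8-mer


@dataclass(frozen=True)
class PrecursorAlignment:
    """One read placed on one precursor locus."""

    sequence: str
    count: int
    precursor: str
    start: int  # 1-based position of the read's 5' end on the precursor
    body_len: int
    mismatches: tuple[tuple[int, str, str], ...]  # (precursor pos, ref, read nt)
    tail: str
    weight: float = 1.0

    @property
    def body_end(self) -> int:
        return self.start + self.body_len - 1


def _try_offset(
    read: str,
    precursor_seq: str,
    start: int,
    max_mismatch: int,
    max_tail: int,
) -> PrecursorAlignment | None:
    """Best (longest-body) decomposition of ``read`` at 1-based ``start``."""
    plen = len(precursor_seq)
    rlen = len(read)
    max_body = min(rlen, plen - start + 1)
    for body_len in range(max_body, max(rlen - max_tail, 1) - 1, -1):
        mism: list[tuple[int, str, str]] = []
        ok = True
        for i in range(body_len):
            ref = precursor_seq[start - 1 + i]
            obs = read[i]
            if obs != ref:
                mism.append((start + i, ref, obs))
                if len(mism) > max_mismatch:
                    ok = False
                    break
        if not ok:
            continue
        tail = read[body_len:]
        if tail:
            # a mismatch adjacent to the tail belongs to the tail: the body
            # may not end in a mismatch when a tail follows
            if mism and mism[-1][0] == start + body_len - 1:
                continue
            tail_pos = start + body_len  # precursor position of the first tail base
            if tail_pos <= plen and precursor_seq[tail_pos - 1] == tail[0]:
                # first tail base is templated: a longer body already failed on
                # mismatches, so this split only hides a body mismatch — reject
                continue
        return PrecursorAlignment(
            sequence=read,
            count=0,
            precursor="",
            start=start,
            body_len=body_len,
            mismatches=tuple(mism),
            tail=tail,
        )
    return None


def align_read(
    read: str,
    precursor: PreMiRNA | tuple[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> list[PrecursorAlignment]:
    """All admissible alignments of one read sequence to one precursor."""
    if isinstance(precursor, PreMiRNA):
        name, seq = precursor.name, precursor.sequence
    else:
        name, seq = precursor
    out: list[PrecursorAlignment] = []
    # every start where at least min body length fits
    min_body = max(len(read) - max_tail, 1)
    for start in range(1, len(seq) - min_body + 2):
        aln = _try_offset(read, seq, start, max_mismatch, max_tail)
        if aln is not None:
            out.append(replace(aln, precursor=name))
    return out


class PrecursorIndex:
    """Seed-and-verify index over a precursor set.

    With a body of >= 2 * seed length and at most one internal mismatch, one
    of the read's first two non-overlapping seed-length words is an exact
    match, so exact k-mer lookup enumerates every candidate offset.
    """

    def __init__(self, precursors: Sequence[PreMiRNA]):
        self.precursors = list(precursors)
        self._kmers: dict[str, list[tuple[int, int]]] = {}
        for pi, p in enumerate(self.precursors):
            s = p.sequence
            for i in range(len(s) - _SEED_LEN + 1):
                self._kmers.setdefault(s[i : i + _SEED_LEN], []).append((pi, i + 1))

    def align(
        self,
        read: str,
        max_mismatch: int = DEFAULT_MAX_MISMATCH,
        max_tail: int = DEFAULT_MAX_TAIL,
    ) -> list[PrecursorAlignment]:
        candidates: set[tuple[int, int]] = set()
        for word_start in (0, _SEED_LEN):
            word = read[word_start : word_start + _SEED_LEN]
            if len(word) < _SEED_LEN:
                continue
            for pi, kpos in self._kmers.get(word, ()):
                start = kpos - word_start
                if start >= 1:
                    candidates.add((pi, start))
        out: list[PrecursorAlignment] = []
        for pi, start in sorted(candidates):
            p = self.precursors[pi]
            aln = _try_offset(read, p.sequence, start, max_mismatch, max_tail)
            if aln is not None:
                out.append(replace(aln, precursor=p.name))
        return out


def align_sample(
    unique_reads: Iterable[UniqueRead],
    precursors: Sequence[PreMiRNA] | PrecursorIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> tuple[list[PrecursorAlignment], int]:
    """Align every unique read; returns (alignments, unmapped-read count)."""
    index = (
        precursors
        if isinstance(precursors, PrecursorIndex)
        else PrecursorIndex(precursors)
    )
    alignments: list[PrecursorAlignment] = []
    unmapped = 0
    for u in unique_reads:
        hits = index.align(u.sequence, max_mismatch=max_mismatch, max_tail=max_tail)
        if not hits:
            unmapped += 1
            continue
        alignments.extend(replace(h, count=u.count) for h in hits)
    return alignments, unmapped


def cross_mapping_weights(
    alignments: Sequence[PrecursorAlignment],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[PrecursorAlignment]:
    """Assign multi-mapping weights by expression-proportional reallocation.

    Weights start uniform over each read's loci; precursor expression is the
    weighted sum of read counts; each read's weights are then re-split in
    proportion to its loci's expressions, until the largest weight change
    falls below ``tol``. Single-locus reads keep weight 1.
    """
    groups: dict[str, list[int]] = {}
    for i, a in enumerate(alignments):
        groups.setdefault(a.sequence, []).append(i)
    weights = [0.0] * len(alignments)
    for idxs in groups.values():
        w0 = 1.0 / len(idxs)
        for i in idxs:
            weights[i] = w0
    multi = [idxs for idxs in groups.values() if len(idxs) > 1]
    if multi:
        for _ in range(max_iter):
            expr: dict[str, float] = {}
            for i, a in enumerate(alignments):
                expr[a.precursor] = expr.get(a.precursor, 0.0) + a.count * weights[i]
            delta = 0.0
            for idxs in multi:
                total = sum(expr[alignments[i].precursor] for i in idxs)
                if total <= 0.0:
                    logger.warning(
                        "cross_mapping_weights: zero expression at all loci of a "
                        "read; reverting to uniform weights"
                    )
                    new = [1.0 / len(idxs)] * len(idxs)
                else:
                    new = [expr[alignments[i].precursor] / total for i in idxs]
                for i, w in zip(idxs, new):
                    delta = max(delta, abs(w - weights[i]))
                    weights[i] = w
            if delta < tol:
                break
    return [replace(a, weight=w) for a, w in zip(alignments, weights)]


def write_alignment_tsv(alignments: Iterable[PrecursorAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tcount\tprecursor\tstart\tbody_len\tmismatches\ttail\tweight\n")
        for a in alignments:
            mm = ";".join(f"{p}:{r}>{o}" for p, r, o in a.mismatches)
            fh.write(
                f"{a.sequence}\t{a.count}\t{a.precursor}\t{a.start}\t{a.body_len}\t"
                f"{mm}\t{a.tail}\t{a.weight:.6f}\n"
            )
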