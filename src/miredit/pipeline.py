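"""End-to-end orchestration: reads -> site calls -> cohort matrix.

Ties the stages together for one cell (`process_cell`) and a cohort
(`run_cohort`): quality filtering, collapsing, precursor alignment,
cross-mapping weighting, pileups, site calling, and — once all cells are
called — cohort-context classification (the SNP rule needs the maximum
editing level across samples) and matrix assembly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import preprocess as pp
from .cohort_patterns import EditingMatrix, combine_samples
from .precursor_align import PrecursorIndex, align_sample, cross_mapping_weights
from .reference_io import PreMiRNA, SiteKey, SNPRecord
from .site_calling import (
    SampleProfile,
    build_pileups,
    call_sites,
    classify_profile,
)


def process_cell(
    reads: Iterable[pp.RawRead] | Mapping[str, int],
    index: PrecursorIndex,
    sample_id: str,
    cell_type: str = "",
    q_min: int = pp.DEFAULT_Q_MIN,
    min_len: int = pp.DEFAULT_MIN_LEN,
    error_rate: float = 1e-3,
) -> SampleProfile:
    """Call M/E sites for one cell.

    ``reads`` is either a stream of raw reads (quality-filtered here) or an
    already-collapsed ``{sequence: count}`` mapping.
    """
    stats = pp.QCStats(sample_id=sample_id)
    if isinstance(reads, Mapping):
        unique = [
            pp.UniqueRead(sequence=s, count=n, sample_id=sample_id)
            for s, n in sorted(reads.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(s) >= min_len
        ]
        stats.qualified = stats.raw = sum(n for _s, n in reads.items())
        stats.long_enough = sum(u.count for u in unique)
    else:
        qualified = pp.qualify_reads(reads, q_min=q_min, stats=stats)
        unique = pp.collapse_unique(
            qualified, min_len=min_len, sample_id=sample_id, stats=stats
        )
    alignments, _unmapped = align_sample(unique, index)
    weighted = cross_mapping_weights(alignments)
    precursors = {p.name: p for p in index.precursors}
    pileups = build_pileups(weighted, precursors)
    calls = call_sites(pileups, e=error_rate)
    coverage = {
        (prec, pos): pileup.coverage
        for prec, d in pileups.items()
        for pos, pileup in d.items()
    }
    return SampleProfile(
        sample_id=sample_id,
        cell_type=cell_type,
        calls=calls,
        coverage=coverage,
        total_qualified_reads=stats.qualified,
    )


def cohort_max_levels(profiles: Sequence[SampleProfile]) -> dict[SiteKey, float]:
    out: dict[SiteKey, float] = {}
    for p in profiles:
        for c in p.calls:
            if c.level > out.get(c.key, 0.0):
                out[c.key] = c.level
    return out


def run_cohort(
    cells: Sequence[tuple[str, str, Iterable[pp.RawRead] | Mapping[str, int]]],
    precursors: Sequence[PreMiRNA],
    snp_catalog: Sequence[SNPRecord] = (),
    min_prevalence: float = 0.05,
    error_rate: float = 1e-3,
) -> tuple[list[SampleProfile], EditingMatrix]:
    """Process every (sample_id, cell_type, reads) cell and combine.

    Classification runs after all cells are called, so the SNP rule can see
    the cohort-wide maximum level of each site.
    """
    index = PrecursorIndex(precursors)
    profiles = [
        process_cell(reads, index, sample_id, cell_type, error_rate=error_rate)
        for sample_id, cell_type, reads in cells
    ]
    max_levels = cohort_max_levels(profiles)
    prec_map = {p.name: p for p in precursors}
    profiles = [
        classify_profile(p, prec_map, snp_catalog, max_levels) for p in profiles
    ]
    matrix = combine_samples(profiles, min_prevalence=min_prevalence)
    return profiles, matrix


def run_cohort_fastq(
    fastq_paths: Mapping[str, str | Path],
    cell_types: Mapping[str, str],
    precursors: Sequence[PreMiRNA],
    snp_catalog: Sequence[SNPRecord] = (),
    min_prevalence: float = 0.05,
    error_rate: float = 1e-3,
) -> tuple[list[SampleProfile], EditingMatrix]:
    """Like :func:`run_cohort`, reading each cell's reads from a FASTQ file."""
    cells = [
        (sid, cell_types.get(sid, ""), pp.read_fastq(path))
        for sid, path in sorted(fastq_paths.items())
    ]
    return run_cohort(
        cells,
        precursors,
        snp_catalog,
        min_prevalence=min_prevalence,
        error_rate=error_rate,
    )
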