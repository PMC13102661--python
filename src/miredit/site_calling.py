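"""Per-cell mutation/editing (M/E) site calling from weighted alignments.

Pileups accumulate, per precursor position, cross-mapping-weighted counts of
every observed nucleotide: body matches feed the templated reference,
body mismatches feed their alternative nucleotide, and tail base *j* of a
read whose body ends at position *e* feeds position *e + j* (tail bases past
the precursor's last base are tallied separately and are never callable,
since a site name requires a templated reference nucleotide).

A candidate site (position, alternative) is *significant* when

* its relative editing level — weighted alternative count over weighted
  coverage — is at least 5%,
* at least 10 raw reads support the event,
* its Benjamini-Hochberg-adjusted binomial p-value is below 0.05, where the
  null is that alternative reads arise from sequencing error at rate
  ``e = 10^(-Q/10)`` with Q the read-score threshold of 30 (e = 0.001).

Each significant site is classified into one of nine types: A-to-I, C-to-U,
3'-A, 3'-U, 3'-Other, 5'-editing, Other, SNP, Pseudo.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .precursor_align import PrecursorAlignment
from .reference_io import (
    MatureAnnotation,
    PreMiRNA,
    SiteKey,
    SNPRecord,
    format_site_name,
    revcomp,
)

logger = logging.getLogger(__name__)

DEFAULT_ERROR_RATE = 1e-3  # 10^(-30/10), from the Q30 read-score threshold
DEFAULT_MIN_LEVEL = 0.05
DEFAULT_MIN_SUPPORT = 10
DEFAULT_ALPHA = 0.05
PSEUDO_WEIGHT_THRESHOLD = 0.5

SITE_TYPES = (
    "A-to-I",
    "C-to-U",
    "3'-A",
    "3'-U",
    "3'-Other",
    "5'-editing",
    "Other",
    "SNP",
    "Pseudo",
)


class SiteCallingError(ValueError):
    pass


@dataclass
class _AltEvidence:
    weighted: float = 0.0
    raw: int = 0
    weight_sum: float = 0.0  # for the mean cross-mapping weight of supports
    arm_votes: Counter = field(default_factory=Counter)
    from_tail: int = 0  # raw supports contributed by tail bases


@dataclass
class PositionPileup:
    precursor: str
    position: int
    ref: str
    weighted: Counter = field(default_factory=Counter)  # nt -> weighted count
    raw: Counter = field(default_factory=Counter)  # nt -> raw read count
    alt_evidence: dict[str, _AltEvidence] = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        return sum(self.weighted.values())

    @property
    def raw_coverage(self) -> int:
        return sum(self.raw.values())


def _overlap_arm(
    matures: Sequence[MatureAnnotation], start: int, end: int
) -> str | None:
    """Arm whose interval overlaps [start, end] the most (read attribution)."""
    best, best_ov = None, 0
    for m in matures:
        ov = min(end, m.end) - max(start, m.start) + 1
        if ov > best_ov:
            best, best_ov = m.arm, ov
    return best


def build_pileups(
    alignments: Iterable[PrecursorAlignment],
    precursors: Mapping[str, PreMiRNA],
) -> dict[str, dict[int, PositionPileup]]:
    """Aggregate weighted alignments into per-precursor, per-position pileups."""
    pileups: dict[str, dict[int, PositionPileup]] = {}
    overhang: Counter = Counter()  # (precursor, relative pos past end) -> raw count

    def get(prec: PreMiRNA, pos: int) -> PositionPileup:
        d = pileups.setdefault(prec.name, {})
        if pos not in d:
            d[pos] = PositionPileup(
                precursor=prec.name, position=pos, ref=prec.sequence[pos - 1]
            )
        return d[pos]

    for a in alignments:
        prec = precursors[a.precursor]
        w = a.count * a.weight
        arm = _overlap_arm(prec.matures, a.start, a.body_end)
        mism = {pos: obs for pos, _ref, obs in a.mismatches}
        for i in range(a.body_len):
            pos = a.start + i
            pp = get(prec, pos)
            nt = mism.get(pos, pp.ref)
            pp.weighted[nt] += w
            pp.raw[nt] += a.count
            if nt != pp.ref:
                ev = pp.alt_evidence.setdefault(nt, _AltEvidence())
                ev.weighted += w
                ev.raw += a.count
                ev.weight_sum += a.weight * a.count
                if arm:
                    ev.arm_votes[arm] += a.count
        for j, nt in enumerate(a.tail, start=1):
            pos = a.body_end + j
            if pos > len(prec.sequence):
                overhang[(prec.name, pos - len(prec.sequence))] += a.count
                continue
            pp = get(prec, pos)
            pp.weighted[nt] += w
            pp.raw[nt] += a.count
            if nt != pp.ref:
                ev = pp.alt_evidence.setdefault(nt, _AltEvidence())
                ev.weighted += w
                ev.raw += a.count
                ev.weight_sum += a.weight * a.count
                ev.from_tail += a.count
                if arm:
                    ev.arm_votes[arm] += a.count
    if overhang:
        logger.debug(
            "build_pileups: %d raw tail bases past precursor ends (not callable)",
            sum(overhang.values()),
        )
    return pileups


def editing_level(pileup: PositionPileup, alt: str) -> float:
    """Weighted alternative count over total weighted coverage."""
    n = pileup.coverage
    if n <= 0:
        raise SiteCallingError("editing level undefined at zero coverage")
    return pileup.weighted.get(alt, 0.0) / n


def binomial_site_pvalue(
    k_int: int, n_int: int, e: float = DEFAULT_ERROR_RATE
) -> float:
    """P(X >= k) for X ~ Binomial(n, e): error-only null for a site's support."""
    if not (0 <= k_int <= n_int):
        raise SiteCallingError("require 0 <= k <= n")
    if not (0.0 < e < 1.0):
        raise SiteCallingError("error rate must lie in (0, 1)")
    if k_int == 0:
        return 1.0
    return float(binom.sf(k_int - 1, n_int, e))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = list(pvalues)
    if not pvals:
        return []
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise SiteCallingError(f"p-value {p} outside [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


@dataclass(frozen=True)
class SiteCall:
    key: SiteKey
    level: float
    k: float  # weighted edited support
    n: float  # weighted coverage
    raw_support: int
    raw_coverage: int
    p: float
    p_adj: float
    significant: bool
    mean_weight: float
    arm: str | None  # arm attributed from supporting reads
    tail_fraction: float  # share of raw support contributed by tail bases
    type: str = "Other"

    @property
    def name(self) -> str:
        return format_site_name(self.key)


@dataclass
class SampleProfile:
    sample_id: str
    cell_type: str = ""
    calls: list[SiteCall] = field(default_factory=list)
    coverage: dict[tuple[str, int], float] = field(default_factory=dict)
    total_qualified_reads: int = 0

    def significant_calls(self) -> list[SiteCall]:
        return [c for c in self.calls if c.significant]


def call_sites(
    pileups: dict[str, dict[int, PositionPileup]],
    e: float = DEFAULT_ERROR_RATE,
    min_level: float = DEFAULT_MIN_LEVEL,
    min_support: int = DEFAULT_MIN_SUPPORT,
    alpha: float = DEFAULT_ALPHA,
) -> list[SiteCall]:
    """Evaluate every candidate (position, alternative) in one sample.

    All candidates are emitted with their significance flag; the BH
    adjustment runs across all candidates of the sample. The editing level
    uses cross-mapping-weighted counts while the >= ``min_support`` rule uses
    raw integer read counts (conservative reading of "at least 10 reads").
    """
    candidates: list[tuple[PositionPileup, str, _AltEvidence]] = []
    for prec in sorted(pileups):
        for pos in sorted(pileups[prec]):
            pp = pileups[prec][pos]
            for alt in sorted(pp.alt_evidence):
                if pp.alt_evidence[alt].raw >= 1:
                    candidates.append((pp, alt, pp.alt_evidence[alt]))
    if candidates:
        import numpy as np

        ks = np.array([ev.raw for _pp, _alt, ev in candidates])
        ns = np.array([pp.raw_coverage for pp, _alt, _ev in candidates])
        pvals = np.minimum(binom.sf(ks - 1, ns, e), 1.0).tolist()
    else:
        pvals = []
    padj = bh_adjust(pvals)
    calls: list[SiteCall] = []
    for (pp, alt, ev), p, pa in zip(candidates, pvals, padj):
        level = editing_level(pp, alt)
        significant = level >= min_level and ev.raw >= min_support and pa < alpha
        arm = None
        if ev.arm_votes:
            arm = ev.arm_votes.most_common(1)[0][0]
        calls.append(
            SiteCall(
                key=SiteKey(precursor=pp.precursor, position=pp.position, ref=pp.ref, alt=alt),
                level=level,
                k=ev.weighted,
                n=pp.coverage,
                raw_support=ev.raw,
                raw_coverage=pp.raw_coverage,
                p=p,
                p_adj=pa,
                significant=significant,
                mean_weight=ev.weight_sum / ev.raw if ev.raw else 1.0,
                arm=arm,
                tail_fraction=ev.from_tail / ev.raw if ev.raw else 0.0,
            )
        )
    return calls


def _matches_snp(
    key: SiteKey, prec: PreMiRNA, snp_catalog: Sequence[SNPRecord]
) -> bool:
    gpos = prec.genomic_position(key.position)
    ref, alt = key.ref, key.alt
    if prec.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    return any(
        s.chrom == prec.chrom and s.position == gpos and s.ref == ref and s.alt == alt
        for s in snp_catalog
    )


def classify_site(
    call: SiteCall,
    prec: PreMiRNA,
    snp_catalog: Sequence[SNPRecord] = (),
    cohort_max_level: Mapping[SiteKey, float] | None = None,
) -> str:
    """Assign one of the nine M/E types to a called site.

    Decision order: SNP (catalog position/allele match and a 100% editing
    level in at least one cohort sample), Pseudo (mean cross-mapping weight
    of supporting reads < 0.5), then position relative to the mature arm the
    supporting reads overlap — past its 3' end gives 3'-A / 3'-U / 3'-Other
    keyed by the added nucleotide, before its 5' start gives 5'-editing, and
    within the mature body A>G is A-to-I, C>T is C-to-U, anything else Other.
    """
    key = call.key
    if snp_catalog and _matches_snp(key, prec, snp_catalog):
        max_level = call.level
        if cohort_max_level is not None:
            max_level = max(max_level, cohort_max_level.get(key, 0.0))
        if max_level >= 1.0 - 1e-9:
            return "SNP"
    if call.mean_weight < PSEUDO_WEIGHT_THRESHOLD:
        return "Pseudo"
    if not prec.matures:
        logger.warning(
            "classify_site: %s has no mature annotation; treating whole "
            "precursor as mature body",
            prec.name,
        )
        arm_interval = (1, len(prec.sequence))
    else:
        by_arm = {m.arm: m for m in prec.matures}
        mature = by_arm.get(call.arm) if call.arm else None
        if mature is None:
            # no read-overlap attribution: nearest arm whose 3' end precedes
            # the site; sites between arms default to the upstream arm
            upstream = [m for m in prec.matures if m.end < key.position]
            mature = upstream[-1] if upstream else prec.matures[0]
        arm_interval = (mature.start, mature.end)
    start, end = arm_interval
    if key.position > end:
        return {"A": "3'-A", "T": "3'-U"}.get(key.alt, "3'-Other")
    if key.position < start:
        return "5'-editing"
    if key.ref == "A" and key.alt == "G":
        return "A-to-I"
    if key.ref == "C" and key.alt == "T":
        return "C-to-U"
    return "Other"


def classify_profile(
    profile: SampleProfile,
    precursors: Mapping[str, PreMiRNA],
    snp_catalog: Sequence[SNPRecord] = (),
    cohort_max_level: Mapping[SiteKey, float] | None = None,
) -> SampleProfile:
    """Return a copy of the profile with every call typed."""
    typed = [
        replace(
            c,
            type=classify_site(
                c, precursors[c.key.precursor], snp_catalog, cohort_max_level
            ),
        )
        for c in profile.calls
    ]
    return SampleProfile(
        sample_id=profile.sample_id,
        cell_type=profile.cell_type,
        calls=typed,
        coverage=profile.coverage,
        total_qualified_reads=profile.total_qualified_reads,
    )


def tptm(count: float, total_qualified_reads: int) -> float:
    """Tags Per Ten Million sequencing reads."""
    if total_qualified_reads <= 0:
        raise SiteCallingError("TPTM undefined for non-positive read totals")
    return count / total_qualified_reads * 1e7


def write_site_tsv(profile: SampleProfile, path) -> None:
    """Per-sample site table, deterministically ordered (precursor, pos, alt)."""
    rows = sorted(profile.calls, key=lambda c: (c.key.precursor, c.key.position, c.key.alt))
    with open(path, "w") as fh:
        fh.write("name\ttype\tlevel\tsupport\tcoverage\tp\tp_adj\tsignificant\n")
        for c in rows:
            fh.write(
                f"{c.name}\t{c.type}\t{c.level:.6f}\t{c.raw_support}\t"
                f"{c.raw_coverage}\t{c.p:.6g}\t{c.p_adj:.6g}\t"
                f"{int(c.significant)}\n"
            )
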