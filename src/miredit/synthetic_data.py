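"""Synthetic single-cell small-RNA cohort generator with planted ground truth.

Generates a complete toy study: hairpin precursors with annotated 5p/3p arms
on a toy genome, per-cell reads with planted mutation/editing events,
cell-type structure, and enzyme expression coupled to 3' addition levels —
plus truth tables, so every pipeline stage is testable without downloads.

Planting model
--------------
Per cell, each precursor's read count is drawn from a negative binomial
(configurable to Poisson) and split evenly between the two arms. A read is a
copy of its mature arm; planted events modify it independently per read:

* central events (seed or mid-arm) substitute the site's alternative
  nucleotide with probability equal to the cell's true editing level, drawn
  per (site, cell) from a Beta distribution matched to the cell type's mean
  and variance-tier standard deviation (degenerate means are constants),
* 3' events: each arm read covers the position one past the arm's 3' end
  with probability ``p_cover3``; a covering read carries the added
  (non-templated) nucleotide with probability equal to the level, otherwise
  the templated continuation — so the measured level at the position equals
  the planted level in expectation,
* 5' events mirror this with a one-base templated 5' extension,
* enzyme-coupled sites take their per-cell level from the cell's (z-scored)
  expression of the coupled enzyme: ``level = clip(intercept + slope * z +
  noise)``,
* a cross-mapping decoy pair plants a Pseudo site: a highly expressed decoy
  precursor shares a target precursor's 5p arm up to one substitution, so
  decoy reads call an apparent site on the target whose supporting reads
  carry low cross-mapping weight.

Uniform sequencing errors at rate ``e`` are applied per base (at most one
per read; multi-error reads are negligible at e = 0.001). All quality
strings satisfy the Q30-over-first-25 filter except an optional contaminated
fraction of extra junk reads, which carry one low-quality base.

Everything is bit-reproducible from ``config.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_io import (
    DNA,
    MatureAnnotation,
    PreMiRNA,
    SiteKey,
    SNPRecord,
    format_site_name,
)

QUAL_GOOD = "I"  # Phred 40
QUAL_BAD = "#"  # Phred 2


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSpec:
    """One planted site: where it sits and how its level varies by type."""

    precursor: int  # index into the generated precursor list
    arm: str  # "5p" | "3p"
    region: str  # "seed" | "central" | "3prime" | "5prime"
    alt: str  # DNA alphabet
    mean: float | Mapping[str, float]
    std: float | Mapping[str, float]
    label: str  # intended classification
    ref: str | None = None  # forced templated base (None: derived from label)
    coupled_enzyme: str | None = None

    def mean_for(self, cell_type: str) -> float:
        return self.mean[cell_type] if isinstance(self.mean, Mapping) else self.mean

    def std_for(self, cell_type: str) -> float:
        return self.std[cell_type] if isinstance(self.std, Mapping) else self.std


@dataclass(frozen=True)
class EnzymeCoupling:
    enzyme: str
    site_index: int  # index into config.sites
    intercept: float
    slope: float
    noise_sd: float


@dataclass
class SimConfig:
    seed: int = 0
    n_precursors: int = 20
    precursor_len: tuple[int, int] = (70, 90)
    arm_len: int = 22
    cell_types: dict[str, int] = field(
        default_factory=lambda: {
            "GBM": 20, "HEK293FT": 20, "Leuk": 20, "nESC": 20, "pESC": 20
        }
    )
    sites: list[SiteSpec] = field(default_factory=list)
    couplings: list[EnzymeCoupling] = field(default_factory=list)
    enzymes: tuple[str, ...] = (
        "TENT2", "TENT4A", "TENT4B", "TENT5A", "TENT5B",
        "TENT5C", "TENT5D", "TUT1", "TUT4", "TUT7",
    )
    coverage_mean: float = 150.0
    coverage_dispersion: float = 5.0  # negative-binomial size; None -> Poisson
    coverage_model: str = "nb"  # "nb" | "poisson"
    error_rate: float = 1e-3
    low_q_fraction: float = 0.02  # extra junk reads failing the Q30 filter
    p_cover3: float = 0.5  # chance an arm read covers the 3'-site position
    p_cover5: float = 0.5
    decoy: bool = True  # plant the cross-mapping decoy pair (Pseudo site)
    decoy_target: int = 0  # precursor index carrying the Pseudo site
    decoy_coverage_factor: float = 5.0
    collapsed: bool = False  # emit collapsed counts instead of raw reads

    def __post_init__(self) -> None:
        if self.coverage_mean <= 0:
            raise SimConfigError("coverage mean must be positive")
        if 2 * self.arm_len + 6 > self.precursor_len[0]:
            raise SimConfigError("arm lengths exceed the shortest precursor")
        for s in self.sites:
            for ct in self.cell_types:
                m, sd = s.mean_for(ct), s.std_for(ct)
                if not 0.0 <= m <= 1.0:
                    raise SimConfigError(f"site mean {m} outside [0,1]")
                if sd > 0 and 0.0 < m < 1.0 and sd**2 >= m * (1 - m):
                    raise SimConfigError(
                        f"site std {sd} unattainable on [0,1] at mean {m}"
                    )


_LABEL_REF = {"A-to-I": "A", "C-to-U": "C"}


@dataclass(frozen=True)
class ResolvedSite:
    spec: SiteSpec
    key: SiteKey
    arm: MatureAnnotation
    index: int  # position in config.sites

    @property
    def name(self) -> str:
        return format_site_name(self.key)


@dataclass
class SimReference:
    precursors: list[PreMiRNA]
    sites: list[ResolvedSite]
    snp_records: list[SNPRecord]
    decoy_name: str | None = None
    pseudo_site: SiteKey | None = None


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [DNA[i] for i in rng.integers(0, 4, size=n)]


def simulate_reference(config: SimConfig) -> SimReference:
    """Build precursors, arms, toy-genome loci, planted-site keys, SNP VCF rows."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lo, hi = config.precursor_len
    precursors: list[PreMiRNA] = []
    seqs: list[list[str]] = []
    arms_by_prec: list[dict[str, MatureAnnotation]] = []
    cursor = 1000
    strands = ["+", "+", "+", "-"]  # a quarter of loci on the minus strand
    for i in range(config.n_precursors):
        plen = int(rng.integers(lo, hi + 1))
        seq = _rand_seq(rng, plen)
        a5 = MatureAnnotation(name=f"sim-mir-{i + 1}-5p", start=2, end=1 + config.arm_len, arm="5p")
        a3 = MatureAnnotation(
            name=f"sim-mir-{i + 1}-3p", start=plen - 3 - config.arm_len + 1, end=plen - 3, arm="3p"
        )
        seqs.append(seq)
        arms_by_prec.append({"5p": a5, "3p": a3})
        precursors.append(
            PreMiRNA(
                name=f"sim-mir-{i + 1}",
                sequence="".join(seq),
                chrom="chrS",
                start=cursor,
                end=cursor + plen - 1,
                strand=strands[i % len(strands)],
                matures=(a5, a3),
            )
        )
        cursor += plen + 100

    resolved: list[ResolvedSite] = []
    snp_records: list[SNPRecord] = []
    for idx, spec in enumerate(config.sites):
        arm = arms_by_prec[spec.precursor][spec.arm]
        if spec.region == "seed":
            pos = arm.start + 3
        elif spec.region == "central":
            pos = arm.start + 11
        elif spec.region == "3prime":
            pos = arm.end + 1
        elif spec.region == "5prime":
            pos = arm.start - 1
        else:
            raise SimConfigError(f"unknown region {spec.region!r}")
        ref = spec.ref or _LABEL_REF.get(spec.label)
        seq = seqs[spec.precursor]
        if ref is None:
            ref = seq[pos - 1]
            if ref == spec.alt:  # templated base must differ from the variant
                ref = next(b for b in DNA if b != spec.alt)
        seq[pos - 1] = ref
        key = SiteKey(
            precursor=precursors[spec.precursor].name, position=pos, ref=ref, alt=spec.alt
        )
        resolved.append(ResolvedSite(spec=spec, key=key, arm=arm, index=idx))
        if spec.label == "SNP":
            p = precursors[spec.precursor]
            gref, galt = ref, spec.alt
            if p.strand == "-":
                from .reference_io import revcomp

                gref, galt = revcomp(gref), revcomp(galt)
            snp_records.append(
                SNPRecord(
                    chrom=p.chrom,
                    position=p.genomic_position(pos),
                    ref=gref,
                    alt=galt,
                    identifier=f"rsSIM{idx}",
                )
            )

    # forced bases may have changed sequences; rebuild the records
    precursors = [
        dataclasses.replace(p, sequence="".join(s)) for p, s in zip(precursors, seqs)
    ]

    decoy_name = None
    pseudo_site = None
    if config.decoy:
        target = precursors[config.decoy_target]
        a5 = arms_by_prec[config.decoy_target]["5p"]
        # occupied positions on the target's 5p arm must stay clear
        taken = {
            r.key.position
            for r in resolved
            if r.key.precursor == target.name
        }
        j = next(
            p
            for p in range(a5.start + 8, a5.end - 3)
            if p not in taken
        )
        target_seq = list(target.sequence)
        if target_seq[j - 1] == "G":
            target_seq[j - 1] = "A"
        target = dataclasses.replace(target, sequence="".join(target_seq))
        precursors[config.decoy_target] = target
        plen = len(target.sequence)
        decoy_seq = _rand_seq(rng, plen)
        decoy_seq[a5.start - 1 : a5.end] = list(target.sequence[a5.start - 1 : a5.end])
        decoy_seq[j - 1] = "G"  # the single substitution shared arms differ by
        decoy_name = "sim-mir-decoy"
        d5 = MatureAnnotation(name="sim-mir-decoy-5p", start=a5.start, end=a5.end, arm="5p")
        d3 = MatureAnnotation(
            name="sim-mir-decoy-3p", start=plen - 3 - config.arm_len + 1, end=plen - 3, arm="3p"
        )
        precursors.append(
            PreMiRNA(
                name=decoy_name,
                sequence="".join(decoy_seq),
                chrom="chrS",
                start=cursor,
                end=cursor + plen - 1,
                strand="+",
                matures=(d5, d3),
            )
        )
        pseudo_site = SiteKey(
            precursor=target.name, position=j, ref=target.sequence[j - 1], alt="G"
        )
    return SimReference(
        precursors=precursors,
        sites=resolved,
        snp_records=snp_records,
        decoy_name=decoy_name,
        pseudo_site=pseudo_site,
    )


def _beta_levels(
    rng: np.random.Generator, mean: float, std: float, n: int
) -> np.ndarray:
    """Per-cell levels on [0, 1] with the requested mean and std (Beta MoM)."""
    if std <= 0 or mean <= 0.0 or mean >= 1.0:
        return np.full(n, float(mean))
    nu = mean * (1 - mean) / std**2 - 1.0
    a, b = mean * nu, (1 - mean) * nu
    return rng.beta(a, b, size=n)


def simulate_enzyme_expression(
    config: SimConfig, cell_ids: Sequence[str]
) -> pd.DataFrame:
    """Log-normal enzyme expression per cell (genes x cells, TPM-like)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    data = rng.lognormal(mean=2.0, sigma=0.6, size=(len(config.enzymes), len(cell_ids)))
    return pd.DataFrame(data, index=list(config.enzymes), columns=list(cell_ids))


def _coupled_levels(
    config: SimConfig,
    expression: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Per-cell levels for enzyme-coupled sites: intercept + slope*z + noise."""
    out: dict[int, np.ndarray] = {}
    for c in config.couplings:
        e = expression.loc[c.enzyme].to_numpy(dtype=float)
        z = (e - e.mean()) / e.std() if e.std() > 0 else np.zeros_like(e)
        raw = c.intercept + c.slope * z + rng.normal(0.0, c.noise_sd, size=e.size)
        clipped = np.clip(raw, 0.0, 1.0)
        if np.mean(raw != clipped) > 0.5:
            import logging

            logging.getLogger(__name__).warning(
                "coupling %s->site %d clips >50%% of levels", c.enzyme, c.site_index
            )
        out[c.site_index] = clipped
    return out


@dataclass
class SimCell:
    sample_id: str
    cell_type: str
    reads: list[tuple[str, str]] = field(default_factory=list)  # (seq, qual)
    collapsed: dict[str, int] = field(default_factory=dict)
    n_good_reads: int = 0


@dataclass
class SimCohort:
    config: SimConfig
    reference: SimReference
    cells: list[SimCell]
    truth: pd.DataFrame  # one row per (planted site, cell)
    expression: pd.DataFrame
    true_levels: pd.DataFrame  # sites x cells planted levels


def _draw_coverage(
    rng: np.random.Generator, config: SimConfig, scale: float = 1.0
) -> int:
    """Reads for one precursor in one cell; ``scale`` > 1 models a locus that
    is constitutively more expressed (mean and NB size scale together, so the
    relative dispersion shrinks)."""
    m = config.coverage_mean * scale
    if config.coverage_model == "poisson" or not config.coverage_dispersion:
        return int(rng.poisson(m))
    size = config.coverage_dispersion * scale
    return int(rng.negative_binomial(size, size / (size + m)))


def simulate_cells(
    config: SimConfig,
    reference: SimReference,
    expression: pd.DataFrame | None = None,
) -> SimCohort:
    """Generate per-cell reads and the ground-truth tables."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    cell_ids: list[str] = []
    cell_types: list[str] = []
    for ct, n in config.cell_types.items():
        for i in range(n):
            cell_ids.append(f"{ct}_{i + 1:03d}")
            cell_types.append(ct)
    if expression is None:
        expression = simulate_enzyme_expression(config, cell_ids)
    coupled = _coupled_levels(config, expression, rng)

    # planted per-cell levels, drawn per site from the type's Beta
    n_cells = len(cell_ids)
    levels = np.zeros((len(reference.sites), n_cells))
    type_slices: dict[str, np.ndarray] = {}
    ct_arr = np.array(cell_types)
    for ct in config.cell_types:
        type_slices[ct] = np.where(ct_arr == ct)[0]
    for si, rs in enumerate(reference.sites):
        if rs.index in coupled:
            levels[si] = coupled[rs.index]
            continue
        for ct, idxs in type_slices.items():
            levels[si, idxs] = _beta_levels(
                rng, rs.spec.mean_for(ct), rs.spec.std_for(ct), idxs.size
            )

    sites_by_prec: dict[str, list[tuple[int, ResolvedSite]]] = {}
    for si, rs in enumerate(reference.sites):
        sites_by_prec.setdefault(rs.key.precursor, []).append((si, rs))

    by_name = {p.name: p for p in reference.precursors}
    regular = [p for p in reference.precursors if p.name != reference.decoy_name]

    cells: list[SimCell] = []
    truth_rows: list[dict] = []
    for ci, (cid, ct) in enumerate(zip(cell_ids, cell_types)):
        groups: dict[str, int] = {}
        site_stats: dict[int, list[int]] = {}  # si -> [n_cover, k_edit]

        def add(seq: str, n: int) -> None:
            if n > 0:
                groups[seq] = groups.get(seq, 0) + n

        for p in reference.precursors:
            scale = (
                config.decoy_coverage_factor
                if p.name == reference.decoy_name
                else 1.0
            )
            cov = _draw_coverage(rng, config, scale)
            if cov <= 0:
                continue
            n5 = int(rng.binomial(cov, 0.5))
            for arm_tag, n_arm in (("5p", n5), ("3p", cov - n5)):
                if n_arm <= 0:
                    continue
                arm = next(m for m in p.matures if m.arm == arm_tag)
                arm_seq = p.sequence[arm.start - 1 : arm.end]
                arm_sites = [
                    (si, rs)
                    for si, rs in sites_by_prec.get(p.name, [])
                    if rs.spec.arm == arm_tag
                ]
                s5 = [x for x in arm_sites if x[1].spec.region == "5prime"]
                s3 = [x for x in arm_sites if x[1].spec.region == "3prime"]
                central = [
                    x for x in arm_sites if x[1].spec.region in ("seed", "central")
                ]
                # state: list of (prefix, body chars, suffix, count)
                states = [(list(arm_seq), n_arm, "", "")]  # (body, n, pre, post)
                if s5:
                    si, rs = s5[0]
                    lam = levels[si, ci]
                    n_cov = int(rng.binomial(n_arm, config.p_cover5))
                    k = int(rng.binomial(n_cov, lam))
                    st = site_stats.setdefault(si, [0, 0])
                    st[0] += n_cov
                    st[1] += k
                    body = list(arm_seq)
                    states = [
                        (body, n_arm - n_cov, "", ""),
                        (body, n_cov - k, rs.key.ref, ""),
                        (body, k, rs.key.alt, ""),
                    ]
                for si, rs in central:
                    lam = levels[si, ci]
                    off = rs.key.position - arm.start  # 0-based within the arm
                    new_states = []
                    for body, n, pre, post in states:
                        k = int(rng.binomial(n, lam))
                        st = site_stats.setdefault(si, [0, 0])
                        st[0] += n
                        st[1] += k
                        if k:
                            edited = list(body)
                            edited[off] = rs.key.alt
                            new_states.append((edited, k, pre, post))
                        if n - k:
                            new_states.append((body, n - k, pre, post))
                    states = new_states
                if s3:
                    si, rs = s3[0]
                    lam = levels[si, ci]
                    templ = p.sequence[arm.end] if arm.end < len(p.sequence) else ""
                    new_states = []
                    for body, n, pre, post in states:
                        n_cov = int(rng.binomial(n, config.p_cover3))
                        k = int(rng.binomial(n_cov, lam))
                        st = site_stats.setdefault(si, [0, 0])
                        st[0] += n_cov
                        st[1] += k
                        new_states.append((body, n - n_cov, pre, post))
                        new_states.append((body, n_cov - k, pre, post + templ))
                        new_states.append((body, k, pre, post + rs.key.alt))
                    states = new_states
                for body, n, pre, post in states:
                    add(pre + "".join(body) + post, n)

        # sequencing errors: at most one substituted base per affected read
        seqs = list(groups)
        counts = np.array([groups[s] for s in seqs])
        lens = np.array([len(s) for s in seqs])
        total_bases = int((counts * lens).sum())
        n_err = int(rng.binomial(total_bases, config.error_rate))
        if n_err and len(seqs):
            probs = counts * lens / total_bases
            picks = rng.choice(len(seqs), size=n_err, p=probs)
            for gi in picks:
                s = seqs[gi]
                if groups.get(s, 0) <= 0:
                    continue
                pos = int(rng.integers(0, len(s)))
                alt = DNA[int(rng.integers(0, 3))]
                if alt == s[pos]:
                    alt = DNA[3]
                groups[s] -= 1
                mutated = s[:pos] + alt + s[pos + 1 :]
                groups[mutated] = groups.get(mutated, 0) + 1
        groups = {s: n for s, n in groups.items() if n > 0}

        n_good = sum(groups.values())
        cell = SimCell(sample_id=cid, cell_type=ct, n_good_reads=n_good)
        if config.collapsed:
            cell.collapsed = groups
        else:
            reads: list[tuple[str, str]] = []
            for s, n in groups.items():
                reads.extend((s, QUAL_GOOD * len(s)) for _ in range(n))
            n_junk = int(round(config.low_q_fraction * n_good))
            if n_junk and reads:
                picks = rng.integers(0, len(reads), size=n_junk)
                for ri in picks:
                    s, _q = reads[int(ri)]
                    bad = int(rng.integers(0, min(25, len(s))))
                    q = QUAL_GOOD * bad + QUAL_BAD + QUAL_GOOD * (len(s) - bad - 1)
                    reads.append((s, q))
            order = rng.permutation(len(reads))
            cell.reads = [reads[i] for i in order]
        cells.append(cell)

        for si, rs in enumerate(reference.sites):
            n_cov, k = site_stats.get(si, [0, 0])
            truth_rows.append(
                {
                    "site": rs.name,
                    "sample_id": cid,
                    "cell_type": ct,
                    "true_level": levels[si, ci],
                    "realized_coverage": n_cov,
                    "realized_support": k,
                    "site_class": rs.spec.label,
                }
            )

    truth = pd.DataFrame(truth_rows)
    true_levels = pd.DataFrame(
        levels, index=[rs.name for rs in reference.sites], columns=cell_ids
    )
    return SimCohort(
        config=config,
        reference=reference,
        cells=cells,
        truth=truth,
        expression=expression,
        true_levels=true_levels,
    )


def simulate(config: SimConfig) -> SimCohort:
    """Reference + cells + expression + truth, all from ``config.seed``."""
    reference = simulate_reference(config)
    return simulate_cells(config, reference)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study scenario: 5 cell types x 20 cells, 20 precursors,
    ~30 planted sites spanning all nine classes.

    Cell types are named after the cohort the generator emulates (GBM,
    HEK293FT, Leuk, pESC, nESC). Each type receives three exclusive 3'-addition
    sites (in-type mean 0.8, zero elsewhere); three shared sites carry the
    low/medium/high variance tiers (std 0.05 / 0.25 / 0.35 at mean 0.5);
    central A-to-I, C-to-U, Other and 5'-editing sites are shared; three 3'
    sites are coupled to TENT2 (adenine), TUT7 (uracil) and TENT4A (cytosine);
    one SNP-like site sits at level 1.0; a decoy precursor pair plants a
    Pseudo site.
    """
    types = ["GBM", "HEK293FT", "Leuk", "nESC", "pESC"]
    sites: list[SiteSpec] = []

    def per_type(hot: str, val: float) -> dict[str, float]:
        return {t: (val if t == hot else 0.0) for t in types}

    # 15 cell-type-exclusive sites (mostly 3' additions, as in real cohorts)
    spec_plan = [("3prime", "A", "3'-A"), ("3prime", "T", "3'-U"), ("central", "G", "A-to-I")]
    prec = 1  # precursor 0 is reserved for the decoy's Pseudo site
    for ti, t in enumerate(types):
        for k, (region, alt, label) in enumerate(spec_plan):
            arm = "5p" if k % 2 == 0 else "3p"
            ref = "A" if label == "A-to-I" else None
            sites.append(
                SiteSpec(
                    precursor=prec, arm=arm, region=region, alt=alt,
                    mean=per_type(t, 0.8), std=0.05, label=label, ref=ref,
                )
            )
            if k == 1:
                prec += 1
        prec += 1
    # variance-tier sites, shared across types at mean 0.5
    for std, arm in ((0.05, "5p"), (0.25, "3p"), (0.35, "5p")):
        sites.append(
            SiteSpec(
                precursor=prec, arm=arm, region="central", alt="T",
                mean=0.5, std=std, label="Other", ref="G",
            )
        )
        prec += 1 if arm == "3p" else 0
    prec += 1
    # shared central editing and a 5' event
    sites.append(SiteSpec(precursor=prec, arm="5p", region="seed", alt="G",
                          mean=0.45, std=0.1, label="A-to-I"))
    sites.append(SiteSpec(precursor=prec, arm="3p", region="central", alt="G",
                          mean=0.3, std=0.08, label="A-to-I"))
    sites.append(SiteSpec(precursor=prec + 1, arm="5p", region="central", alt="T",
                          mean=0.35, std=0.08, label="C-to-U"))
    sites.append(SiteSpec(precursor=prec + 1, arm="3p", region="5prime", alt="C",
                          mean=0.4, std=0.08, label="5'-editing", ref="A"))
    # enzyme-coupled 3' sites (levels follow expression across all cells)
    coupled_specs = [
        ("TENT2", "A", "3'-A"),
        ("TUT7", "T", "3'-U"),
        ("TENT4A", "C", "3'-Other"),
    ]
    couplings: list[EnzymeCoupling] = []
    for k, (enz, alt, label) in enumerate(coupled_specs):
        sites.append(
            SiteSpec(
                precursor=prec + 2 + k, arm="5p", region="3prime", alt=alt,
                mean=0.4, std=0.1, label=label, coupled_enzyme=enz,
            )
        )
        couplings.append(
            EnzymeCoupling(
                enzyme=enz, site_index=len(sites) - 1,
                intercept=0.4, slope=0.18, noise_sd=0.08,
            )
        )
    # SNP-like site: level 1.0 everywhere, catalog-matching
    sites.append(SiteSpec(precursor=prec + 5, arm="5p", region="central", alt="G",
                          mean=1.0, std=0.0, label="SNP", ref="A"))
    cfg = SimConfig(seed=seed, sites=sites, couplings=couplings, **overrides)
    return cfg


def simulate_level_matrix(
    seed: int,
    cell_types: Mapping[str, int],
    site_means: Mapping[str, Mapping[str, float] | float],
    site_stds: Mapping[str, Mapping[str, float] | float],
):
    """Directly simulate an editing-level matrix (no reads).

    Levels are Beta draws matched to each site's per-type mean and std, as
    in the read-level generator but skipping sequencing; useful for studying
    the cohort statistics at exactly known level distributions.
    """
    from .cohort_patterns import EditingMatrix

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    ids: list[str] = []
    labels: list[str] = []
    for ct, n in cell_types.items():
        ids.extend(f"{ct}_{i + 1:03d}" for i in range(n))
        labels.extend([ct] * n)
    labels_arr = np.array(labels)
    data = np.zeros((len(site_means), len(ids)))
    for si, site in enumerate(site_means):
        means, stds = site_means[site], site_stds[site]
        for ct in cell_types:
            m = means[ct] if isinstance(means, Mapping) else means
            s = stds[ct] if isinstance(stds, Mapping) else stds
            idxs = np.where(labels_arr == ct)[0]
            data[si, idxs] = _beta_levels(rng, m, s, idxs.size)
    levels = pd.DataFrame(data, index=list(site_means), columns=ids)
    return EditingMatrix(levels=levels, cell_types=pd.Series(labels, index=ids))


# ---------------------------------------------------------------------------
# writers

def write_reference_fasta(reference: SimReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in reference.precursors:
            fh.write(f">{p.name}\n{p.sequence}\n")


def write_reference_gff3(reference: SimReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in reference.precursors:
            fh.write(
                f"{p.chrom}\t.\tmiRNA_primary_transcript\t{p.start}\t{p.end}\t.\t"
                f"{p.strand}\t.\tID={p.name};Name={p.name}\n"
            )
            for m in p.matures:
                if p.strand == "+":
                    gs = p.start + m.start - 1
                    ge = p.start + m.end - 1
                else:
                    gs = p.end - m.end + 1
                    ge = p.end - m.start + 1
                fh.write(
                    f"{p.chrom}\t.\tmiRNA\t{gs}\t{ge}\t.\t{p.strand}\t.\t"
                    f"ID={m.name};Name={m.name};Derives_from={p.name}\n"
                )


def write_snp_vcf(reference: SimReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrS>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(reference.snp_records, key=lambda r: r.position):
            fh.write(f"{s.chrom}\t{s.position}\t{s.identifier}\t{s.ref}\t{s.alt}\t.\t.\t.\n")


def write_cell_fastq(cell: SimCell, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(cell.reads, 1):
            fh.write(f"@{cell.sample_id}_r{i}\n{seq}\n+\n{qual}\n")


def write_cohort(cohort: SimCohort, outdir: str | Path) -> None:
    """Write the full synthetic study to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference_fasta(cohort.reference, outdir / "precursors.fa")
    write_reference_gff3(cohort.reference, outdir / "precursors.gff3")
    if cohort.reference.snp_records:
        write_snp_vcf(cohort.reference, outdir / "snp_catalog.vcf")
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    rows = []
    for cell in cohort.cells:
        rows.append({"cell_id": cell.sample_id, "cell_type": cell.cell_type})
        if not cohort.config.collapsed:
            write_cell_fastq(cell, fastq_dir / f"{cell.sample_id}.fastq")
    pd.DataFrame(rows).to_csv(outdir / "cell_annotation.tsv", sep="\t", index=False)
    cohort.truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    cohort.true_levels.to_csv(outdir / "truth_levels.tsv", sep="\t", float_format="%.6f")
    cohort.expression.to_csv(outdir / "enzyme_expression.tsv", sep="\t", float_format="%.6f")
    with open(outdir / "seed.txt", "w") as fh:
        fh.write(f"{cohort.config.seed}\n")
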