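"""Correlation of terminal-nucleotidyltransferase expression with 3' editing.

For cells with both small-RNA editing profiles and gene expression, each
(enzyme, 3'-site) pair receives a Pearson correlation over shared cells with
a two-sided P from the t statistic (n - 2 degrees of freedom). A pair is
*positively significant* when r > 0 and P < 0.05; no correction is applied
across pairs by default (each pair is reported at its own per-pair P, with a
Benjamini-Hochberg option behind a flag). The mediation summary collapses
pairs into an enzyme x added-nucleotide grid of supported (Y) / not
supported (N) flags: a grid cell is supported when at least one positively
significant pair falls in it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .cohort_patterns import _pearson_with_p
from .reference_io import parse_site_name
from .site_calling import bh_adjust

logger = logging.getLogger(__name__)

#: TENT-family terminal nucleotidyltransferases considered by default.
DEFAULT_ENZYMES = (
    "TENT2",
    "TENT4A",
    "TENT4B",
    "TENT5A",
    "TENT5B",
    "TENT5C",
    "TENT5D",
    "TUT1",
    "TUT4",
    "TUT7",
)

NUCLEOTIDE_COLUMNS = ("Adenine", "Uracil", "Cytosine", "Guanine")
_ALT_TO_COLUMN = {"A": "Adenine", "T": "Uracil", "U": "Uracil", "C": "Cytosine", "G": "Guanine"}

THREE_PRIME_TYPES = ("3'-A", "3'-U", "3'-Other")


class EnzymeCorrError(ValueError):
    pass


@dataclass(frozen=True)
class EnzymeSiteCorrelation:
    enzyme: str
    site: str
    nucleotide: str  # added-nucleotide class (Adenine/Uracil/Cytosine/Guanine)
    r: float
    p: float
    n: int
    positive_significant: bool


def added_nucleotide_class(site_name: str) -> str:
    """Added-nucleotide class of a 3' site: its alternative nucleotide."""
    key = parse_site_name(site_name)
    return _ALT_TO_COLUMN[key.alt]


def correlate_enzyme_editing(
    expression: pd.DataFrame,
    editing: pd.DataFrame,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
    site_types: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[EnzymeSiteCorrelation]:
    """Pearson r and P for every (enzyme, 3'-site) pair over shared cells.

    ``expression`` is genes x cells (non-negative, e.g. TPM); ``editing`` is
    sites x cells. When ``site_types`` is given, sites are restricted to the
    3' addition types. Pairs where either vector has zero variance are
    reported with undefined (NaN) r and are never significant.
    """
    if (expression.to_numpy(dtype=float) < 0).any():
        raise EnzymeCorrError("expression values must be non-negative")
    shared = [c for c in editing.columns if c in set(expression.columns)]
    if len(shared) < 3:
        raise EnzymeCorrError(
            f"need >= 3 shared cells between expression and editing, got {len(shared)}"
        )
    sites = list(editing.index)
    if site_types is not None:
        sites = [s for s in sites if site_types.get(s) in THREE_PRIME_TYPES]
    results: list[EnzymeSiteCorrelation] = []
    for enzyme in enzymes:
        if enzyme not in expression.index:
            logger.warning("enzyme %s absent from the expression matrix; skipped", enzyme)
            continue
        e = expression.loc[enzyme, shared].to_numpy(dtype=float)
        for site in sites:
            lv = editing.loc[site, shared].astype(float).fillna(0.0).to_numpy()
            r, p = _pearson_with_p(e, lv)
            sig = bool(not math.isnan(r) and r > 0 and p < alpha)
            results.append(
                EnzymeSiteCorrelation(
                    enzyme=enzyme,
                    site=site,
                    nucleotide=added_nucleotide_class(site),
                    r=r,
                    p=p,
                    n=len(shared),
                    positive_significant=sig,
                )
            )
    if adjust:
        logger.warning(
            "BH adjustment across enzyme-site pairs enabled; the default "
            "reporting convention is per-pair P < %.2g", alpha
        )
        finite = [i for i, c in enumerate(results) if not math.isnan(c.p)]
        padj = bh_adjust([results[i].p for i in finite])
        for i, pa in zip(finite, padj):
            c = results[i]
            results[i] = replace(
                c, p=pa, positive_significant=bool(not math.isnan(c.r) and c.r > 0 and pa < alpha)
            )
    return results


@dataclass
class MediationSummary:
    grid: pd.DataFrame  # enzymes x nucleotides, "Y"/"N"
    counts: pd.DataFrame  # enzymes x nucleotides, number of supporting sites

    def supported(self, enzyme: str, nucleotide: str) -> bool:
        return self.grid.loc[enzyme, nucleotide] == "Y"


def mediation_table(
    correlations: Sequence[EnzymeSiteCorrelation],
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
) -> MediationSummary:
    """Enzyme x added-nucleotide grid of supported mediation relationships."""
    counts = pd.DataFrame(0, index=list(enzymes), columns=list(NUCLEOTIDE_COLUMNS))
    for c in correlations:
        if c.positive_significant and c.enzyme in counts.index:
            counts.loc[c.enzyme, c.nucleotide] += 1
    grid = counts.map(lambda n: "Y" if n > 0 else "N")
    return MediationSummary(grid=grid, counts=counts)


def correlations_to_frame(correlations: Sequence[EnzymeSiteCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in correlations])


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise EnzymeCorrError("duplicate gene names in expression matrix")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6f")
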