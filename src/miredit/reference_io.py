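"""Reference data I/O and the site-name codec shared by every pipeline stage.

Handles pre-miRNA hairpin FASTA, the miRBase-dialect GFF3 of precursor and
mature coordinates, a VCF-subset SNP catalog, and TSV editing matrices.

Conventions (used package-wide):

* internal alphabet is DNA (``ACGT``); RNA ``U`` is normalized to ``T`` on
  input and rendered back as ``U``/``u`` only on report output,
* all coordinates are 1-based inclusive, both precursor-local and genomic,
* a mutation/editing site is named ``<precursor>_<pos>_<REF>_<alt>`` with the
  templated nucleotide in upper case and the variant in lower case, e.g.
  ``hsa-mir-376a-1_49_A_g`` for an A-to-I event on the 49th nucleotide.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _to_rna(seq: str) -> str:
    """Render a DNA-alphabet string in RNA letters, preserving case."""
    return seq.replace("T", "U").replace("t", "u")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA located on its precursor (1-based inclusive)."""

    name: str
    start: int
    end: int
    arm: str  # "5p" | "3p"

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        if not 18 <= length <= 26:
            raise ReferenceError(
                f"mature {self.name}: length {length} outside [18, 26]"
            )
        if self.arm not in ("5p", "3p"):
            raise ReferenceError(f"mature {self.name}: arm must be 5p or 3p")

    @property
    def seed(self) -> tuple[int, int]:
        """Seed region: nucleotides 2-8 of the mature (precursor coords)."""
        return (self.start + 1, self.start + 7)


@dataclass(frozen=True)
class PreMiRNA:
    """A pre-miRNA hairpin with its genomic locus and mature arms."""

    name: str
    sequence: str  # DNA alphabet, upper case
    chrom: str
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str  # "+" | "-"
    matures: tuple[MatureAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not 40 <= n <= 200:
            raise ReferenceError(f"{self.name}: precursor length {n} outside [40, 200]")
        if self.end - self.start + 1 != n:
            raise ReferenceError(
                f"{self.name}: locus span {self.end - self.start + 1} != sequence length {n}"
            )
        if self.strand not in ("+", "-"):
            raise ReferenceError(f"{self.name}: strand must be + or -")
        if not 1 <= len(self.matures) <= 2:
            raise ReferenceError(f"{self.name}: expected 1-2 mature arms")
        for m in self.matures:
            if m.start < 1 or m.end > n:
                raise ReferenceError(
                    f"{self.name}: mature {m.name} interval ({m.start},{m.end}) "
                    f"outside precursor [1,{n}]"
                )

    def genomic_position(self, pos: int) -> int:
        """Project a 1-based precursor position onto the genome."""
        if self.strand == "+":
            return self.start + pos - 1
        return self.end - pos + 1

    def mature_sequence(self, m: MatureAnnotation) -> str:
        return self.sequence[m.start - 1 : m.end]


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    position: int  # 1-based genomic
    ref: str
    alt: str
    identifier: str = "."

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ReferenceError("SNP alleles must be single nucleotides")
        if self.ref == self.alt:
            raise ReferenceError("SNP ref and alt alleles are identical")


@dataclass(frozen=True, order=True)
class SiteKey:
    """Identity of one M/E site: precursor, position, ref>alt (DNA alphabet)."""

    precursor: str
    position: int
    ref: str  # upper-case DNA
    alt: str  # upper-case DNA internally; rendered lower-case RNA

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ReferenceError(f"site {self.precursor}:{self.position}: ref == alt")
        if self.position < 1:
            raise ReferenceError("site position must be >= 1")
        if self.ref not in DNA or self.alt not in DNA:
            raise ReferenceError("site alleles must be single DNA nucleotides")


_SITE_NAME_RE = re.compile(
    r"^(?P<prec>.+)_(?P<pos>\d+)_(?P<ref>[ACGU])_(?P<alt>[acgu])$"
)


def format_site_name(key: SiteKey) -> str:
    """``hsa-mir-376a-1_49_A_g`` — ref upper / alt lower, RNA alphabet."""
    return (
        f"{key.precursor}_{key.position}_{_to_rna(key.ref)}_{_to_rna(key.alt.lower())}"
    )


def edited_mirna_name(key: SiteKey) -> str:
    """Name of the edited miRNA itself, e.g. ``hsa-mir-376a-1_49g``.

    The precursor-qualified form is kept (copy suffixes like ``-1`` are not
    stripped) so paralogous precursors stay distinguishable.
    """
    return f"{key.precursor}_{key.position}{_to_rna(key.alt.lower())}"


def parse_site_name(name: str) -> SiteKey:
    m = _SITE_NAME_RE.match(name)
    if m is None:
        raise ReferenceError(f"cannot parse site name {name!r}")
    return SiteKey(
        precursor=m.group("prec"),
        position=int(m.group("pos")),
        ref=_to_dna(m.group("ref")),
        alt=_to_dna(m.group("alt")),
    )


def read_precursor_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read precursor hairpins; U is normalized to T, order preserved."""
    path = Path(path)
    # SeqIO silently skips junk before the first header; reject it explicitly.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ReferenceError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                )
            break
        else:
            raise ReferenceError(f"{path}: empty FASTA file")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ReferenceError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seq = _to_dna(str(rec.seq))
        if not seq:
            raise ReferenceError(f"{path}: record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise ReferenceError(f"{path}: no FASTA records found")
    return records


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ReferenceError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_mirna_gff3(
    path: str | Path, precursors: Iterable[tuple[str, str]]
) -> list[PreMiRNA]:
    """Read a miRBase-dialect GFF3 and attach matures to their precursors.

    Mature genomic coordinates are converted to precursor-local 1-based
    coordinates, strand-aware: on the minus strand,
    ``local_start = precursor_end - mature_end + 1``.
    """
    precursor_list = list(precursors)
    seq_by_name = dict(precursor_list)
    if len(seq_by_name) != len(precursor_list):
        raise ReferenceError("duplicate precursor names")
    primaries: dict[str, dict] = {}
    matures: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ReferenceError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attr = _parse_gff3_attributes(attrs)
            entry = {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "id": attr.get("ID", ""),
                "name": attr.get("Name", attr.get("ID", "")),
                "derives_from": attr.get("Derives_from"),
                "lineno": lineno,
            }
            if ftype == "miRNA_primary_transcript":
                primaries[entry["id"]] = entry
                primaries.setdefault(entry["name"], entry)
            elif ftype == "miRNA":
                matures.append(entry)
    out: dict[str, PreMiRNA] = {}
    mature_lists: dict[str, list[MatureAnnotation]] = {}
    for m in matures:
        parent_key = m["derives_from"]
        if parent_key is None or parent_key not in primaries:
            raise ReferenceError(
                f"{path}: line {m['lineno']}: mature {m['name']!r} has unknown "
                f"Derives_from {parent_key!r}"
            )
        p = primaries[parent_key]
        if p["name"] not in seq_by_name:
            raise ReferenceError(
                f"{path}: precursor {p['name']!r} not present in the FASTA"
            )
        if m["start"] < p["start"] or m["end"] > p["end"]:
            raise ReferenceError(
                f"{path}: mature {m['name']!r} lies outside precursor {p['name']!r}"
            )
        if p["strand"] == "+":
            local_start = m["start"] - p["start"] + 1
            local_end = m["end"] - p["start"] + 1
        else:
            local_start = p["end"] - m["end"] + 1
            local_end = p["end"] - m["start"] + 1
        # arm: mature midpoint in the 5' or 3' half of the hairpin
        length = p["end"] - p["start"] + 1
        arm = "5p" if (local_start + local_end) / 2 <= length / 2 else "3p"
        mature_lists.setdefault(p["name"], []).append(
            MatureAnnotation(name=m["name"], start=local_start, end=local_end, arm=arm)
        )
    for pid, p in primaries.items():
        if pid != p["id"]:  # skip the Name alias entries
            continue
        name = p["name"]
        if name not in seq_by_name:
            continue
        out[name] = PreMiRNA(
            name=name,
            sequence=seq_by_name[name],
            chrom=p["chrom"],
            start=p["start"],
            end=p["end"],
            strand=p["strand"],
            matures=tuple(
                sorted(mature_lists.get(name, []), key=lambda a: a.start)
            ),
        )
    return list(out.values())


def read_snp_catalog(path: str | Path) -> list[SNPRecord]:
    """Read an SNV catalog from a VCF 4.x subset.

    Multi-allelic rows are split; indels are skipped with a logged count.
    """
    path = Path(path)
    with open(path) as fh:
        header_ok = any(line.startswith("#CHROM") for line in fh if line.startswith("#"))
    if not header_ok:
        raise ReferenceError(f"{path}: missing #CHROM header line")
    from cyvcf2 import VCF

    records: list[SNPRecord] = []
    skipped = 0
    for v in VCF(str(path)):
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1 or alt == "*":
                skipped += 1
                continue
            records.append(
                SNPRecord(
                    chrom=v.CHROM,
                    position=v.POS,
                    ref=_to_dna(v.REF),
                    alt=_to_dna(alt),
                    identifier=v.ID or ".",
                )
            )
    if skipped:
        logger.info("read_snp_catalog: skipped %d non-SNV allele rows", skipped)
    return records


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a sites x cells editing-level matrix as TSV.

    Levels carry 6 decimals; missing coverage is encoded as ``NA``.
    """
    if matrix.index.has_duplicates:
        raise ReferenceError("duplicate site names in matrix rows")
    if matrix.columns.has_duplicates:
        raise ReferenceError("duplicate cell ids in matrix columns")
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f", index_label="site")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = None
    if df.index.has_duplicates:
        raise ReferenceError("duplicate site names in matrix rows")
    if df.columns.has_duplicates:
        raise ReferenceError("duplicate cell ids in matrix columns")
    values = df.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ReferenceError("editing levels outside [0, 1]")
    return df
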