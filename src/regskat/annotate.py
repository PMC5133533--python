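"""Functional annotation of variants and annotation-derived test weights.

Each variant is placed into one of six regulatory-evidence categories
(1 = strongest evidence the site is functional, 6 = no evidence), taken
from a RegulomeDB-style category string when available and falling back
to a PolyPhen2 prediction for nonsynonymous variants that RegulomeDB
does not cover.  The categories feed two families of weights:

* variance-scale weights ``w_j^2`` for kernel (SKAT-type) tests, via a
  quadratic transform of the reverse category order, and
* burden weights ``w_j`` for collapsing tests, which use the same
  quadratic transform directly.

MAF-based weights (the Beta(1,25) density and the Madsen-Browning
``1/(MAF(1-MAF))``) live here too, since they play the same role.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationError",
    "FunctionalCategory",
    "AnnotationRecord",
    "assign_category",
    "reg_weight_squared",
    "reg_burden_weight",
    "beta_weight",
    "mb_weight",
    "read_annotation",
    "write_annotation",
    "categories_from_table",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation strings, naming the offending variant."""


# PolyPhen2 qualitative predictions mapped onto the 6-level category scale.
_POLYPHEN_TO_CATEGORY = {
    "probably damaging": 1,
    "possibly damaging": 3,
    "benign": 5,
}

_VALID_SOURCES = ("regulomedb", "polyphen2", "unannotated")


@dataclass(frozen=True)
class FunctionalCategory:
    """A variant's functional-evidence category and where it came from."""

    value: int
    source: str

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"category must be in 1..6, got {self.value!r}")
        if self.source not in _VALID_SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")
        if self.source == "unannotated" and self.value != 6:
            raise ValueError("unannotated variants must be in category 6")


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of the annotation table for a single (ref, alt) pair.

    Multi-allelic sites are represented as separate records, one per
    alternate allele.  ``None`` (or ``""``/``"."`` in the file) marks an
    absent annotation.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    regulomedb_category: Optional[str] = None
    polyphen2_prediction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based, must be >= 1")

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref_allele}>{self.alt_allele}"


def _normalise_polyphen(raw: str) -> str:
    return raw.strip().lower().replace("_", " ")


def assign_category(record: AnnotationRecord) -> FunctionalCategory:
    """Assign a functional category, RegulomeDB first, PolyPhen2 as fallback.

    A RegulomeDB sub-category string such as ``"2b"`` collapses to its
    leading major-category digit.  Variants absent from both sources go
    to category 6.  RegulomeDB always wins when both annotations exist.
    """
    reg = record.regulomedb_category
    if reg is not None and reg.strip() not in ("", "."):
        reg = reg.strip()
        if not reg[0].isdigit() or int(reg[0]) not in (1, 2, 3, 4, 5, 6):
            raise AnnotationError(
                f"unparseable RegulomeDB category {reg!r} for {record.variant_id}"
            )
        return FunctionalCategory(int(reg[0]), "regulomedb")

    pp = record.polyphen2_prediction
    if pp is not None and pp.strip() not in ("", "."):
        key = _normalise_polyphen(pp)
        if key not in _POLYPHEN_TO_CATEGORY:
            raise AnnotationError(
                f"unknown PolyPhen2 prediction {pp!r} for {record.variant_id}"
            )
        return FunctionalCategory(_POLYPHEN_TO_CATEGORY[key], "polyphen2")

    return FunctionalCategory(6, "unannotated")


def reg_weight_squared(category: FunctionalCategory | int) -> float:
    """Variance-scale weight ``w^2 = f(s) = s^2`` with ``s = 7 - category``.

    The reverse ordering makes strong-evidence categories heavy
    (category 1 -> 36) and evidence-free ones light (category 6 -> 1);
    the quadratic shape suppresses the low-confidence categories.
    """
    value = category.value if isinstance(category, FunctionalCategory) else int(category)
    if value not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"category must be in 1..6, got {value!r}")
    return float((7 - value) ** 2)


def reg_burden_weight(category: FunctionalCategory | int) -> float:
    """Burden-scale weight for annotation-weighted collapsing: ``w = f(s)``.

    The collapsing test uses the quadratic transform itself as the
    per-variant weight, not its square root.
    """
    return reg_weight_squared(category)


def beta_weight(maf: float) -> float:
    """Beta(1,25) density at the MAF: ``25 (1 - maf)^24``.

    The default SKAT weighting; up-weights rarer variants smoothly.
    Only defined on (0, 0.5].
    """
    maf = float(maf)
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    # closed form of scipy.stats.beta(1, 25).pdf(maf); cheap and exact
    return 25.0 * (1.0 - maf) ** 24


def mb_weight(maf: float) -> float:
    """Madsen-Browning weight ``1/(maf (1 - maf))`` on (0, 0.5]."""
    maf = float(maf)
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    return 1.0 / (maf * (1.0 - maf))


# ---------------------------------------------------------------------------
# Annotation table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "regdb_category", "polyphen2"]


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_annotation(path, strip_chr_prefix: bool = True) -> pd.DataFrame:
    """Read a TSV annotation table (``chrom pos ref alt regdb_category polyphen2``).

    Empty strings and ``"."`` mean "annotation absent".  With
    ``strip_chr_prefix`` chromosome names are normalised by removing a
    leading ``chr``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
                     keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    df = df[_TABLE_COLUMNS].copy()
    df["pos"] = df["pos"].astype(int)
    if strip_chr_prefix:
        df["chrom"] = df["chrom"].map(_strip_chr)
    df["regdb_category"] = df["regdb_category"].replace(".", "")
    df["polyphen2"] = df["polyphen2"].replace(".", "")
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        first = df[dup].iloc[0]
        raise AnnotationError(
            f"duplicate annotation record at {first['chrom']}:{first['pos']}"
            f":{first['ref']}>{first['alt']}"
        )
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=_TABLE_COLUMNS)


def categories_from_table(df: pd.DataFrame) -> list[FunctionalCategory]:
    """Assign a :class:`FunctionalCategory` to every row of an annotation table."""
    out = []
    for row in df.itertuples(index=False):
        rec = AnnotationRecord(
            chromosome=str(row.chrom),
            position=int(row.pos),
            ref_allele=str(row.ref),
            alt_allele=str(row.alt),
            regulomedb_category=str(row.regdb_category) or None,
            polyphen2_prediction=str(row.polyphen2) or None,
        )
        out.append(assign_category(rec))
    return out


def category_values(categories) -> np.ndarray:
    """Integer category values as an array, for vectorised weighting."""
    return np.array(
        [c.value if isinstance(c, FunctionalCategory) else int(c) for c in categories],
        dtype=int,
    )
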