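"""Pyrimidine-referenced SBS-6 and SBS-96 mutational catalogues.

Substitutions are re-expressed so the mutated base is a pyrimidine (C or T):
a purine-reference change is reverse-complemented, flanks included, before
classification.  SBS-96 stratifies the six substitution types by the 5' and
3' flanking bases read from the transcript (sense) strand of the reference,
giving the COSMIC-style 6 x 4 x 4 = 96 trinucleotide classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import DataConsistencyError
from .variants import LibraryVariants

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = ("A", "C", "G", "T")

SBS6_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SBS6_CLASSES
    for five in _BASES
    for three in _BASES
)


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


def canonical_sbs_class(ref: str, alt: str, five_prime: str, three_prime: str) -> str:
    """SBS-96 class string ``X[P>Q]Y`` with the reference base a pyrimidine.

    Purine-reference changes are reverse-complemented (all four bases
    complemented and the flanks swapped) before formatting.
    """
    for b in (ref, alt, five_prime, three_prime):
        if b not in _BASES:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError(f"alt equals ref ({ref})")
    if ref in ("C", "T"):
        return f"{five_prime}[{ref}>{alt}]{three_prime}"
    return f"{_comp(three_prime)}[{_comp(ref)}>{_comp(alt)}]{_comp(five_prime)}"


def canonical_sbs6_class(ref: str, alt: str) -> str:
    """SBS-6 class of a ref>alt change, pyrimidine-referenced."""
    if ref in ("C", "T"):
        key = f"{ref}>{alt}"
    else:
        key = f"{_comp(ref)}>{_comp(alt)}"
    if key not in SBS6_CLASSES:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    return key


@dataclass
class SBS6Catalogue:
    """Counts over the six pyrimidine-referenced substitution classes."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SBS6_CLASSES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "SBS6Catalogue") -> "SBS6Catalogue":
        return SBS6Catalogue({c: self.counts[c] + other.counts[c] for c in SBS6_CLASSES})


@dataclass
class SBS96Catalogue:
    """Counts over the 96 trinucleotide classes, with exclusion tallies.

    Records at a transcript edge (no 5' or 3' flank) and records whose REF
    disagrees with the reference base are excluded from the 96 classes and
    tallied so totals reconcile with the input record count.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SBS96_CLASSES}
    )
    n_edge_excluded: int = 0
    n_ref_mismatch: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "SBS96Catalogue") -> "SBS96Catalogue":
        return SBS96Catalogue(
            {c: self.counts[c] + other.counts[c] for c in SBS96_CLASSES},
            self.n_edge_excluded + other.n_edge_excluded,
            self.n_ref_mismatch + other.n_ref_mismatch,
        )

    def marginal_sbs6(self) -> SBS6Catalogue:
        """Collapse flanks, yielding the SBS-6 catalogue of the same records."""
        out = SBS6Catalogue()
        for cls, n in self.counts.items():
            out.counts[cls[2:5]] += n
        return out


def build_sbs6(lib: LibraryVariants) -> SBS6Catalogue:
    """SBS-6 catalogue of a library; every record maps to exactly one class."""
    cat = SBS6Catalogue()
    for rec in lib.records:
        cat.counts[canonical_sbs6_class(rec.ref, rec.alt)] += 1
    return cat


def build_sbs96(lib: LibraryVariants, reference: Mapping[str, str]) -> SBS96Catalogue:
    """SBS-96 catalogue with flanks read from the reference transcript strand.

    Raises DataConsistencyError for records on transcripts absent from the
    reference.  Ref-mismatching records are excluded and logged, never
    silently recoded.
    """
    cat = SBS96Catalogue()
    for rec in lib.records:
        seq = reference.get(rec.transcript_id)
        if seq is None:
            raise DataConsistencyError(
                f"transcript {rec.transcript_id!r} not in reference"
            )
        seq = seq.upper()
        if not (1 <= rec.pos <= len(seq)) or seq[rec.pos - 1] != rec.ref:
            logger.warning(
                "%s: REF mismatch at %s:%d (VCF %s, reference %s)",
                lib.library_id, rec.transcript_id, rec.pos, rec.ref,
                seq[rec.pos - 1] if 1 <= rec.pos <= len(seq) else "out-of-range",
            )
            cat.n_ref_mismatch += 1
            continue
        if rec.pos == 1 or rec.pos == len(seq):
            cat.n_edge_excluded += 1
            continue
        cls = canonical_sbs_class(rec.ref, rec.alt, seq[rec.pos - 2], seq[rec.pos])
        cat.counts[cls] += 1
    return cat


def purine_lead_class(cls: str) -> str:
    """Reverse-complemented rendering of an SBS-96 class (purine reference)."""
    five, ref, alt, three = cls[0], cls[2], cls[4], cls[6]
    return f"{_comp(three)}[{_comp(ref)}>{_comp(alt)}]{_comp(five)}"


def catalogue_matrix(
    catalogues: Mapping[str, SBS96Catalogue], *, purine_lead: bool = False
) -> pd.DataFrame:
    """96 x n_libraries count matrix (classes as rows, libraries as columns).

    Row order is the canonical class order (substitution type, then 5' and 3'
    flanks lexicographically).  ``purine_lead=True`` relabels rows with the
    purine-referenced rendering of each class.
    """
    df = pd.DataFrame(
        {lib: [cat.counts[c] for c in SBS96_CLASSES] for lib, cat in catalogues.items()},
        index=list(SBS96_CLASSES),
    )
    if purine_lead:
        df.index = [purine_lead_class(c) for c in SBS96_CLASSES]
    df.index.name = "class"
    return df


def plot_sbs96_heatmap(matrix: pd.DataFrame, ax=None):
    """Minimal heatmap hook for a 96 x n catalogue matrix (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 14))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=4)
    ax.figure.colorbar(im, ax=ax, label="SNV count")
    return ax
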