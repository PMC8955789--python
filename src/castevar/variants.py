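"""Per-library SNV extraction from VCF, depth filtering, counts and ts/tv.

Only biallelic single-nucleotide alleles are kept: indels, MNVs, symbolic
and spanning-deletion alleles are dropped, and multi-allelic rows are
decomposed so each single-base ALT becomes its own record (a strict mode
drops multi-allelic rows instead).  Read depth is taken from the sample
FORMAT DP field when present, falling back to INFO DP, else 0.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

from cyvcf2 import VCF

from .errors import VcfParseError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

# Transition pairs on either strand: A<->G and C<->T.
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


@dataclass(frozen=True)
class SNVRecord:
    """One biallelic SNV on a transcript (1-based VCF coordinates)."""

    transcript_id: str
    pos: int
    ref: str
    alt: str
    depth: int = 0

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single ACGT bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"alt equals ref ({self.ref}) at {self.transcript_id}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_transition(self) -> bool:
        return frozenset((self.ref, self.alt)) in _TRANSITIONS


@dataclass
class LibraryVariants:
    """All SNVs of one sequencing library, with its caste/population labels."""

    library_id: str
    caste: str = ""
    population: str = ""
    records: list[SNVRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def read_snvs(
    vcf_path: str | os.PathLike,
    *,
    library_id: str | None = None,
    caste: str = "",
    population: str = "",
    strict_multiallelic: bool = False,
) -> LibraryVariants:
    """Read a VCF and isolate biallelic SNVs into a LibraryVariants.

    Multi-allelic rows are decomposed into one record per single-base ALT
    unless ``strict_multiallelic`` is set, in which case they are dropped
    whole.  Duplicate (transcript, pos, alt) triples: last read wins, with a
    logged warning.
    """
    path = Path(vcf_path)
    if not path.is_file():
        raise FileNotFoundError(f"VCF not found: {path}")
    if library_id is None:
        library_id = path.name.removesuffix(".gz").removesuffix(".vcf")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports open/parse failures generically
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    seen: dict[tuple[str, int, str], int] = {}
    records: list[SNVRecord] = []
    try:
        for v in vcf:
            ref = v.REF
            alts = v.ALT
            if strict_multiallelic and len(alts) > 1:
                continue
            if len(ref) != 1 or ref not in _BASES:
                continue
            depth = _read_depth(v)
            for alt in alts:
                if len(alt) != 1 or alt not in _BASES or alt == ref:
                    continue
                rec = SNVRecord(v.CHROM, v.POS, ref, alt, depth)
                key = (rec.transcript_id, rec.pos, rec.alt)
                if key in seen:
                    logger.warning(
                        "%s: duplicate record %s:%d %s>%s, keeping the last one",
                        path.name, rec.transcript_id, rec.pos, rec.ref, rec.alt,
                    )
                    records[seen[key]] = rec
                else:
                    seen[key] = len(records)
                    records.append(rec)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed row in {path}: {exc}") from exc
    finally:
        vcf.close()
    return LibraryVariants(library_id, caste, population, records)


def _read_depth(variant) -> int:
    fmt_dp = None
    try:
        fmt_dp = variant.format("DP")
    except KeyError:
        fmt_dp = None
    if fmt_dp is not None and len(fmt_dp) > 0:
        d = int(fmt_dp[0][0])
        if d >= 0:
            return d
    info_dp = variant.INFO.get("DP")
    if info_dp is not None:
        return int(info_dp)
    return 0


def filter_by_depth(lib: LibraryVariants, min_depth: int = 10, *, strict: bool = True) -> LibraryVariants:
    """Retain records whose depth exceeds ``min_depth``.

    The comparison is strict (depth > min_depth) by default, matching the
    high-quality "depth > 10" convention; ``strict=False`` retains
    depth >= min_depth.  Record order is preserved.
    """
    if min_depth < 0:
        raise ValueError(f"min_depth must be >= 0, got {min_depth}")
    if strict:
        kept = [r for r in lib.records if r.depth > min_depth]
    else:
        kept = [r for r in lib.records if r.depth >= min_depth]
    return replace(lib, records=kept)


def count_snvs(lib: LibraryVariants) -> int:
    """Total number of SNV records in the library."""
    return len(lib.records)


def titv_ratio(lib: LibraryVariants) -> float | None:
    """Transition/transversion ratio; None when there are no transversions.

    Transitions are A<->G and C<->T (strand-symmetric); every other ref->alt
    pair is a transversion.
    """
    ts = sum(1 for r in lib.records if r.is_transition)
    tv = len(lib.records) - ts
    if tv == 0:
        return None
    return ts / tv
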