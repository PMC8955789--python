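"""Coding-region selection analysis: ORF detection, Nei-Gojobori site counts,
SNV classification, and Jukes-Cantor-corrected dN/dS.

The estimator follows the approximate (NG86) method: every single-base change
in a codon is classified against the standard genetic code as synonymous,
nonsynonymous or stop-gain; per-codon fractional site counts (thirds) are
summed over the open reading frame; observed substitution proportions
``p = substitutions / sites`` are corrected for multiple hits with the
Jukes-Cantor distance ``d = -(3/4) ln(1 - 4p/3)``, and the ratio dN/dS is
reported per library, either over the whole transcriptome or over a subset
of (caste-associated) transcripts.

Coordinates are 1-based and inclusive throughout (VCF/FASTA convention);
transcripts are sense-strand, so only the forward strand is scanned for ORFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data import CodonTable

from .errors import DegenerateInputError, ReferenceMismatchError, SaturationError

__all__ = [
    "OpenReadingFrame",
    "SiteCounts",
    "DnDsEstimate",
    "find_longest_orf",
    "ng86_site_counts",
    "classify_snv",
    "jc_distance",
    "dnds_from_counts",
    "estimate_dnds",
    "build_coding_table",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA
BASES = ("A", "C", "G", "T")
_BASESET = frozenset(BASES)

# Substitution classes (shared with the synthetic generator's ground truth).
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOPGAIN = "stopgain"
NONCODING = "noncoding"


@dataclass(frozen=True)
class OpenReadingFrame:
    """Longest start/stop-bounded coding span of a transcript.

    ``start``/``end`` are 1-based inclusive; ``start`` points at the A of ATG
    and ``end`` at the last base of the stop codon.
    """

    transcript_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def frame(self) -> int:
        return (self.start - 1) % 3


@dataclass(frozen=True)
class SiteCounts:
    """NG86 fractional synonymous/nonsynonymous site counts for a coding span.

    Counts are exact thirds (stored as integer numbers of single-base changes
    divided by 3).  Changes that create a stop codon contribute to neither
    class; their site mass is reported separately so the per-codon total of 3
    reconciles.
    """

    syn_sites: float
    nonsyn_sites: float
    stop_adjacent_sites: float
    n_codons: int

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            self.syn_sites + other.syn_sites,
            self.nonsyn_sites + other.nonsyn_sites,
            self.stop_adjacent_sites + other.stop_adjacent_sites,
            self.n_codons + other.n_codons,
        )


@dataclass(frozen=True)
class DnDsEstimate:
    """p_S, p_N, their Jukes-Cantor corrections d_S, d_N, and the ratio.

    ``ratio`` is None when d_S = 0 (undefined, by contract a value rather
    than an error).  Side tallies record what was excluded from p_S/p_N.
    """

    p_s: float
    p_n: float
    d_s: float
    d_n: float
    ratio: float | None
    n_syn: int = 0
    n_nonsyn: int = 0
    n_stopgain: int = 0
    n_noncoding: int = 0
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _BASESET
    if bad:
        raise ValueError(f"non-ACGTU characters in sequence: {sorted(bad)!r}")
    return seq


def find_longest_orf(sequence: str, transcript_id: str = "") -> OpenReadingFrame | None:
    """Return the longest forward-strand ORF bound by ATG and a stop codon.

    All three frames are scanned; an ORF runs from an ATG to the first
    in-frame stop (the stop codon is included in the span).  Ties are broken
    by the smallest start.  Returns None when no start/stop-bounded frame
    exists.
    """
    seq = _validate_sequence(sequence)
    n = len(seq)
    best: tuple[int, int] | None = None  # (length, start0)
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    length = i + 3 - open_start
                    if best is None or length > best[0] or (
                        length == best[0] and open_start < best[1]
                    ):
                        best = (length, open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    if best is None:
        return None
    length, start0 = best
    return OpenReadingFrame(transcript_id, start0 + 1, start0 + length)


def ng86_site_counts(orf_sequence: str) -> SiteCounts:
    """NG86 fractional site counts for an in-frame coding sequence.

    A trailing stop codon, if present, is removed before counting.  Each of
    the nine single-base changes per codon is classified against the standard
    genetic code; synonymous and nonsynonymous changes each add 1/3 of a site
    at their position, stop-creating changes are excluded (tallied as
    ``stop_adjacent_sites``).
    """
    seq = _validate_sequence(orf_sequence)
    if len(seq) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    syn_changes = 0
    stop_changes = 0
    n_codons = len(seq) // 3
    for c in range(n_codons):
        codon = seq[3 * c : 3 * c + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {c + 1}")
        aa = CODON_TO_AA[codon]
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    stop_changes += 1
                elif CODON_TO_AA[mutant] == aa:
                    syn_changes += 1
    total_changes = 9 * n_codons
    nonsyn_changes = total_changes - syn_changes - stop_changes
    return SiteCounts(syn_changes / 3, nonsyn_changes / 3, stop_changes / 3, n_codons)


def classify_change(seq: str, orf: OpenReadingFrame | None, pos: int, alt: str) -> str:
    """Classify the single-base change ``pos -> alt`` on a transcript.

    Positions outside the ORF (or with no ORF, or inside the terminal stop
    codon) are noncoding; otherwise the containing codon is mutated and
    translated.  ``seq`` must already be an upper-case ACGT string.
    """
    if orf is None or pos < orf.start or pos > orf.end - 3:
        return NONCODING
    offset = pos - orf.start
    codon_start0 = orf.start - 1 + 3 * (offset // 3)
    codon = seq[codon_start0 : codon_start0 + 3]
    within = offset % 3
    mutant = codon[:within] + alt + codon[within + 1 :]
    if mutant in STOP_CODONS:
        return STOPGAIN
    if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
        return SYNONYMOUS
    return NONSYNONYMOUS


def classify_snv(orf: OpenReadingFrame | None, snv, reference: Mapping[str, str]) -> str:
    """Classify an SNVRecord as synonymous/nonsynonymous/stop-gain/noncoding.

    Raises ReferenceMismatchError when the record's REF allele disagrees with
    the reference base at its position.
    """
    seq = reference[snv.transcript_id].upper()
    if not (1 <= snv.pos <= len(seq)):
        raise ReferenceMismatchError(
            f"{snv.transcript_id}:{snv.pos} outside transcript of length {len(seq)}"
        )
    if seq[snv.pos - 1] != snv.ref:
        raise ReferenceMismatchError(
            f"{snv.transcript_id}:{snv.pos} REF {snv.ref} != reference base {seq[snv.pos - 1]}"
        )
    return classify_change(seq, orf, snv.pos, snv.alt)


def jc_distance(p: float) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - 4p/3).

    Defined for 0 <= p < 3/4; strictly increasing and >= p on that range.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dnds_from_counts(
    syn_subs: float,
    nonsyn_subs: float,
    syn_sites: float,
    nonsyn_sites: float,
    *,
    n_stopgain: int = 0,
    n_noncoding: int = 0,
) -> DnDsEstimate:
    """Assemble a DnDsEstimate from pooled substitution and site counts."""
    if syn_sites <= 0 or nonsyn_sites <= 0:
        raise DegenerateInputError("no synonymous/nonsynonymous sites to normalise by")
    p_s = syn_subs / syn_sites
    p_n = nonsyn_subs / nonsyn_sites
    d_s = jc_distance(p_s)
    d_n = jc_distance(p_n)
    ratio = d_n / d_s if d_s > 0 else None
    return DnDsEstimate(
        p_s=p_s,
        p_n=p_n,
        d_s=d_s,
        d_n=d_n,
        ratio=ratio,
        n_syn=int(syn_subs),
        n_nonsyn=int(nonsyn_subs),
        n_stopgain=n_stopgain,
        n_noncoding=n_noncoding,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
    )


@dataclass(frozen=True)
class TranscriptCoding:
    """Cached longest ORF and NG86 site counts for one transcript."""

    orf: OpenReadingFrame | None
    sites: SiteCounts | None


def build_coding_table(reference: Mapping[str, str]) -> dict[str, TranscriptCoding]:
    """Locate the longest ORF and its site counts for every transcript."""
    table: dict[str, TranscriptCoding] = {}
    for tid, seq in reference.items():
        orf = find_longest_orf(seq, tid)
        if orf is None:
            table[tid] = TranscriptCoding(None, None)
        else:
            cds = seq.upper()[orf.start - 1 : orf.end]
            table[tid] = TranscriptCoding(orf, ng86_site_counts(cds))
    return table


def estimate_dnds(
    lib,
    reference: Mapping[str, str],
    subset: Iterable[str] | None = None,
    *,
    coding_table: Mapping[str, TranscriptCoding] | None = None,
    mode: str = "pooled",
):
    """Jukes-Cantor-corrected dN/dS for one library.

    In the default pooled mode, substitution and site counts are summed over
    every (subset-)transcript with an ORF before normalisation; this is
    robust to transcripts with zero synonymous hits.  ``mode='per-transcript'``
    instead returns ``{transcript_id: DnDsEstimate}`` for transcripts with an
    ORF and at least one classifiable scheme of sites (ratio None where d_S=0).

    Noncoding SNVs, stop-gains and SNVs on ORF-less transcripts are excluded
    from p_S/p_N and reported in the estimate's side tallies.
    """
    if mode not in ("pooled", "per-transcript"):
        raise ValueError(f"unknown dN/dS mode {mode!r}")
    if coding_table is None:
        coding_table = build_coding_table(reference)
    subset_ids = set(subset) if subset is not None else None

    scope_ids = [
        tid
        for tid in reference
        if subset_ids is None or tid in subset_ids
    ]
    per_syn: dict[str, int] = {}
    per_nonsyn: dict[str, int] = {}
    n_stopgain = 0
    n_noncoding = 0
    for rec in lib.records:
        tid = rec.transcript_id
        if subset_ids is not None and tid not in subset_ids:
            continue
        coding = coding_table[tid]
        if coding.orf is None:
            n_noncoding += 1
            continue
        cls = classify_snv(coding.orf, rec, reference)
        if cls == SYNONYMOUS:
            per_syn[tid] = per_syn.get(tid, 0) + 1
        elif cls == NONSYNONYMOUS:
            per_nonsyn[tid] = per_nonsyn.get(tid, 0) + 1
        elif cls == STOPGAIN:
            n_stopgain += 1
        else:
            n_noncoding += 1

    if mode == "per-transcript":
        out: dict[str, DnDsEstimate] = {}
        for tid in scope_ids:
            coding = coding_table[tid]
            if coding.sites is None:
                continue
            out[tid] = dnds_from_counts(
                per_syn.get(tid, 0),
                per_nonsyn.get(tid, 0),
                coding.sites.syn_sites,
                coding.sites.nonsyn_sites,
            )
        return out

    syn_sites = sum(
        coding_table[tid].sites.syn_sites
        for tid in scope_ids
        if coding_table[tid].sites is not None
    )
    nonsyn_sites = sum(
        coding_table[tid].sites.nonsyn_sites
        for tid in scope_ids
        if coding_table[tid].sites is not None
    )
    return dnds_from_counts(
        sum(per_syn.values()),
        sum(per_nonsyn.values()),
        syn_sites,
        nonsyn_sites,
        n_stopgain=n_stopgain,
        n_noncoding=n_noncoding,
    )
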