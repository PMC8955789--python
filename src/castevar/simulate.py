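"""Synthetic study generator with planted, recoverable ground truth.

Emulates the sampled design of a caste/population RNA-seq variant study:
nine libraries in a 3-caste (nymph, soldier, worker) x 3-population
(Raleigh, Boston, Toronto) grid, a shared reference transcriptome whose
transcripts each embed a longest ORF by construction, per-library planted
SNVs with a controllable transition/transversion target and a
negative-binomial read-depth model, and a designated caste-associated
transcript subset in which soldier libraries carry an elevated
nonsynonymous substitution rate.

Every planted variant carries a ground-truth label (synonymous /
nonsynonymous / stopgain / noncoding, transition / transversion) produced by
the same classification core the estimator uses, so downstream recovery is
exactly testable.  A single master seed drives everything; per-library
substreams are derived by stable hashing of the library id, so adding a
library does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, GenerationError, SaturationError
from .selection import (
    NONCODING,
    NONSYNONYMOUS,
    STOP_CODONS,
    SYNONYMOUS,
    TranscriptCoding,
    build_coding_table,
    classify_change,
    jc_distance,
)
from .variants import LibraryVariants, SNVRecord

CASTES = ("nymph", "soldier", "worker")
POPULATIONS = ("Raleigh", "Boston", "Toronto")

_BASES = ("A", "C", "G", "T")
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_REFERENCE_STREAM_TAG = 7


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study; identical config + seed gives
    byte-identical outputs.

    ``titv_target`` is the expected transitions/transversions ratio of
    planted changes before any nonsynonymous reweighting.
    ``nonsyn_enrichment`` multiplies the odds of every nonsynonymous change
    (all libraries); ``soldier_nonsyn_enrichment`` further multiplies those
    odds for variants in subset transcripts of soldier libraries.
    ``library_effect_sd`` is the lognormal sigma of a mean-one per-library
    multiplier on nonsynonymous odds, modelling between-library
    overdispersion of replicate libraries.
    """

    n_transcripts: int = 300
    orf_codons_range: tuple[int, int] = (100, 300)
    utr_len_range: tuple[int, int] = (20, 100)
    gc_content: float = 0.45
    variants_per_library: int = 30_000
    titv_target: float = 1.7
    depth_mean: float = 40.0
    depth_dispersion: float = 5.0
    subset_fraction: float = 0.05
    nonsyn_enrichment: float = 1.0
    soldier_nonsyn_enrichment: float = 1.0
    library_effect_sd: float = 0.08
    population_count_multipliers: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be positive")
        for name, lo_hi in (("orf_codons_range", self.orf_codons_range),
                            ("utr_len_range", self.utr_len_range)):
            lo, hi = lo_hi
            if lo > hi or lo < 0:
                raise ConfigurationError(f"{name} {lo_hi} is empty or negative")
        if self.orf_codons_range[0] < 1:
            raise ConfigurationError("ORFs need at least one inner codon")
        if not (0.0 < self.gc_content < 1.0):
            raise ConfigurationError(f"gc_content must be in (0,1), got {self.gc_content}")
        if self.variants_per_library < 0:
            raise ConfigurationError("variants_per_library must be >= 0")
        if self.titv_target <= 0:
            raise ConfigurationError("titv_target must be positive")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("depth model parameters must be positive")
        if not (0.0 <= self.subset_fraction <= 1.0):
            raise ConfigurationError("subset_fraction must be in [0,1]")
        if self.nonsyn_enrichment <= 0:
            raise ConfigurationError("nonsyn_enrichment must be positive")
        if self.soldier_nonsyn_enrichment < 1.0:
            raise ConfigurationError("soldier_nonsyn_enrichment must be >= 1")
        if self.library_effect_sd < 0:
            raise ConfigurationError("library_effect_sd must be >= 0")


@dataclass(frozen=True)
class LibraryMeta:
    library_id: str
    caste: str
    population: str


@dataclass(frozen=True)
class StudyDesign:
    """Nine labelled libraries (one per caste x population cell) plus the
    caste-associated transcript subset."""

    libraries: tuple[LibraryMeta, ...]
    subset_ids: frozenset[str]

    def validate(self, reference: Mapping[str, str] | None = None) -> None:
        cells = {(m.caste, m.population) for m in self.libraries}
        expected = {(c, p) for c in CASTES for p in POPULATIONS}
        if cells != expected or len(self.libraries) != 9:
            raise ConfigurationError("design must have exactly one library per caste x population cell")
        if reference is not None and not self.subset_ids <= set(reference):
            raise ConfigurationError("subset_ids must be a subset of reference transcript IDs")

    def library(self, library_id: str) -> LibraryMeta:
        for m in self.libraries:
            if m.library_id == library_id:
                return m
        raise ConfigurationError(f"library {library_id!r} not in design")


@dataclass(frozen=True)
class PlantedVariant:
    """Ground-truth row for one planted SNV."""

    library_id: str
    transcript: str
    pos: int
    ref: str
    alt: str
    klass: str
    titv: str  # "transition" | "transversion"


def _library_seed(master_seed: int, library_id: str) -> int:
    digest = hashlib.sha256(library_id.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _library_rng(master_seed: int, library_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master_seed % (2**31), _library_seed(master_seed, library_id)])
    )


def default_design(subset_ids=()) -> StudyDesign:
    libraries = tuple(
        LibraryMeta(f"{pop}_{caste}", caste, pop)
        for caste in CASTES
        for pop in POPULATIONS
    )
    return StudyDesign(libraries, frozenset(subset_ids))


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(_BASES)[rng.choice(4, size=n, p=p)]) if n else ""


def _draw_sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _draw_bases(rng, 3, gc)
        if codon not in STOP_CODONS:
            return codon


_STOP_LIST = tuple(sorted(STOP_CODONS))


def generate_reference(config: SimulationConfig) -> tuple[dict[str, str], StudyDesign]:
    """Generate the reference transcriptome and the 9-library study design.

    Each transcript is 5'UTR + ATG + k inner sense codons + stop + 3'UTR;
    the embedded ORF is verified by re-scanning to be the transcript's
    longest ORF (the transcript is redrawn otherwise, so UTRs may freely
    contain starts and stops).
    """
    config.validate()
    from .selection import find_longest_orf

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed % (2**31), _REFERENCE_STREAM_TAG])
    )
    reference: dict[str, str] = {}
    width = max(4, len(str(config.n_transcripts)))
    for i in range(config.n_transcripts):
        tid = f"transcript_{i + 1:0{width}d}"
        for _attempt in range(200):
            k = int(rng.integers(config.orf_codons_range[0], config.orf_codons_range[1] + 1))
            utr5 = int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
            utr3 = int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
            inner = "".join(_draw_sense_codon(rng, config.gc_content) for _ in range(k))
            stop = _STOP_LIST[int(rng.integers(3))]
            seq = _draw_bases(rng, utr5, config.gc_content) + "ATG" + inner + stop \
                + _draw_bases(rng, utr3, config.gc_content)
            orf = find_longest_orf(seq, tid)
            if orf is not None and orf.start == utr5 + 1 and orf.end == utr5 + 3 * (k + 2):
                reference[tid] = seq
                break
        else:
            raise GenerationError(f"could not embed a dominant ORF in {tid}")
    ids = list(reference)
    n_subset = math.ceil(config.subset_fraction * config.n_transcripts)
    subset = sorted(
        np.array(ids)[rng.choice(len(ids), size=n_subset, replace=False)].tolist()
    ) if n_subset else []
    design = default_design(subset)
    design.validate(reference)
    return reference, design


# --- per-position change tables -------------------------------------------

def build_site_tables(
    reference: Mapping[str, str],
    coding_table: Mapping[str, TranscriptCoding] | None = None,
) -> dict[str, list[tuple[str, tuple[tuple[str, str], ...]]]]:
    """For each transcript, per position: (ref, ((alt, class) x3)).

    Alt order is transition first, then the two transversions alphabetically;
    classes come from the same core used by the estimator's classify step.
    """
    if coding_table is None:
        coding_table = build_coding_table(reference)
    tables = {}
    for tid, raw in reference.items():
        seq = raw.upper()
        orf = coding_table[tid].orf
        rows = []
        for pos0, ref in enumerate(seq):
            ts_alt = _TRANSITION_OF[ref]
            tv_alts = sorted(b for b in _BASES if b != ref and b != ts_alt)
            alts = (ts_alt, tv_alts[0], tv_alts[1])
            rows.append(
                (ref, tuple((a, classify_change(seq, orf, pos0 + 1, a)) for a in alts))
            )
        tables[tid] = rows
    return tables


@dataclass
class SitePrep:
    """Precomputed per-site quantities shared by all libraries of a study.

    ``w_syn``/``w_non``/``w_stop`` hold, per global site index, the base
    (transition/transversion) weight mass of the synonymous, nonsynonymous
    and stop-gain alternatives at that site (all zero at noncoding sites;
    base weights at a site always sum to one).
    """

    tids: list[str]
    offsets: np.ndarray  # cumulative transcript start offsets, len = n + 1
    tables: dict
    w_syn: np.ndarray
    w_non: np.ndarray
    w_stop: np.ndarray


def prepare_sites(
    reference: Mapping[str, str],
    config: SimulationConfig,
    coding_table: Mapping[str, TranscriptCoding] | None = None,
    site_tables=None,
) -> SitePrep:
    """Build the flattened per-site weight arrays for the planting model."""
    if site_tables is None:
        site_tables = build_site_tables(reference, coding_table)
    r = config.titv_target
    base_w = (r / (1.0 + r), 0.5 / (1.0 + r), 0.5 / (1.0 + r))
    tids = list(reference)
    lengths = [len(reference[t]) for t in tids]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    w_syn = np.zeros(total)
    w_non = np.zeros(total)
    w_stop = np.zeros(total)
    i = 0
    for tid in tids:
        for _ref, alt_rows in site_tables[tid]:
            s = n = x = 0.0
            for w, (_, cls) in zip(base_w, alt_rows):
                if cls == SYNONYMOUS:
                    s += w
                elif cls == NONSYNONYMOUS:
                    n += w
                elif cls != NONCODING:
                    x += w
            w_syn[i] = s
            w_non[i] = n
            w_stop[i] = x
            i += 1
    return SitePrep(tids, offsets, site_tables, w_syn, w_non, w_stop)


def _subset_site_mask(prep: SitePrep, subset_ids) -> np.ndarray:
    mask = np.zeros(int(prep.offsets[-1]), dtype=bool)
    for i, tid in enumerate(prep.tids):
        if tid in subset_ids:
            mask[int(prep.offsets[i]) : int(prep.offsets[i + 1])] = True
    return mask


def plant_variants(
    reference: Mapping[str, str],
    design: StudyDesign,
    config: SimulationConfig,
    library_id: str,
    *,
    sites: SitePrep | None = None,
) -> tuple[LibraryVariants, list[PlantedVariant]]:
    """Plant SNVs for one library and return them with ground-truth labels.

    Each variant is a (site, alternative-base) pair drawn without
    replacement from the joint change distribution: uniform over transcript
    positions, with the alternative base carrying transition probability
    titv_target/(1+titv_target) (transversions split evenly) and the odds of
    every nonsynonymous change multiplied by the configured enrichment (and
    the library's overdispersion draw).  With all multipliers at one this
    reduces to uniform site placement.  Site selection uses exact
    sequential weighted sampling without replacement (Gumbel top-k); depths
    follow the negative-binomial model.
    """
    config.validate()
    meta = design.library(library_id)
    rng = _library_rng(config.seed, library_id)
    if sites is None:
        sites = prepare_sites(reference, config)

    mult = 1.0
    if config.population_count_multipliers:
        mult = float(config.population_count_multipliers.get(meta.population, 1.0))
    n_variants = int(round(config.variants_per_library * mult))

    sd = config.library_effect_sd
    jitter = float(np.exp(rng.normal(-0.5 * sd * sd, sd))) if sd > 0 else 1.0

    total_len = int(sites.offsets[-1])
    if n_variants > total_len:
        raise GenerationError(
            f"{n_variants} variants requested but only {total_len} sites available"
        )
    if n_variants == 0:
        return LibraryVariants(library_id, meta.caste, meta.population, []), []

    is_soldier_lib = meta.caste == "soldier"
    ns_mult_plain = config.nonsyn_enrichment * jitter
    ns_mult_subset = ns_mult_plain * (
        config.soldier_nonsyn_enrichment if is_soldier_lib else 1.0
    )
    m_site = np.full(total_len, ns_mult_plain)
    if design.subset_ids and ns_mult_subset != ns_mult_plain:
        m_site[_subset_site_mask(sites, design.subset_ids)] = ns_mult_subset
    # Total change weight per site; base weights sum to 1 at every site.
    z_site = 1.0 + (m_site - 1.0) * sites.w_non

    keys = np.log(z_site) + rng.gumbel(size=total_len)
    chosen = np.sort(np.argpartition(keys, total_len - n_variants)[-n_variants:])
    t_of_site = np.searchsorted(sites.offsets, chosen, side="right") - 1

    r = config.titv_target
    base_w = (r / (1.0 + r), 0.5 / (1.0 + r), 0.5 / (1.0 + r))
    depths = rng.negative_binomial(
        config.depth_dispersion,
        config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
        size=n_variants,
    )
    unif = rng.random(n_variants)

    records: list[SNVRecord] = []
    truth: list[PlantedVariant] = []
    for i in range(n_variants):
        ti = int(t_of_site[i])
        tid = sites.tids[ti]
        pos = int(chosen[i] - sites.offsets[ti]) + 1
        ref, alt_rows = sites.tables[tid][pos - 1]
        ns_mult = float(m_site[chosen[i]])
        weights = [
            w * (ns_mult if cls == NONSYNONYMOUS else 1.0)
            for w, (_, cls) in zip(base_w, alt_rows)
        ]
        u = unif[i] * (weights[0] + weights[1] + weights[2])
        if u < weights[0]:
            choice = 0
        elif u < weights[0] + weights[1]:
            choice = 1
        else:
            choice = 2
        alt, cls = alt_rows[choice]
        records.append(SNVRecord(tid, pos, ref, alt, int(depths[i])))
        truth.append(
            PlantedVariant(
                library_id, tid, pos, ref, alt, cls,
                "transition" if choice == 0 else "transversion",
            )
        )
    lib = LibraryVariants(library_id, meta.caste, meta.population, records)
    return lib, truth


# --- file emission ---------------------------------------------------------

def write_vcf(lib: LibraryVariants, reference: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write a minimal single-sample VCFv4.2 with DP in INFO and FORMAT."""
    lines = ["##fileformat=VCFv4.2", "##source=castevar-simulate"]
    lines += [f"##contig=<ID={tid},length={len(seq)}>" for tid, seq in reference.items()]
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + lib.library_id
    )
    for rec in lib.records:
        lines.append(
            f"{rec.transcript_id}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
            f"DP={rec.depth}\tDP\t{rec.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(reference: Mapping[str, str], path: str | os.PathLike) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=tid, description="") for tid, seq in reference.items()]
    seqio_write(records, str(path), "fasta")


def generate_study(config: SimulationConfig, out_dir: str | os.PathLike) -> dict:
    """Write a complete synthetic study and return its file manifest.

    Emits the reference FASTA, nine single-sample VCFs, a metadata TSV, the
    subset-ID list, and the ground-truth table of planted per-variant labels.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, design = generate_reference(config)
    sites = prepare_sites(reference, config)

    manifest: dict = {
        "reference": str(out / "reference.fasta"),
        "metadata": str(out / "metadata.tsv"),
        "subset": str(out / "subset_ids.txt"),
        "ground_truth": str(out / "ground_truth.tsv"),
        "vcfs": {},
        "seed": config.seed,
    }
    write_fasta(reference, manifest["reference"])
    with open(manifest["metadata"], "w") as fh:
        fh.write("library_id\tcaste\tpopulation\n")
        for m in design.libraries:
            fh.write(f"{m.library_id}\t{m.caste}\t{m.population}\n")
    Path(manifest["subset"]).write_text(
        "".join(f"{tid}\n" for tid in sorted(design.subset_ids))
    )
    with open(manifest["ground_truth"], "w") as truth_fh:
        truth_fh.write("library_id\ttranscript\tpos\tref\talt\tclass\ttitv\n")
        for m in design.libraries:
            lib, truth = plant_variants(
                reference, design, config, m.library_id, sites=sites
            )
            vcf_path = out / f"{m.library_id}.vcf"
            write_vcf(lib, reference, vcf_path)
            manifest["vcfs"][m.library_id] = str(vcf_path)
            for row in truth:
                truth_fh.write(
                    f"{row.library_id}\t{row.transcript}\t{row.pos}\t{row.ref}\t"
                    f"{row.alt}\t{row.klass}\t{row.titv}\n"
                )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest"] = str(manifest_path)
    return manifest


# --- analytic calibration of the enrichment multipliers --------------------

def _inclusion_probs(z_site: np.ndarray, n_variants: int) -> np.ndarray:
    """Hajek approximation to successive-sampling inclusion probabilities:
    pi_i = 1 - exp(-t z_i), with t chosen so the probabilities sum to n."""

    def total(t):
        return float(np.sum(-np.expm1(-t * z_site))) - n_variants

    t = brentq(total, 1e-12, 60.0 / float(np.min(z_site)), xtol=1e-12, rtol=1e-12)
    return -np.expm1(-t * z_site)


def expected_pooled_dnds(
    coding_table,
    prep: SitePrep,
    scope_ids,
    config: SimulationConfig,
    nonsyn_mult_plain: float,
    nonsyn_mult_subset: float | None = None,
    subset_ids=frozenset(),
) -> float:
    """Expected pooled dN/dS over a transcript scope under the planting model.

    ``nonsyn_mult_plain`` is the library's total nonsynonymous-odds
    multiplier outside the subset; ``nonsyn_mult_subset`` (defaulting to the
    plain value) applies inside ``subset_ids``.  Inclusion of each (site,
    alt) change follows the weighted without-replacement sampling the
    generator uses, approximated through per-site inclusion probabilities.
    """
    if nonsyn_mult_subset is None:
        nonsyn_mult_subset = nonsyn_mult_plain
    total_len = int(prep.offsets[-1])
    m_site = np.full(total_len, nonsyn_mult_plain)
    if subset_ids and nonsyn_mult_subset != nonsyn_mult_plain:
        m_site[_subset_site_mask(prep, subset_ids)] = nonsyn_mult_subset
    z_site = 1.0 + (m_site - 1.0) * prep.w_non
    pi = _inclusion_probs(z_site, config.variants_per_library)

    scope_mask = _subset_site_mask(prep, set(scope_ids))
    e_syn = float(np.sum(pi[scope_mask] * prep.w_syn[scope_mask] / z_site[scope_mask]))
    e_non = float(
        np.sum(pi[scope_mask] * m_site[scope_mask] * prep.w_non[scope_mask] / z_site[scope_mask])
    )
    syn_sites = sum(
        coding_table[t].sites.syn_sites for t in scope_ids if coding_table[t].sites
    )
    nonsyn_sites = sum(
        coding_table[t].sites.nonsyn_sites for t in scope_ids if coding_table[t].sites
    )
    return jc_distance(e_non / nonsyn_sites) / jc_distance(e_syn / syn_sites)


def calibrate_config(
    config: SimulationConfig,
    background_dnds: float = 1.7,
    soldier_subset_dnds: float = 4.3,
) -> SimulationConfig:
    """Solve the enrichment multipliers so the expected pooled dN/dS hits the
    requested background (all libraries, whole transcriptome) and
    soldier-subset values, and return the calibrated config.

    The solution is analytic in expectation (no simulation): the expected
    class mix of planted changes is a closed function of the reference and
    the multipliers and is strictly increasing in the nonsynonymous odds.
    """
    reference, design = generate_reference(config)
    coding_table = build_coding_table(reference)
    prep = prepare_sites(reference, config, coding_table)
    whole = list(reference)
    subset = sorted(design.subset_ids)
    if not subset:
        raise ConfigurationError("cannot calibrate soldier enrichment with an empty subset")

    def f_background(log_e):
        e = math.exp(log_e)
        return expected_pooled_dnds(coding_table, prep, whole, config, e) - background_dnds

    e_background = math.exp(brentq(f_background, -12.0, 12.0, xtol=1e-12))

    def f_soldier(log_e):
        e = math.exp(log_e)
        try:
            ratio = expected_pooled_dnds(
                coding_table, prep, subset, config,
                e_background, e, design.subset_ids,
            )
        except SaturationError:
            # p_N beyond the JC domain: the ratio is far above any target.
            return 1e9
        return ratio - soldier_subset_dnds

    e_soldier = math.exp(brentq(f_soldier, math.log(e_background), 14.0, xtol=1e-12))
    return replace(
        config,
        nonsyn_enrichment=e_background,
        soldier_nonsyn_enrichment=max(1.0, e_soldier / e_background),
    )
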