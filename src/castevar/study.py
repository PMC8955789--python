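"""Study-level model and results.

``SelectionStudy`` is the model object: it is built from a reference
transcriptome, per-library SNV sets with caste/population labels and an
optional caste-associated transcript subset, and holds the analysis
settings (depth filter, dN/dS mode, post-hoc adjustment).  ``fit()`` runs
the full downstream analysis — depth filtering, SNV counts, ts/tv, SBS-6/96
catalogues, pooled dN/dS per library (whole transcriptome and subset), and
the caste/population group tests — and returns a ``SelectionStudyResults``
carrying tidy tables, a text ``summary()`` and a ``save()`` writer.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .catalogue import SBS96Catalogue, build_sbs6, build_sbs96, catalogue_matrix
from .errors import ConfigurationError, DegenerateInputError
from .selection import build_coding_table, estimate_dnds
from .simulate import SimulationConfig, generate_study, plant_variants
from .stats import anova_oneway, dunn_posthoc, kruskal_wallis, tukey_hsd
from .variants import LibraryVariants, count_snvs, filter_by_depth, read_snvs, titv_ratio


def read_reference(path: str | os.PathLike) -> dict[str, str]:
    """Load a multi-FASTA reference transcriptome as {id: sequence}."""
    reference = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not reference:
        raise ConfigurationError(f"no FASTA records in {path}")
    return reference


def read_subset(path: str | os.PathLike) -> set[str]:
    """Load a one-transcript-ID-per-line subset file."""
    lines = Path(path).read_text().split()
    return {line.strip() for line in lines if line.strip()}


class SelectionStudy:
    """Model for a 9-library caste x population variant study.

    Parameters
    ----------
    reference : mapping of transcript id to sequence.
    libraries : labelled per-library SNV sets (unfiltered).
    subset_ids : caste-associated transcript subset, or None.
    min_depth, strict_depth : read-depth filter (keep depth > min_depth when
        strict, >= otherwise).
    dnds_mode : 'pooled' (counts summed within a library before
        normalisation) or 'per-transcript'.
    adjustment : p-value adjustment for Dunn's post-hoc.
    """

    def __init__(
        self,
        reference: dict[str, str],
        libraries: list[LibraryVariants],
        subset_ids: set[str] | None = None,
        *,
        min_depth: int = 10,
        strict_depth: bool = True,
        dnds_mode: str = "pooled",
        adjustment: str = "fdr_bh",
    ):
        if not libraries:
            raise ConfigurationError("no libraries given")
        if subset_ids is not None:
            missing = set(subset_ids) - set(reference)
            if missing:
                raise ConfigurationError(
                    f"subset transcripts absent from reference: {sorted(missing)[:5]}"
                )
        self.reference = reference
        self.libraries = libraries
        self.subset_ids = set(subset_ids) if subset_ids is not None else None
        self.min_depth = min_depth
        self.strict_depth = strict_depth
        self.dnds_mode = dnds_mode
        self.adjustment = adjustment

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        reference_fasta: str | os.PathLike,
        vcfs: list[str | os.PathLike] | str | os.PathLike,
        metadata_tsv: str | os.PathLike,
        subset_path: str | os.PathLike | None = None,
        **kwargs,
    ) -> "SelectionStudy":
        """Build a study from a reference FASTA, per-library VCFs (a list or
        a directory) and a library metadata TSV."""
        if isinstance(vcfs, (str, os.PathLike)) and Path(vcfs).is_dir():
            vcf_paths = sorted(Path(vcfs).glob("*.vcf")) + sorted(Path(vcfs).glob("*.vcf.gz"))
        elif isinstance(vcfs, (str, os.PathLike)):
            vcf_paths = [Path(vcfs)]
        else:
            vcf_paths = [Path(p) for p in vcfs]
        if not vcf_paths:
            raise ConfigurationError("no VCF files found")
        meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
        required = {"library_id", "caste", "population"}
        if not required <= set(meta.columns):
            raise ConfigurationError(
                f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
            )
        meta = meta.set_index("library_id")
        orphans = [
            p.name for p in vcf_paths
            if p.name.removesuffix(".gz").removesuffix(".vcf") not in meta.index
        ]
        if orphans:
            raise ConfigurationError(f"VCFs without metadata: {orphans}")
        reference = read_reference(reference_fasta)
        libraries = []
        for p in vcf_paths:
            lid = p.name.removesuffix(".gz").removesuffix(".vcf")
            libraries.append(
                read_snvs(
                    p,
                    library_id=lid,
                    caste=meta.loc[lid, "caste"],
                    population=meta.loc[lid, "population"],
                )
            )
        subset = read_subset(subset_path) if subset_path else None
        return cls(reference, libraries, subset, **kwargs)

    @classmethod
    def from_simulation(cls, config: SimulationConfig, **kwargs) -> "SelectionStudy":
        """Build a study in memory from the synthetic generator."""
        from .simulate import generate_reference, prepare_sites

        reference, design = generate_reference(config)
        sites = prepare_sites(reference, config)
        libraries = [
            plant_variants(reference, design, config, m.library_id, sites=sites)[0]
            for m in design.libraries
        ]
        return cls(reference, libraries, set(design.subset_ids), **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "SelectionStudyResults":
        coding_table = build_coding_table(self.reference)
        lib_rows = []
        dnds_rows = []
        sbs6 = {}
        sbs96: dict[str, SBS96Catalogue] = {}
        for lib in self.libraries:
            filtered = filter_by_depth(lib, self.min_depth, strict=self.strict_depth)
            ratio = titv_ratio(filtered)
            row = {
                "library_id": lib.library_id,
                "caste": lib.caste,
                "population": lib.population,
                "n_raw": count_snvs(lib),
                "n_snv": count_snvs(filtered),
                "titv": np.nan if ratio is None else ratio,
            }
            sbs6[lib.library_id] = build_sbs6(filtered)
            sbs96[lib.library_id] = build_sbs96(filtered, self.reference)
            scopes = [("whole", None)]
            if self.subset_ids is not None:
                scopes.append(("subset", self.subset_ids))
            for scope, subset in scopes:
                try:
                    est = estimate_dnds(
                        filtered, self.reference, subset,
                        coding_table=coding_table, mode="pooled",
                    )
                except DegenerateInputError:
                    est = None
                dnds_rows.append(
                    {
                        "library_id": lib.library_id,
                        "scope": scope,
                        "p_s": est.p_s if est else np.nan,
                        "p_n": est.p_n if est else np.nan,
                        "d_s": est.d_s if est else np.nan,
                        "d_n": est.d_n if est else np.nan,
                        "dnds": est.ratio if est and est.ratio is not None else np.nan,
                        "n_syn": est.n_syn if est else 0,
                        "n_nonsyn": est.n_nonsyn if est else 0,
                        "n_stopgain": est.n_stopgain if est else 0,
                        "n_noncoding": est.n_noncoding if est else 0,
                    }
                )
                if scope == "whole":
                    row["dnds_whole"] = est.ratio if est and est.ratio is not None else np.nan
                else:
                    row["dnds_subset"] = est.ratio if est and est.ratio is not None else np.nan
            lib_rows.append(row)

        per_library = pd.DataFrame(lib_rows)
        dnds = pd.DataFrame(dnds_rows)
        per_transcript = None
        if self.dnds_mode == "per-transcript":
            pt_rows = []
            for lib in self.libraries:
                filtered = filter_by_depth(lib, self.min_depth, strict=self.strict_depth)
                ests = estimate_dnds(
                    filtered, self.reference, None,
                    coding_table=coding_table, mode="per-transcript",
                )
                for tid, est in ests.items():
                    pt_rows.append(
                        {
                            "library_id": lib.library_id,
                            "transcript_id": tid,
                            "p_s": est.p_s,
                            "p_n": est.p_n,
                            "dnds": est.ratio if est.ratio is not None else np.nan,
                        }
                    )
            per_transcript = pd.DataFrame(pt_rows)

        tests = self._group_tests(per_library)
        table1 = summarize_table1(per_library)
        return SelectionStudyResults(
            model=self,
            per_library=per_library,
            dnds=dnds,
            sbs6=sbs6,
            sbs96=sbs96,
            tests=tests,
            table1=table1,
            per_transcript=per_transcript,
        )

    def _group_tests(self, per_library: pd.DataFrame) -> pd.DataFrame:
        rows = []

        def grouped(measure: str, grouping: str):
            out = {}
            for label, sub in per_library.groupby(grouping):
                vals = sub[measure].dropna().tolist()
                if vals:
                    out[str(label)] = vals
            return out

        def add_omnibus(measure, grouping, result):
            rows.append(
                {
                    "measure": measure, "grouping": grouping, "test": result.test,
                    "statistic": result.statistic,
                    "df": _fmt_df(result.df),
                    "p": result.p_value if result.p_value is not None else np.nan,
                    "pair": "", "estimate": np.nan, "p_adj": np.nan,
                }
            )

        def add_pairwise(measure, grouping, result):
            for c in result.pairwise or []:
                rows.append(
                    {
                        "measure": measure, "grouping": grouping, "test": result.test,
                        "statistic": np.nan, "df": "",
                        "p": c.p_raw, "pair": f"{c.label_a}-{c.label_b}",
                        "estimate": c.estimate, "p_adj": c.p_adj,
                    }
                )

        for grouping in ("caste", "population"):
            g = grouped("n_snv", grouping)
            if len(g) >= 2:
                add_omnibus("snv_count", grouping, kruskal_wallis(g))
                add_pairwise("snv_count", grouping, dunn_posthoc(g, self.adjustment))
            g = grouped("titv", grouping)
            if len(g) >= 2:
                add_omnibus("titv", grouping, anova_oneway(g))
            for measure in ("dnds_whole", "dnds_subset"):
                if measure not in per_library.columns:
                    continue
                g = grouped(measure, grouping)
                if len(g) >= 2:
                    add_omnibus(measure, grouping, anova_oneway(g))
                    add_pairwise(measure, grouping, tukey_hsd(g))
        return pd.DataFrame(rows)


def _fmt_df(df) -> str:
    if df is None:
        return ""
    if isinstance(df, tuple):
        return f"{df[0]},{df[1]}"
    return str(df)


def summarize_table1(per_library: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample SD (n-1) of SNV counts by caste and by population."""
    rows = []
    for grouping in ("caste", "population"):
        for label, sub in per_library.groupby(grouping, sort=False):
            vals = sub["n_snv"].to_numpy(dtype=float)
            rows.append(
                {
                    "grouping": grouping,
                    "label": str(label),
                    "n_libraries": len(vals),
                    "snv_count_mean": float(np.mean(vals)),
                    "snv_count_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SelectionStudyResults:
    """Fitted results of a SelectionStudy."""

    model: SelectionStudy
    per_library: pd.DataFrame
    dnds: pd.DataFrame
    sbs6: dict
    sbs96: dict[str, SBS96Catalogue]
    tests: pd.DataFrame
    table1: pd.DataFrame
    per_transcript: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Caste/population SNV selection study", "=" * 44]
        lines.append(f"libraries: {len(self.per_library)}   "
                     f"min_depth > {self.model.min_depth} (strict={self.model.strict_depth})")
        lines.append("")
        lines.append("Per-library summary (filtered SNVs):")
        lines.append(
            self.per_library.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            )
        )
        lines.append("")
        lines.append("SNV count mean +/- SD by group:")
        lines.append(self.table1.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
        lines.append("")
        lines.append("Group tests (omnibus rows, then post-hoc pairs):")
        lines.append(self.tests.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def save(self, out_dir: str | os.PathLike, extra_manifest: dict | None = None) -> dict:
        """Write all report tables as TSV plus a machine-readable manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ff = "%.12g"
        paths = {}

        def write(df: pd.DataFrame, name: str):
            p = out / name
            df.to_csv(p, sep="\t", index=False, float_format=ff)
            paths[name] = str(p)

        write(self.per_library, "per_library_summary.tsv")
        write(self.dnds, "dnds_estimates.tsv")
        sbs6_long = pd.DataFrame(
            [
                {"library_id": lid, "class": cls, "count": n}
                for lid, cat in self.sbs6.items()
                for cls, n in cat.counts.items()
            ]
        )
        write(sbs6_long, "sbs6_catalogues.tsv")
        mat = catalogue_matrix(self.sbs96).reset_index()
        write(mat, "sbs96_matrix.tsv")
        excl = pd.DataFrame(
            [
                {
                    "library_id": lid,
                    "n_edge_excluded": cat.n_edge_excluded,
                    "n_ref_mismatch": cat.n_ref_mismatch,
                }
                for lid, cat in self.sbs96.items()
            ]
        )
        write(excl, "sbs96_exclusions.tsv")
        write(self.tests, "group_tests.tsv")
        write(self.table1, "table1_summary.tsv")
        if self.per_transcript is not None:
            write(self.per_transcript, "dnds_per_transcript.tsv")

        manifest = {
            "castevar_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "min_depth": self.model.min_depth,
            "strict_depth": self.model.strict_depth,
            "dnds_mode": self.model.dnds_mode,
            "adjustment": self.model.adjustment,
            "sd_convention": "sample (n-1)",
            "outputs": paths,
        }
        if extra_manifest:
            manifest.update(extra_manifest)
        mp = out / "run_manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        manifest["manifest"] = str(mp)
        return manifest


# --- pipeline driver -------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate a study, or ingest VCFs)."""

    mode: str = "simulate"  # "simulate" | "ingest"
    out_dir: str = "castevar_run"
    reference: str | None = None
    vcf_dir: str | None = None
    metadata: str | None = None
    subset: str | None = None
    min_depth: int = 10
    strict_depth: bool = True
    dnds_mode: str = "pooled"
    adjustment: str = "fdr_bh"
    seed: int = 0
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigurationError(f"mode must be simulate or ingest, got {self.mode!r}")
        if self.mode == "ingest":
            missing = [
                name for name, v in (
                    ("reference", self.reference),
                    ("vcf_dir", self.vcf_dir),
                    ("metadata", self.metadata),
                ) if not v
            ]
            if missing:
                raise ConfigurationError(f"ingest mode requires paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config {path} is not a key: value mapping")
        sim_data = data.pop("simulation", None)
        sim_flat = {
            k.removeprefix("simulation_"): v
            for k, v in list(data.items())
            if k.startswith("simulation_")
        }
        for k in list(data):
            if k.startswith("simulation_"):
                data.pop(k)
        known = set(cls.__dataclass_fields__) - {"simulation"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        sim = None
        if sim_data or sim_flat:
            merged = dict(sim_data or {}, **sim_flat)
            sim_known = set(SimulationConfig.__dataclass_fields__)
            bad = set(merged) - sim_known
            if bad:
                raise ConfigurationError(f"unknown simulation keys: {sorted(bad)}")
            for key in ("orf_codons_range", "utr_len_range"):
                if key in merged and isinstance(merged[key], list):
                    merged[key] = tuple(merged[key])
            sim = SimulationConfig(**merged)
        return cls(simulation=sim, **data)


def run_study(cfg: PipelineConfig) -> dict:
    """Run the full study per configuration and return the report manifest.

    In simulate mode the synthetic study files are written first and then
    ingested through the same file-reading path as real data, so a later
    ingest run pointed at those files reproduces the reports exactly.
    """
    cfg.validate()
    out = Path(cfg.out_dir)

    if cfg.mode == "simulate":
        sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
        if cfg.simulation is None or cfg.seed != 0:
            sim = SimulationConfig(**{**sim.__dict__, "seed": cfg.seed or sim.seed})
        study_manifest = generate_study(sim, out / "study")
        reference = study_manifest["reference"]
        vcfs = sorted(study_manifest["vcfs"].values())
        metadata = study_manifest["metadata"]
        subset = study_manifest["subset"]
    else:
        reference = cfg.reference
        vcfs = cfg.vcf_dir
        metadata = cfg.metadata
        subset = cfg.subset
        study_manifest = None

    model = SelectionStudy.from_files(
        reference, vcfs, metadata, subset,
        min_depth=cfg.min_depth,
        strict_depth=cfg.strict_depth,
        dnds_mode=cfg.dnds_mode,
        adjustment=cfg.adjustment,
    )
    results = model.fit()
    report_manifest = results.save(
        out / "reports", extra_manifest={"seed": cfg.seed, "mode": cfg.mode}
    )
    manifest = {"reports": report_manifest}
    if study_manifest is not None:
        manifest["study"] = study_manifest
    return manifest
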