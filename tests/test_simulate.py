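"""Synthetic-study generator: construction, determinism, planted truth."""

import filecmp
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
import scipy.stats

from castevar import (
    ConfigurationError,
    GenerationError,
    SimulationConfig,
    generate_reference,
    generate_study,
    plant_variants,
    read_snvs,
)
from castevar.selection import STOP_CODONS, classify_snv, build_coding_table
from castevar.simulate import CASTES, POPULATIONS, prepare_sites


class TestGenerateReference:
    def test_minimal_transcript_is_nine_nt(self):
        cfg = SimulationConfig(
            n_transcripts=1, orf_codons_range=(1, 1), utr_len_range=(0, 0), seed=4
        )
        reference, _ = generate_reference(cfg)
        (seq,) = reference.values()
        assert len(seq) == 9
        assert seq.startswith("ATG") and seq[-3:] in STOP_CODONS

    def test_embedded_orf_is_longest(self, small_study):
        reference, _, coding_table, _ = small_study
        # re-scan: every transcript's longest ORF is the planted one by
        # construction (starts with ATG right after the 5'UTR)
        for tid, coding in coding_table.items():
            assert coding.orf is not None
            cds = reference[tid][coding.orf.start - 1 : coding.orf.end]
            assert cds.startswith("ATG")

    def test_subset_size_and_membership(self):
        cfg = SimulationConfig(
            n_transcripts=100, orf_codons_range=(5, 10), utr_len_range=(0, 10),
            subset_fraction=0.1, seed=9,
        )
        reference, design = generate_reference(cfg)
        assert len(design.subset_ids) == 10
        assert design.subset_ids <= set(reference)

    def test_design_covers_grid(self, small_study):
        _, design, _, _ = small_study
        assert len(design.libraries) == 9
        assert {(m.caste, m.population) for m in design.libraries} == {
            (c, p) for c in CASTES for p in POPULATIONS
        }

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.2])
    def test_impossible_composition_rejected(self, gc):
        with pytest.raises(ConfigurationError):
            generate_reference(SimulationConfig(gc_content=gc))


class TestPlantVariants:
    def test_exact_count_unique_sites_alt_differs(self, small_study, small_config):
        reference, design, _, prep = small_study
        lib, truth = plant_variants(
            reference, design, small_config, "Raleigh_nymph", sites=prep
        )
        assert len(lib.records) == small_config.variants_per_library
        sites = [(r.transcript_id, r.pos) for r in lib.records]
        assert len(set(sites)) == len(sites)
        assert all(r.ref != r.alt for r in lib.records)
        assert all(reference[r.transcript_id][r.pos - 1] == r.ref for r in lib.records)
        assert len(truth) == len(lib.records)

    def test_planted_labels_agree_with_classifier(self, small_study, small_config):
        reference, design, coding_table, prep = small_study
        lib, truth = plant_variants(
            reference, design, small_config, "Toronto_soldier", sites=prep
        )
        for rec, row in zip(lib.records, truth):
            got = classify_snv(coding_table[rec.transcript_id].orf, rec, reference)
            assert got == row.klass

    def test_truth_classes_partition(self, small_study, small_config):
        reference, design, _, prep = small_study
        _, truth = plant_variants(
            reference, design, small_config, "Boston_worker", sites=prep
        )
        classes = Counter(t.klass for t in truth)
        assert set(classes) <= {"synonymous", "nonsynonymous", "stopgain", "noncoding"}
        assert sum(classes.values()) == small_config.variants_per_library

    def test_unknown_library_rejected(self, small_study, small_config):
        reference, design, _, prep = small_study
        with pytest.raises(ConfigurationError):
            plant_variants(reference, design, small_config, "Paris_queen", sites=prep)

    def test_too_many_variants_rejected(self):
        cfg = SimulationConfig(
            n_transcripts=2, orf_codons_range=(2, 2), utr_len_range=(0, 0),
            variants_per_library=1000, seed=1,
        )
        reference, design = generate_reference(cfg)
        with pytest.raises(GenerationError):
            plant_variants(reference, design, cfg, "Raleigh_nymph")

    def test_null_enrichment_subset_symmetry(self):
        """With soldier_nonsyn_enrichment=1 the syn/nonsyn mix of subset and
        non-subset transcripts is statistically indistinguishable."""
        failures = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_transcripts=60, orf_codons_range=(20, 60), utr_len_range=(5, 30),
                variants_per_library=3000, subset_fraction=0.3,
                soldier_nonsyn_enrichment=1.0, seed=100 + seed,
            )
            reference, design = generate_reference(cfg)
            _, truth = plant_variants(reference, design, cfg, "Raleigh_soldier")
            table = np.zeros((2, 2))
            for row in truth:
                if row.klass not in ("synonymous", "nonsynonymous"):
                    continue
                i = 1 if row.transcript in design.subset_ids else 0
                j = 1 if row.klass == "nonsynonymous" else 0
                table[i, j] += 1
            p = scipy.stats.chi2_contingency(table)[1]
            if p <= 0.01:
                failures += 1
        assert failures <= 1

    def test_population_count_multiplier(self, small_study, small_config):
        reference, design, _, prep = small_study
        cfg = replace(small_config, population_count_multipliers={"Boston": 0.5})
        lib, _ = plant_variants(reference, design, cfg, "Boston_nymph", sites=prep)
        assert len(lib.records) == small_config.variants_per_library // 2


class TestGenerateStudy:
    CFG = SimulationConfig(
        n_transcripts=25, orf_codons_range=(10, 30), utr_len_range=(0, 20),
        variants_per_library=300, seed=21,
    )

    def test_manifest_and_conservation(self, tmp_path):
        manifest = generate_study(self.CFG, tmp_path / "study")
        assert len(manifest["vcfs"]) == 9
        truth_lines = (
            (tmp_path / "study" / "ground_truth.tsv").read_text().strip().splitlines()
        )
        assert len(truth_lines) == 1 + 9 * self.CFG.variants_per_library
        for lib_id, vcf in manifest["vcfs"].items():
            lib = read_snvs(vcf)
            assert len(lib.records) == self.CFG.variants_per_library
            assert lib.library_id == lib_id

    def test_byte_identical_determinism(self, tmp_path):
        m1 = generate_study(self.CFG, tmp_path / "a")
        m2 = generate_study(self.CFG, tmp_path / "b")
        for key in ("reference", "metadata", "subset", "ground_truth"):
            assert filecmp.cmp(m1[key], m2[key], shallow=False), key
        for lib_id in m1["vcfs"]:
            assert filecmp.cmp(m1["vcfs"][lib_id], m2["vcfs"][lib_id], shallow=False)

    def test_different_seed_differs(self, tmp_path):
        m1 = generate_study(self.CFG, tmp_path / "a")
        m2 = generate_study(replace(self.CFG, seed=self.CFG.seed + 1), tmp_path / "c")
        assert any(
            not filecmp.cmp(m1["vcfs"][k], m2["vcfs"][k], shallow=False)
            for k in m1["vcfs"]
        )

    def test_zero_variants_gives_valid_empty_vcfs(self, tmp_path):
        cfg = replace(self.CFG, variants_per_library=0)
        manifest = generate_study(cfg, tmp_path / "empty")
        for vcf in manifest["vcfs"].values():
            assert len(read_snvs(vcf).records) == 0

    def test_depth_filter_oracle_recount(self, tmp_path):
        """Retained count equals a brute-force recount of depths > 10."""
        from castevar import filter_by_depth

        manifest = generate_study(self.CFG, tmp_path / "study")
        for vcf in manifest["vcfs"].values():
            lib = read_snvs(vcf)
            expected = sum(1 for r in lib.records if r.depth > 10)
            assert len(filter_by_depth(lib, 10).records) == expected
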