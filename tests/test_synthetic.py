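"""Synthetic-data generators: determinism, structural validity, truth-label
soundness and cohort statistics."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from exomefunnel.consequence import annotate
from exomefunnel.errors import ConfigError
from exomefunnel.funnel import run_funnel_calls, subtract_known, subtract_shared
from exomefunnel.segregation import build_cross_table, classify_hearing
from exomefunnel.synthetic import (
    CohortConfig,
    ScenarioConfig,
    generate_cohort,
    generate_reference_and_genes,
    generate_validation_genotypes,
    generate_variant_scenario,
)
from exomefunnel.variants import read_gene_models, read_variant_calls, variant_key


@pytest.fixture(scope="module")
def scenario():
    return generate_variant_scenario(ScenarioConfig(seed=42))


class TestReferenceAndGenes:
    def test_all_transcripts_pass_validation(self):
        models = generate_reference_and_genes(ScenarioConfig(seed=5))
        models.validate()
        coding = [t for t in models.transcripts if t.biotype == "protein_coding"]
        assert coding, "expected protein-coding genes"
        for t in coding:
            cds = models.coding_sequence(t)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG") and cds[-3:] in ("TAA", "TAG", "TGA")

    def test_no_genes_config(self):
        models = generate_reference_and_genes(ScenarioConfig(seed=0, n_genes=0))
        assert models.transcripts == []
        assert len(models.reference) == 2

    def test_deterministic_per_seed(self):
        a = generate_reference_and_genes(ScenarioConfig(seed=9))
        b = generate_reference_and_genes(ScenarioConfig(seed=9))
        assert a.reference == b.reference
        assert [(t.transcript_id, t.exons, t.cds, t.strand) for t in a.transcripts] == [
            (t.transcript_id, t.exons, t.cds, t.strand) for t in b.transcripts
        ]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ConfigError):
            generate_reference_and_genes(
                ScenarioConfig(seed=0, chromosome_length=2_000, n_genes=40)
            )


class TestScenario:
    def test_truth_covers_every_mutant_call(self, scenario):
        assert len(scenario.truth) == len(scenario.mutant_calls)
        assert set(scenario.truth["label"]) <= {
            "shared", "panel", "low_quality", "noncoding", "synonymous",
            "indel", "indel_artifact", "causal",
        }
        assert (scenario.truth["label"] == "causal").sum() == 1

    def test_causal_call_is_a_confident_het_missense(self, scenario):
        causal = scenario.causal
        assert causal.genotype == "het"
        assert causal.snp_quality >= 20
        assert causal.mapping_quality > 45 and causal.read_depth > 10
        ann = annotate(causal, scenario.models)
        assert ann.category == "nonsynonymous"
        assert ann.consequence.detail == "Y:C"

    def test_causal_absent_from_background_and_panels(self, scenario):
        key = variant_key(scenario.causal)
        assert key not in {variant_key(v) for v in scenario.background_calls}
        for panel in scenario.panels:
            assert key not in {variant_key(v) for v in panel}

    def test_truth_label_soundness_under_subtraction(self, scenario):
        """No shared call survives background subtraction; no panel call
        survives panel subtraction."""
        private = subtract_shared(scenario.mutant_calls, scenario.background_calls)
        labels = {scenario.truth_label(v) for v in private}
        assert "shared" not in labels
        unknown = subtract_known(private, scenario.panels)
        assert "panel" not in {scenario.truth_label(v) for v in unknown}
        # everything not shared/panel survives both subtractions
        assert len(unknown) == (~scenario.truth["label"].isin(["shared", "panel"])).sum()

    def test_minimal_scenario_is_just_the_causal_call(self):
        cfg = ScenarioConfig(
            seed=1, n_shared_variants=0, n_panel_variants=0, n_panel_only=0,
            n_background_private=0, n_low_quality=0, n_noncoding=0,
            n_synonymous=0, n_indel_clusters=0,
        )
        sc = generate_variant_scenario(cfg)
        assert len(sc.mutant_calls) == 1
        assert sc.truth_label(sc.mutant_calls[0]) == "causal"

    def test_funnel_recovers_planted_causal(self, scenario):
        val = generate_validation_genotypes(scenario)
        report = run_funnel_calls(
            scenario.mutant_calls, scenario.background_calls,
            scenario.panels, scenario.models, validation=val,
        )
        assert variant_key(scenario.causal) in {
            variant_key(c.variant) for c in report.candidates
        }
        assert [variant_key(c.variant) for c in report.confirmed] == [
            variant_key(scenario.causal)
        ]

    def test_artifact_cluster_flagged_causal_unflagged(self, scenario):
        val = generate_validation_genotypes(scenario)
        report = run_funnel_calls(
            scenario.mutant_calls, scenario.background_calls,
            scenario.panels, scenario.models, validation=val,
        )
        flags = {f.candidate_key: f.flagged for f in report.proximity_flags}
        for c in report.candidates:
            key = variant_key(c.variant)
            label = scenario.truth_label(c.variant)
            if label == "indel_artifact":
                assert flags[key], "artifact SNV next to its indel must be flagged"
            if label == "causal":
                assert not flags[key], "isolated causal SNV must not be flagged"

    def test_underpowered_causal_fails_stage_b(self):
        cfg = ScenarioConfig(seed=3, causal_qualities=(199.0, 228.0, 60.0, 10))
        sc = generate_variant_scenario(cfg)
        report = run_funnel_calls(
            sc.mutant_calls, sc.background_calls, sc.panels, sc.models
        )
        assert variant_key(sc.causal) not in {
            variant_key(c.variant) for c in report.candidates
        }

    def test_funnel_report_idempotent_byte_for_byte(self, scenario):
        val = generate_validation_genotypes(scenario)
        args = (
            scenario.mutant_calls, scenario.background_calls,
            scenario.panels, scenario.models,
        )
        a = run_funnel_calls(*args, validation=val).to_tsv()
        b = run_funnel_calls(*args, validation=val).to_tsv()
        assert a == b


class TestScenarioFiles:
    def test_outputs_byte_identical_per_seed(self, tmp_path):
        h = []
        for d in ("run1", "run2"):
            out = tmp_path / d
            generate_variant_scenario(ScenarioConfig(seed=17)).write(out)
            h.append(
                {
                    p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(Path(out).iterdir())
                }
            )
        assert h[0] == h[1]
        assert {"genome.fa", "genes.gff3", "mutant.vcf", "validation.tsv"} <= set(h[0])

    def test_files_round_trip_through_readers(self, tmp_path):
        sc = generate_variant_scenario(ScenarioConfig(seed=23))
        paths = sc.write(tmp_path)
        assert read_variant_calls(paths["mutant"]) == sc.mutant_calls
        models = read_gene_models(paths["gff3"], paths["fasta"])
        assert len(models.transcripts) == len(sc.models.transcripts)
        assert models.reference == sc.models.reference


class TestValidationGenotypes:
    def test_patterns_by_truth_label(self, scenario):
        val = {v.key: v for v in generate_validation_genotypes(scenario)}
        for call in scenario.mutant_calls:
            rec = val[variant_key(call)]
            label = scenario.truth_label(call)
            if label == "causal":
                assert rec.mutant_has_alt() and not rec.background_has_alt()
            elif label == "indel_artifact":
                assert rec.background_call == "deletion"
                assert rec.mutant_call == "deletion"
            elif label == "low_quality":
                assert rec.mutant_call == rec.background_call
                assert not rec.mutant_has_alt()
            elif label in ("shared", "panel"):
                assert rec.mutant_has_alt() and rec.background_has_alt()


class TestCohort:
    def test_hom_viability_zero_forces_no_homozygotes(self):
        cohort = generate_cohort(CohortConfig(seed=2))
        assert sum(r.genotype == "hom" for r in cohort) == 0
        assert len(cohort) == 111 + 85

    def test_deterministic_per_seed(self):
        assert generate_cohort(CohortConfig(seed=4)) == generate_cohort(CohortConfig(seed=4))

    def test_affected_fraction_converges_to_true_penetrance(self):
        cfg = CohortConfig(seed=7, n_het_x_het=0, n_het_x_wt=10_000)
        cohort = generate_cohort(cfg)
        hets = [r for r in cohort if r.genotype == "het"]
        assert len(hets) >= 4_000
        frac = np.mean(
            [classify_hearing(r.click_threshold) == "affected" for r in hets]
        )
        se = np.sqrt(cfg.pi_affected * (1 - cfg.pi_affected) / len(hets))
        assert abs(frac - cfg.pi_affected) <= 2 * se

    def test_thresholds_respect_class_boundaries(self):
        cohort = generate_cohort(CohortConfig(seed=9))
        for r in cohort:
            assert 0.0 <= r.click_threshold <= 97.0
            if r.genotype == "wt":
                assert r.click_threshold < 50.0  # wild types never reach 'affected'

    def test_simulated_intercross_resembles_published_het_row(self):
        """Class counts among simulated het x het heterozygotes are
        chi-square-compatible (alpha = 0.01) with the published het row in
        >= 95% of seeds."""
        expected = np.array([32, 21, 19]) / 72
        ok = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cohort = generate_cohort(CohortConfig(seed=seed))
            table = build_cross_table(cohort, "het_x_het")
            obs = table.counts.loc["het"].to_numpy()
            p = stats.chisquare(obs, f_exp=obs.sum() * expected).pvalue
            ok += p > 0.01
        assert ok / n_seeds >= 0.95

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(pi_affected=0.7, pi_intermediate=0.5).validate()
        with pytest.raises(ConfigError):
            CohortConfig(hom_viability=1.5).validate()
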