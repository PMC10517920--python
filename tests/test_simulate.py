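"""Synthetic cohort generator: determinism, HWE sampling, planted truth."""

import math

import numpy as np
import pytest

from lsdincidence.acmg import classify
from lsdincidence.cohort import read_cohort_vcf
from lsdincidence.evidence import is_candidate, severity_score
from lsdincidence.panel import GenePanelEntry, Inheritance, read_panel, write_panel
from lsdincidence.simulate import (
    SyntheticSpecError,
    SyntheticTruth,
    SyntheticVariant,
    default_truth,
    emit_evidence,
    expected_report,
    generate_panel,
    read_truth,
    simulate_genotypes,
    write_truth,
)


def _truth(variants, n=1000, seed=3):
    return SyntheticTruth(variants=tuple(variants), n_individuals=n, seed=seed)


def _single_gene_panel():
    return [
        GenePanelEntry("SG", "Synthetic disorder", Inheritance.AR, "NM_S",
                       "1", ((1000, 1399),))
    ]


class TestGeneratePanel:
    def test_deterministic_and_valid(self, tmp_path):
        p1 = generate_panel(2, exons_per_gene=3, seed=7)
        p2 = generate_panel(2, exons_per_gene=3, seed=7)
        assert p1 == p2
        assert len(p1) == 2
        assert sum(len(e.exon_intervals) for e in p1) == 6
        # round-trips through the panel module's own validation
        path = tmp_path / "panel.json"
        write_panel(p1, path)
        assert read_panel(path) == p1

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            generate_panel(0)

    def test_xl_and_shared_disease_layout(self):
        panel = generate_panel(6, seed=1, n_xl=2, shared_disease_pairs=1)
        assert sum(e.inheritance is Inheritance.XL for e in panel) == 2
        ar_diseases = [e.disease_name for e in panel
                       if e.inheritance is Inheritance.AR]
        assert len(ar_diseases) - len(set(ar_diseases)) == 1


class TestSimulateGenotypes:
    def test_byte_identical_under_same_seed(self, tmp_path):
        panel = _single_gene_panel()
        truth = _truth(
            [SyntheticVariant("SG", 1010, "A", "G", 0.01, "P", "clinvar_pathogenic")]
        )
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        simulate_genotypes(truth, panel, a)
        simulate_genotypes(truth, panel, b)
        assert a.read_bytes() == b.read_bytes()

    def test_zero_frequency_all_reference(self, tmp_path):
        panel = _single_gene_panel()
        truth = _truth(
            [SyntheticVariant("SG", 1010, "A", "G", 0.0, "P", "clinvar_pathogenic")]
        )
        path = simulate_genotypes(truth, panel, tmp_path / "z.vcf")
        (v,) = read_cohort_vcf(path, panel)
        assert v.allele_count == 0

    def test_half_frequency_heterozygote_fraction(self, tmp_path):
        """At f = 0.5, HWE gives E[het] = 0.5; check within 3 binomial SE."""
        panel = _single_gene_panel()
        n = 10_000
        truth = _truth(
            [SyntheticVariant("SG", 1010, "A", "G", 0.5, "P", "clinvar_pathogenic")],
            n=n, seed=11,
        )
        path = simulate_genotypes(truth, panel, tmp_path / "h.vcf")
        text = path.read_text().splitlines()[-1]
        n_het = text.count("0/1")
        se = math.sqrt(0.5 * 0.5 / n)
        assert abs(n_het / n - 0.5) < 3 * se

    def test_recovered_af_close_to_planted(self, tmp_path):
        """Planted f = 0.01 at n = 1495 is recovered within 3 binomial SE."""
        panel = _single_gene_panel()
        f, n = 0.01, 1495
        truth = _truth(
            [SyntheticVariant("SG", 1010, "A", "G", f, "P", "clinvar_pathogenic")],
            n=n, seed=5,
        )
        path = simulate_genotypes(truth, panel, tmp_path / "r.vcf")
        (v,) = read_cohort_vcf(path, panel)
        se = math.sqrt(f * (1 - f) / (2 * n))
        assert abs(float(v.allele_frequency) - f) < 3 * se

    def test_frequency_at_one_rejected(self):
        with pytest.raises(SyntheticSpecError):
            SyntheticVariant("SG", 1010, "A", "G", 1.0, "P", "clinvar_pathogenic")


class TestEmitEvidence:
    def test_templates_recover_planted_classes(self):
        panel = generate_panel(3, seed=0)
        truth = default_truth(panel, seed=0, n_individuals=50)
        records = emit_evidence(truth, panel)
        by_key = {r.variant_key: r for r in records}
        assert len(by_key) == len(truth.variants)
        from lsdincidence.simulate import variant_key

        for v in truth.variants:
            rec = by_key[variant_key(v, panel)]
            decision = is_candidate(rec.variant_key, rec)
            assert decision.accepted == v.is_candidate, v
            if v.is_candidate:
                assert classify(rec.acmg_criteria).acmg_class is v.acmg_class

    def test_benign_template_fails_candidacy(self):
        panel = _single_gene_panel()
        truth = _truth(
            [SyntheticVariant("SG", 1010, "A", "G", 0.01, "B", "clinvar_benign")]
        )
        (rec,) = emit_evidence(truth, panel)
        assert not is_candidate(rec.variant_key, rec).accepted

    def test_lowscore_template_fails_severity_clause(self):
        panel = _single_gene_panel()
        truth = _truth(
            [SyntheticVariant("SG", 1010, "A", "G", 0.001, "VUS",
                              "unreported_lowscore")]
        )
        (rec,) = emit_evidence(truth, panel)
        assert severity_score(rec).score == 4
        decision = is_candidate(rec.variant_key, rec)
        assert not decision.accepted
        assert decision.reason == "unreported_low_severity"

    def test_template_class_mismatch_rejected(self):
        with pytest.raises(SyntheticSpecError, match="incompatible"):
            SyntheticVariant("SG", 1010, "A", "G", 0.01, "B", "clinvar_pathogenic")


class TestExpectedReport:
    def test_single_gene_closed_form(self):
        """Planted pathogenic frequency 0.0065 -> 4.23 per 100,000."""
        panel = _single_gene_panel()
        truth = _truth(
            [SyntheticVariant("SG", 1010, "A", "G", 0.0065, "P",
                              "clinvar_pathogenic")]
        )
        report = expected_report(truth, panel, "conservative")
        assert report["Synthetic disorder"].incidence_per_100k == 4.23

    def test_empty_truth_zero_report(self):
        report = expected_report(_truth([]), _single_gene_panel())
        assert report == {}

    def test_additive_over_diseases_and_modes(self):
        panel = generate_panel(4, seed=2)
        truth = default_truth(panel, seed=0, n_individuals=50)
        cons = expected_report(truth, panel, "conservative")
        ext = expected_report(truth, panel, "extended")
        for disease, rep in cons.items():
            assert ext[disease].q == pytest.approx(rep.q + 0.002)  # one VUS/gene
            assert ext[disease].incidence >= rep.incidence
        total = sum(r.incidence for r in cons.values()) * 1e5
        per_gene_q = np.linspace(0.001, 0.02, 4)
        assert total == pytest.approx(float(np.sum(per_gene_q**2)) * 1e5)

    def test_per_gene_frequency_budget_enforced(self):
        with pytest.raises(SyntheticSpecError, match=">= 1"):
            _truth(
                [
                    SyntheticVariant("SG", 1010 + i, "A", "G", 0.4, "P",
                                     "clinvar_pathogenic")
                    for i in range(3)
                ]
            )


def test_truth_spec_round_trip(tmp_path):
    panel = generate_panel(2, seed=0)
    truth = default_truth(panel, seed=9, n_individuals=77)
    for name in ("t.yaml", "t.json"):
        path = tmp_path / name
        write_truth(truth, path)
        assert read_truth(path) == truth
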