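"""Synthetic cohort generator: seeding, planting, QC noise, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from archvar.carrier_discovery import discover_carriers
from archvar.synthetic_cohort import (
    CategoricalTrait,
    CohortConfig,
    ContinuousTrait,
    EffectSpec,
    PlantError,
    PlantSpec,
    QCNoise,
    dosage_from_carriers,
    generate_genotypes,
    generate_phenotypes,
    generate_samples,
    planted_census,
)
from archvar.variant_catalog import VariantSite

SITE = VariantSite("SSH2", "17", 29632016, "T", "C")
SITEX = VariantSite("TKTL1", "X", 154315258, "G", "A")


class TestConfig:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_cluster={"EUR": -1}, seed=1)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(age_range=(70.0, 40.0)), dict(sex_ratio=1.2),
         dict(related_fraction=-0.1), dict(n_per_cluster={"MARS": 5})],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(n_per_cluster={"EUR": 10}, seed=1)
        base.update(kwargs)
        with pytest.raises(ValueError):
            CohortConfig(**base)


class TestGenerateSamples:
    def test_single_cluster(self):
        samples, _ = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 100}, seed=7)
        )
        assert len(samples) == 100
        assert (samples["generating_cluster"] == "EUR").all()
        assert samples["sample_id"].is_unique
        lo, hi = 40.0, 70.0
        assert samples["age"].between(lo, hi).all()

    def test_no_relatedness_when_fraction_zero(self):
        _, kinship = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 50}, seed=7, related_fraction=0.0)
        )
        assert kinship.empty

    def test_seeding_contract(self):
        cfg = CohortConfig(n_per_cluster={"EUR": 40, "AFR": 20}, seed=9,
                           related_fraction=0.2)
        a_s, a_k = generate_samples(cfg)
        b_s, b_k = generate_samples(cfg)
        pd.testing.assert_frame_equal(a_s, b_s)
        pd.testing.assert_frame_equal(a_k, b_k)
        c_s, _ = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 40, "AFR": 20}, seed=10,
                         related_fraction=0.2)
        )
        assert not a_s.equals(c_s)

    def test_mislabel_fraction_reports_uncategorized(self):
        samples, _ = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 400}, seed=3, mislabel_fraction=0.25)
        )
        frac = (samples["supercluster"] == "Uncategorized").mean()
        assert 0.15 < frac < 0.35

    def test_kinship_pairs_disjoint_by_default(self):
        _, kinship = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 100}, seed=5, related_fraction=0.5)
        )
        ids = pd.concat([kinship["id1"], kinship["id2"]])
        assert ids.is_unique

    def test_kinship_chain_mode_builds_hub(self):
        _, kinship = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 50}, seed=5,
                         related_fraction=0.2, kinship_chain=True)
        )
        assert kinship["id1"].nunique() == 1
        assert len(kinship) > 1


class TestGenerateGenotypes:
    def test_null_plant_has_no_alt_alleles(self, tmp_path):
        samples, _ = generate_samples(CohortConfig(n_per_cluster={"EUR": 20}, seed=1))
        vcf = generate_genotypes(samples, [SITE], PlantSpec(), tmp_path / "g.vcf", seed=1)
        body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 1
        assert "0/1" not in body[0] and "1/1" not in body[0]

    def test_infeasible_plant_names_site_and_stratum(self, tmp_path):
        samples, _ = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 5}, seed=1, sex_ratio=1.0)
        )
        plant = PlantSpec(counts={SITE.key: {("EUR", "female"): {"het": 99}}})
        with pytest.raises(PlantError, match=r"chr17:29632016.*EUR.*female"):
            generate_genotypes(samples, [SITE], plant, tmp_path / "g.vcf", seed=1)

    def test_hemi_class_on_autosome_rejected(self, tmp_path):
        samples, _ = generate_samples(CohortConfig(n_per_cluster={"EUR": 5}, seed=1))
        plant = PlantSpec(
            counts={SITE.key: {("EUR", "male"): {"hemi_alt": 1}}}
        )
        with pytest.raises(PlantError, match="hemi"):
            generate_genotypes(samples, [SITE], plant, tmp_path / "g.vcf", seed=1)

    @pytest.mark.parametrize("dialect,token", [("haploid", "\t1:"), ("diploid", "\t1/1:")])
    def test_male_x_dialects(self, tmp_path, dialect, token):
        samples, _ = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 10}, seed=2, sex_ratio=0.0)
        )
        plant = PlantSpec(counts={SITEX.key: {("EUR", "male"): {"hemi_alt": 10}}})
        vcf = generate_genotypes(
            samples, [SITEX], plant, tmp_path / "g.vcf", seed=2,
            male_x_dialect=dialect,
        )
        body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")][0]
        assert token in body
        res = discover_carriers(vcf, [SITEX], samples)
        assert res.census.site_total(SITEX, "hemi_alt") == 10

    def test_planted_counts_exact_before_noise(self, tmp_path):
        """Planted class counts equal the pre-noise census exactly even
        when heavy QC noise is injected afterwards."""
        samples, _ = generate_samples(CohortConfig(n_per_cluster={"EUR": 200}, seed=6))
        plant = PlantSpec(
            counts={SITE.key: {("EUR", "female"): {"het": 8},
                               ("EUR", "male"): {"hom_alt": 2}}}
        )
        census = planted_census([SITE], samples, plant, seed=6)
        assert census[SITE.key]["het"] == 8
        assert census[SITE.key]["hom_alt"] == 2
        assert census[SITE.key]["hom_ref"] == 190
        # same plant, with noise: GT class distribution in the file unchanged
        vcf = generate_genotypes(
            samples, [SITE], plant, tmp_path / "g.vcf", seed=6,
            qc_noise=QCNoise(low_gq_rate=0.2, low_dp_rate=0.2),
        )
        body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")][0]
        assert body.count("0/1:") == 8 and body.count("1/1:") == 2

    def test_noise_violates_exactly_assigned_filter(self, tmp_path):
        """Each injected noise genotype fails exactly its assigned
        filter and nothing else."""
        samples, _ = generate_samples(CohortConfig(n_per_cluster={"EUR": 300}, seed=8))
        plant = PlantSpec(counts={SITE.key: {("EUR", "female"): {"het": 60}}})
        for noise, reason in [
            (QCNoise(low_gq_rate=0.5), "low_gq"),
            (QCNoise(low_dp_rate=0.5), "low_dp"),
            (QCNoise(skewed_ab_rate=0.5), "allele_balance"),
        ]:
            vcf = generate_genotypes(
                samples, [SITE], plant, tmp_path / "g.vcf", seed=8, qc_noise=noise
            )
            res = discover_carriers(vcf, [SITE], samples, keep_calls=True)
            reasons = {c.qc_fail_reason for c in res.calls if not c.qc_pass}
            assert reasons <= {reason, "none"}

    def test_skewed_ab_rate_recovered(self, tmp_path):
        """Fraction of AB-failing hets ~ the configured 0.1 rate within
        binomial error."""
        samples, _ = generate_samples(CohortConfig(n_per_cluster={"EUR": 3000}, seed=9))
        n_het = 1500
        plant = PlantSpec(
            counts={SITE.key: {("EUR", "female"): {"het": n_het}}}
        )
        # make the stratum feasible regardless of the sex draw
        n_f = (samples["sex"] == "female").sum()
        assert n_f >= n_het
        rate = 0.1
        vcf = generate_genotypes(
            samples, [SITE], plant, tmp_path / "g.vcf", seed=9,
            qc_noise=QCNoise(skewed_ab_rate=rate),
        )
        res = discover_carriers(vcf, [SITE], samples)
        failed = res.census.site_total(SITE, "qc_failed")
        se = np.sqrt(rate * (1 - rate) / n_het)
        assert abs(failed / n_het - rate) < 4 * se

    def test_site_fail_fraction_sets_filter(self, tmp_path):
        samples, _ = generate_samples(CohortConfig(n_per_cluster={"EUR": 10}, seed=2))
        vcf = generate_genotypes(
            samples, [SITE], PlantSpec(), tmp_path / "g.vcf", seed=2,
            qc_noise=QCNoise(site_fail_fraction=1.0),
        )
        body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")][0]
        assert "\tFAIL_RF\t" in body
        res = discover_carriers(vcf, [SITE], samples)
        assert res.census.site_total(SITE, "qc_failed") == 10


class TestGeneratePhenotypes:
    @pytest.fixture(scope="class")
    def cohort(self):
        samples, _ = generate_samples(
            CohortConfig(n_per_cluster={"EUR": 2000}, seed=21)
        )
        dosage = {sid: 1 for sid in samples["sample_id"].iloc[:500]}
        return samples, dosage

    def test_null_effect_means_equal(self, cohort):
        samples, dosage = cohort
        effects = EffectSpec(continuous={"t": ContinuousTrait(10.0, 2.0, beta=0.0)})
        tables = generate_phenotypes(samples, dosage, effects, seed=1)
        merged = tables.continuous.assign(
            carrier=tables.continuous["sample_id"].isin(dosage)
        )
        a = merged.loc[merged["carrier"], "t"]
        b = merged.loc[~merged["carrier"], "t"]
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_planted_beta_recovered_within_2se(self, cohort):
        """beta = 1.0 SD: carrier-minus-noncarrier mean difference
        recovers beta*sd within 2 SE."""
        samples, dosage = cohort
        beta, sd = 1.0, 2.0
        effects = EffectSpec(continuous={"t": ContinuousTrait(10.0, sd, beta=beta)})
        tables = generate_phenotypes(samples, dosage, effects, seed=2)
        merged = tables.continuous.assign(
            carrier=tables.continuous["sample_id"].isin(dosage)
        )
        a = merged.loc[merged["carrier"], "t"]
        b = merged.loc[~merged["carrier"], "t"]
        diff = a.mean() - b.mean()
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(diff - beta * sd) < 2 * se

    def test_categorical_frequencies_recovered(self, cohort):
        samples, _ = cohort
        probs = {"X": 0.5, "Y": 0.3, "Z": 0.2}
        effects = EffectSpec(categorical={"c": CategoricalTrait(probs)})
        tables = generate_phenotypes(samples, {}, effects, seed=3)
        freq = tables.categorical["c"].value_counts(normalize=True)
        for level, p in probs.items():
            se = np.sqrt(p * (1 - p) / len(samples))
            assert abs(freq[level] - p) < 4 * se

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CategoricalTrait({"A": 0.5, "B": 0.4})

    def test_unknown_shift_level_rejected(self):
        with pytest.raises(ValueError, match="unknown trait level"):
            CategoricalTrait({"A": 1.0}, carrier_logodds={"B": 0.5})

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            ContinuousTrait(10.0, 0.0)

    def test_missingness_uses_nonresponse_codes(self, cohort):
        samples, _ = cohort
        effects = EffectSpec(
            categorical={"c": CategoricalTrait({"A": 0.7, "B": 0.3})},
            missing_rate=0.2,
        )
        tables = generate_phenotypes(samples, {}, effects, seed=4)
        from archvar.phenotype_compare import NONRESPONSE_LEVELS

        vals = tables.categorical["c"]
        frac = vals.isin(NONRESPONSE_LEVELS).mean()
        assert 0.15 < frac < 0.25


class TestDosage:
    def test_coding(self):
        carriers = pd.DataFrame(
            {"sample_id": ["A", "B", "C", "C"],
             "zygosity": ["het", "hemi_alt", "het", "hom_alt"]}
        )
        assert dosage_from_carriers(carriers) == {"A": 1, "B": 1, "C": 3}
        assert dosage_from_carriers(carriers, male_x_coding=2)["B"] == 2
        with pytest.raises(ValueError):
            dosage_from_carriers(carriers, male_x_coding=3)
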