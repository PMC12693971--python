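"""Genotype QC, sex-aware zygosity, and carrier discovery from VCF."""

from collections import Counter

import pandas as pd
import pytest

from archvar.carrier_discovery import (
    CENSUS_CLASSES,
    GenotypeCall,
    QCThresholds,
    classify_zygosity,
    discover_carriers,
    find_cocarriage,
    qc_genotype,
)
from archvar.synthetic_cohort import (
    CohortConfig,
    PlantSpec,
    QCNoise,
    generate_genotypes,
    generate_samples,
    planted_census,
)
from archvar.variant_catalog import VariantSite

SITE17 = VariantSite("SSH2", "17", 29632016, "T", "C")
SITEX = VariantSite("TKTL1", "X", 154315258, "G", "A")


def _call(site=SITE17, gt="0/1", gq=99, dp=30, ad=(15, 15), filt="PASS", sex="female"):
    return GenotypeCall(
        sample_id="S1",
        site=site,
        gt=gt,
        genotype_quality=gq,
        depth=dp,
        allele_depths=ad,
        site_filter=filt,
        zygosity=classify_zygosity(gt, site.chromosome, sex),
    )


class TestQCGenotype:
    def test_clean_het_passes(self):
        out = qc_genotype(_call())
        assert out.qc_pass and out.qc_fail_reason == "none"

    def test_depth_bound_is_strict(self):
        # DP = 10 fails "DP > 10"; DP = 11 passes
        assert qc_genotype(_call(dp=10, ad=(5, 5))).qc_fail_reason == "low_dp"
        assert qc_genotype(_call(dp=11, ad=(5, 6))).qc_pass

    def test_gq_bound_is_strict(self):
        assert qc_genotype(_call(gq=20)).qc_fail_reason == "low_gq"
        assert qc_genotype(_call(gq=21)).qc_pass

    def test_allele_balance_bounds_exclusive(self):
        # AD (23, 7): AB = 7/30 = 0.2333 < 0.25 -> fail
        assert qc_genotype(_call(ad=(23, 7))).qc_fail_reason == "allele_balance"
        # AB exactly 0.25 fails the open interval
        assert qc_genotype(_call(dp=40, ad=(30, 10))).qc_fail_reason == "allele_balance"
        assert qc_genotype(_call(dp=40, ad=(29, 11))).qc_pass

    def test_allele_balance_only_gates_hets(self):
        hom = _call(gt="1/1", ad=(0, 30))
        assert qc_genotype(hom).qc_pass

    def test_failure_reason_order(self):
        # site filter outranks GQ outranks DP outranks AB
        c = _call(filt="FAIL_RF", gq=5, dp=5, ad=(29, 1))
        assert qc_genotype(c).qc_fail_reason == "site_filter"
        c = _call(gq=5, dp=5, ad=(29, 1))
        assert qc_genotype(c).qc_fail_reason == "low_gq"
        c = _call(dp=5, ad=(4, 1))
        assert qc_genotype(c).qc_fail_reason == "low_dp"

    def test_missing_fields_fail_as_missing(self):
        c = _call()
        c.genotype_quality = None
        assert qc_genotype(c).qc_fail_reason == "missing"

    def test_site_qual_check_optional(self):
        c = _call()
        c.site_qual = 15.0
        assert qc_genotype(c).qc_pass  # off by default
        strict = QCThresholds(site_qual_min=20.0)
        assert qc_genotype(c, strict).qc_fail_reason == "site_filter"


class TestClassifyZygosity:
    @pytest.mark.parametrize(
        "gt,chrom,sex,expected",
        [
            ("0/0", "17", "female", "hom_ref"),
            ("0/1", "17", "female", "het"),
            ("1/0", "17", "male", "het"),
            ("1/1", "17", "female", "hom_alt"),
            ("0|1", "17", "female", "het"),
            ("1", "X", "male", "hemi_alt"),
            ("0", "X", "male", "hemi_ref"),
            ("1/1", "X", "male", "hemi_alt"),  # diploid dialect
            ("0/0", "X", "male", "hemi_ref"),
            ("0/1", "X", "male", "anomalous"),
            ("0/1", "X", "female", "het"),
            ("1/1", "X", "female", "hom_alt"),
            ("./.", "17", "female", "missing"),
            (".", "17", "female", "missing"),
            ("0/2", "17", "female", "missing"),  # other ALT allele
            ("1", "17", "female", "missing"),  # haploid on an autosome
            ("garbage", "17", "female", "missing"),
        ],
    )
    def test_classification(self, gt, chrom, sex, expected):
        assert classify_zygosity(gt, chrom, sex) == expected

    def test_bad_sex_rejected(self):
        with pytest.raises(ValueError):
            classify_zygosity("0/1", "17", "unknown")


@pytest.fixture(scope="module")
def planted_cohort(tmp_path_factory):
    cfg = CohortConfig(
        n_per_cluster={"EUR": 120, "AFR": 60, "EAS": 40}, seed=11, sex_ratio=0.5
    )
    samples, _ = generate_samples(cfg)
    plant = PlantSpec(
        counts={
            SITE17.key: {
                ("EUR", "female"): {"het": 4},
                ("AFR", "male"): {"het": 2, "hom_alt": 1},
            },
            SITEX.key: {
                ("EUR", "female"): {"het": 3, "hom_alt": 1},
                ("EUR", "male"): {"hemi_alt": 2},
            },
        }
    )
    vcf = generate_genotypes(
        samples, [SITE17, SITEX], plant,
        tmp_path_factory.mktemp("planted") / "g.vcf", seed=11,
    )
    return samples, plant, vcf


class TestDiscovery:
    def test_round_trip_census_at_zero_noise(self, planted_cohort):
        """With no QC noise the discovery census equals the planted
        census exactly, for both autosomal and X-hemizygous classes."""
        samples, plant, vcf = planted_cohort
        expected = planted_census([SITE17, SITEX], samples, plant, seed=11)
        res = discover_carriers(vcf, [SITE17, SITEX], samples)
        for site in (SITE17, SITEX):
            observed = Counter()
            for counter in res.census.counts[site.key].values():
                observed.update(counter)
            assert observed == expected[site.key]
        # 4 + (2+1) autosomal and (3+1) + 2 X carrier genotypes planted
        assert res.carrier_instances() == 13
        assert res.unique_carriers() <= 13

    def test_census_conservation(self, planted_cohort):
        """Sum over all census classes equals the queried sample count
        at every site."""
        samples, _, vcf = planted_cohort
        res = discover_carriers(vcf, [SITE17, SITEX], samples)
        for site in (SITE17, SITEX):
            total = sum(res.census.site_total(site, cls) for cls in CENSUS_CLASSES)
            assert total == len(samples)
            assert res.census.queried_n[site.key] == len(samples)

    def test_qc_failed_never_counted_as_carrier(self, tmp_path):
        """A single planted het that fails allele balance yields zero
        carriers and is excluded from the class census."""
        cfg = CohortConfig(n_per_cluster={"EUR": 30}, seed=3)
        samples, _ = generate_samples(cfg)
        plant = PlantSpec(counts={SITE17.key: {("EUR", "female"): {"het": 1}}})
        vcf = generate_genotypes(
            samples, [SITE17], plant, tmp_path / "g.vcf", seed=3,
            qc_noise=QCNoise(skewed_ab_rate=1.0),
        )
        res = discover_carriers(vcf, [SITE17], samples)
        assert res.unique_carriers() == 0
        assert res.census.site_total(SITE17, "het") == 0
        assert res.census.site_total(SITE17, "qc_failed") == 1

    def test_all_hom_ref_gives_zero_carriers(self, tmp_path):
        cfg = CohortConfig(n_per_cluster={"EUR": 25}, seed=4)
        samples, _ = generate_samples(cfg)
        vcf = generate_genotypes(samples, [SITE17], PlantSpec(), tmp_path / "g.vcf", seed=4)
        res = discover_carriers(vcf, [SITE17], samples)
        assert res.unique_carriers() == 0
        assert res.census.site_total(SITE17, "hom_ref") == 25

    def test_absent_site_reported_unqueryable(self, tmp_path):
        cfg = CohortConfig(n_per_cluster={"EUR": 10}, seed=5)
        samples, _ = generate_samples(cfg)
        vcf = generate_genotypes(samples, [SITE17], PlantSpec(), tmp_path / "g.vcf", seed=5)
        ghost = VariantSite("GRM6", "5", 178994530, "G", "T")
        res = discover_carriers(vcf, [SITE17, ghost], samples)
        assert res.census.unqueryable == [ghost.key]

    def test_other_alt_allele_renders_missing(self, tmp_path):
        """A genotype referencing a non-archaic ALT allele is treated
        as missing for this analysis."""
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr17,length=260000000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr17\t29632016\t.\tT\tC,G\t5000\tPASS\t.\tGT:GQ:DP:AD\t"
            "0/2:99:30:15,0,15\t0/1:99:30:15,15,0\n"
        )
        samples = pd.DataFrame(
            {"sample_id": ["S1", "S2"], "sex": ["female", "female"],
             "supercluster": ["EUR", "EUR"]}
        )
        res = discover_carriers(vcf, [SITE17], samples)
        assert res.census.site_total(SITE17, "missing") == 1
        assert res.census.site_total(SITE17, "het") == 1
        assert res.carrier_ids() == ["S2"]

    def test_male_x_anomalous_het_logged_not_counted(self, tmp_path):
        vcf = tmp_path / "anom.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chrX,length=157000000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tM1\n"
            "chrX\t154315258\t.\tG\tA\t5000\tPASS\t.\tGT:GQ:DP:AD\t0/1:99:30:15,15\n"
        )
        samples = pd.DataFrame(
            {"sample_id": ["M1"], "sex": ["male"], "supercluster": ["EUR"]}
        )
        res = discover_carriers(vcf, [SITEX], samples)
        assert res.unique_carriers() == 0
        assert res.census.site_total(SITEX, "anomalous") == 1


class TestCocarriage:
    def test_empty_when_no_multicarriers(self):
        carriers = pd.DataFrame(
            {"sample_id": ["A"], "gene": ["SSH2"], "chrom": ["17"],
             "pos_hg38": [29632016], "zygosity": ["het"]}
        )
        assert find_cocarriage(carriers).empty

    def test_groups_and_cross_gene_reporting(self):
        carriers = pd.DataFrame(
            {
                "sample_id": ["A", "A", "A", "B", "B"],
                "gene": ["SPAG5", "SPAG5", "SPAG5", "TKTL1", "KIF26B"],
                "chrom": ["17", "17", "17", "X", "1"],
                "pos_hg38": [28592016, 28592759, 28598560, 154315258, 245419603],
                "zygosity": ["het"] * 5,
            }
        )
        cc = find_cocarriage(carriers)
        assert len(cc) == 2
        a = cc[cc["sample_id"] == "A"].iloc[0]
        assert a["n_sites"] == 3 and a["genes"] == "SPAG5"
        b = cc[cc["sample_id"] == "B"].iloc[0]
        assert b["genes"] == "KIF26B;TKTL1"  # reported once, both genes

    def test_unique_carriers_bounded_by_instances(self, table1_bundle):
        res = discover_carriers(
            table1_bundle.vcf_path, table1_bundle.catalog, table1_bundle.samples
        )
        assert res.unique_carriers() <= res.carrier_instances()
        cc = find_cocarriage(res.carriers)
        overlap = res.carrier_instances() - res.unique_carriers()
        assert overlap == (cc["n_sites"] - 1).sum()
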