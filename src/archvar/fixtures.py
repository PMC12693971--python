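"""Deterministic fixture bundles realizing the reference study
configurations the pipeline is validated against.

Each fixture reproduces a published cohort configuration of the UK
Biobank archaic-variant survey this package reimplements — carrier
genotype counts per ancestry supercluster and sex, strict-label
membership, relatedness structure — exactly at the carrier level, while
noncarrier denominators are scaled down (the full ~452k-sample cohort
is neither available nor needed for carrier-level checks).  Placeholder
catalog sites padding the 42-site list to its published size are
synthetic: the full source table is not public, so positions and genes
outside the published per-site census are invented (clearly named
``PADGENE*``).

Registry: ``table1``, ``table2_tktl1``, ``ssh2_cohort``,
``tktl1_imaging``, ``tktl1_qualification``, ``catalog42``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_cohort import (
    PlantSpec,
    QCNoise,
    _truncated_normal,
    generate_genotypes,
    generate_phenotypes,
    EffectSpec,
    ContinuousTrait,
    CategoricalTrait,
    ParcelTrait,
)
from .variant_catalog import CurationRules, VariantSite, write_catalog

# --- published per-site carrier census (autosomal fixed-site survey) -------
# (gene, chrom, pos_hg38, ref, archaic)
TABLE1_SITES = [
    ("KIF26B", "1", 245419603, "A", "G"),
    ("NOTO", "2", 73210883, "T", "A"),
    ("GRM6", "5", 178994530, "G", "T"),
    ("ADAM18", "8", 39680099, "C", "T"),
    ("ADAM18", "8", 39706833, "G", "A"),
    ("DCHS1", "11", 6633538, "C", "T"),
    ("KNL1", "15", 40620662, "G", "A"),
    ("KNL1", "15", 40623442, "A", "G"),
    ("ZNF106", "15", 42450114, "C", "T"),
    ("SPAG5", "17", 28592016, "G", "C"),
    ("SPAG5", "17", 28592759, "C", "T"),
    ("SPAG5", "17", 28598560, "A", "G"),
    ("SSH2", "17", 29632016, "T", "C"),
    ("RFNG", "17", 82049104, "G", "A"),
    ("GREB1L", "18", 21505418, "A", "G"),
    ("LMNB2", "19", 2434035, "A", "T"),
    ("C3", "19", 6685100, "G", "A"),
]

#: Heterozygous carrier counts per supercluster for each census site,
#: plus the single homozygous archaic carrier (GRM6, Uncategorized).
TABLE1_HET = {
    ("1", 245419603): {"AFR": 2, "Uncategorized": 3},
    ("2", 73210883): {"EAS": 3, "Uncategorized": 3},
    ("5", 178994530): {"EUR": 3, "AFR": 12, "Uncategorized": 28},
    ("8", 39680099): {"EAS": 2, "EUR": 1},
    ("8", 39706833): {"EAS": 2},
    ("11", 6633538): {"Uncategorized": 1},
    ("15", 40620662): {"EAS": 1, "EUR": 3, "Uncategorized": 2},
    ("15", 40623442): {"EAS": 1, "Uncategorized": 1},
    ("15", 42450114): {"EAS": 4, "Uncategorized": 1},
    ("17", 28592016): {"AFR": 5},
    ("17", 28592759): {"EUR": 1, "AFR": 5},
    ("17", 28598560): {"AFR": 5},
    ("17", 29632016): {"EUR": 21},
    ("17", 82049104): {"EUR": 2},
    ("18", 21505418): {"EAS": 1},
    ("19", 2434035): {"EAS": 2},
    ("19", 6685100): {"EUR": 2},
}
TABLE1_HOM_ALT = {("5", 178994530): {"Uncategorized": 1}}

TKTL1_SITE = ("TKTL1", "X", 154315258, "G", "A")

#: TKTL1 carrier census: 45 heterozygous + 1 homozygous female, 16
#: hemizygous male carriers, by supercluster.
TABLE2_HET_F = {"EUR": 12, "AFR": 10, "Uncategorized": 23}
TABLE2_HOM_F = {"Uncategorized": 1}
TABLE2_HEMI_M = {"EUR": 4, "AFR": 1, "Uncategorized": 11}
#: Noncarrier denominators, scaled ~1/1000 from the published census.
TABLE2_REF_SCALED = {  # cluster -> (hemi_ref males, hom_ref females)
    "SAS": (5, 4),
    "EAS": (1, 2),
    "EUR": (193, 230),
    "AFR": (2, 3),
    "Uncategorized": (6, 8),
}

#: Sites excluded during catalog curation, with reasons.  Alleles at
#: excluded sites are synthetic placeholders (not published).
EXCLUDED_SITES = [
    ("C1orf159", "1", 1091245, "A", "G", "non_exonic"),
    ("DNHD1", "11", 6534188, "A", "G", "non_exonic"),
    ("DNMT3L", "21", 44251169, "A", "G", "non_exonic"),
    ("TBC1D3", "17", 38202786, "A", "G", "ambiguous_liftover"),
]

#: The one retained site whose VCF FILTER is non-PASS at query time.
NONPASS_SITE = ("9", 6606647)

FIXTURE_SEEDS = {
    "table1": 101,
    "table2_tktl1": 202,
    "ssh2_cohort": 303,
    "tktl1_imaging": 404,
    "tktl1_qualification": 505,
    "catalog42": 606,
}


@dataclass
class FixtureBundle:
    name: str
    out_dir: Path
    catalog: list[VariantSite]
    catalog_path: Path
    rules: CurationRules | None = None
    rules_path: Path | None = None
    vcf_path: Path | None = None
    samples: pd.DataFrame | None = None
    samples_path: Path | None = None
    kinship: pd.DataFrame | None = None
    kinship_path: Path | None = None
    phenotypes: dict[str, pd.DataFrame] = field(default_factory=dict)


def _padded_catalog() -> tuple[list[VariantSite], CurationRules]:
    """The 42-site source catalog (census sites verbatim, padded with
    synthetic PADGENE sites) plus its curation rules."""
    sites = [
        VariantSite(g, c, p, r, a, "fixed_af1") for g, c, p, r, a in TABLE1_SITES
    ]
    # 21 padding sites over 19 synthetic genes (two genes contribute two
    # sites each), one of them at the known non-PASS position.
    pad = []
    pad_chroms = ["3", "4", "6", "7", "9", "10", "12", "13", "14", "16",
                  "20", "22", "2", "3", "4", "6", "7", "10", "12", "13", "14"]
    genes = [f"PADGENE{i:02d}" for i in range(1, 20)] + ["PADGENE01", "PADGENE02"]
    for i, (chrom, gene) in enumerate(zip(pad_chroms, genes)):
        pos = 5_000_000 + 17 * (i + 1)
        if chrom == "9" and i == 4:
            pos = NONPASS_SITE[1]
        pad.append(VariantSite(gene, chrom, pos, "C", "T", "fixed_af1"))
    excl = [
        VariantSite(g, c, p, r, a, "fixed_af1") for g, c, p, r, a, _ in EXCLUDED_SITES
    ]
    catalog = sites + pad + excl
    assert len(catalog) == 42
    rules = CurationRules(
        exclusions={(c, p): reason for _, c, p, _, _, reason in EXCLUDED_SITES},
        inclusions=[VariantSite(*TKTL1_SITE, catalog_status="high_frequency")],
    )
    return catalog, rules


def _samples_block(
    prefix: str,
    start: int,
    n: int,
    sex: str,
    cluster: str,
    ages: np.ndarray,
    strict: bool = False,
    pc: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A block of metadata rows with shared sex/cluster and given ages."""
    from .synthetic_cohort import DEFAULT_PC_CENTROIDS, CLUSTER_SELF_REPORT

    centroid = DEFAULT_PC_CENTROIDS[cluster]
    if pc is None:
        if rng is not None:
            pcs = rng.normal(centroid, 2.0, size=(n, 4))
        else:
            pcs = np.tile(centroid, (n, 1))
    else:
        pcs = np.tile([pc[0], pc[1], centroid[2], centroid[3]], (n, 1))
        if rng is not None:
            pcs[:, :2] += rng.uniform(-1.0, 1.0, size=(n, 2))
    return pd.DataFrame(
        {
            "sample_id": [f"{prefix}{start + i:06d}" for i in range(n)],
            "sex": sex,
            "age": np.round(ages, 2),
            "generating_cluster": cluster,
            "self_report_code": CLUSTER_SELF_REPORT[cluster],
            "supercluster": cluster,
            "strict_label": "White_British" if strict else "none",
            "pc1": np.round(pcs[:, 0], 4),
            "pc2": np.round(pcs[:, 1], 4),
            "pc3": np.round(pcs[:, 2], 4),
            "pc4": np.round(pcs[:, 3], 4),
            "sex_mismatch": False,
            "aneuploidy": False,
            "het_outlier": False,
            "high_missingness": False,
        }
    )


def _write_tables(bundle: FixtureBundle) -> None:
    d = bundle.out_dir
    write_catalog(bundle.catalog, bundle.catalog_path)
    if bundle.samples is not None:
        bundle.samples_path = d / "samples.tsv"
        bundle.samples.to_csv(bundle.samples_path, sep="\t", index=False)
    if bundle.kinship is not None:
        bundle.kinship_path = d / "kinship.tsv"
        bundle.kinship.to_csv(bundle.kinship_path, sep="\t", index=False)
    for key, df in bundle.phenotypes.items():
        df.to_csv(d / f"phenotypes_{key}.tsv", sep="\t", index=False)


def build_fixture(name: str, out_dir: str | Path, seed: int | None = None) -> FixtureBundle:
    """Build a named fixture bundle under ``out_dir``.

    With the default ``seed=None`` the registry's fixed internal seed is
    used, so the same name always yields byte-identical bundles; an
    explicit seed re-randomizes the incidental structure (ages, PCs,
    which individual carries which allele) while preserving the
    configuration's counts.
    """
    builders = {
        "table1": _build_table1,
        "table2_tktl1": _build_table2,
        "ssh2_cohort": _build_ssh2,
        "tktl1_imaging": _build_tktl1_imaging,
        "tktl1_qualification": _build_tktl1_qualification,
        "catalog42": _build_catalog42,
    }
    if name not in builders:
        raise KeyError(
            f"unknown fixture {name!r}; registry: {sorted(builders)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = FIXTURE_SEEDS[name]
    bundle = builders[name](out_dir, seed)
    _write_tables(bundle)
    with open(out_dir / "fixture.yaml", "w") as fh:
        yaml.safe_dump({"fixture": name, "seed": seed}, fh)
    return bundle


def _build_catalog42(out_dir: Path, seed: int) -> FixtureBundle:
    catalog, rules = _padded_catalog()
    rules_path = out_dir / "curation_rules.yaml"
    with open(rules_path, "w") as fh:
        yaml.safe_dump(
            {
                "exclusions": [
                    {"chrom": c, "pos_hg38": p, "reason": reason}
                    for (c, p), reason in sorted(rules.exclusions.items())
                ],
                "inclusions": [
                    {
                        "gene": s.gene, "chrom": s.chromosome, "pos_hg38": s.position,
                        "ref": s.ref_allele, "archaic": s.archaic_allele,
                        "status": s.catalog_status,
                    }
                    for s in rules.inclusions
                ],
            },
            fh,
        )
    return FixtureBundle(
        name="catalog42", out_dir=out_dir, catalog=catalog,
        catalog_path=out_dir / "catalog.tsv", rules=rules, rules_path=rules_path,
    )


def _build_table1(out_dir: Path, seed: int) -> FixtureBundle:
    """The autosomal census fixture: carrier counts per supercluster as
    published, including the enumerated co-carriage (the SPAG5 triple
    carried by five individuals, one ADAM18 pair, one KNL1 pair);
    noncarrier denominators scaled down."""
    rng = np.random.default_rng(seed)
    sizes = {"EUR": 430, "AFR": 60, "SAS": 86, "EAS": 19, "Uncategorized": 140}
    blocks = []
    start = 1
    for cluster, n in sizes.items():
        ages = _truncated_normal(rng, 57.0, 8.0, 40.0, 70.0, n)
        sexes = np.where(rng.random(n) < 0.54, "female", "male")
        df = _samples_block("T1S", start, n, "female", cluster, ages, rng=rng)
        df["sex"] = sexes
        blocks.append(df)
        start += n
    samples = pd.concat(blocks, ignore_index=True)
    ids = {
        c: samples.loc[samples["supercluster"] == c, "sample_id"].tolist()
        for c in sizes
    }
    sites = [VariantSite(g, c, p, r, a) for g, c, p, r, a in TABLE1_SITES]
    by_gene_pos = {(s.chromosome, s.position): s for s in sites}

    explicit: dict[tuple[str, int], dict[str, str]] = {k: {} for k in by_gene_pos}
    cursor = {c: 0 for c in sizes}

    def take(cluster: str, n: int) -> list[str]:
        sel = ids[cluster][cursor[cluster] : cursor[cluster] + n]
        if len(sel) < n:
            raise RuntimeError(f"fixture cluster {cluster} exhausted")
        cursor[cluster] += n
        return sel

    # co-carried groups first
    spag5 = [("17", 28592016), ("17", 28592759), ("17", 28598560)]
    for sid in take("AFR", 5):
        for key in spag5:
            explicit[key][sid] = "het"
    adam18 = [("8", 39680099), ("8", 39706833)]
    for sid in take("EAS", 2):
        for key in adam18:
            explicit[key][sid] = "het"
    knl1 = [("15", 40620662), ("15", 40623442)]
    for sid in take("EAS", 1) + take("Uncategorized", 1):
        for key in knl1:
            explicit[key][sid] = "het"

    # remaining singleton carriers, per-site per-cluster
    consumed = {
        ("17", 28592016): {"AFR": 5}, ("17", 28592759): {"AFR": 5},
        ("17", 28598560): {"AFR": 5},
        ("8", 39680099): {"EAS": 2}, ("8", 39706833): {"EAS": 2},
        ("15", 40620662): {"EAS": 1, "Uncategorized": 1},
        ("15", 40623442): {"EAS": 1, "Uncategorized": 1},
    }
    for key, per_cluster in TABLE1_HET.items():
        for cluster, count in per_cluster.items():
            remaining = count - consumed.get(key, {}).get(cluster, 0)
            for sid in take(cluster, remaining):
                explicit[key][sid] = "het"
    for key, per_cluster in TABLE1_HOM_ALT.items():
        for cluster, count in per_cluster.items():
            for sid in take(cluster, count):
                explicit[key][sid] = "hom_alt"

    plant = PlantSpec(explicit=explicit)
    vcf_path = generate_genotypes(
        samples, sites, plant, out_dir / "genotypes.vcf", seed=seed
    )
    return FixtureBundle(
        name="table1", out_dir=out_dir, catalog=sites,
        catalog_path=out_dir / "catalog.tsv", vcf_path=vcf_path,
        samples=samples, kinship=pd.DataFrame(columns=["id1", "id2", "coefficient"]),
    )


def _build_table2(out_dir: Path, seed: int) -> FixtureBundle:
    """The X-chromosome TKTL1 census fixture: 45 het + 1 hom female and
    16 hemizygous male carriers, exactly; scaled noncarrier strata."""
    rng = np.random.default_rng(seed)
    site = VariantSite(*TKTL1_SITE, catalog_status="high_frequency")
    blocks, start = [], 1
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for cluster, (m_ref, f_ref) in TABLE2_REF_SCALED.items():
        n_f = f_ref + TABLE2_HET_F.get(cluster, 0) + TABLE2_HOM_F.get(cluster, 0)
        n_m = m_ref + TABLE2_HEMI_M.get(cluster, 0)
        for sex, n in (("female", n_f), ("male", n_m)):
            if n == 0:
                continue
            ages = _truncated_normal(rng, 57.0, 8.0, 40.0, 70.0, n)
            blocks.append(_samples_block("T2S", start, n, sex, cluster, ages, rng=rng))
            start += n
        planted_f = {}
        if TABLE2_HET_F.get(cluster):
            planted_f["het"] = TABLE2_HET_F[cluster]
        if TABLE2_HOM_F.get(cluster):
            planted_f["hom_alt"] = TABLE2_HOM_F[cluster]
        if planted_f:
            counts[(cluster, "female")] = planted_f
        if TABLE2_HEMI_M.get(cluster):
            counts[(cluster, "male")] = {"hemi_alt": TABLE2_HEMI_M[cluster]}
    samples = pd.concat(blocks, ignore_index=True)
    plant = PlantSpec(counts={site.key: counts})
    vcf_path = generate_genotypes(
        samples, [site], plant, out_dir / "genotypes.vcf", seed=seed
    )
    return FixtureBundle(
        name="table2_tktl1", out_dir=out_dir, catalog=[site],
        catalog_path=out_dir / "catalog.tsv", vcf_path=vcf_path,
        samples=samples, kinship=pd.DataFrame(columns=["id1", "id2", "coefficient"]),
    )


def _pool_blocks(
    carriers: pd.DataFrame,
    block: int,
    prefix: str,
    rng: np.random.Generator,
    match_pcs: bool = False,
) -> pd.DataFrame:
    """An eligible-control pool: per carrier, ``block`` same-sex
    candidates within +-1 year (and +-1 PC unit when ``match_pcs``),
    inheriting the carrier's strict label and supercluster.  A dedicated
    block of size >= the matching ratio guarantees greedy feasibility."""
    out, start = [], 1
    for _, carrier in carriers.iterrows():
        ages = carrier["age"] + rng.uniform(-1.0, 1.0, size=block)
        df = _samples_block(
            prefix, start, block, carrier["sex"], carrier["supercluster"], ages,
            strict=carrier["strict_label"] == "White_British",
            pc=(carrier["pc1"], carrier["pc2"]) if match_pcs else None,
            rng=rng,
        )
        out.append(df)
        start += block
    return pd.concat(out, ignore_index=True)


def _build_ssh2(out_dir: Path, seed: int) -> FixtureBundle:
    """The SSH2 cohort: 21 heterozygous carriers, all EUR, 20 carrying
    the strict White British label, one related carrier pair among the
    strict-labeled 20; final pruned strict set = 19 (14 female).  Pool:
    3000 eligible candidates per carrier (63k total)."""
    rng = np.random.default_rng(seed)
    site = VariantSite("SSH2", "17", 29632016, "T", "C")
    n_car = 21
    # Sexes chosen so that after dropping the pruned pair member
    # (SSH2C000002) and the non-strict carrier (SSH2C000021), the
    # retained 19 comprise 14 females and 5 males.
    sexes = (["female"] * 15 + ["male"] * 6)
    ages = _truncated_normal(rng, 59.42, 7.94, 40.0, 70.0, n_car)
    carriers = _samples_block("SSH2C", 1, n_car, "female", "EUR", ages,
                              strict=True, rng=rng)
    carriers["sex"] = sexes
    carriers.loc[carriers["sample_id"] == "SSH2C000021", "strict_label"] = "none"
    kinship = pd.DataFrame(
        [("SSH2C000001", "SSH2C000002", 0.25)],
        columns=["id1", "id2", "coefficient"],
    )
    pool = _pool_blocks(carriers, 3000, "SSH2P", rng)
    samples = pd.concat([carriers, pool], ignore_index=True)
    plant = PlantSpec(explicit={site.key: {
        sid: "het" for sid in carriers["sample_id"]
    }})
    vcf_path = generate_genotypes(
        samples, [site], plant, out_dir / "genotypes.vcf", seed=seed
    )
    dosage = {sid: 1 for sid in carriers["sample_id"]}
    effects = EffectSpec(
        continuous={
            "bmi": ContinuousTrait(27.3, 4.7),
            "whole_body_fat_mass": ContinuousTrait(24.9, 9.5),
            "height": ContinuousTrait(168.5, 9.3),
        },
        categorical={
            "overall_health_rating": CategoricalTrait(
                {"Excellent": 0.16, "Good": 0.58, "Fair": 0.21, "Poor": 0.05}
            ),
            "smoking_status": CategoricalTrait(
                {"Never": 0.55, "Previous": 0.34, "Current": 0.11}
            ),
            "qualification": CategoricalTrait(
                {
                    "College or University degree": 0.32,
                    "A levels/AS levels or equivalent": 0.12,
                    "O levels/GCSEs or equivalent": 0.26,
                    "CSEs or equivalent": 0.06,
                    "NVQ or HND or HNC or equivalent": 0.07,
                    "Other professional qualifications": 0.05,
                    "None of the above": 0.12,
                },
                multiselect=True,
            ),
        },
        missing_rate=0.02,
    )
    phen = generate_phenotypes(samples, dosage, effects, seed=seed + 1)
    return FixtureBundle(
        name="ssh2_cohort", out_dir=out_dir, catalog=[site],
        catalog_path=out_dir / "catalog.tsv", vcf_path=vcf_path,
        samples=samples, kinship=kinship,
        phenotypes={"continuous": phen.continuous, "categorical": phen.categorical},
    )


def _build_tktl1_imaging(out_dir: Path, seed: int) -> FixtureBundle:
    """The TKTL1 imaging cohort: five unrelated carriers with imaging
    data (one female heterozygote, four hemizygous males), age- and
    sex-matchable pool of 600 candidates per carrier across ancestries,
    frontal-parcel phenotypes for everyone."""
    rng = np.random.default_rng(seed)
    site = VariantSite(*TKTL1_SITE, catalog_status="high_frequency")
    ages = _truncated_normal(rng, 71.2, 6.14, 60.0, 82.0, 5)
    carriers = _samples_block("TKIC", 1, 5, "male", "EUR", ages, rng=rng)
    carriers.loc[carriers["sample_id"] == "TKIC000001", "sex"] = "female"
    clusters = ["EUR", "EUR", "AFR", "Uncategorized", "EUR"]
    carriers["supercluster"] = clusters
    carriers["generating_cluster"] = clusters
    pool = _pool_blocks(carriers, 600, "TKIP", rng)
    samples = pd.concat([carriers, pool], ignore_index=True)
    explicit = {
        site.key: {
            sid: ("het" if sex == "female" else "hemi_alt")
            for sid, sex in zip(carriers["sample_id"], carriers["sex"])
        }
    }
    vcf_path = generate_genotypes(
        samples, [site], PlantSpec(explicit=explicit),
        out_dir / "genotypes.vcf", seed=seed,
    )
    dosage = {sid: 1 for sid in carriers["sample_id"]}
    phen = generate_phenotypes(
        samples, dosage, EffectSpec(parcels=ParcelTrait()), seed=seed + 1
    )
    return FixtureBundle(
        name="tktl1_imaging", out_dir=out_dir, catalog=[site],
        catalog_path=out_dir / "catalog.tsv", vcf_path=vcf_path,
        samples=samples, kinship=pd.DataFrame(columns=["id1", "id2", "coefficient"]),
        phenotypes={"parcels": phen.parcels},
    )


def _build_tktl1_qualification(out_dir: Path, seed: int) -> FixtureBundle:
    """The TKTL1 qualification cohort: 30 unrelated carriers (21 female;
    11 AFR, 10 EUR, 9 Uncategorized), PC/age/sex-matchable pool of 40
    candidates per carrier, qualification phenotypes."""
    rng = np.random.default_rng(seed)
    site = VariantSite(*TKTL1_SITE, catalog_status="high_frequency")
    ages = _truncated_normal(rng, 54.4, 7.67, 40.0, 70.0, 30)
    carriers = _samples_block("TKQC", 1, 30, "female", "EUR", ages, rng=rng)
    clusters = ["AFR"] * 11 + ["EUR"] * 10 + ["Uncategorized"] * 9
    sexes = (["female"] * 8 + ["male"] * 3        # AFR: 8F 3M
             + ["female"] * 7 + ["male"] * 3      # EUR: 7F 3M
             + ["female"] * 6 + ["male"] * 3)     # Uncat: 6F 3M -> 21F 9M
    carriers["supercluster"] = clusters
    carriers["generating_cluster"] = clusters
    carriers["sex"] = sexes
    from .synthetic_cohort import DEFAULT_PC_CENTROIDS

    for i, cluster in enumerate(clusters):
        cx = DEFAULT_PC_CENTROIDS[cluster]
        carriers.loc[i, ["pc1", "pc2", "pc3", "pc4"]] = np.round(
            np.asarray(cx) + rng.normal(0, 2.0, 4), 4
        )
    pool = _pool_blocks(carriers, 40, "TKQP", rng, match_pcs=True)
    samples = pd.concat([carriers, pool], ignore_index=True)
    explicit = {
        site.key: {
            sid: ("het" if sex == "female" else "hemi_alt")
            for sid, sex in zip(carriers["sample_id"], carriers["sex"])
        }
    }
    vcf_path = generate_genotypes(
        samples, [site], PlantSpec(explicit=explicit),
        out_dir / "genotypes.vcf", seed=seed,
    )
    dosage = {sid: 1 for sid in carriers["sample_id"]}
    effects = EffectSpec(
        categorical={
            "qualification": CategoricalTrait(
                {
                    "College or University degree": 0.33,
                    "A levels/AS levels or equivalent": 0.12,
                    "O levels/GCSEs or equivalent": 0.25,
                    "CSEs or equivalent": 0.06,
                    "NVQ or HND or HNC or equivalent": 0.07,
                    "Other professional qualifications": 0.05,
                    "None of the above": 0.12,
                },
                multiselect=True,
            )
        },
        missing_rate=0.02,
    )
    phen = generate_phenotypes(samples, dosage, effects, seed=seed + 1)
    return FixtureBundle(
        name="tktl1_qualification", out_dir=out_dir, catalog=[site],
        catalog_path=out_dir / "catalog.tsv", vcf_path=vcf_path,
        samples=samples, kinship=pd.DataFrame(columns=["id1", "id2", "coefficient"]),
        phenotypes={"categorical": phen.categorical},
    )
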