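"""Seeded synthetic biobank cohorts: samples, genotypes, phenotypes.

The generator emulates the statistical structure the downstream
pipeline assumes — multi-ancestry PC cluster geometry, rare archaic
alleles planted at exact per-stratum genotype counts (or frequencies),
genotype-quality noise that trips each QC filter individually,
third-degree-and-closer kinship pairs, and phenotypes with a
configurable additive carrier effect.  Identical seed and configuration
give byte-identical outputs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .carrier_discovery import ZYGOSITIES
from .phenotype_compare import NONRESPONSE_LEVELS
from .variant_catalog import VariantSite

SUPERCLUSTERS = ("EUR", "AFR", "SAS", "EAS", "Uncategorized")

#: Representative self-report code per generating cluster.
CLUSTER_SELF_REPORT = {
    "EUR": "British",
    "AFR": "African",
    "SAS": "Indian",
    "EAS": "Chinese",
    "Uncategorized": "Mixed",
}

#: Default isotropic PC centroids (arbitrary PC units), separated far
#: beyond the default spread so box assignment is unambiguous.
DEFAULT_PC_CENTROIDS = {
    "EUR": (0.0, 0.0, 0.0, 0.0),
    "AFR": (120.0, 60.0, 0.0, 0.0),
    "SAS": (40.0, -50.0, 15.0, 0.0),
    "EAS": (70.0, -90.0, -15.0, 0.0),
    "Uncategorized": (50.0, -20.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort configuration.

    Ages are Normal(age_mean, age_sd) truncated to ``age_range``
    (default Normal(57, 8) on [40, 70], the typical middle-aged biobank
    window).  ``related_fraction`` of samples are placed in disjoint
    kinship pairs with coefficients drawn from ``kinship_levels``;
    ``kinship_chain`` instead attaches several relatives to one hub
    sample to exercise pruning prioritization.
    """

    n_per_cluster: Mapping[str, int]
    seed: int
    pc_centroids: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PC_CENTROIDS)
    )
    pc_spread: float | Mapping[str, float] = 3.0
    age_mean: float = 57.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 70.0)
    sex_ratio: float = 0.54  # fraction female
    related_fraction: float = 0.0
    kinship_levels: tuple[float, ...] = (0.25, 0.125, 0.0625)
    kinship_chain: bool = False
    mislabel_fraction: float = 0.0  # cluster-generated samples self-reporting Uncategorized
    strict_label_fraction: float = 0.9  # EUR samples carrying the strict label
    qc_flag_rate: float = 0.0  # per-flag rate of sample-QC failures
    id_prefix: str = "S"

    def __post_init__(self) -> None:
        for cluster, n in self.n_per_cluster.items():
            if cluster not in SUPERCLUSTERS:
                raise ValueError(f"unknown cluster {cluster!r}")
            if n < 0:
                raise ValueError(f"negative count for cluster {cluster}")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range min must be < max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.related_fraction <= 1.0:
            raise ValueError("related_fraction must lie in [0, 1]")

    def spread_for(self, cluster: str) -> float:
        if isinstance(self.pc_spread, Mapping):
            return float(self.pc_spread[cluster])
        return float(self.pc_spread)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float, hi: float, size: int,
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_samples(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the sample metadata table and kinship pair table.

    One row per sample: unique id, sex, age within range, self-report
    code consistent with the generating cluster (a configurable
    fraction mislabeled as Uncategorized), PCs 1-4 from the cluster
    centroid +- spread, and sample-QC flags set at ``qc_flag_rate``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    idx = 0
    for cluster in SUPERCLUSTERS:
        n = int(config.n_per_cluster.get(cluster, 0))
        if n == 0:
            continue
        centroid = np.asarray(config.pc_centroids[cluster], dtype=float)
        spread = config.spread_for(cluster)
        if cluster == "Uncategorized":
            spread *= 6.0  # the unlabeled group is highly dispersed
        pcs = rng.normal(centroid, spread, size=(n, 4))
        ages = _truncated_normal(
            rng, config.age_mean, config.age_sd, *config.age_range, size=n
        )
        female = rng.random(n) < config.sex_ratio
        mislabel = rng.random(n) < config.mislabel_fraction
        strict = (
            (rng.random(n) < config.strict_label_fraction)
            if cluster == "EUR"
            else np.zeros(n, dtype=bool)
        )
        flags = rng.random((n, 4)) < config.qc_flag_rate
        for i in range(n):
            idx += 1
            code = (
                "Mixed" if (mislabel[i] and cluster != "Uncategorized")
                else CLUSTER_SELF_REPORT[cluster]
            )
            rows.append(
                {
                    "sample_id": f"{config.id_prefix}{idx:06d}",
                    "sex": "female" if female[i] else "male",
                    "age": round(float(ages[i]), 2),
                    "generating_cluster": cluster,
                    "self_report_code": code,
                    "supercluster": "Uncategorized" if code == "Mixed" else cluster,
                    "strict_label": "White_British" if (strict[i] and not mislabel[i]) else "none",
                    "pc1": round(float(pcs[i, 0]), 4),
                    "pc2": round(float(pcs[i, 1]), 4),
                    "pc3": round(float(pcs[i, 2]), 4),
                    "pc4": round(float(pcs[i, 3]), 4),
                    "sex_mismatch": bool(flags[i, 0]),
                    "aneuploidy": bool(flags[i, 1]),
                    "het_outlier": bool(flags[i, 2]),
                    "high_missingness": bool(flags[i, 3]),
                }
            )
    samples = pd.DataFrame(rows)
    kinship = _generate_kinship(samples, config, rng)
    return samples, kinship


def _generate_kinship(
    samples: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    cols = ["id1", "id2", "coefficient"]
    n_related = int(round(config.related_fraction * len(samples)))
    if n_related < 2:
        return pd.DataFrame(columns=cols)
    ids = rng.permutation(samples["sample_id"].to_numpy())
    pairs = []
    if config.kinship_chain:
        hub = ids[0]
        for other in ids[1 : n_related]:
            pairs.append((hub, other, float(rng.choice(config.kinship_levels))))
    else:
        for i in range(0, n_related - 1, 2):
            pairs.append(
                (ids[i], ids[i + 1], float(rng.choice(config.kinship_levels)))
            )
    return pd.DataFrame(pairs, columns=cols)


# ---------------------------------------------------------------------------
# genotype planting


@dataclass
class PlantSpec:
    """What to plant at each catalog site.

    Exactly one of three modes per site:

    * ``counts``: per (site key, supercluster, sex) a mapping of
      genotype class -> count; unplanted samples default to
      hom_ref/hemi_ref.
    * ``freqs``: per site key a per-supercluster archaic allele
      frequency; genotypes drawn binomially.
    * ``explicit``: per site key a mapping sample_id -> genotype class.
    """

    counts: dict[tuple[str, int], dict[tuple[str, str], dict[str, int]]] = field(
        default_factory=dict
    )
    freqs: dict[tuple[str, int], dict[str, float]] = field(default_factory=dict)
    explicit: dict[tuple[str, int], dict[str, str]] = field(default_factory=dict)


class PlantError(ValueError):
    """Plant counts infeasible for a stratum."""


@dataclass(frozen=True)
class QCNoise:
    """Rates of injected genotype-quality failures.

    Each noise genotype violates exactly one filter: ``low_gq`` sets
    GQ <= 20 (quality kept otherwise clean), ``low_dp`` sets DP <= 10,
    ``skewed_ab`` (heterozygotes only) pushes allele balance outside
    the open (0.25, 0.75) window.  ``site_fail_fraction`` of sites get
    a non-PASS FILTER label instead.
    """

    low_gq_rate: float = 0.0
    low_dp_rate: float = 0.0
    skewed_ab_rate: float = 0.0
    site_fail_fraction: float = 0.0
    fail_label: str = "FAIL_RF"


_CONTIG_LENGTHS = {str(i): 260_000_000 for i in range(1, 23)} | {"X": 157_000_000}


def _zygosity_for_sample(
    site: VariantSite, sex: str, cls: str
) -> None:
    hemi = site.chromosome == "X" and sex == "male"
    if cls.startswith("hemi") and not hemi:
        raise PlantError(
            f"{site.label}: class {cls} only valid for male chrX samples"
        )
    if hemi and cls in ("het", "hom_alt", "hom_ref"):
        raise PlantError(
            f"{site.label}: diploid class {cls} planted on male chrX"
        )


def _assign_classes(
    site: VariantSite,
    samples: pd.DataFrame,
    plant: PlantSpec,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Resolve the plant spec to one genotype class per sample."""
    hemi_mask = (site.chromosome == "X") & (samples["sex"] == "male")
    assignment = {
        sid: ("hemi_ref" if hemi else "hom_ref")
        for sid, hemi in zip(samples["sample_id"], hemi_mask)
    }
    key = site.key
    sex_by_id = dict(zip(samples["sample_id"], samples["sex"]))
    if key in plant.explicit:
        for sid, cls in plant.explicit[key].items():
            if sid not in assignment:
                raise PlantError(f"{site.label}: unknown sample {sid}")
            _zygosity_for_sample(site, sex_by_id[sid], cls)
            assignment[sid] = cls
        return assignment
    if key in plant.counts:
        for (cluster, sex), classes in sorted(plant.counts[key].items()):
            stratum = samples[
                (samples["supercluster"] == cluster) & (samples["sex"] == sex)
            ]
            demand = sum(classes.values())
            if demand > len(stratum):
                raise PlantError(
                    f"{site.label}: stratum ({cluster}, {sex}) has "
                    f"{len(stratum)} samples, plant needs {demand}"
                )
            chosen = rng.choice(
                stratum["sample_id"].to_numpy(), size=demand, replace=False
            )
            pos = 0
            for cls in sorted(classes):
                _zygosity_for_sample(site, sex, cls)
                for _ in range(classes[cls]):
                    assignment[chosen[pos]] = cls
                    pos += 1
        return assignment
    if key in plant.freqs:
        cluster_by_id = dict(zip(samples["sample_id"], samples["supercluster"]))
        for sid in assignment:
            cluster = cluster_by_id[sid]
            f = plant.freqs[key].get(cluster, 0.0)
            hemi = site.chromosome == "X" and sex_by_id[sid] == "male"
            if hemi:
                assignment[sid] = "hemi_alt" if rng.random() < f else "hemi_ref"
            else:
                dose = rng.binomial(2, f)
                assignment[sid] = ("hom_ref", "het", "hom_alt")[dose]
        return assignment
    return assignment  # site not in plant: all reference


def planted_census(
    sites: Sequence[VariantSite],
    samples: pd.DataFrame,
    plant: PlantSpec,
    seed: int,
) -> dict[tuple[str, int], Counter]:
    """The genotype-class census the plant realizes (pre-noise), using
    the same RNG stream as :func:`generate_genotypes`."""
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, int], Counter] = {}
    for site in sorted(sites, key=lambda s: s.key):
        assignment = _assign_classes(site, samples, plant, rng)
        out[site.key] = Counter(assignment.values())
    return out


def generate_genotypes(
    samples: pd.DataFrame,
    sites: Sequence[VariantSite],
    plant: PlantSpec,
    out_path: str | Path,
    seed: int,
    qc_noise: QCNoise = QCNoise(),
    male_x_dialect: str = "haploid",
) -> Path:
    """Write a VCF v4.2 realizing the plant exactly, with QC noise.

    FORMAT is GT:GQ:DP:AD.  Male chrX genotypes are written haploid
    ("1") or diploid ("1/1") per ``male_x_dialect``.  Noise genotypes
    each violate exactly one filter; ``site_fail_fraction`` of sites
    get a non-PASS FILTER label.  Records are rendered as text in
    vectorized batches (cohort-scale sample columns), and the output is
    read back with pysam downstream.
    """
    if male_x_dialect not in ("haploid", "diploid"):
        raise ValueError("male_x_dialect must be 'haploid' or 'diploid'")
    out_path = Path(out_path)
    rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))

    sample_ids = samples["sample_id"].tolist()
    sexes = samples["sex"].to_numpy()

    # class assignment consumes `rng` in key order, exactly as
    # planted_census does, so the two always agree
    assignments: dict[tuple[str, int], dict[str, str]] = {}
    for site in sorted(sites, key=lambda s: s.key):
        assignments[site.key] = _assign_classes(site, samples, plant, rng)

    failing_sites = {
        s.key
        for s in sorted(sites, key=lambda s: s.key)
        if noise_rng.random() < qc_noise.site_fail_fraction
    }

    lines = ["##fileformat=VCFv4.2"]
    for contig in list(_CONTIG_LENGTHS):
        lines.append(f"##contig=<ID=chr{contig},length={_CONTIG_LENGTHS[contig]}>")
    lines.append(
        f'##FILTER=<ID={qc_noise.fail_label},Description="Synthetic site-level failure">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )

    contig_rank = {c: i for i, c in enumerate(_CONTIG_LENGTHS)}
    for site in sorted(sites, key=lambda s: (contig_rank[s.chromosome], s.position)):
        order = [assignments[site.key][sid] for sid in sample_ids]
        cols = _render_site_columns(
            np.array(order), sexes, site, qc_noise, noise_rng, male_x_dialect
        )
        filt = qc_noise.fail_label if site.key in failing_sites else "PASS"
        lines.append(
            f"chr{site.chromosome}\t{site.position}\t.\t{site.ref_allele}\t"
            f"{site.archaic_allele}\t5000\t{filt}\t.\tGT:GQ:DP:AD\t" + "\t".join(cols)
        )
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


def _render_site_columns(
    classes: np.ndarray,
    sexes: np.ndarray,
    site: VariantSite,
    noise: QCNoise,
    rng: np.random.Generator,
    male_x_dialect: str,
) -> list[str]:
    """GT:GQ:DP:AD sample columns for one site, vectorized.

    Noise genotypes each violate exactly one filter: low_gq draws
    GQ <= 20 (strict "GQ > 20" fails), low_dp draws DP <= 10, and
    skewed_ab (hets only) pushes the archaic-read fraction outside the
    open (0.25, 0.75) window while clean hets are clamped safely inside.
    """
    n = len(classes)
    is_het = classes == "het"
    gq = rng.integers(60, 100, size=n)
    dp = rng.integers(20, 61, size=n)
    u = rng.random(n)
    lg, ld, sk = noise.low_gq_rate, noise.low_dp_rate, noise.skewed_ab_rate
    low_gq = u < lg
    low_dp = ~low_gq & (u < lg + ld)
    skew = is_het & ~low_gq & ~low_dp & (u < lg + ld + sk)
    if low_gq.any():
        gq[low_gq] = rng.integers(2, 21, size=int(low_gq.sum()))
    if low_dp.any():
        dp[low_dp] = rng.integers(4, 11, size=int(low_dp.sum()))

    frac = rng.uniform(0.40, 0.60, size=n)
    skew_hi = rng.random(n) < 0.5
    frac = np.where(skew, np.where(skew_hi, 0.85, 0.12), frac)
    alt = np.rint(frac * dp).astype(int)
    lo_clamp = np.ceil(0.26 * dp).astype(int)
    hi_clamp = (0.74 * dp).astype(int)
    alt = np.where(skew, np.clip(alt, 0, dp), np.clip(alt, lo_clamp, hi_clamp))

    n_alt = np.select(
        [classes == "hom_alt", np.isin(classes, ("het", "hemi_alt"))], [2, 1], 0
    )
    ad_ref = np.where(is_het, dp - alt, np.where(n_alt > 0, 0, dp))
    ad_alt = np.where(is_het, alt, np.where(n_alt > 0, dp, 0))

    hemi = (site.chromosome == "X") & (sexes == "male")
    if male_x_dialect == "haploid":
        gt_hemi = np.where(n_alt > 0, "1", "0")
    else:
        gt_hemi = np.where(n_alt > 0, "1/1", "0/0")
    gt_dip = np.select([n_alt == 0, n_alt == 1], ["0/0", "0/1"], "1/1")
    gt = np.where(hemi, gt_hemi, gt_dip)

    return [
        f"{g}:{q}:{d}:{ar},{aa}"
        for g, q, d, ar, aa in zip(gt, gq, dp, ad_ref, ad_alt)
    ]


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class ContinuousTrait:
    mean: float
    sd: float
    beta: float = 0.0  # SD units per archaic allele dosage

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("trait SD must be > 0")


@dataclass(frozen=True)
class CategoricalTrait:
    probs: Mapping[str, float]
    carrier_logodds: Mapping[str, float] | None = None
    multiselect: bool = False  # emit "|"-joined multi-select responses

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"level probabilities sum to {total}, not 1")
        if self.carrier_logodds:
            unknown = set(self.carrier_logodds) - set(self.probs)
            if unknown:
                raise ValueError(f"unknown trait level(s) {sorted(unknown)}")


@dataclass(frozen=True)
class ParcelTrait:
    """Per-parcel cortical surface area (mm^2) and thickness (mm)."""

    area_mean: float = 3000.0
    area_sd: float = 300.0
    thickness_mean: float = 2.5
    thickness_sd: float = 0.12
    beta_area: float = 0.0
    beta_thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.area_sd <= 0 or self.thickness_sd <= 0:
            raise ValueError("parcel SDs must be > 0")


@dataclass
class EffectSpec:
    continuous: dict[str, ContinuousTrait] = field(default_factory=dict)
    categorical: dict[str, CategoricalTrait] = field(default_factory=dict)
    parcels: ParcelTrait | None = None
    missing_rate: float = 0.0


@dataclass
class PhenotypeTables:
    continuous: pd.DataFrame  # sample_id + one column per trait
    categorical: pd.DataFrame  # sample_id + one column per trait
    parcels: pd.DataFrame  # long form: sample_id, hemisphere, parcel, area, thickness


def generate_phenotypes(
    samples: pd.DataFrame,
    dosage: Mapping[str, int],
    effects: EffectSpec,
    seed: int,
) -> PhenotypeTables:
    """Draw phenotypes with an additive carrier effect.

    Continuous traits are Normal(mean + beta*sd*dosage, sd); categorical
    levels follow the stated probabilities, log-odds-shifted for
    carriers when specified; cortical parcels get per-parcel Normal
    draws with the carrier effect in SD units.  ``missing_rate``
    replaces continuous values with NaN and categorical responses with
    a nonresponse code, exercising the downstream merge rule.
    """
    rng = np.random.default_rng(seed)
    ids = samples["sample_id"].tolist()
    dose = np.array([int(dosage.get(sid, 0)) for sid in ids])

    cont = pd.DataFrame({"sample_id": ids})
    for trait, spec in effects.continuous.items():
        vals = rng.normal(
            spec.mean + spec.beta * spec.sd * dose, spec.sd, size=len(ids)
        )
        if effects.missing_rate:
            vals = np.where(
                rng.random(len(ids)) < effects.missing_rate, np.nan, vals
            )
        cont[trait] = np.round(vals, 4)

    cat = pd.DataFrame({"sample_id": ids})
    for trait, spec in effects.categorical.items():
        levels = list(spec.probs)
        base = np.array([spec.probs[l] for l in levels], dtype=float)
        responses = []
        for i in range(len(ids)):
            p = base
            if dose[i] > 0 and spec.carrier_logodds:
                logit = np.log(np.clip(base, 1e-12, None))
                logit = logit + np.array(
                    [dose[i] * spec.carrier_logodds.get(l, 0.0) for l in levels]
                )
                p = np.exp(logit - logit.max())
                p = p / p.sum()
            primary = levels[int(rng.choice(len(levels), p=p))]
            if effects.missing_rate and rng.random() < effects.missing_rate:
                responses.append(str(rng.choice(NONRESPONSE_LEVELS)))
                continue
            if spec.multiselect and rng.random() < 0.3:
                extra = levels[int(rng.choice(len(levels), p=base))]
                picked = {primary, extra}
                responses.append("|".join(sorted(picked)))
            else:
                responses.append(primary)
        cat[trait] = responses

    parcel_rows = []
    if effects.parcels is not None:
        from .phenotype_compare import FRONTAL_PARCELS

        p = effects.parcels
        for sid, d in zip(ids, dose):
            for hemi in ("lh", "rh"):
                areas = rng.normal(
                    p.area_mean + p.beta_area * p.area_sd * d,
                    p.area_sd, size=len(FRONTAL_PARCELS),
                )
                thicks = rng.normal(
                    p.thickness_mean + p.beta_thickness * p.thickness_sd * d,
                    p.thickness_sd, size=len(FRONTAL_PARCELS),
                )
                for parcel, a, t in zip(FRONTAL_PARCELS, areas, thicks):
                    parcel_rows.append(
                        {
                            "sample_id": sid,
                            "hemisphere": hemi,
                            "parcel": parcel,
                            "area_mm2": round(max(float(a), 1.0), 2),
                            "thickness_mm": round(max(float(t), 0.5), 4),
                        }
                    )
    parcels = pd.DataFrame(
        parcel_rows,
        columns=["sample_id", "hemisphere", "parcel", "area_mm2", "thickness_mm"],
    )
    return PhenotypeTables(continuous=cont, categorical=cat, parcels=parcels)


def dosage_from_carriers(
    carriers: pd.DataFrame, male_x_coding: int = 1
) -> dict[str, int]:
    """Archaic-allele dosage per sample from a discovery carrier table.

    het -> 1, hom_alt -> 2, hemi_alt -> ``male_x_coding`` (default 1,
    configurable to 2); summed over sites for multi-carriers.
    """
    if male_x_coding not in (1, 2):
        raise ValueError("male_x_coding must be 1 or 2")
    per_class = {"het": 1, "hom_alt": 2, "hemi_alt": male_x_coding}
    out: dict[str, int] = {}
    for sid, zyg in zip(carriers["sample_id"], carriers["zygosity"]):
        out[sid] = out.get(sid, 0) + per_class.get(zyg, 0)
    return out
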