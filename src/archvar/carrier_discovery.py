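"""Carrier discovery from exome VCF data at catalog sites.

Identifies carriers of the archaic allele under per-genotype QC
(site FILTER = PASS, GQ > 20, DP > 10, heterozygous allele balance
strictly between 25% and 75%), with sex-aware zygosity on chromosome X
(males are hemizygous), and tabulates per-ancestry genotype censuses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .variant_catalog import VariantSite

ZYGOSITIES = ("hom_ref", "het", "hom_alt", "hemi_ref", "hemi_alt")
CARRIER_CLASSES = frozenset({"het", "hom_alt", "hemi_alt"})
CENSUS_CLASSES = ZYGOSITIES + ("anomalous", "qc_failed", "missing")

SUPERCLUSTERS = ("SAS", "EAS", "EUR", "AFR", "Uncategorized")


@dataclass(frozen=True)
class QCThresholds:
    """Genotype-level QC bounds; all comparisons are strict."""

    gq_min: int = 20
    dp_min: int = 10
    ab_low: float = 0.25
    ab_high: float = 0.75
    require_pass: bool = True
    site_qual_min: float | None = None  # optional site-level QUAL check, off by default


@dataclass
class GenotypeCall:
    """One sample x site genotype with quality fields and QC verdict.

    ``zygosity`` is sex- and chromosome-aware: on chrX a male genotype
    is hemizygous (``hemi_ref``/``hemi_alt``); a male chrX heterozygote
    is flagged ``anomalous`` and excluded from the census proper.
    """

    sample_id: str
    site: VariantSite
    gt: str
    genotype_quality: int | None
    depth: int | None
    allele_depths: tuple[int, int] | None  # (ref, archaic)
    site_filter: str = "PASS"
    site_qual: float | None = None
    zygosity: str = "missing"
    qc_pass: bool = False
    qc_fail_reason: str = "none"

    @property
    def allele_balance(self) -> float | None:
        """Archaic-read fraction; defined only for hets with reads."""
        if self.zygosity != "het" or not self.allele_depths:
            return None
        ref_d, alt_d = self.allele_depths
        total = ref_d + alt_d
        return alt_d / total if total > 0 else None

    @property
    def is_carrier(self) -> bool:
        return self.qc_pass and self.zygosity in CARRIER_CLASSES


def classify_zygosity(gt: str, chromosome: str, sex: str) -> str:
    """Classify a normalized GT string ("0", "1", "0/0", "0/1", "1/1",
    "./." ...; 1 = archaic allele) given chromosome and sample sex.

    Autosomes and female chrX follow diploid rules; male chrX calls are
    hemizygous whether written haploid ("1") or diploid ("1/1").  A male
    chrX heterozygote is ``anomalous``; anything unparseable is
    ``missing``.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be male/female, got {sex!r}")
    alleles = gt.replace("|", "/").split("/")
    if any(a in (".", "") for a in alleles):
        return "missing"
    try:
        dose = [int(a) for a in alleles]
    except ValueError:
        return "missing"
    if any(a not in (0, 1) for a in dose):
        return "missing"  # allele other than ref/archaic
    chrom = chromosome.removeprefix("chr")
    hemizygous = chrom == "X" and sex == "male"
    if len(dose) == 1:
        if not hemizygous:
            return "missing"  # haploid call on a diploid context
        return "hemi_alt" if dose[0] == 1 else "hemi_ref"
    if len(dose) != 2:
        return "missing"
    n_alt = sum(dose)
    if hemizygous:
        if n_alt == 1:
            return "anomalous"
        return "hemi_alt" if n_alt == 2 else "hemi_ref"
    return {0: "hom_ref", 1: "het", 2: "hom_alt"}[n_alt]


def qc_genotype(call: GenotypeCall, thresholds: QCThresholds = QCThresholds()) -> GenotypeCall:
    """Apply genotype QC; first failing rule wins, in the fixed order
    site_filter -> low_gq -> low_dp -> allele_balance."""
    if call.zygosity == "missing":
        return replace(call, qc_pass=False, qc_fail_reason="missing")
    if thresholds.require_pass and call.site_filter != "PASS":
        return replace(call, qc_pass=False, qc_fail_reason="site_filter")
    if thresholds.site_qual_min is not None and (
        call.site_qual is None or call.site_qual <= thresholds.site_qual_min
    ):
        return replace(call, qc_pass=False, qc_fail_reason="site_filter")
    if call.genotype_quality is None or call.depth is None:
        return replace(call, qc_pass=False, qc_fail_reason="missing")
    if not call.genotype_quality > thresholds.gq_min:
        return replace(call, qc_pass=False, qc_fail_reason="low_gq")
    if not call.depth > thresholds.dp_min:
        return replace(call, qc_pass=False, qc_fail_reason="low_dp")
    if call.zygosity == "het":
        ab = call.allele_balance
        if ab is None or not (thresholds.ab_low < ab < thresholds.ab_high):
            return replace(call, qc_pass=False, qc_fail_reason="allele_balance")
    return replace(call, qc_pass=True, qc_fail_reason="none")


@dataclass
class CarrierCensus:
    """Per site x supercluster x zygosity-class counts plus QC attrition.

    ``counts[site.key][supercluster][cls]`` for cls in CENSUS_CLASSES;
    per-site denominators differ because QC attrition is per genotype.
    """

    counts: dict[tuple[str, int], dict[str, Counter]] = field(default_factory=dict)
    queried_n: dict[tuple[str, int], int] = field(default_factory=dict)
    unqueryable: list[tuple[str, int]] = field(default_factory=list)

    def add(self, site: VariantSite, supercluster: str, cls: str) -> None:
        per_site = self.counts.setdefault(site.key, {})
        per_site.setdefault(supercluster, Counter())[cls] += 1
        self.queried_n[site.key] = self.queried_n.get(site.key, 0) + 1

    def site_total(self, site: VariantSite, cls: str) -> int:
        return sum(c.get(cls, 0) for c in self.counts.get(site.key, {}).values())

    def carriers_at(self, site: VariantSite) -> int:
        return sum(self.site_total(site, c) for c in ("het", "hom_alt", "hemi_alt"))

    def to_frame(self, sites: Sequence[VariantSite]) -> pd.DataFrame:
        """Long-form census table (one row per site x supercluster)."""
        rows = []
        for site in sites:
            per_site = self.counts.get(site.key, {})
            for sc in SUPERCLUSTERS:
                counter = per_site.get(sc, Counter())
                row = {
                    "gene": site.gene,
                    "chrom": site.chromosome,
                    "pos_hg38": site.position,
                    "supercluster": sc,
                }
                row.update({cls: counter.get(cls, 0) for cls in CENSUS_CLASSES})
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class DiscoveryResult:
    carriers: pd.DataFrame  # sample_id, gene, chrom, pos_hg38, zygosity
    census: CarrierCensus
    calls: list[GenotypeCall]

    def unique_carriers(self) -> int:
        return self.carriers["sample_id"].nunique()

    def carrier_instances(self) -> int:
        return len(self.carriers)

    def carrier_ids(self, site: VariantSite | None = None) -> list[str]:
        df = self.carriers
        if site is not None:
            df = df[(df["chrom"] == site.chromosome) & (df["pos_hg38"] == site.position)]
        return sorted(df["sample_id"].unique())


def _normalize_gt(
    sample_rec, record_alleles: tuple[str, ...], ref: str, archaic: str
) -> str:
    """Rewrite a pysam genotype as a "0/1"-style string with 1 = the
    configured archaic allele; any other ALT allele maps to "2"
    (rendered missing downstream)."""
    gt = sample_rec.get("GT")
    if gt is None or all(a is None for a in gt):
        return "."
    mapped = []
    for a in gt:
        if a is None:
            mapped.append(".")
            continue
        base = record_alleles[a]
        if base == ref:
            mapped.append("0")
        elif base == archaic:
            mapped.append("1")
        else:
            mapped.append("2")
    return "/".join(mapped)


def discover_carriers(
    vcf_path: str | Path,
    sites: Sequence[VariantSite],
    samples: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    keep_calls: bool = False,
) -> DiscoveryResult:
    """Scan a VCF for archaic-allele carriers at the catalog sites.

    ``samples`` needs columns sample_id, sex, supercluster and is
    assumed restricted to sample-level-QC passes.  A carrier is any
    QC-passing genotype with >= 1 archaic allele.  Catalog sites absent
    from the VCF are reported in ``census.unqueryable``, never silently
    skipped.
    """
    required = {"sample_id", "sex", "supercluster"}
    if not required <= set(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    meta = samples.set_index("sample_id")
    site_by_key = {s.key: s for s in sites}

    census = CarrierCensus()
    carrier_rows: list[dict] = []
    kept: list[GenotypeCall] = []
    seen_keys: set[tuple[str, int]] = set()

    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = [s for s in vcf.header.samples if s in meta.index]
        for record in vcf:
            key = (record.chrom.removeprefix("chr"), record.pos)
            site = site_by_key.get(key)
            if site is None:
                continue
            seen_keys.add(key)
            filter_keys = list(record.filter.keys())
            site_filter = filter_keys[0] if filter_keys else "PASS"
            alleles = tuple(record.alleles)
            for sid in vcf_samples:
                srec = record.samples[sid]
                sex = meta.at[sid, "sex"]
                sc = meta.at[sid, "supercluster"]
                gt = _normalize_gt(srec, alleles, site.ref_allele, site.archaic_allele)
                ad = srec.get("AD")
                call = GenotypeCall(
                    sample_id=sid,
                    site=site,
                    gt=gt,
                    genotype_quality=srec.get("GQ"),
                    depth=srec.get("DP"),
                    allele_depths=tuple(int(x) for x in ad[:2]) if ad is not None else None,
                    site_filter=site_filter,
                    site_qual=record.qual,
                    zygosity=classify_zygosity(gt, site.chromosome, sex),
                )
                call = qc_genotype(call, thresholds)
                if call.zygosity == "anomalous":
                    census.add(site, sc, "anomalous")
                elif not call.qc_pass:
                    census.add(
                        site, sc, "missing" if call.qc_fail_reason == "missing" else "qc_failed"
                    )
                else:
                    census.add(site, sc, call.zygosity)
                    if call.is_carrier:
                        carrier_rows.append(
                            {
                                "sample_id": sid,
                                "gene": site.gene,
                                "chrom": site.chromosome,
                                "pos_hg38": site.position,
                                "zygosity": call.zygosity,
                            }
                        )
                if keep_calls:
                    kept.append(call)

    census.unqueryable = sorted(k for k in site_by_key if k not in seen_keys)
    carriers = pd.DataFrame(
        carrier_rows, columns=["sample_id", "gene", "chrom", "pos_hg38", "zygosity"]
    )
    return DiscoveryResult(carriers=carriers, census=census, calls=kept)


def find_cocarriage(carriers: pd.DataFrame) -> pd.DataFrame:
    """Samples carrying more than one archaic allele site.

    Returns one row per multi-carrier with the sorted site labels and
    the distinct genes involved (cross-gene co-carriage is reported
    once, with both genes listed).
    """
    if carriers.empty:
        return pd.DataFrame(columns=["sample_id", "n_sites", "sites", "genes"])
    rows = []
    for sid, grp in carriers.groupby("sample_id"):
        if len(grp) < 2:
            continue
        ordered = grp.sort_values(["chrom", "pos_hg38"])
        rows.append(
            {
                "sample_id": sid,
                "n_sites": len(grp),
                "sites": ";".join(
                    f"chr{c}:{p}" for c, p in zip(ordered["chrom"], ordered["pos_hg38"])
                ),
                "genes": ";".join(sorted(set(ordered["gene"]))),
            }
        )
    return (
        pd.DataFrame(rows, columns=["sample_id", "n_sites", "sites", "genes"])
        .sort_values("sample_id")
        .reset_index(drop=True)
    )
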