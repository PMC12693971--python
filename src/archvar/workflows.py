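"""End-to-end study workflows over the reference fixture bundles.

Each function runs one published analysis configuration from scratch —
building the fixture, running discovery/pruning/matching through the
library — and returns the headline quantities.  Used by the analysis
drivers and the reproduction script alike.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ancestry_relatedness import prune_related
from .carrier_discovery import DiscoveryResult, discover_carriers
from .cohort_matching import PRESETS, MatchedCohort, match_cohort
from .fixtures import FixtureBundle, build_fixture
from .variant_catalog import curate, drop_sites
from .power import bonferroni, detectable_beta


def catalog_curation_counts(out_dir: str | Path) -> dict[str, int]:
    """Curate the 42-site source catalog: retained site and gene counts,
    plus queryable sites after dropping the non-PASS position."""
    bundle = build_fixture("catalog42", out_dir)
    res = curate(bundle.catalog, bundle.rules)
    queryable = drop_sites(res.retained, [("9", 6606647)], "non_pass_filter")
    return {
        "sites_in_source": len(bundle.catalog),
        "sites_retained": res.n_sites,
        "genes_retained": res.n_genes,
        "sites_queryable": queryable.n_sites,
    }


def tktl1_census(
    out_dir: str | Path, seed: int | None = None
) -> tuple[dict[str, int], DiscoveryResult, FixtureBundle]:
    """Sex-aware TKTL1 discovery on the X-chromosome census fixture."""
    bundle = build_fixture("table2_tktl1", out_dir, seed=seed)
    disc = discover_carriers(bundle.vcf_path, bundle.catalog, bundle.samples)
    site = bundle.catalog[0]
    counts = {
        "unique_carriers": disc.unique_carriers(),
        "het_female": disc.census.site_total(site, "het"),
        "hom_female": disc.census.site_total(site, "hom_alt"),
        "hemi_male": disc.census.site_total(site, "hemi_alt"),
    }
    return counts, disc, bundle


def ssh2_pruned_carriers(
    out_dir: str | Path, seed: int | None = None
) -> tuple[list[str], FixtureBundle, DiscoveryResult]:
    """SSH2 carrier set after the strict ancestry-label restriction and
    carrier-prioritized relatedness pruning."""
    bundle = build_fixture("ssh2_cohort", out_dir, seed=seed)
    disc = discover_carriers(bundle.vcf_path, bundle.catalog, bundle.samples)
    carrier_ids = disc.carrier_ids()
    meta = bundle.samples.set_index("sample_id")
    strict = [
        s for s in carrier_ids if meta.at[s, "strict_label"] == "White_British"
    ]
    retained, _ = prune_related(strict, bundle.kinship, carriers=carrier_ids)
    return retained, bundle, disc


def _matched_for(
    bundle: FixtureBundle, carrier_ids: list[str], preset: str
) -> MatchedCohort:
    carriers = bundle.samples[bundle.samples["sample_id"].isin(set(carrier_ids))]
    # pool = QC-passing noncarriers (fixture pools carry no QC flags)
    pool = bundle.samples[~bundle.samples["sample_id"].isin(set(carrier_ids))]
    return match_cohort(carriers, pool, PRESETS[preset])


def ssh2_matched_cohort(
    out_dir: str | Path, seed: int | None = None
) -> MatchedCohort:
    """SSH2 design: 2079 unique controls per pruned carrier, exact sex
    and strict label, age caliper."""
    retained, bundle, disc = ssh2_pruned_carriers(out_dir, seed=seed)
    # pool excludes every carrier (pruned ones included): controls must
    # be noncarriers at the site
    pool_ok = ~bundle.samples["sample_id"].isin(set(disc.carrier_ids()))
    carriers = bundle.samples[bundle.samples["sample_id"].isin(retained)]
    return match_cohort(carriers, bundle.samples[pool_ok], PRESETS["ssh2"])


def tktl1_imaging_cohort(
    out_dir: str | Path, seed: int | None = None
) -> MatchedCohort:
    """TKTL1 imaging design: 429 age/sex-matched controls per carrier,
    across ancestries."""
    bundle = build_fixture("tktl1_imaging", out_dir, seed=seed)
    disc = discover_carriers(bundle.vcf_path, bundle.catalog, bundle.samples)
    ids = disc.carrier_ids()
    return _matched_for(bundle, ids, "tktl1_imaging")


def tktl1_qualification_cohort(
    out_dir: str | Path, seed: int | None = None
) -> MatchedCohort:
    """TKTL1 qualification design: 20 controls per carrier with PC1/PC2,
    age, and sex calipers."""
    bundle = build_fixture("tktl1_qualification", out_dir, seed=seed)
    disc = discover_carriers(bundle.vcf_path, bundle.catalog, bundle.samples)
    ids = disc.carrier_ids()
    return _matched_for(bundle, ids, "tktl1_qualification")


def ssh2_power_analysis(
    maf: float = 0.00005,
    n: int = 423_887,
    alpha_family: float = 0.05,
    m_tests: int = 12,
    target_power: float = 0.80,
) -> dict[str, float]:
    """Detectable standardized effect for the SSH2 design: twelve
    Bonferroni-corrected traits, the full QC-passing sample."""
    alpha, display = bonferroni(alpha_family, m_tests)
    beta = detectable_beta(maf, n, alpha, target_power)
    return {
        "alpha_per_test": alpha,
        "alpha_display": display,
        "detectable_beta": beta,
        "target_power": target_power,
        "maf": maf,
        "n": n,
    }
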