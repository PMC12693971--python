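"""Archaic-variant catalog: loading, validation, and curation.

A catalog row is one genomic position (hg38, 1-based) at which archaic
hominins carry the ancestral allele while present-day humans carry a
derived allele at or near fixation.  Curation applies position-level
exclusion rules (non-exonic, ambiguous liftover, non-PASS site filter)
and explicit high-frequency inclusions, and reports retained site and
distinct-gene counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

VALID_BASES = frozenset("ACGT")
VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])
EXCLUSION_REASONS = frozenset(
    {"non_exonic", "ambiguous_liftover", "non_pass_filter", "none"}
)


class CatalogError(ValueError):
    """Malformed catalog input."""


@dataclass(frozen=True)
class VariantSite:
    """One catalog entry.

    ``archaic_allele`` is the ancestral allele shared with archaic
    hominins; ``ref_allele`` the hg38 reference (the derived human
    allele at these sites).  ``catalog_status`` records whether the
    site entered the catalog as fully fixed (``fixed_af1``) or as a
    near-fixed high-frequency change (``high_frequency``).
    """

    gene: str
    chromosome: str
    position: int
    ref_allele: str
    archaic_allele: str
    catalog_status: str = "fixed_af1"
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.chromosome not in VALID_CHROMS:
            raise CatalogError(f"invalid chromosome {self.chromosome!r}")
        if self.position <= 0:
            raise CatalogError(f"nonpositive position {self.position}")
        if self.ref_allele not in VALID_BASES:
            raise CatalogError(f"malformed ref allele {self.ref_allele!r}")
        if self.archaic_allele not in VALID_BASES:
            raise CatalogError(f"malformed archaic allele {self.archaic_allele!r}")
        if self.ref_allele == self.archaic_allele:
            raise CatalogError(
                f"{self.gene} {self.chromosome}:{self.position}: "
                "ref and archaic alleles are identical"
            )
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise CatalogError(f"unknown exclusion reason {self.exclusion_reason!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chromosome, self.position)

    @property
    def label(self) -> str:
        return f"chr{self.chromosome}:{self.position}"


REQUIRED_COLUMNS = ("gene", "chrom", "pos_hg38", "ref", "archaic")


def load_catalog(path: str | Path) -> list[VariantSite]:
    """Load and validate a catalog TSV/CSV.

    Required columns: gene, chrom, pos_hg38, ref, archaic; optional
    ``status`` (default ``fixed_af1``).  Duplicate chromosome+position
    pairs are rejected.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog missing required columns: {missing}")
    sites: list[VariantSite] = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        pos = int(row.pos_hg38)
        chrom = str(row.chrom).removeprefix("chr")
        site = VariantSite(
            gene=str(row.gene),
            chromosome=chrom,
            position=pos,
            ref_allele=str(row.ref).upper(),
            archaic_allele=str(row.archaic).upper(),
            catalog_status=str(getattr(row, "status", "fixed_af1")),
        )
        if site.key in seen:
            raise CatalogError(f"duplicate catalog site {site.label}")
        seen.add(site.key)
        sites.append(site)
    return sites


def write_catalog(sites: Iterable[VariantSite], path: str | Path) -> None:
    """Write sites as the canonical catalog TSV."""
    df = pd.DataFrame(
        {
            "gene": [s.gene for s in sites],
            "chrom": [s.chromosome for s in sites],
            "pos_hg38": [s.position for s in sites],
            "ref": [s.ref_allele for s in sites],
            "archaic": [s.archaic_allele for s in sites],
            "status": [s.catalog_status for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class CurationRules:
    """Position-level curation: exclusions with reasons, plus explicit
    high-frequency inclusions appended to the retained list."""

    exclusions: dict[tuple[str, int], str] = field(default_factory=dict)
    inclusions: list[VariantSite] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurationRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        excl = {}
        for item in raw.get("exclusions", []):
            chrom = str(item["chrom"]).removeprefix("chr")
            excl[(chrom, int(item["pos_hg38"]))] = str(item["reason"])
        incl = [
            VariantSite(
                gene=str(i["gene"]),
                chromosome=str(i["chrom"]).removeprefix("chr"),
                position=int(i["pos_hg38"]),
                ref_allele=str(i["ref"]).upper(),
                archaic_allele=str(i["archaic"]).upper(),
                catalog_status=str(i.get("status", "high_frequency")),
            )
            for i in raw.get("inclusions", [])
        ]
        return cls(exclusions=excl, inclusions=incl)


@dataclass(frozen=True)
class CurationResult:
    retained: list[VariantSite]
    excluded: list[VariantSite]  # carry exclusion_reason

    @property
    def n_sites(self) -> int:
        return len(self.retained)

    @property
    def n_genes(self) -> int:
        return len({s.gene for s in self.retained})


def curate(sites: Sequence[VariantSite], rules: CurationRules) -> CurationResult:
    """Apply curation rules: retained = input - exclusions + inclusions.

    An exclusion rule naming a position absent from the catalog warns and
    is skipped.  Idempotent under re-application of the same rules.
    """
    for reason in rules.exclusions.values():
        if reason not in EXCLUSION_REASONS - {"none"}:
            raise CatalogError(f"unknown exclusion reason {reason!r}")
    present = {s.key for s in sites}
    for key in rules.exclusions:
        if key not in present:
            warnings.warn(
                f"exclusion rule references absent site chr{key[0]}:{key[1]}",
                stacklevel=2,
            )
    retained: list[VariantSite] = []
    excluded: list[VariantSite] = []
    for site in sites:
        reason = rules.exclusions.get(site.key)
        if reason is not None:
            excluded.append(replace(site, excluded=True, exclusion_reason=reason))
        else:
            retained.append(site)
    retained_keys = {s.key for s in retained}
    for inc in rules.inclusions:
        if inc.key not in retained_keys:
            retained.append(inc)
            retained_keys.add(inc.key)
    return CurationResult(retained=retained, excluded=excluded)


def drop_sites(
    sites: Sequence[VariantSite], positions: Iterable[tuple[str, int]], reason: str
) -> CurationResult:
    """Drop the named positions with one shared reason (e.g. the
    site-filter failure discovered at query time)."""
    rules = CurationRules(exclusions={
        (str(c).removeprefix("chr"), int(p)): reason for c, p in positions
    })
    return curate(sites, rules)
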