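"""Carrier-vs-matched-cohort phenotype summaries.

No hypothesis testing is performed: with a handful of rare-allele
carriers the informative comparison is where each carrier sits within
the matched noncarrier distribution.  Continuous traits get carrier
means with t-based 95% CIs against control quartiles and 1.5*IQR
whiskers; categorical traits get per-level proportions with Wilson
score intervals; qualification responses collapse to the highest
reported level; frontal-lobe composites sum / average the 11
Desikan-Killiany frontal parcels per hemisphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Nonresponse options collapsed to one combined level before summarizing.
NONRESPONSE_LEVELS = ("Do not know", "Do not want to answer", "None of the above")
COMBINED_NONRESPONSE = "Nonresponse/none of the above"

#: Highest-first qualification ranking (an explicit package choice; the
#: biobank field is multi-select, only the highest level is analyzed).
QUALIFICATION_RANKING = (
    "College or University degree",
    "A levels/AS levels or equivalent",
    "O levels/GCSEs or equivalent",
    "CSEs or equivalent",
    "NVQ or HND or HNC or equivalent",
    "Other professional qualifications",
    COMBINED_NONRESPONSE,
)

#: Desikan-Killiany parcels composing the frontal lobe.
FRONTAL_PARCELS = (
    "superiorfrontal",
    "rostralmiddlefrontal",
    "caudalmiddlefrontal",
    "parsopercularis",
    "parstriangularis",
    "parsorbitalis",
    "lateralorbitofrontal",
    "medialorbitofrontal",
    "precentral",
    "paracentral",
    "frontalpole",
)


def merge_nonresponse(levels: Mapping[str, int]) -> dict[str, int]:
    """Collapse the nonresponse options into one combined level;
    counts are additive, other levels pass through unchanged."""
    merged: dict[str, int] = {}
    for level, count in levels.items():
        key = COMBINED_NONRESPONSE if level in NONRESPONSE_LEVELS else level
        merged[key] = merged.get(key, 0) + count
    return merged


def highest_qualification(
    reported: Iterable[str],
    ranking: Sequence[str] = QUALIFICATION_RANKING,
) -> str | None:
    """Highest reported qualification under a total order (index 0 is
    highest).  Nonresponse options are merged before ranking.  Empty
    report set -> None (missing)."""
    merged = {
        COMBINED_NONRESPONSE if r in NONRESPONSE_LEVELS else r for r in reported
    }
    if not merged:
        return None
    unknown = merged - set(ranking)
    if unknown:
        raise ValueError(f"levels absent from ranking: {sorted(unknown)}")
    return min(merged, key=ranking.index)


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    carrier_n: int
    carrier_mean: float
    carrier_ci: tuple[float, float] | None  # None when n = 1 (flagged)
    control_n: int
    control_quartiles: tuple[float, float, float]  # 25th, 50th, 75th
    whiskers: tuple[float, float]  # 1.5*IQR bounds clipped to data range
    carrier_percentiles: tuple[float, ...]  # per-carrier rank in controls


def summarize_continuous(
    trait: str,
    carrier_values: Sequence[float],
    control_values: Sequence[float],
    ci_method: str = "t",
) -> TraitSummary:
    """Continuous-trait placement of carriers within the control
    distribution.

    The carrier 95% CI uses the t distribution with n-1 df by default
    (``ci_method="normal"`` switches to the z interval).  Control
    quartiles use linear interpolation between order statistics;
    whiskers extend 1.5*IQR beyond the quartiles, clipped to the
    observed control range.  Per-carrier percentile is the fraction of
    controls strictly below, with midpoint correction for ties.
    """
    x = np.asarray(carrier_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one carrier value")
    if len(y) < 4:
        raise ValueError("need at least four control values")
    mean = float(np.mean(x))
    if len(x) == 1:
        ci = None
    else:
        se = float(np.std(x, ddof=1)) / math.sqrt(len(x))
        if ci_method == "t":
            crit = float(stats.t.ppf(0.975, df=len(x) - 1))
        elif ci_method == "normal":
            crit = float(stats.norm.ppf(0.975))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        ci = (mean - crit * se, mean + crit * se)
    q25, q50, q75 = (float(np.quantile(y, q)) for q in (0.25, 0.5, 0.75))
    iqr = q75 - q25
    lo = max(float(y.min()), q25 - 1.5 * iqr)
    hi = min(float(y.max()), q75 + 1.5 * iqr)
    y_sorted = np.sort(y)
    below = np.searchsorted(y_sorted, x, side="left")
    at_or_below = np.searchsorted(y_sorted, x, side="right")
    pct = (below + 0.5 * (at_or_below - below)) / len(y)
    return TraitSummary(
        trait=trait,
        carrier_n=len(x),
        carrier_mean=mean,
        carrier_ci=ci,
        control_n=len(y),
        control_quartiles=(q25, q50, q75),
        whiskers=(lo, hi),
        carrier_percentiles=tuple(float(p) for p in pct),
    )


def proportions_wilson(
    k: int, n: int, z: float = 1.959963984540054
) -> tuple[float, tuple[float, float]]:
    """Wilson score interval for a binomial proportion.

    Returns (k/n, (low, high)) with
    center = (p + z^2/2n) / (1 + z^2/n) and half-width
    (z / (1 + z^2/n)) * sqrt(p(1-p)/n + z^2/4n^2), clipped to [0, 1].
    Inverts the score test, so coverage holds up at extreme proportions
    where the Wald interval collapses.
    """
    if n < 1:
        raise ValueError("n must be >= 1 (n = 0 proportion is undefined)")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if z <= 0:
        raise ValueError("z must be > 0")
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    # at k = 0 / k = n the closed form gives exactly 0 / 1; pin them so
    # roundoff never pushes the bound inside k/n
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)
    return p, (lo, hi)


@dataclass(frozen=True)
class CategoricalSummary:
    trait: str
    levels: tuple[str, ...]
    arms: dict[str, pd.DataFrame]  # arm -> level, count, proportion, wilson bounds


def summarize_categorical(
    trait: str,
    arm_counts: Mapping[str, Mapping[str, int]],
    z: float = 1.959963984540054,
) -> CategoricalSummary:
    """Per-level proportions with Wilson 95% intervals for each arm,
    after nonresponse merging.  Proportions per arm sum to 1 exactly."""
    merged = {arm: merge_nonresponse(counts) for arm, counts in arm_counts.items()}
    levels = tuple(sorted({lvl for c in merged.values() for lvl in c}))
    arms: dict[str, pd.DataFrame] = {}
    for arm, counts in merged.items():
        n = sum(counts.values())
        rows = []
        for lvl in levels:
            kk = counts.get(lvl, 0)
            if n == 0:
                rows.append({"level": lvl, "count": 0, "proportion": float("nan"),
                             "wilson_low": float("nan"), "wilson_high": float("nan")})
                continue
            p, (lo, hi) = proportions_wilson(kk, n, z)
            rows.append({"level": lvl, "count": kk, "proportion": p,
                         "wilson_low": lo, "wilson_high": hi})
        arms[arm] = pd.DataFrame(rows)
    return CategoricalSummary(trait=trait, levels=levels, arms=arms)


@dataclass(frozen=True)
class FrontalComposite:
    sample_id: str
    hemisphere: str  # lh | rh
    surface_area_total: float  # mm^2, sum over the 11 parcels
    thickness_mean: float  # mm, unweighted mean over the 11 parcels


def frontal_composites(
    parcels: pd.DataFrame,
    weights: str = "unweighted",
) -> tuple[list[FrontalComposite], list[tuple[str, str]]]:
    """Frontal-lobe composites per sample and hemisphere.

    ``parcels`` is long-form with columns sample_id, hemisphere, parcel,
    area_mm2, thickness_mm covering the 11 frontal parcels.  Area is the
    parcel sum; thickness the unweighted parcel mean by default
    (``weights="area"`` switches to area weighting).  A sample missing
    any parcel in a hemisphere yields no composite for it and is
    returned in the skip log.  Negative parcel values are an error.
    """
    needed = {"sample_id", "hemisphere", "parcel", "area_mm2", "thickness_mm"}
    if not needed <= set(parcels.columns):
        raise ValueError(f"parcel table needs columns {sorted(needed)}")
    if (parcels["area_mm2"] < 0).any() or (parcels["thickness_mm"] < 0).any():
        raise ValueError("negative parcel value")
    out: list[FrontalComposite] = []
    skipped: list[tuple[str, str]] = []
    wanted = set(FRONTAL_PARCELS)
    for (sid, hemi), grp in parcels.groupby(["sample_id", "hemisphere"], sort=True):
        grp = grp[grp["parcel"].isin(wanted)].drop_duplicates("parcel")
        if set(grp["parcel"]) != wanted:
            skipped.append((sid, hemi))
            continue
        area = float(grp["area_mm2"].sum())
        if weights == "area":
            thick = float(
                np.average(grp["thickness_mm"], weights=grp["area_mm2"])
            )
        else:
            thick = float(grp["thickness_mm"].mean())
        out.append(FrontalComposite(sid, hemi, area, thick))
    return out, skipped
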