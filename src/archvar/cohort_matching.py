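"""Matched noncarrier cohort construction.

Each carrier receives exactly k globally unique controls drawn from a
pool of QC-passing, unrelated noncarriers, under exact constraints
(sex, supercluster, strict ancestry label) and calipers (age, PC1/PC2
half-widths).  Assignment is greedy in ascending carrier-id order;
within a carrier, candidates are ranked by absolute age difference,
then PC1/PC2 Euclidean distance, then sample id.

Shipped presets mirror the study designs this package reimplements:
``ssh2`` (exact sex + strict label, age +-2.5, 2079 controls/carrier),
``tktl1_imaging`` (age +-2.5 and sex only, across ancestries, 429
controls/carrier), ``tktl1_sensitivity`` (PC1/PC2 +-2.5, age +-2.5,
sex, 10/carrier) and ``tktl1_qualification`` (same calipers, 20/carrier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


class MatchingError(RuntimeError):
    """A carrier could not receive its full complement of controls."""


@dataclass(frozen=True)
class MatchSpec:
    """Matching design: ratio, exact fields, calipers."""

    ratio: int
    exact_on: tuple[str, ...] = ("sex",)
    age_caliper: float | None = None
    pc_calipers: dict[str, float] | None = None  # e.g. {"pc1": 2.5, "pc2": 2.5}

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio k must be >= 1")
        if self.age_caliper is not None and self.age_caliper < 0:
            raise ValueError("age caliper must be >= 0")
        for v in (self.pc_calipers or {}).values():
            if v < 0:
                raise ValueError("PC calipers must be >= 0")
        allowed = {"sex", "supercluster", "strict_label"}
        if not set(self.exact_on) <= allowed:
            raise ValueError(f"exact_on fields must be within {sorted(allowed)}")

    @classmethod
    def from_yaml(cls, path) -> "MatchSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            ratio=int(raw["ratio"]),
            exact_on=tuple(raw.get("exact_on", ["sex"])),
            age_caliper=raw.get("age_caliper"),
            pc_calipers=raw.get("pc_calipers"),
        )


PRESETS: dict[str, MatchSpec] = {
    "ssh2": MatchSpec(
        ratio=2079, exact_on=("sex", "strict_label"), age_caliper=2.5
    ),
    "tktl1_imaging": MatchSpec(ratio=429, exact_on=("sex",), age_caliper=2.5),
    "tktl1_sensitivity": MatchSpec(
        ratio=10, exact_on=("sex",), age_caliper=2.5,
        pc_calipers={"pc1": 2.5, "pc2": 2.5},
    ),
    "tktl1_qualification": MatchSpec(
        ratio=20, exact_on=("sex",), age_caliper=2.5,
        pc_calipers={"pc1": 2.5, "pc2": 2.5},
    ),
}


def eligible_controls(
    carrier: pd.Series, pool: pd.DataFrame, spec: MatchSpec
) -> pd.DataFrame:
    """Candidates from the pool satisfying every exact field and caliper
    relative to one carrier, sorted by (|age diff|, PC1/PC2 distance,
    sample_id).  An empty frame is a valid result."""
    mask = np.ones(len(pool), dtype=bool)
    for field_name in spec.exact_on:
        mask &= (pool[field_name] == carrier[field_name]).to_numpy()
    if spec.age_caliper is not None:
        mask &= (
            (pool["age"] - carrier["age"]).abs() <= spec.age_caliper
        ).to_numpy()
    for pc, width in (spec.pc_calipers or {}).items():
        mask &= ((pool[pc] - carrier[pc]).abs() <= width).to_numpy()
    cand = pool[mask].copy()
    cand["_age_diff"] = (cand["age"] - carrier["age"]).abs()
    if {"pc1", "pc2"} <= set(cand.columns):
        cand["_pc_dist"] = np.hypot(
            cand["pc1"] - carrier.get("pc1", 0.0),
            cand["pc2"] - carrier.get("pc2", 0.0),
        )
    else:
        cand["_pc_dist"] = 0.0
    cand = cand.sort_values(["_age_diff", "_pc_dist", "sample_id"])
    return cand.drop(columns=["_age_diff", "_pc_dist"])


@dataclass
class MatchedCohort:
    """Carriers with k globally unique controls each, plus provenance."""

    spec: MatchSpec
    assignments: dict[str, list[str]]  # carrier id -> control ids
    carriers: pd.DataFrame
    controls: pd.DataFrame

    @property
    def control_ids(self) -> list[str]:
        out: list[str] = []
        for ids in self.assignments.values():
            out.extend(ids)
        return out

    @property
    def n_controls(self) -> int:
        return len(set(self.control_ids))

    def audit(self) -> int:
        """Re-check every matched pair against the spec; return the
        number of violations (0 on a valid cohort)."""
        violations = 0
        pool = self.controls.set_index("sample_id")
        for cid, ctrl_ids in self.assignments.items():
            carrier = self.carriers.set_index("sample_id").loc[cid]
            for sid in ctrl_ids:
                ctrl = pool.loc[sid]
                for f in self.spec.exact_on:
                    if ctrl[f] != carrier[f]:
                        violations += 1
                if self.spec.age_caliper is not None and (
                    abs(ctrl["age"] - carrier["age"]) > self.spec.age_caliper
                ):
                    violations += 1
                for pc, w in (self.spec.pc_calipers or {}).items():
                    if abs(ctrl[pc] - carrier[pc]) > w:
                        violations += 1
        ids = self.control_ids
        if len(ids) != len(set(ids)):
            violations += len(ids) - len(set(ids))
        return violations


def match_cohort(
    carriers: pd.DataFrame,
    pool: pd.DataFrame,
    spec: MatchSpec,
    allow_partial: bool = False,
) -> MatchedCohort:
    """Greedy matched-cohort construction with global control uniqueness.

    Carriers are processed in ascending sample_id order; each consumes
    its k best-ranked remaining candidates, which leave the pool.  A
    carrier with fewer than k remaining candidates raises
    :class:`MatchingError` naming the carrier and shortfall, unless
    ``allow_partial``.
    """
    if carriers["sample_id"].isin(pool["sample_id"]).any():
        raise ValueError("pool must be disjoint from the carrier set")
    assignments: dict[str, list[str]] = {}
    available = pool.copy()
    taken: list[pd.DataFrame] = []
    for _, carrier in carriers.sort_values("sample_id").iterrows():
        cand = eligible_controls(carrier, available, spec)
        if len(cand) < spec.ratio and not allow_partial:
            raise MatchingError(
                f"carrier {carrier['sample_id']}: only {len(cand)} eligible "
                f"controls remain, need {spec.ratio} "
                f"(shortfall {spec.ratio - len(cand)})"
            )
        chosen = cand.head(spec.ratio)
        assignments[carrier["sample_id"]] = chosen["sample_id"].tolist()
        taken.append(chosen)
        available = available[~available["sample_id"].isin(chosen["sample_id"])]
    controls = (
        pd.concat(taken, ignore_index=True)
        if taken
        else pool.head(0).copy()
    )
    return MatchedCohort(
        spec=spec, assignments=assignments,
        carriers=carriers.reset_index(drop=True), controls=controls,
    )


@dataclass(frozen=True)
class ArmSummary:
    n: int
    n_female: int
    age_mean: float
    age_sd: float
    degenerate_sd: bool = False  # single-sample arm: SD reported as 0


def _summarize_arm(df: pd.DataFrame) -> ArmSummary:
    ages = df["age"].to_numpy(dtype=float)
    degenerate = len(ages) < 2
    sd = 0.0 if degenerate else float(np.std(ages, ddof=1))
    return ArmSummary(
        n=len(df),
        n_female=int((df["sex"] == "female").sum()),
        age_mean=float(np.mean(ages)) if len(ages) else float("nan"),
        age_sd=sd,
        degenerate_sd=degenerate,
    )


def summarize_cohort(cohort: MatchedCohort) -> dict[str, ArmSummary]:
    """Per-arm n, female count, and age mean +- SD (n-1 denominator)."""
    ctrl_ids = set(cohort.control_ids)
    controls = cohort.controls[
        cohort.controls["sample_id"].isin(ctrl_ids)
    ].drop_duplicates("sample_id")
    return {
        "carriers": _summarize_arm(cohort.carriers),
        "controls": _summarize_arm(controls),
    }
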