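#!/usr/bin/env python
"""Carrier-vs-cohort phenotype summaries.

SSH2: continuous traits (carrier mean with t-based 95% CI against the
matched-control quartiles and per-carrier percentile placement) and
categorical traits (highest qualification, nonresponse merged, Wilson
95% intervals per level).  TKTL1 imaging: frontal-lobe surface-area
and thickness composites per hemisphere for carriers vs controls.
"""

import json
from pathlib import Path

import pandas as pd

from archvar.fixtures import build_fixture
from archvar.carrier_discovery import discover_carriers
from archvar.phenotype_compare import (
    frontal_composites,
    highest_qualification,
    summarize_categorical,
    summarize_continuous,
)
from archvar.workflows import ssh2_matched_cohort, tktl1_imaging_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "06_phenotypes"
SCRATCH = ROOT / "scratch" / "06_phenotypes"


def _qualification_counts(series: pd.Series) -> dict[str, int]:
    counts: dict[str, int] = {}
    for raw in series.dropna():
        level = highest_qualification(set(str(raw).split("|")))
        if level:
            counts[level] = counts.get(level, 0) + 1
    return counts


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- SSH2: continuous + categorical traits against 39,501 controls
    cohort = ssh2_matched_cohort(SCRATCH / "ssh2_fixture")
    bundle = build_fixture("ssh2_cohort", SCRATCH / "ssh2_fixture" )
    cont = bundle.phenotypes["continuous"].set_index("sample_id")
    cat = bundle.phenotypes["categorical"].set_index("sample_id")
    carrier_ids = cohort.carriers["sample_id"].tolist()
    control_ids = cohort.control_ids

    rows = []
    for trait in ("bmi", "whole_body_fat_mass", "height"):
        s = summarize_continuous(
            trait,
            cont.loc[carrier_ids, trait].dropna().tolist(),
            cont.loc[control_ids, trait].dropna().tolist(),
        )
        inside = sum(1 for p in s.carrier_percentiles if 0.25 <= p <= 0.75)
        rows.append(
            {
                "trait": trait,
                "carrier_n": s.carrier_n,
                "carrier_mean": round(s.carrier_mean, 3),
                "ci_low": round(s.carrier_ci[0], 3),
                "ci_high": round(s.carrier_ci[1], 3),
                "control_q25": round(s.control_quartiles[0], 3),
                "control_median": round(s.control_quartiles[1], 3),
                "control_q75": round(s.control_quartiles[2], 3),
                "carriers_inside_iqr": inside,
            }
        )
        print(
            f"SSH2 {trait}: carrier mean {s.carrier_mean:.2f} "
            f"[{s.carrier_ci[0]:.2f}, {s.carrier_ci[1]:.2f}]; "
            f"control IQR [{s.control_quartiles[0]:.2f}, "
            f"{s.control_quartiles[2]:.2f}]; {inside}/{s.carrier_n} carriers in IQR"
        )
    pd.DataFrame(rows).to_csv(OUT / "ssh2_continuous.tsv", sep="\t", index=False)

    qual = summarize_categorical(
        "qualification",
        {
            "carriers": _qualification_counts(cat.loc[carrier_ids, "qualification"]),
            "controls": _qualification_counts(cat.loc[control_ids, "qualification"]),
        },
    )
    for arm, df in qual.arms.items():
        df.to_csv(OUT / f"ssh2_qualification_{arm}.tsv", sep="\t", index=False)
    top = qual.arms["carriers"].sort_values("proportion", ascending=False).iloc[0]
    print(
        f"SSH2 qualification, carriers: modal level {top['level']!r} "
        f"at {top['proportion']:.2f} "
        f"[{top['wilson_low']:.2f}, {top['wilson_high']:.2f}] (Wilson 95%)"
    )

    # --- TKTL1 imaging: frontal composites
    icohort = tktl1_imaging_cohort(SCRATCH / "tktl1_fixture")
    ibundle = build_fixture("tktl1_imaging", SCRATCH / "tktl1_fixture")
    comps, skipped = frontal_composites(ibundle.phenotypes["parcels"])
    comp_df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "hemisphere": c.hemisphere,
                "area_mm2": c.surface_area_total,
                "thickness_mm": c.thickness_mean,
            }
            for c in comps
        ]
    )
    comp_df["arm"] = comp_df["sample_id"].map(
        lambda s: "carrier" if s in set(icohort.carriers["sample_id"]) else "control"
    )
    comp_df.to_csv(SCRATCH / "tktl1_frontal_composites.tsv", sep="\t", index=False)
    comp_df.groupby(["arm", "hemisphere"]).agg(
        n=("sample_id", "size"),
        area_mean=("area_mm2", "mean"),
        thickness_mean=("thickness_mm", "mean"),
    ).round(2).reset_index().to_csv(
        OUT / "tktl1_frontal_summary.tsv", sep="\t", index=False
    )
    ctrl_ids = set(icohort.control_ids)
    report = {}
    for hemi in ("lh", "rh"):
        sub = comp_df[comp_df["hemisphere"] == hemi]
        s = summarize_continuous(
            f"frontal_area_{hemi}",
            sub.loc[sub["arm"] == "carrier", "area_mm2"].tolist(),
            sub.loc[sub["sample_id"].isin(ctrl_ids), "area_mm2"].tolist(),
        )
        inside = sum(1 for p in s.carrier_percentiles if 0.25 <= p <= 0.75)
        report[hemi] = {"carriers_inside_iqr": inside, "carrier_n": s.carrier_n}
        print(
            f"TKTL1 frontal area ({hemi}): {inside}/{s.carrier_n} carriers "
            f"within the control IQR"
        )
    (OUT / "tktl1_report.json").write_text(json.dumps(report, indent=2) + "\n")


if __name__ == "__main__":
    main()
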