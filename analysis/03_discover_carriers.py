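#!/usr/bin/env python
"""Carrier discovery on the census fixtures.

Runs QC-aware, sex-aware discovery on the autosomal census fixture
(17 sites; expects 118 carrier genotypes with the SPAG5/ADAM18/KNL1
co-carriage pattern) and on the X-chromosome TKTL1 fixture (expects
62 unique carriers: 45 het + 1 hom females, 16 hemizygous males).
"""

from pathlib import Path

from archvar.carrier_discovery import discover_carriers, find_cocarriage
from archvar.fixtures import build_fixture
from archvar.workflows import tktl1_census

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "03_discovery"
SCRATCH = ROOT / "scratch" / "03_discovery"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    b1 = build_fixture("table1", SCRATCH / "table1_fixture")
    r1 = discover_carriers(b1.vcf_path, b1.catalog, b1.samples)
    r1.census.to_frame(b1.catalog).to_csv(OUT / "census_autosomal.tsv", sep="\t", index=False)
    cc = find_cocarriage(r1.carriers)
    cc.to_csv(OUT / "cocarriage.tsv", sep="\t", index=False)
    print(
        f"autosomal census: {r1.unique_carriers()} unique carriers of "
        f"{r1.carrier_instances()} carrier genotypes across "
        f"{r1.carriers['gene'].nunique()} genes"
    )
    print(f"co-carriage: {len(cc)} multi-carriers "
          f"({dict(cc['genes'].value_counts())})")

    counts, r2, b2 = tktl1_census(SCRATCH / "table2_fixture")
    r2.census.to_frame(b2.catalog).to_csv(OUT / "census_tktl1.tsv", sep="\t", index=False)
    print(
        f"TKTL1: {counts['unique_carriers']} unique carriers "
        f"({counts['het_female']} het F, {counts['hom_female']} hom F, "
        f"{counts['hemi_male']} hemizygous M)"
    )


if __name__ == "__main__":
    main()
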