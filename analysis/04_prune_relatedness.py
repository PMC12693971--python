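#!/usr/bin/env python
"""SSH2 carrier curation: strict ancestry label + relatedness pruning.

Restricts the 21 discovered SSH2 carriers to the strict White British
label (20) and prunes the one related pair with the carrier-prioritized
greedy rule, leaving 19 unrelated carriers (14 female).
"""

from pathlib import Path

import pandas as pd

from archvar.workflows import ssh2_pruned_carriers

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "04_pruning"
SCRATCH = ROOT / "scratch" / "04_pruning"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    retained, bundle, disc = ssh2_pruned_carriers(SCRATCH / "ssh2_fixture")
    car = bundle.samples[bundle.samples["sample_id"].isin(retained)]
    car.to_csv(OUT / "ssh2_carriers_final.tsv", sep="\t", index=False)
    print(
        f"{disc.unique_carriers()} discovered -> "
        f"{len(retained)} strict-labeled unrelated carriers "
        f"({(car['sex'] == 'female').sum()} female; "
        f"mean age {car['age'].mean():.2f} +- {car['age'].std(ddof=1):.2f})"
    )


if __name__ == "__main__":
    main()
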