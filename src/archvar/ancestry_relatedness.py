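"""Sample-level QC, ancestry supercluster assignment, relatedness pruning.

Superclusters (EUR, AFR, SAS, EAS) come from self-reported ancestry
harmonized with hard cutoffs on the first four genetic principal
components: labeled samples keep their cluster only while their PCs sit
inside that cluster's box; "Uncategorized" samples falling inside
exactly one box are rescued into it.  Related pairs above a kinship
threshold (default 0.0442, the third-degree bound) are pruned greedily
with carrier-prioritized retention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PC_COLUMNS = ("pc1", "pc2", "pc3", "pc4")
QC_FLAGS = ("sex_mismatch", "aneuploidy", "het_outlier", "high_missingness")
NAMED_CLUSTERS = ("EUR", "AFR", "SAS", "EAS")

#: Default self-report code -> supercluster mapping (UK-biobank-style
#: ethnic background labels); configurable at call sites.
DEFAULT_SELF_REPORT_MAP: dict[str, str] = {
    "British": "EUR",
    "Irish": "EUR",
    "White": "EUR",
    "Any other white background": "EUR",
    "African": "AFR",
    "Caribbean": "AFR",
    "Black or Black British": "AFR",
    "Any other Black background": "AFR",
    "Indian": "SAS",
    "Pakistani": "SAS",
    "Bangladeshi": "SAS",
    "Asian or Asian British": "SAS",
    "Any other Asian background": "SAS",
    "Chinese": "EAS",
    "Mixed": "Uncategorized",
    "Other": "Uncategorized",
    "Other ethnic group": "Uncategorized",
    "Do not know": "Uncategorized",
    "Do not want to answer": "Uncategorized",
}


def apply_sample_qc(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples with any sample-level QC flag set.

    Flags: reported/inferred sex mismatch, putative sex-chromosome
    aneuploidy, PC-corrected heterozygosity outlier, high genotype
    missingness.  Returns (retained, exclusion log); the log has one row
    per excluded sample listing every triggering flag.
    """
    missing = [f for f in QC_FLAGS if f not in samples.columns]
    if missing:
        raise ValueError(f"samples table missing QC flag columns: {missing}")
    flags = samples[list(QC_FLAGS)].astype(bool)
    bad = flags.any(axis=1)
    log = pd.DataFrame(
        {
            "sample_id": samples.loc[bad, "sample_id"],
            "flags": flags[bad].apply(
                lambda r: ";".join(f for f in QC_FLAGS if r[f]), axis=1
            ),
        }
    ).reset_index(drop=True)
    return samples[~bad].reset_index(drop=True), log


def map_self_report(
    code: str, mapping: Mapping[str, str] = DEFAULT_SELF_REPORT_MAP
) -> str:
    """Map a self-reported ancestry code to a supercluster label.

    Unknown codes fall back to "Uncategorized" with a warning.
    """
    try:
        return mapping[code]
    except KeyError:
        warnings.warn(f"unknown self-report code {code!r}; using Uncategorized",
                      stacklevel=2)
        return "Uncategorized"


@dataclass(frozen=True)
class PCBoxes:
    """Per-supercluster axis-aligned intervals on PC1-PC4."""

    boxes: Mapping[str, np.ndarray]  # cluster -> (4, 2) array of [low, high]

    def contains(self, cluster: str, pcs: Sequence[float]) -> bool:
        box = self.boxes.get(cluster)
        if box is None:
            return False
        p = np.asarray(pcs, dtype=float)
        return bool(np.all((box[:, 0] <= p) & (p <= box[:, 1])))

    def memberships(self, pcs: Sequence[float]) -> list[str]:
        return [c for c in self.boxes if self.contains(c, pcs)]


def fit_pc_boxes(
    samples: pd.DataFrame,
    q: float = 0.01,
    min_cluster_size: int = 20,
    clusters: Sequence[str] = NAMED_CLUSTERS,
) -> PCBoxes:
    """Fit per-cluster PC boxes as the [q, 1-q] empirical quantile
    interval of each labeled cluster's PC1-PC4.

    Clusters below ``min_cluster_size`` get no box (they cannot absorb
    reassignments).  q = 0 spans the cluster min/max exactly.
    """
    if not 0 <= q < 0.5:
        raise ValueError("quantile q must be in [0, 0.5)")
    boxes: dict[str, np.ndarray] = {}
    for cluster in clusters:
        sub = samples[samples["supercluster"] == cluster]
        if len(sub) < min_cluster_size:
            continue
        pcs = sub[list(PC_COLUMNS)].to_numpy(dtype=float)
        lo = np.quantile(pcs, q, axis=0)
        hi = np.quantile(pcs, 1.0 - q, axis=0)
        boxes[cluster] = np.column_stack([lo, hi])
    return PCBoxes(boxes=boxes)


def assign_supercluster(sample: pd.Series | Mapping, boxes: PCBoxes) -> str:
    """Final supercluster for one sample given fitted PC boxes.

    A named-cluster sample keeps its label iff its PCs sit inside its
    own box, else becomes Uncategorized.  An Uncategorized sample inside
    exactly one box is reassigned there; inside zero or several boxes it
    stays Uncategorized.  A sample never moves directly between two
    named clusters.
    """
    label = sample["supercluster"]
    pcs = [sample[c] for c in PC_COLUMNS]
    if label in NAMED_CLUSTERS:
        return label if boxes.contains(label, pcs) else "Uncategorized"
    hits = boxes.memberships(pcs)
    return hits[0] if len(hits) == 1 else "Uncategorized"


def assign_superclusters(samples: pd.DataFrame, boxes: PCBoxes) -> pd.DataFrame:
    """Vector form of :func:`assign_supercluster`; returns a copy with
    the final label in ``supercluster`` and the input label preserved in
    ``self_report_cluster``."""
    out = samples.copy()
    out["self_report_cluster"] = out["supercluster"]
    out["supercluster"] = [
        assign_supercluster(row, boxes) for _, row in samples.iterrows()
    ]
    return out


@dataclass(frozen=True)
class Removal:
    sample_id: str
    partner_id: str
    kinship: float
    rule: str  # noncarrier_first | higher_degree | lexicographic


def _check_symmetric(pairs: pd.DataFrame) -> None:
    seen = {}
    for a, b, k in pairs.itertuples(index=False):
        key = frozenset((a, b))
        if key in seen and not np.isclose(seen[key], k):
            raise ValueError(f"asymmetric kinship for pair {a},{b}")
        seen[key] = k


def prune_related(
    samples: Iterable[str],
    kinship: pd.DataFrame,
    carriers: Iterable[str] = (),
    threshold: float = 0.0442,
) -> tuple[list[str], list[Removal]]:
    """Greedy relatedness pruning above a kinship threshold.

    ``kinship`` has columns id1, id2, coefficient (symmetric; each pair
    listed once or twice consistently).  While any retained pair exceeds
    the threshold, remove one member chosen by: (1) noncarrier before
    carrier, (2) higher degree in the remaining over-threshold kinship
    graph, (3) lexicographically larger sample id.  Returns the retained
    ids (input order preserved) and the removal log.
    """
    ids = list(samples)
    id_set = set(ids)
    carrier_set = set(carriers)
    kin = kinship.rename(
        columns={kinship.columns[0]: "id1", kinship.columns[1]: "id2",
                 kinship.columns[2]: "coefficient"}
    )
    if ((kin["coefficient"] < 0) | (kin["coefficient"] > 0.5)).any():
        raise ValueError("kinship coefficients must lie in [0, 0.5]")
    _check_symmetric(kin[["id1", "id2", "coefficient"]])

    # adjacency over pairs above threshold, restricted to the sample set
    adj: dict[str, dict[str, float]] = {}
    for a, b, k in kin[["id1", "id2", "coefficient"]].itertuples(index=False):
        if k <= threshold or a not in id_set or b not in id_set or a == b:
            continue
        adj.setdefault(a, {})[b] = k
        adj.setdefault(b, {})[a] = k

    removed: list[Removal] = []
    retained = set(ids)

    def degree(s: str) -> int:
        return sum(1 for n in adj.get(s, {}) if n in retained)

    while True:
        active = [s for s in adj if s in retained and degree(s) > 0]
        if not active:
            break
        # candidate ordering: noncarriers first, then higher degree,
        # then the lexicographically larger sample id (deterministic)
        victim = None
        victim_key = None
        for s in active:
            key = (s in carrier_set, -degree(s))
            if (
                victim is None
                or key < victim_key
                or (key == victim_key and s > victim)
            ):
                victim, victim_key = s, key
        partner = max(
            (n for n in adj[victim] if n in retained),
            key=lambda n: adj[victim][n],
        )
        if victim not in carrier_set and partner in carrier_set:
            rule = "noncarrier_first"
        elif degree(victim) > 1:
            rule = "higher_degree"
        else:
            rule = "lexicographic"
        removed.append(
            Removal(victim, partner, adj[victim][partner], rule)
        )
        retained.discard(victim)

    return [s for s in ids if s in retained], removed


def max_retained_kinship(retained: Iterable[str], kinship: pd.DataFrame) -> float:
    """Largest kinship coefficient among retained pairs (exhaustive scan;
    0 if none listed)."""
    rset = set(retained)
    kin = kinship[
        kinship.iloc[:, 0].isin(rset) & kinship.iloc[:, 1].isin(rset)
    ]
    return float(kin.iloc[:, 2].max()) if len(kin) else 0.0
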