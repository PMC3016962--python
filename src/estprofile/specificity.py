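"""Expression-pattern classification from spatio-temporal profiles.

Genes are called ubiquitous (housekeeping-like), tissue-specific,
stage-specific, mixed, or insufficient-data from two per-axis
statistics:

* dominance — the largest share of the gene's ESTs carried by a single
  canonical tissue (or stage); near 1 for a gene expressed exclusively
  in one place, like a sericin in the middle silk gland or a chorion
  protein in the pupa.
* breadth — the fraction of *qualifying* pools (pool total >= pool_min)
  in which the gene is detected at all; near 1 for housekeeping genes
  such as ribosomal proteins.  An unsampled tissue cannot count
  against ubiquity, hence the qualification.

Records whose label normalizes to the unknown category still count
toward support, but the unknown category is never a specificity target
and never enters breadth: "all my ESTs are uncharacterized" is absence
of evidence, not evidence of specificity.

The call is deterministic and ordered: insufficient support first, then
tissue specificity, then stage specificity, then ubiquity, else mixed.
Tissue wins when both dominances pass; both are recorded so the tie is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .est_io import ESTCorpus
from .profile import DEFAULT_POOL_MIN, SpatioTemporalProfile, build_profile, pool_sizes
from .unigene import ClusterTable, extract_gene
from .vocab import Vocabulary

CALLS = ("ubiquitous", "tissue_specific", "stage_specific", "mixed", "insufficient_data")


@dataclass
class SpecificityParams:
    """Thresholds for the specificity caller.

    min_support: minimum gene EST count for any call (default 3).
    dominance: minimum single-pool share for a specific call (default 0.95).
    breadth: minimum detected fraction of qualifying pools for a
        ubiquitous call (default 0.80).
    pool_min: minimum pool total for a pool to qualify toward breadth.
    """

    min_support: int = 3
    dominance: float = 0.95
    breadth: float = 0.80
    pool_min: int = DEFAULT_POOL_MIN

    def __post_init__(self) -> None:
        if not 0 < self.dominance <= 1 or not 0 < self.breadth <= 1:
            raise ValueError("dominance and breadth thresholds must lie in (0, 1]")
        if self.min_support < 0 or self.pool_min < 0:
            raise ValueError("min_support and pool_min must be non-negative")


@dataclass
class SpecificityCall:
    cluster_id: str
    call: str
    target: str | None
    support: int
    dominance_tissue: float
    breadth_tissue: float
    dominance_stage: float
    breadth_stage: float

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def _axis_stats(
    axis_counts: dict[str, int],
    pool_totals: dict[str, int],
    unknown_label: str,
    support: int,
    pool_min: int,
) -> tuple[float, float, str | None]:
    """(dominance, breadth, dominant label) over canonical labels."""
    known = {lab: n for lab, n in axis_counts.items() if lab != unknown_label and n > 0}
    if support > 0 and known:
        top = max(known, key=lambda lab: (known[lab], lab))
        dominance = known[top] / support
    else:
        top, dominance = None, 0.0
    qualifying = [
        lab for lab, N in pool_totals.items() if lab != unknown_label and N >= pool_min
    ]
    breadth = (
        sum(1 for lab in qualifying if axis_counts.get(lab, 0) > 0) / len(qualifying)
        if qualifying
        else 0.0
    )
    return dominance, breadth, top


def classify(
    profile: SpatioTemporalProfile,
    params: SpecificityParams | None = None,
    unknown_label: str = "uncharacterized",
) -> SpecificityCall:
    """Call one gene's expression pattern from its profile."""
    p = params or SpecificityParams()
    support = profile.support
    dom_t, br_t, top_t = _axis_stats(
        profile.tissue_counts(), profile.pools.tissue_totals, unknown_label, support, p.pool_min
    )
    dom_s, br_s, top_s = _axis_stats(
        profile.stage_counts(), profile.pools.stage_totals, unknown_label, support, p.pool_min
    )
    if support < p.min_support:
        call, target = "insufficient_data", None
    elif top_t is not None and dom_t >= p.dominance:
        call, target = "tissue_specific", top_t
    elif top_s is not None and dom_s >= p.dominance:
        call, target = "stage_specific", top_s
    elif br_t >= p.breadth:
        call, target = "ubiquitous", None
    else:
        call, target = "mixed", None
    return SpecificityCall(
        cluster_id=profile.cluster_id,
        call=call,
        target=target,
        support=support,
        dominance_tissue=dom_t,
        breadth_tissue=br_t,
        dominance_stage=dom_s,
        breadth_stage=br_s,
    )


def classify_all(
    corpus: ESTCorpus,
    cluster_table: ClusterTable,
    vocab_tissue: Vocabulary,
    vocab_stage: Vocabulary,
    params: SpecificityParams | None = None,
) -> pd.DataFrame:
    """One call per cluster, in stable cluster-id order.

    Returns a table with columns cluster_id, call, target, support,
    dominance_tissue, breadth_tissue, dominance_stage, breadth_stage.
    """
    p = params or SpecificityParams()
    pools = pool_sizes(corpus, vocab_tissue, vocab_stage)
    rows = []
    for cid in sorted(cluster_table):
        gene = extract_gene(corpus, cluster_table, cid)
        prof = build_profile(gene, pools, vocab_tissue, vocab_stage, pool_min=p.pool_min)
        call = classify(prof, p, unknown_label=vocab_tissue.unknown_label)
        rows.append(vars(call))
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "call",
            "target",
            "support",
            "dominance_tissue",
            "breadth_tissue",
            "dominance_stage",
            "breadth_stage",
        ],
    )
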