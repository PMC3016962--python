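"""Reusable validation experiments on synthetic data.

These drive both the test suite and the reproduction script: class
recovery of the specificity caller, reproduction of the three anchor
expression patterns (a housekeeping-like gene, a middle-silk-gland
exclusive gene, a pupa-exclusive gene), and the direction of a designed
two-dataset GO enrichment.

The class-recovery experiment runs the caller at a dominance threshold
of 0.8 rather than the strict default 0.95.  Under label-corruption
noise at rate e, the expected dominance of a perfectly specific gene is
1 - e (plus a small return term), so any threshold above 1 - e is
unattainable in expectation regardless of EST depth; 0.8 sits below
1 - e for the 10% noise regime studied here while staying far above the
highest dominance a designed non-specific gene can reach (~1/3).  The
strict default remains appropriate for clean data and is what the
anchor-case experiment uses.
"""

from __future__ import annotations

import pandas as pd

from .est_io import ESTCorpus, ESTRecord
from .goannot import (
    best_hit_per_query,
    filter_hits,
    load_obo,
    load_protein2go,
    parse_blast_tab,
    summarize_go,
)
from .specificity import SpecificityParams, classify_all
from .synthgen import GeneratorConfig, generate_blast_and_go, generate_expression_dataset
from .unigene import ClusterTable
from .vocab import Vocabulary

RECOVERY_PARAMS = SpecificityParams(min_support=3, dominance=0.8, breadth=0.8, pool_min=30)


def class_recovery(
    n_genes: int = 500, noise_rate: float = 0.0, seed: int = 0
) -> tuple[float, pd.DataFrame]:
    """Fraction of synthetic genes whose class the caller recovers.

    Returns (recovery fraction, confusion matrix true x called).
    """
    config = GeneratorConfig(seed=seed, n_genes=n_genes, noise_rate=noise_rate)
    corpus, clusters, truth = generate_expression_dataset(config)
    vt, vs = Vocabulary.default("tissue"), Vocabulary.default("stage")
    calls = classify_all(corpus, clusters, vt, vs, params=RECOVERY_PARAMS)
    merged = truth.merge(calls, on="cluster_id")
    confusion = pd.crosstab(merged["true_class"], merged["call"])
    recovery = float((merged["true_class"] == merged["call"]).mean())
    return recovery, confusion


def _anchor_corpus() -> tuple[ESTCorpus, ClusterTable]:
    """A deterministic corpus realizing the three anchor expression patterns."""
    vt, vs = Vocabulary.default("tissue"), Vocabulary.default("stage")
    tissues = [t for t in vt.canonical_terms if t != "middle silk gland"][:9]
    tissues.append("middle silk gland")
    stages = [s for s in vs.canonical_terms if s != "pupa"][:4] + ["pupa"]
    records: list[ESTRecord] = []
    counter = 0

    def add(tissue: str, stage: str) -> str:
        nonlocal counter
        counter += 1
        acc = f"ANC{counter:05d}"
        records.append(ESTRecord(acc, tissue_raw=tissue, stage_raw=stage))
        return acc

    for t in tissues:  # background: every pool comfortably above pool_min
        for s in stages:
            for _ in range(40):
                add(t, s)
    members: dict[str, list[str]] = {"Anchor.house": [], "Anchor.msg": [], "Anchor.pupa": []}
    for i, t in enumerate(tissues):  # detected in every tissue, stages cycled
        members["Anchor.house"] += [add(t, stages[i % len(stages)]) for _ in range(2)]
    for i in range(12):  # exclusively middle silk gland
        members["Anchor.msg"].append(add("middle silk gland", stages[i % len(stages)]))
    for i in range(12):  # exclusively pupa
        members["Anchor.pupa"].append(add(tissues[i % len(tissues)], "pupa"))
    return ESTCorpus(records), ClusterTable(members=members)


def anchor_calls() -> pd.DataFrame:
    """Classify the three anchor genes with the strict default thresholds."""
    corpus, clusters = _anchor_corpus()
    vt, vs = Vocabulary.default("tissue"), Vocabulary.default("stage")
    return classify_all(corpus, clusters, vt, vs, params=SpecificityParams())


def enrichment_direction_rate(
    n_replicates: int = 100, seed: int = 0, n_queries: int = 200, level: int = 2
) -> float:
    """Fraction of replicates recovering the designed GO enrichment direction.

    Each replicate generates a fresh BLAST + GO fixture in which dataset
    A is biased toward one molecular_function branch, runs the full
    annotate-and-summarize path, and checks percent_A > percent_B for
    that branch.
    """
    import tempfile

    hits_ok = 0
    for r in range(n_replicates):
        config = GeneratorConfig(seed=(seed * 100_003 + r) % (2**31), n_queries=n_queries)
        with tempfile.TemporaryDirectory() as tmp:
            out = generate_blast_and_go(config, tmp)
            hits = parse_blast_tab(out["blast"])
            best = best_hit_per_query(filter_hits(hits))
            ontology = load_obo(out["obo"])
            protein2go = load_protein2go(out["protein2go"])
            summary = summarize_go(best, protein2go, ontology, level, out["datasets"])
        table = summary.term_table.set_index("term")
        branch = out["enriched_branch"]
        if branch in table.index and table.at[branch, "pct_A"] > table.at[branch, "pct_B"]:
            hits_ok += 1
    return hits_ok / n_replicates
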