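"""BLASTx hit ingestion, best-hit selection and GO category rollup.

The module consumes standard 12-column BLAST tabular output (BLASTx of
ESTs against a protein set run out of process), filters at an e-value
cutoff (default 1e-10, inclusive), and selects one "most meaningful"
hit per EST: minimum e-value, ties broken by maximum bit score, then
lexicographically smallest subject id — a deterministic reading of
best-hit practice.

Best hits are mapped to GO via a subject->GO table and rolled up to a
fixed ontology level (shortest is_a distance from the namespace root;
the root itself is level 1), producing a WEGO-style multi-dataset
summary: per GO term, the count and percentage of annotated ESTs in
each dataset.  An EST may contribute to several terms, so percentages
need not sum to 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-10

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class BlastParseError(ValueError):
    pass


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output (unused columns kept opaquely)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query and subject ids must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")
        if not math.isfinite(self.bit_score):
            raise ValueError(f"non-finite bit score {self.bit_score}")


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output; ``#`` comment lines skipped."""
    path = Path(path)
    hits: list[BlastHit] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise BlastParseError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(cols)}"
                )
            try:
                hit = BlastHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                    extra=tuple(cols[4:10]) + tuple(cols[12:]),
                )
            except ValueError as exc:
                raise BlastParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def filter_hits(
    hits: list[BlastHit], cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> list[BlastHit]:
    """Retain hits with e-value <= cutoff (inclusive); order preserved."""
    if cutoff <= 0:
        raise ValueError("e-value cutoff must be positive")
    return [h for h in hits if h.e_value <= cutoff]


def best_hit_per_query(hits: list[BlastHit]) -> dict[str, BlastHit]:
    """The most meaningful match per query.

    Minimum e-value; ties resolved by maximum bit score, then by
    lexicographically smallest subject id.
    """
    best: dict[str, BlastHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or (hit.e_value, -hit.bit_score, hit.subject_id) < (
            cur.e_value,
            -cur.bit_score,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return best


# ---------------------------------------------------------------------------
# GO ontology


class GeneOntology:
    """An is_a DAG of GO terms with per-term namespace, name and level.

    Level is the shortest is_a distance from the term's namespace root,
    with the root itself at level 1.  Only is_a edges are traversed;
    obsolete terms are excluded at load time.
    """

    def __init__(self, terms: dict[str, dict]) -> None:
        self.terms = terms
        graph = nx.DiGraph()  # edge: child -> is_a parent
        for tid, data in terms.items():
            if data.get("namespace") not in NAMESPACES:
                raise ValueError(f"term {tid} lacks a valid namespace")
            graph.add_node(tid)
            for parent in data.get("is_a", ()):
                if parent in terms:
                    graph.add_edge(tid, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"is_a cycle detected: {cycle}")
        self.graph = graph
        self.roots = {
            ns: sorted(t for t in terms if graph.out_degree(t) == 0
                       and terms[t]["namespace"] == ns)
            for ns in NAMESPACES
        }
        # level via BFS from each namespace root along reversed edges
        self.level: dict[str, int] = {}
        for ns, roots in self.roots.items():
            for root in roots:
                for term, dist in nx.single_source_shortest_path_length(
                    graph.reverse(copy=False), root
                ).items():
                    lvl = dist + 1
                    if term not in self.level or lvl < self.level[term]:
                        self.level[term] = lvl

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def name(self, term_id: str) -> str:
        return self.terms[term_id].get("name", term_id)

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id]["namespace"]

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via is_a (excluding itself)."""
        return nx.descendants(self.graph, term_id)

    def rollup(self, term_id: str, level: int) -> set[str]:
        """Ancestors-or-self of ``term_id`` sitting exactly at ``level``."""
        candidates = self.ancestors(term_id) | {term_id}
        return {t for t in candidates if self.level.get(t) == level}


def load_obo(path: str | Path) -> GeneOntology:
    """Load an OBO 1.2 ontology (via obonet) into a :class:`GeneOntology`."""
    graph = obonet.read_obo(str(path))  # excludes obsolete terms
    terms: dict[str, dict] = {}
    for tid, data in graph.nodes(data=True):
        if "namespace" not in data:
            raise ValueError(f"term {tid} has no namespace")
        terms[tid] = {
            "name": data.get("name", tid),
            "namespace": data["namespace"],
            "is_a": list(data.get("is_a", [])),
        }
    return GeneOntology(terms)


def load_protein2go(path: str | Path) -> dict[str, list[str]]:
    """Load a two-column subject_id<TAB>GO:id mapping; duplicates collapsed."""
    mapping: dict[str, list[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            subject, go_id = line.split("\t")[:2]
            bucket = mapping.setdefault(subject, [])
            if go_id not in bucket:
                bucket.append(go_id)
    return mapping


# ---------------------------------------------------------------------------
# WEGO-style summary


@dataclass
class GOSummary:
    """Per-term counts/percentages of annotated ESTs for >=1 datasets."""

    labels: list[str]
    annotated: dict[str, int]
    namespace_annotated: dict[str, dict[str, int]]  # label -> namespace -> n
    term_table: pd.DataFrame = field(repr=False)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.term_table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


def summarize_go(
    best_hits: dict[str, "BlastHit"],
    protein2go: dict[str, list[str]],
    ontology: GeneOntology,
    level: int,
    datasets: dict[str, set[str]],
) -> GOSummary:
    """Roll annotated ESTs up to a fixed GO level per dataset.

    An EST is annotated when its best hit maps to at least one GO term
    known to the ontology.  Each of its terms is propagated to the
    ancestors (or itself) at the requested level, and each ancestor
    counts the EST once (distinct-EST rule).  Percent values are
    relative to the dataset's annotated-EST count.
    """
    if level < 1:
        raise ValueError("GO level must be >= 1")
    labels = list(datasets)
    annotated: dict[str, int] = {}
    ns_annotated: dict[str, dict[str, int]] = {}
    members: dict[str, dict[str, set[str]]] = {}  # label -> term -> ESTs
    for label in labels:
        ann: set[str] = set()
        ns_sets: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
        term_members: dict[str, set[str]] = {}
        for acc in sorted(datasets[label]):
            hit = best_hits.get(acc)
            if hit is None:
                continue
            go_ids = protein2go.get(hit.subject_id, [])
            valid = []
            for gid in go_ids:
                if gid in ontology:
                    valid.append(gid)
                else:
                    logger.warning("unknown GO id %s for %s; skipped", gid, hit.subject_id)
            if not valid:
                continue
            ann.add(acc)
            for gid in valid:
                ns_sets[ontology.namespace(gid)].add(acc)
                for target in ontology.rollup(gid, level):
                    term_members.setdefault(target, set()).add(acc)
        annotated[label] = len(ann)
        ns_annotated[label] = {ns: len(s) for ns, s in ns_sets.items()}
        members[label] = term_members
    all_terms = sorted(
        {t for label in labels for t in members[label]},
        key=lambda t: (ontology.namespace(t), t),
    )
    rows = []
    for term in all_terms:
        row: dict[str, object] = {
            "term": term,
            "namespace": ontology.namespace(term),
            "name": ontology.name(term),
        }
        for label in labels:
            n = len(members[label].get(term, ()))
            row[f"count_{label}"] = n
            row[f"pct_{label}"] = 100.0 * n / annotated[label] if annotated[label] else 0.0
        rows.append(row)
    columns = ["term", "namespace", "name"] + [
        c for label in labels for c in (f"count_{label}", f"pct_{label}")
    ]
    return GOSummary(
        labels=labels,
        annotated=annotated,
        namespace_annotated=ns_annotated,
        term_table=pd.DataFrame(rows, columns=columns),
    )


def plot_go_summary(summary: GOSummary, path: str | Path):
    """Grouped bar chart of term percentages per namespace, log-scaled y."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    df = summary.term_table
    if df.empty:
        logger.warning("empty GO summary, plot skipped")
        return None
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(df)), 5))
    x = np.arange(len(df))
    width = 0.8 / max(1, len(summary.labels))
    for i, label in enumerate(summary.labels):
        ax.bar(x + i * width, df[f"pct_{label}"].clip(lower=1e-2), width, label=label)
    ax.set_yscale("log")
    ax.set_ylabel("% of annotated ESTs")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(df["name"], rotation=80, ha="right", fontsize=6)
    # shade namespace blocks for readability
    boundaries = df["namespace"].ne(df["namespace"].shift()).to_numpy().nonzero()[0]
    for start in boundaries[1::2]:
        end = boundaries[boundaries > start]
        ax.axvspan(start - 0.5, (end[0] if len(end) else len(df)) - 0.5, alpha=0.08)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
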