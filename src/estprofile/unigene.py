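"""Gene-oriented EST cluster tables (UniGene-style) and per-gene lookup.

A cluster table attributes each EST accession to at most one gene
cluster.  The native on-disk format is a two-column TSV
(``cluster_id<TAB>accession``); a converter for UniGene ``.data``
stanza files is provided for legacy inputs.  Resolution against a
corpus reports missing accessions explicitly — the cluster membership
and the EST corpus typically come from different snapshots, so
mismatches are expected rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .est_io import ESTCorpus, ESTRecord


class ClusterValidationError(ValueError):
    """An accession claimed by two clusters, or a malformed table."""


@dataclass
class ClusterTable:
    """Mapping cluster_id -> ordered EST accessions, plus optional titles."""

    members: dict[str, list[str]] = field(default_factory=dict)
    titles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for cid, accs in self.members.items():
            if len(set(accs)) != len(accs):
                raise ClusterValidationError(f"{cid}: duplicate accession in cluster")
            for acc in accs:
                if acc in owner:
                    raise ClusterValidationError(
                        f"accession {acc} claimed by clusters {owner[acc]} and {cid}"
                    )
                owner[acc] = cid

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)


@dataclass
class GeneESTSet:
    """A cluster's membership resolved against a corpus."""

    cluster_id: str
    records: list[ESTRecord]
    missing: list[str]

    @property
    def size(self) -> int:
        return len(self.records) + len(self.missing)


def load_cluster_table(path: str | Path) -> ClusterTable:
    """Load a two-column (cluster_id, accession) TSV.

    Repeated identical pairs collapse to one membership; an accession
    appearing under two clusters raises :class:`ClusterValidationError`.
    Lines starting with ``#`` are comments.
    """
    path = Path(path)
    members: dict[str, list[str]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ClusterValidationError(
                    f"{path}:{lineno}: expected cluster_id and accession"
                )
            cid, acc = parts[0], parts[1]
            if (cid, acc) in seen_pairs:
                continue
            seen_pairs.add((cid, acc))
            members.setdefault(cid, []).append(acc)
    return ClusterTable(members=members)


def convert_unigene_data(path: str | Path, out_path: str | Path) -> Path:
    """Convert a UniGene ``.data`` stanza file to the native two-column TSV.

    Only ``ID``, ``TITLE`` and ``SEQUENCE`` lines (``ACC=...``) are used.
    """
    path, out_path = Path(path), Path(out_path)
    rows: list[tuple[str, str]] = []
    current = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("ID"):
                current = line.split(None, 1)[1].strip()
            elif line.startswith("SEQUENCE") and current:
                for fieldspec in line.split(None, 1)[1].split(";"):
                    fieldspec = fieldspec.strip()
                    if fieldspec.startswith("ACC="):
                        acc = fieldspec[4:].split(".")[0]
                        rows.append((current, acc))
    with out_path.open("w", encoding="utf-8", newline="\n") as fh:
        for cid, acc in rows:
            fh.write(f"{cid}\t{acc}\n")
    return out_path


def extract_gene(
    corpus: ESTCorpus, cluster_table: ClusterTable, cluster_id: str
) -> GeneESTSet:
    """Resolve one cluster's accessions against the corpus.

    Pure lookup: neither input is modified.  Record order follows the
    cluster file order.
    """
    if cluster_id not in cluster_table:
        raise KeyError(f"unknown cluster id {cluster_id!r}")
    index = corpus.by_accession()
    records: list[ESTRecord] = []
    missing: list[str] = []
    for acc in cluster_table.members[cluster_id]:
        rec = index.get(acc)
        if rec is None:
            missing.append(acc)
        else:
            records.append(rec)
    return GeneESTSet(cluster_id=cluster_id, records=records, missing=missing)
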