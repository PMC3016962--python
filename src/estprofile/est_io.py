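"""Reading, writing and deduplicating EST records.

Two on-disk representations are supported:

* dbEST-style FASTA, where the description line ("defline") carries
  free-text library metadata.  Deflines are heterogeneous across
  submitters, so extraction is driven by an ordered-regex rule set
  (:class:`DeflineRules`) with an optional library-id lookup table.
* the "EST Source" flat text format: one EST per line, whitespace
  separated columns ``accession tissue stage sex strain``.

Metadata is stored verbatim at this layer; controlled-vocabulary
normalization happens in :mod:`estprofile.vocab`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

_IUPAC_NT = set("ACGTURYSWKMBDHVN")

#: placeholder written for an empty field that precedes a non-empty one,
#: so that positional parsing of the space-delimited format stays sound.
EMPTY_FIELD = "-"

_METADATA_FIELDS = ("tissue_raw", "stage_raw", "sex_raw", "strain_raw")


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


@dataclass(frozen=True)
class ESTRecord:
    """A single EST: accession plus verbatim library metadata."""

    accession: str
    tissue_raw: str = ""
    stage_raw: str = ""
    sex_raw: str = ""
    strain_raw: str = ""
    library_id: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("ESTRecord requires a non-empty accession")
        if self.sequence is not None:
            bad = set(self.sequence.upper()) - _IUPAC_NT
            if bad:
                raise ValueError(
                    f"{self.accession}: non-IUPAC nucleotide codes {sorted(bad)!r}"
                )


@dataclass
class ESTCorpus:
    """An ordered collection of :class:`ESTRecord` with parse provenance."""

    records: list[ESTRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ESTRecord]:
        return iter(self.records)

    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def by_accession(self) -> dict[str, ESTRecord]:
        out: dict[str, ESTRecord] = {}
        for r in self.records:
            out.setdefault(r.accession, r)
        return out


def parse_est_source(path: str | Path) -> ESTCorpus:
    """Parse the flat "EST Source" format: one EST per line.

    Tokens map positionally to accession, tissue, stage, sex, strain;
    missing trailing tokens yield empty fields, and the ``-`` placeholder
    reads back as empty.
    """
    path = Path(path)
    records: list[ESTRecord] = []
    skipped = 0
    n_lines = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            n_lines += 1
            tokens = line.split()
            if not tokens:
                skipped += 1
                continue
            fields = [t if t != EMPTY_FIELD else "" for t in tokens[1:5]]
            fields += [""] * (4 - len(fields))
            records.append(ESTRecord(tokens[0], *fields))
    if not records:
        logger.warning("%s: no EST records found", path)
    return ESTCorpus(
        records,
        provenance={
            "sources": [str(path)],
            "lines_read": n_lines,
            "records_read": len(records),
            "records_dropped": skipped,
        },
    )


def write_est_source(corpus: ESTCorpus, path: str | Path) -> Path:
    """Write a corpus in the flat EST Source format (UTF-8, LF endings).

    Internal whitespace in a field is replaced by underscores; empty
    fields before a non-empty one are written as ``-`` and trailing empty
    fields are omitted, so ``parse_est_source`` round-trips the corpus.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in corpus:
            cols = [re.sub(r"\s+", "_", getattr(rec, f)) for f in _METADATA_FIELDS]
            while cols and not cols[-1]:
                cols.pop()
            line = " ".join([rec.accession] + [c or EMPTY_FIELD for c in cols])
            fh.write(line + "\n")
    return path


# ---------------------------------------------------------------------------
# dbEST FASTA deflines

#: default ordered patterns per field, covering the ``/key="value"`` and
#: ``key: value`` defline styles seen in dbEST submissions.
DEFAULT_DEFLINE_PATTERNS: dict[str, list[str]] = {
    "tissue_raw": [
        r'/tissue(?:_type)?="([^"]*)"',
        r"\btissue(?:_type)?:\s*([^;|/]+)",
    ],
    "stage_raw": [
        r'/dev(?:elopmental)?_stage="([^"]*)"',
        r"\bdev(?:elopmental)?[_ ]stage:\s*([^;|/]+)",
    ],
    "sex_raw": [r'/sex="([^"]*)"', r"\bsex:\s*([^;|/]+)"],
    "strain_raw": [r'/strain="([^"]*)"', r"\bstrain:\s*([^;|/]+)"],
    "library_id": [r'/(?:clone_)?lib(?:rary)?="([^"]*)"', r"\blib(?:rary)?:\s*([^;|/]+)"],
}


class DeflineRules:
    """Ordered regular-expression extraction rules for FASTA deflines.

    Each field has a list of patterns tried in order; the first match
    wins.  ``library_lookup`` maps a library id to default metadata used
    to fill fields that no pattern matched.
    """

    def __init__(
        self,
        patterns: Mapping[str, Sequence[str]] | None = None,
        library_lookup: Mapping[str, Mapping[str, str]] | None = None,
    ) -> None:
        patterns = patterns if patterns is not None else DEFAULT_DEFLINE_PATTERNS
        try:
            self.patterns = {
                fld: [re.compile(p) for p in pats] for fld, pats in patterns.items()
            }
        except re.error as exc:
            raise ValueError(f"invalid defline rule pattern: {exc}") from exc
        self.library_lookup = {k: dict(v) for k, v in (library_lookup or {}).items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeflineRules":
        with Path(path).open(encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ValueError(f"{path}: defline rule file must be a mapping")
        return cls(cfg.get("patterns"), cfg.get("library_lookup"))

    def extract(self, defline: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for fld, pats in self.patterns.items():
            for pat in pats:
                m = pat.search(defline)
                if m:
                    out[fld] = m.group(1).strip()
                    break
        lib = out.get("library_id")
        if lib and lib in self.library_lookup:
            for fld, value in self.library_lookup[lib].items():
                out.setdefault(fld, value)
        return out


def parse_dbest_fasta(
    path: str | Path, defline_rules: DeflineRules | None = None
) -> ESTCorpus:
    """Parse a dbEST-style FASTA file into an :class:`ESTCorpus`.

    The accession is the first word of the defline; metadata fields are
    extracted by the first matching rule per field and left empty when no
    rule matches.  Sequences are retained verbatim.
    """
    path = Path(path)
    rules = defline_rules or DeflineRules()
    records: list[ESTRecord] = []
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}:1: sequence data before first FASTA header")
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        meta = rules.extract(seq_rec.description)
        records.append(
            ESTRecord(
                accession=seq_rec.id,
                tissue_raw=meta.get("tissue_raw", ""),
                stage_raw=meta.get("stage_raw", ""),
                sex_raw=meta.get("sex_raw", ""),
                strain_raw=meta.get("strain_raw", ""),
                library_id=meta.get("library_id"),
                sequence=str(seq_rec.seq) or None,
            )
        )
    return ESTCorpus(
        records,
        provenance={
            "sources": [str(path)],
            "records_read": len(records),
            "records_dropped": 0,
        },
    )


def deduplicate(corpus: ESTCorpus) -> ESTCorpus:
    """Keep the first record per accession; count the rest as duplicates."""
    seen: set[str] = set()
    kept: list[ESTRecord] = []
    for rec in corpus:
        if rec.accession in seen:
            continue
        seen.add(rec.accession)
        kept.append(rec)
    dupes = len(corpus) - len(kept)
    if dupes:
        logger.info("removed %d duplicate EST record(s)", dupes)
    prov = dict(corpus.provenance)
    prov["duplicate_count"] = dupes
    return ESTCorpus(kept, provenance=prov)


def write_fasta_subset(
    corpus: ESTCorpus, accessions: Iterable[str], path: str | Path
) -> Path:
    """Export the given accessions (those present) as a FASTA subset."""
    path = Path(path)
    index = corpus.by_accession()
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for acc in accessions:
            rec = index.get(acc)
            if rec is None:
                continue
            fh.write(f">{acc}\n{rec.sequence or 'N'}\n")
    return path
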