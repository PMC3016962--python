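"""Controlled-vocabulary normalization and category tallies.

Free-text tissue / stage / sex / strain values from EST library metadata
are mapped to canonical terms by exact match after canonicalization
(lowercase, trim, collapse whitespace and underscores).  Unmapped or
empty values fall into a configurable ``unknown_label`` category
("uncharacterized" by default) — unmapped is a value, never an error.

Default vocabularies for *Bombyx mori* ship as editable YAML files under
``estprofile/data/vocab``; the engine itself is species-agnostic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .est_io import ESTCorpus

logger = logging.getLogger(__name__)

AXES = ("tissue", "stage", "sex", "strain")

_AXIS_FIELD = {
    "tissue": "tissue_raw",
    "stage": "stage_raw",
    "sex": "sex_raw",
    "strain": "strain_raw",
}

DEFAULT_UNKNOWN = "uncharacterized"


def canon(raw: str) -> str:
    """Canonical comparison form: lowercase, underscores to spaces,
    whitespace collapsed and trimmed."""
    return re.sub(r"[\s_]+", " ", raw).strip().lower()


@dataclass
class Vocabulary:
    axis: str
    canonical_terms: list[str]
    synonym_map: dict[str, str] = field(default_factory=dict)
    unknown_label: str = DEFAULT_UNKNOWN

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}; expected one of {AXES}")
        if len(set(self.canonical_terms)) != len(self.canonical_terms):
            raise ValueError(f"{self.axis}: canonical terms not unique")
        if self.unknown_label in self.canonical_terms:
            raise ValueError(f"{self.axis}: unknown_label clashes with a canonical term")
        # lookup keyed on canonical comparison form; terms map to themselves
        self._lookup: dict[str, str] = {}
        for term in self.canonical_terms:
            self._lookup[canon(term)] = term
        for raw, term in self.synonym_map.items():
            if term not in self.canonical_terms:
                raise ValueError(
                    f"{self.axis}: synonym {raw!r} maps to unknown term {term!r}"
                )
            key = canon(raw)
            if self._lookup.get(key, term) != term:
                raise ValueError(f"{self.axis}: synonym {raw!r} maps to two terms")
            self._lookup[key] = term

    @classmethod
    def from_file(cls, path: str | Path, axis: str | None = None) -> "Vocabulary":
        """Load a vocabulary from a YAML file.

        Layout: ``axis``, optional ``unknown_label``, and ``terms`` — a
        list of either bare strings or ``{term: ..., synonyms: [...]}``.
        """
        with Path(path).open(encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        terms: list[str] = []
        synonyms: dict[str, str] = {}
        for entry in cfg.get("terms", []):
            if isinstance(entry, str):
                terms.append(entry)
            else:
                terms.append(entry["term"])
                for syn in entry.get("synonyms", []) or []:
                    synonyms[syn] = entry["term"]
        return cls(
            axis=axis or cfg["axis"],
            canonical_terms=terms,
            synonym_map=synonyms,
            unknown_label=cfg.get("unknown_label", DEFAULT_UNKNOWN),
        )

    @classmethod
    def default(cls, axis: str) -> "Vocabulary":
        """The packaged default *B. mori* vocabulary for an axis."""
        ref = resources.files("estprofile.data.vocab") / f"{axis}.yaml"
        with resources.as_file(ref) as path:
            return cls.from_file(path, axis=axis)

    def normalize(self, raw: str) -> str:
        """Map a raw value to its canonical term, or ``unknown_label``."""
        key = canon(raw)
        if not key:
            return self.unknown_label
        return self._lookup.get(key, self.unknown_label)


def default_vocabularies() -> dict[str, Vocabulary]:
    return {axis: Vocabulary.default(axis) for axis in AXES}


def normalize(raw: str, vocabulary: Vocabulary) -> str:
    return vocabulary.normalize(raw)


@dataclass
class CategoryDistribution:
    """Counts and proportions of canonical terms along one metadata axis."""

    axis: str
    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts do not sum to total")
        if self.total == 0:
            logger.warning("%s: empty corpus, distribution has total 0", self.axis)

    @property
    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {term: n / self.total for term, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        return pd.DataFrame(
            {
                "term": list(self.counts),
                "count": list(self.counts.values()),
                "proportion": [props.get(t, float("nan")) for t in self.counts],
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def _normalized_values(corpus: ESTCorpus, axis: str, vocabulary: Vocabulary) -> list[str]:
    fld = _AXIS_FIELD[axis]
    return [vocabulary.normalize(getattr(rec, fld)) for rec in corpus]


def tally(corpus: ESTCorpus, axis: str, vocabulary: Vocabulary) -> CategoryDistribution:
    """Count every record exactly once under its normalized label.

    Term order follows the vocabulary (then unknown), restricted to
    observed terms.
    """
    values = _normalized_values(corpus, axis, vocabulary)
    counts: dict[str, int] = {}
    for term in list(vocabulary.canonical_terms) + [vocabulary.unknown_label]:
        n = values.count(term)
        if n:
            counts[term] = n
    return CategoryDistribution(axis=axis, counts=counts, total=len(values))


def cross_tally(
    corpus: ESTCorpus,
    axis_a: str,
    axis_b: str,
    vocab_a: Vocabulary,
    vocab_b: Vocabulary,
) -> pd.DataFrame:
    """Joint count table: cell (a, b) = records normalizing to both labels.

    Row sums reproduce ``tally(axis_a)`` and column sums ``tally(axis_b)``.
    Rows/columns follow vocabulary order, restricted to observed terms.
    """
    va = _normalized_values(corpus, axis_a, vocab_a)
    vb = _normalized_values(corpus, axis_b, vocab_b)
    order_a = [t for t in list(vocab_a.canonical_terms) + [vocab_a.unknown_label] if t in set(va)]
    order_b = [t for t in list(vocab_b.canonical_terms) + [vocab_b.unknown_label] if t in set(vb)]
    table = pd.crosstab(pd.Series(va, name=axis_a), pd.Series(vb, name=axis_b))
    return table.reindex(index=order_a, columns=order_b, fill_value=0)
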