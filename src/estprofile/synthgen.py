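"""Seeded synthetic input generation with sidecar truth tables.

Every other module in the package is testable offline against data from
this module: metadata corpora (EST Source + dbEST-style FASTA in mixed
defline dialects), cluster tables with genes designed under the four
expression-class definitions, BLAST tabular files with engineered
ties, OBO ontologies with known levels, and protein-to-GO maps with a
designed two-dataset enrichment.  Each generator writes a
machine-readable truth table next to its files, so downstream tests are
"pipeline output vs. truth".

Default corpus shape mirrors a large public EST collection for
*Bombyx mori*: 28 tissues / 31 stages / 4 sexes / 10 strains with a
heavy-tailed tissue distribution peaking at ovary (14.9%), wing disk
(14.6%) and silk gland (12.4%); stage distribution peaking at
5th-instar day 3 (31.2%), the 5th-instar-to-spinning mixture (16.8%)
and 4th-instar day 2 (9.2%); the Dazao strain at 85.3%; mixed sex at
49.3%.

Determinism: one root seed; every generator draws from a substream
derived from (seed, stream-id), so regeneration under the same seed is
byte-identical and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .est_io import DeflineRules, ESTCorpus, ESTRecord, write_est_source
from .unigene import ClusterTable
from .vocab import Vocabulary

# substream ids (arbitrary but fixed)
_STREAM_CORPUS = 1
_STREAM_GENES = 2
_STREAM_BLAST = 3
_STREAM_GO = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _heavy_tail(peaks: dict[str, float], terms: list[str]) -> dict[str, float]:
    """Probabilities with fixed peak terms and a 1/rank tail over the rest."""
    rest = [t for t in terms if t not in peaks]
    remaining = 1.0 - sum(peaks.values())
    weights = np.array([1.0 / (i + 2) for i in range(len(rest))])
    weights = weights / weights.sum() * remaining
    probs = dict(peaks)
    probs.update({t: float(w) for t, w in zip(rest, weights)})
    return probs


def _default_axis_probs() -> dict[str, dict[str, float]]:
    vocabs = {ax: Vocabulary.default(ax) for ax in ("tissue", "stage", "sex", "strain")}
    return {
        "tissue": _heavy_tail(
            {"ovary": 0.149, "wing disk": 0.146, "silk gland": 0.124},
            vocabs["tissue"].canonical_terms,
        ),
        "stage": _heavy_tail(
            {
                "5th instar day 3 larva": 0.312,
                "5th instar to spinning larva": 0.168,
                "4th instar day 2 larva": 0.092,
            },
            vocabs["stage"].canonical_terms,
        ),
        "sex": _heavy_tail({"mixed": 0.493}, vocabs["sex"].canonical_terms),
        "strain": _heavy_tail({"Dazao": 0.853}, vocabs["strain"].canonical_terms),
    }


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic generators; defaults mirror the real corpus shape."""

    seed: int = 0
    # metadata corpus
    n_records: int = 20_000
    axis_probs: dict[str, dict[str, float]] = dc_field(default_factory=_default_axis_probs)
    duplication_rate: float = 0.05
    missing_rate: float = 0.02
    dialect_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # slash / colon / library-only
    synonym_rate: float = 0.15
    uppercase_rate: float = 0.15
    # expression dataset (gene classes)
    n_genes: int = 100
    n_background: int = 3_000
    n_class_tissues: int = 12
    n_class_stages: int = 8
    ests_per_specific_gene: int = 30
    ests_per_ubiquitous_tissue: int = 2
    mixed_spread: int = 3
    noise_rate: float = 0.0
    # BLAST
    n_queries: int = 500
    hit_rate: float = 0.9
    max_hits_per_query: int = 5
    log10_evalue_range: tuple[float, float] = (-40.0, -4.0)
    above_cutoff_rate: float = 0.1
    tie_rate: float = 0.15
    full_tie_rate: float = 0.05
    # GO DAG
    go_depth: int = 4
    go_branching: int = 3
    extra_parent_rate: float = 0.2
    terms_per_protein: int = 2
    enrichment_weight_a: float = 0.6
    enrichment_weight_b: float = 0.2

    def __post_init__(self) -> None:
        for axis, probs in self.axis_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{axis}: probabilities sum to {total}, not 1")
        for rate in (
            self.duplication_rate,
            self.missing_rate,
            self.noise_rate,
            self.hit_rate,
            self.tie_rate,
            self.full_tie_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")


# ---------------------------------------------------------------------------
# metadata corpus


def _raw_form(term: str, vocab: Vocabulary, rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """A raw spelling of a canonical term: verbatim, uppercased, or a synonym."""
    u = rng.random()
    if u < cfg.synonym_rate:
        syns = [s for s, t in vocab.synonym_map.items() if t == term]
        if syns:
            return syns[int(rng.integers(len(syns)))]
    if u < cfg.synonym_rate + cfg.uppercase_rate:
        return term.upper()
    return term


def generate_corpus(
    config: GeneratorConfig, outdir: str | Path
) -> tuple[Path, Path, Path, pd.DataFrame]:
    """Write a synthetic corpus (EST Source + FASTA + defline rules + truth).

    Returns paths (est_source, fasta, rules_yaml) and the truth table:
    one row per unique record with its true canonical labels, plus the
    accessions duplicated into the files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, _STREAM_CORPUS)
    vocabs = {ax: Vocabulary.default(ax) for ax in ("tissue", "stage", "sex", "strain")}

    axes_draw: dict[str, list[str]] = {}
    for axis, probs in config.axis_probs.items():
        terms = list(probs)
        p = np.array([probs[t] for t in terms], dtype=float)
        p = p / p.sum()
        idx = rng.choice(len(terms), size=config.n_records, p=p)
        axes_draw[axis] = [terms[i] for i in idx]

    records: list[ESTRecord] = []
    truth_rows = []
    lib_lookup: dict[str, dict[str, str]] = {}
    deflines: list[tuple[str, str, str]] = []  # accession, defline, sequence
    dialect_p = np.array(config.dialect_mix, dtype=float)
    dialect_p = dialect_p / dialect_p.sum()
    for i in range(config.n_records):
        acc = f"SYN{i:06d}"
        true = {ax: axes_draw[ax][i] for ax in axes_draw}
        raw = {}
        for ax in ("tissue", "stage", "sex", "strain"):
            if rng.random() < config.missing_rate:
                raw[ax] = ""
            else:
                raw[ax] = _raw_form(true[ax], vocabs[ax], rng, config)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        dialect = int(rng.choice(3, p=dialect_p))
        lib_id = f"LIB{i % 97:03d}"
        if dialect == 0:
            parts = [f'/{key}="{raw[ax]}"' for key, ax in
                     (("tissue", "tissue"), ("dev_stage", "stage"),
                      ("sex", "sex"), ("strain", "strain")) if raw[ax]]
            defline = f"{acc} " + " ".join(parts)
        elif dialect == 1:
            parts = [f"{key}: {raw[ax]}" for key, ax in
                     (("tissue", "tissue"), ("dev stage", "stage"),
                      ("sex", "sex"), ("strain", "strain")) if raw[ax]]
            defline = f"{acc} " + "; ".join(parts)
        else:
            defline = f'{acc} /lib="{lib_id}"'
            lib_lookup.setdefault(
                lib_id,
                {
                    "tissue_raw": raw["tissue"],
                    "stage_raw": raw["stage"],
                    "sex_raw": raw["sex"],
                    "strain_raw": raw["strain"],
                },
            )
            # library metadata defines this record's truth: reuse the
            # first-registered library fields so file and truth agree
            raw = {
                "tissue": lib_lookup[lib_id]["tissue_raw"],
                "stage": lib_lookup[lib_id]["stage_raw"],
                "sex": lib_lookup[lib_id]["sex_raw"],
                "strain": lib_lookup[lib_id]["strain_raw"],
            }
            true = {ax: vocabs[ax].normalize(raw[ax]) for ax in raw}
        records.append(
            ESTRecord(
                accession=acc,
                tissue_raw=raw["tissue"],
                stage_raw=raw["stage"],
                sex_raw=raw["sex"],
                strain_raw=raw["strain"],
                library_id=lib_id if dialect == 2 else None,
                sequence=seq,
            )
        )
        deflines.append((acc, defline, seq))
        truth_rows.append(
            {
                "accession": acc,
                "tissue": vocabs["tissue"].normalize(raw["tissue"]),
                "stage": vocabs["stage"].normalize(raw["stage"]),
                "sex": vocabs["sex"].normalize(raw["sex"]),
                "strain": vocabs["strain"].normalize(raw["strain"]),
                "dialect": dialect,
                "tissue_raw": raw["tissue"],
                "stage_raw": raw["stage"],
                "sex_raw": raw["sex"],
                "strain_raw": raw["strain"],
            }
        )

    n_dup = int(round(config.duplication_rate * config.n_records))
    dup_idx = rng.choice(config.n_records, size=n_dup) if n_dup else np.array([], int)
    all_records = records + [records[int(j)] for j in dup_idx]
    order = rng.permutation(len(all_records))
    shuffled = [all_records[int(k)] for k in order]

    est_source = outdir / "est_source.txt"
    write_est_source(ESTCorpus(shuffled), est_source)
    fasta = outdir / "corpus.fasta"
    defline_map = {acc: (d, s) for acc, d, s in deflines}
    with fasta.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in shuffled:
            d, s = defline_map[rec.accession]
            fh.write(f">{d}\n{s}\n")
    rules_yaml = outdir / "defline_rules.yaml"
    with rules_yaml.open("w", encoding="utf-8") as fh:
        yaml.safe_dump({"library_lookup": lib_lookup}, fh, sort_keys=True)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth_records.tsv", sep="\t", index=False)
    return est_source, fasta, rules_yaml, truth


def corpus_rules(rules_yaml: str | Path) -> DeflineRules:
    """Defline rules (defaults + the generated library lookup)."""
    with Path(rules_yaml).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return DeflineRules(library_lookup=cfg.get("library_lookup"))


# ---------------------------------------------------------------------------
# expression dataset with designed gene classes

CLASS_NAMES = ("ubiquitous", "tissue_specific", "stage_specific", "mixed")


def generate_expression_dataset(
    config: GeneratorConfig,
) -> tuple[ESTCorpus, ClusterTable, pd.DataFrame]:
    """A corpus + cluster table whose genes follow the four class designs.

    Background records give every (tissue, stage) pool comfortable
    depth; each gene's ESTs then realize its class: tissue-specific
    genes sit entirely in one tissue, stage-specific ones in one stage
    with tissues cycled, ubiquitous ones in every tissue, mixed ones in
    a few tissues and stages.  With ``noise_rate`` > 0, each gene EST's
    labels are independently replaced by uniform random labels with that
    probability.  Truth rows carry the designed class, target and
    hotspot cell.
    """
    rng = _rng(config.seed, _STREAM_GENES)
    vt = Vocabulary.default("tissue")
    vs = Vocabulary.default("stage")
    tissues = vt.canonical_terms[: config.n_class_tissues]
    stages = vs.canonical_terms[: config.n_class_stages]

    records: list[ESTRecord] = []
    counter = 0

    def new_acc() -> str:
        nonlocal counter
        counter += 1
        return f"GEN{counter:06d}"

    for _ in range(config.n_background):
        t = tissues[int(rng.integers(len(tissues)))]
        s = stages[int(rng.integers(len(stages)))]
        records.append(ESTRecord(new_acc(), tissue_raw=t, stage_raw=s))

    members: dict[str, list[str]] = {}
    truth_rows = []
    for g in range(config.n_genes):
        cid = f"Syn.{g + 1}"
        klass = CLASS_NAMES[g % len(CLASS_NAMES)]
        cells: list[tuple[str, str]] = []
        target = ""
        if klass == "tissue_specific":
            target = tissues[int(rng.integers(len(tissues)))]
            cells = [
                (target, stages[int(rng.integers(len(stages)))])
                for _ in range(config.ests_per_specific_gene)
            ]
        elif klass == "stage_specific":
            target = stages[int(rng.integers(len(stages)))]
            offset = int(rng.integers(len(tissues)))
            cells = [
                (tissues[(offset + k) % len(tissues)], target)
                for k in range(config.ests_per_specific_gene)
            ]
        elif klass == "ubiquitous":
            for t in tissues:
                for _ in range(config.ests_per_ubiquitous_tissue):
                    cells.append((t, stages[len(cells) % len(stages)]))
        else:  # mixed: a few tissues x a few stages, evenly
            t_pick = [tissues[int(i)] for i in
                      rng.choice(len(tissues), size=config.mixed_spread, replace=False)]
            s_pick = [stages[int(i)] for i in
                      rng.choice(len(stages), size=config.mixed_spread, replace=False)]
            for k in range(config.mixed_spread * config.mixed_spread):
                cells.append((t_pick[k % len(t_pick)], s_pick[k // len(s_pick)]))
        # label noise
        noisy_cells = []
        for t, s in cells:
            if config.noise_rate and rng.random() < config.noise_rate:
                t = tissues[int(rng.integers(len(tissues)))]
                s = stages[int(rng.integers(len(stages)))]
            noisy_cells.append((t, s))
        accs = []
        for t, s in noisy_cells:
            acc = new_acc()
            accs.append(acc)
            records.append(ESTRecord(acc, tissue_raw=t, stage_raw=s))
        members[cid] = accs
        hotspot = max(set(cells), key=lambda c: (cells.count(c), c))
        truth_rows.append(
            {
                "cluster_id": cid,
                "true_class": klass,
                "target": target,
                "n_ests": len(accs),
                "hotspot_tissue": hotspot[0],
                "hotspot_stage": hotspot[1],
            }
        )
    corpus = ESTCorpus(records, provenance={"sources": ["synthetic"]})
    return corpus, ClusterTable(members=members), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# BLAST tabular + GO


def _write_obo(path: Path, terms: dict[str, dict]) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in terms:
            data = terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: {data['name']}\n")
            fh.write(f"namespace: {data['namespace']}\n")
            for parent in data["is_a"]:
                fh.write(f"is_a: {parent} ! {terms[parent]['name']}\n")
            if data.get("obsolete"):
                fh.write("is_obsolete: true\n")


def _build_go_dag(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, dict]:
    """A layered DAG per namespace with known levels and ancestor sets.

    Each term at depth d has one primary parent at depth d-1 and, with
    ``extra_parent_rate``, a second parent at the same depth, so the
    shortest-path level equals the construction depth.
    """
    from .goannot import NAMESPACES

    terms: dict[str, dict] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    for ns in NAMESPACES:
        root = new_id()
        terms[root] = {
            "name": ns.replace("_", " "),
            "namespace": ns,
            "is_a": [],
            "level": 1,
            "ancestors": set(),
        }
        previous = [root]
        for depth in range(2, config.go_depth + 1):
            layer = []
            for parent in previous:
                for b in range(config.go_branching):
                    tid = new_id()
                    is_a = [parent]
                    if len(previous) > 1 and rng.random() < config.extra_parent_rate:
                        other = previous[int(rng.integers(len(previous)))]
                        if other != parent:
                            is_a.append(other)
                    ancestors = set()
                    for p in is_a:
                        ancestors |= terms[p]["ancestors"] | {p}
                    terms[tid] = {
                        "name": f"{ns.split('_')[0]} term {counter}",
                        "namespace": ns,
                        "is_a": is_a,
                        "level": depth,
                        "ancestors": ancestors,
                    }
                    layer.append(tid)
            previous = layer
    # one obsolete term to exercise exclusion on load
    obsolete = new_id()
    terms[obsolete] = {
        "name": "withdrawn term",
        "namespace": "biological_process",
        "is_a": [],
        "level": 1,
        "ancestors": set(),
        "obsolete": True,
    }
    return terms


def generate_blast_and_go(
    config: GeneratorConfig, outdir: str | Path
) -> dict[str, object]:
    """Write BLAST tabular, OBO, protein2go and dataset files + truth tables.

    Two EST datasets (labels A and B) are built over disjoint query
    sets; dataset A's annotated proteins are biased toward one designed
    molecular_function branch (the "enriched branch"), so the WEGO-style
    rollup should rank that branch higher in A than in B.

    Returns a dict of paths plus the truth tables (``truth_best``:
    designed best hit per query after the 1e-10 cutoff; ``truth_terms``:
    per-term true level and ancestor set; ``enriched_branch``: the
    designed level-2 term id).
    """
    from .goannot import DEFAULT_EVALUE_CUTOFF

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, _STREAM_BLAST)
    go_rng = _rng(config.seed, _STREAM_GO)

    terms = _build_go_dag(config, go_rng)
    obo_path = outdir / "ontology.obo"
    _write_obo(obo_path, terms)
    live = {t: d for t, d in terms.items() if not d.get("obsolete")}
    leaves = sorted(
        t for t, d in live.items() if d["level"] == config.go_depth
    )
    mf_level2 = sorted(
        t for t, d in live.items()
        if d["namespace"] == "molecular_function" and d["level"] == 2
    )
    enriched_branch = mf_level2[0]

    # proteins: half lie under the enriched branch, half elsewhere
    def leaf_under(branch: str) -> list[str]:
        return [t for t in leaves if branch in live[t]["ancestors"]]

    branch_leaves = leaf_under(enriched_branch)
    other_leaves = [t for t in leaves if t not in set(branch_leaves)]
    proteins: dict[str, list[str]] = {}
    for i in range(60):
        pid = f"P{i:05d}"
        pool = branch_leaves if i < 30 else other_leaves
        k = 1 + int(rng.integers(config.terms_per_protein))
        picks = sorted({pool[int(j)] for j in rng.integers(len(pool), size=k)})
        proteins[pid] = picks
    branch_proteins = [p for p in proteins if set(proteins[p]) & set(branch_leaves)]
    other_proteins = [p for p in proteins if p not in set(branch_proteins)]

    p2g_path = outdir / "protein2go.tsv"
    with p2g_path.open("w", encoding="utf-8", newline="\n") as fh:
        for pid in proteins:
            for gid in proteins[pid]:
                fh.write(f"{pid}\t{gid}\n")

    # BLAST hits with designed best + engineered ties
    lo, hi = config.log10_evalue_range
    blast_path = outdir / "hits.blast.tsv"
    queries = [f"Q{i:05d}" for i in range(config.n_queries)]
    half = config.n_queries // 2
    dataset_a = set(queries[:half])
    dataset_b = set(queries[half:])
    truth_best_rows = []
    with blast_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# synthetic BLAST tabular (qseqid sseqid pident length mismatch "
                 "gapopen qstart qend sstart send evalue bitscore)\n")
        for q in queries:
            if rng.random() >= config.hit_rate:
                truth_best_rows.append({"query": q, "best_subject": ""})
                continue
            in_a = q in dataset_a
            weight = config.enrichment_weight_a if in_a else config.enrichment_weight_b
            pool = branch_proteins if rng.random() < weight else other_proteins
            best_subject = pool[int(rng.integers(len(pool)))]
            if rng.random() < config.above_cutoff_rate:
                best_e = 10 ** float(rng.uniform(-9, -4))
            else:
                best_e = 10 ** float(rng.uniform(lo, np.log10(DEFAULT_EVALUE_CUTOFF)))
            best_bits = float(np.round(rng.uniform(80, 400), 1))
            rows = [(q, best_subject, best_e, best_bits)]
            n_extra = int(rng.integers(config.max_hits_per_query))
            others = [p for p in proteins if p != best_subject]
            for _ in range(n_extra):
                subj = others[int(rng.integers(len(others)))]
                u = rng.random()
                if u < config.full_tie_rate:
                    # full tie: identical e-value and bit score; designed best
                    # must then be the lexicographically smaller subject
                    rows.append((q, best_subject + "_tie", best_e, best_bits))
                elif u < config.full_tie_rate + config.tie_rate:
                    rows.append((q, subj, best_e, best_bits - 5.0))
                else:
                    e = best_e * 10 ** float(rng.uniform(0.5, 6))
                    rows.append((q, subj, e, max(30.0, best_bits - 40.0)))
            perm = rng.permutation(len(rows))
            for k in perm:
                q_, s_, e_, b_ = rows[int(k)]
                length = int(rng.integers(60, 240))
                pident = float(np.round(rng.uniform(35, 99), 2))
                fh.write(
                    f"{q_}\t{s_}\t{pident}\t{length}\t{int(rng.integers(0, 40))}\t"
                    f"{int(rng.integers(0, 5))}\t1\t{length * 3}\t1\t{length}\t"
                    f"{e_:.3e}\t{b_}\n"
                )
            truth_best_rows.append(
                {
                    "query": q,
                    "best_subject": best_subject if best_e <= DEFAULT_EVALUE_CUTOFF else "",
                }
            )
    truth_best = pd.DataFrame(truth_best_rows)
    truth_best.to_csv(outdir / "truth_best_hits.tsv", sep="\t", index=False)
    truth_terms = pd.DataFrame(
        [
            {
                "term": t,
                "namespace": d["namespace"],
                "level": d["level"],
                "ancestors": ",".join(sorted(d["ancestors"])),
            }
            for t, d in live.items()
        ]
    )
    truth_terms.to_csv(outdir / "truth_terms.tsv", sep="\t", index=False)
    for label, accs in (("A", dataset_a), ("B", dataset_b)):
        with (outdir / f"dataset_{label}.txt").open("w", encoding="utf-8", newline="\n") as fh:
            for acc in sorted(accs):
                fh.write(acc + "\n")
    return {
        "blast": blast_path,
        "obo": obo_path,
        "protein2go": p2g_path,
        "dataset_a": outdir / "dataset_A.txt",
        "dataset_b": outdir / "dataset_B.txt",
        "truth_best": truth_best,
        "truth_terms": truth_terms,
        "enriched_branch": enriched_branch,
        "datasets": {"A": dataset_a, "B": dataset_b},
    }
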