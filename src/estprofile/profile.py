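"""Per-gene spatio-temporal expression profiles.

A gene's expression is estimated from its EST counts: for a pool of
ESTs sharing a normalized tissue label, a stage label, or a joint
(tissue, stage) label, abundance is expressed in transcripts per
million,

    TPM = 1e6 * n / N

where ``n`` is the gene's EST count in the pool and ``N`` the pool's
total EST count.  Tissue-pool and stage-pool TPM are the two marginal
normalizations; cell-level TPM uses the joint (tissue, stage) pool as
denominator, which degenerates to the marginals when one axis is
collapsed.  Pools with no ESTs carry *no* TPM value (no library is not
zero expression), and pools smaller than ``pool_min`` are flagged
low-confidence rather than suppressed — EST coverage limits accuracy,
so the flag keeps the caveat visible without hiding data.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .est_io import ESTCorpus
from .unigene import GeneESTSet
from .vocab import Vocabulary

logger = logging.getLogger(__name__)

DEFAULT_POOL_MIN = 30

Cell = tuple[str, str]


def tpm(n: int, N: int) -> float:
    """Transcripts per million: 1e6 * n / N, exact floating arithmetic."""
    if N <= 0:
        raise ValueError(f"undefined pool: pool total N={N} must be positive")
    if not 0 <= n <= N:
        raise ValueError(f"inconsistent counts: n={n} outside [0, N={N}]")
    return 1e6 * n / N


@dataclass
class PoolSizes:
    """Total EST counts per tissue pool, stage pool and (tissue, stage) cell."""

    tissue_totals: dict[str, int]
    stage_totals: dict[str, int]
    cell_totals: dict[Cell, int]
    tissue_order: list[str] = field(default_factory=list)
    stage_order: list[str] = field(default_factory=list)

    @property
    def corpus_size(self) -> int:
        return sum(self.cell_totals.values())


def pool_sizes(
    corpus: ESTCorpus, vocab_tissue: Vocabulary, vocab_stage: Vocabulary
) -> PoolSizes:
    """Pool totals over normalized labels (unknown-label pools included)."""
    cells = Counter(
        (vocab_tissue.normalize(r.tissue_raw), vocab_stage.normalize(r.stage_raw))
        for r in corpus
    )
    tissue_totals: Counter[str] = Counter()
    stage_totals: Counter[str] = Counter()
    for (t, s), n in cells.items():
        tissue_totals[t] += n
        stage_totals[s] += n
    t_order = [
        t
        for t in list(vocab_tissue.canonical_terms) + [vocab_tissue.unknown_label]
        if t in tissue_totals
    ]
    s_order = [
        s
        for s in list(vocab_stage.canonical_terms) + [vocab_stage.unknown_label]
        if s in stage_totals
    ]
    return PoolSizes(
        tissue_totals=dict(tissue_totals),
        stage_totals=dict(stage_totals),
        cell_totals=dict(cells),
        tissue_order=t_order,
        stage_order=s_order,
    )


@dataclass
class SpatioTemporalProfile:
    """EST counts and TPM values of one gene across tissue x stage cells.

    ``counts`` holds the gene's EST count per cell; ``tpm_tissue`` /
    ``tpm_stage`` are the marginal TPM values (tissue pool and stage
    pool denominators); ``tpm_cell`` uses the joint pool.  Cells whose
    pool is empty have no TPM entry.
    """

    cluster_id: str
    counts: dict[Cell, int]
    pools: PoolSizes
    tpm_tissue: dict[str, float]
    tpm_stage: dict[str, float]
    tpm_cell: dict[Cell, float]
    low_confidence_cells: set[Cell]
    pool_min: int = DEFAULT_POOL_MIN

    @property
    def support(self) -> int:
        """Total gene ESTs mapped into the profile."""
        return sum(self.counts.values())

    def tissue_counts(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for (t, _), n in self.counts.items():
            out[t] += n
        return dict(out)

    def stage_counts(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for (_, s), n in self.counts.items():
            out[s] += n
        return dict(out)

    def argmax_cell(self) -> Cell | None:
        """The hotspot: cell with the highest cell TPM (count tie-break)."""
        if not any(self.counts.values()):
            return None
        return max(
            (c for c, n in self.counts.items() if n > 0),
            key=lambda c: (self.tpm_cell.get(c, 0.0), self.counts[c], c),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat cell table: tissue, stage, count, pool, tpm, low_confidence.

        Rows cover every cell with a non-empty pool or a gene count, in
        vocabulary (biological) axis order.
        """
        cells = set(self.pools.cell_totals) | {c for c, n in self.counts.items() if n}
        t_pos = {t: i for i, t in enumerate(self.pools.tissue_order)}
        s_pos = {s: i for i, s in enumerate(self.pools.stage_order)}
        ordered = sorted(
            cells,
            key=lambda c: (t_pos.get(c[0], len(t_pos)), s_pos.get(c[1], len(s_pos)), c),
        )
        rows = []
        for cell in ordered:
            pool = self.pools.cell_totals.get(cell, 0)
            rows.append(
                {
                    "tissue": cell[0],
                    "stage": cell[1],
                    "count": self.counts.get(cell, 0),
                    "pool": pool,
                    "tpm": self.tpm_cell.get(cell, float("nan")),
                    "low_confidence": cell in self.low_confidence_cells,
                }
            )
        return pd.DataFrame(
            rows, columns=["tissue", "stage", "count", "pool", "tpm", "low_confidence"]
        )


def build_profile(
    gene: GeneESTSet,
    pools: PoolSizes,
    vocab_tissue: Vocabulary,
    vocab_stage: Vocabulary,
    pool_min: int = DEFAULT_POOL_MIN,
) -> SpatioTemporalProfile:
    """Assemble the spatio-temporal profile of one gene.

    Pool sizes must come from the same corpus the gene's records were
    resolved against; a gene EST in a cell absent from the pools is a
    consistency error.
    """
    counts = Counter(
        (vocab_tissue.normalize(r.tissue_raw), vocab_stage.normalize(r.stage_raw))
        for r in gene.records
    )
    if not counts:
        logger.warning("%s: no mapped EST records; all-zero profile", gene.cluster_id)
    for cell, n in counts.items():
        if n > pools.cell_totals.get(cell, 0):
            raise ValueError(
                f"{gene.cluster_id}: {n} gene ESTs in cell {cell} but pool has "
                f"{pools.cell_totals.get(cell, 0)} — pools not from the same corpus?"
            )
    t_counts: Counter[str] = Counter()
    s_counts: Counter[str] = Counter()
    for (t, s), n in counts.items():
        t_counts[t] += n
        s_counts[s] += n
    tpm_tissue = {t: tpm(t_counts.get(t, 0), N) for t, N in pools.tissue_totals.items()}
    tpm_stage = {s: tpm(s_counts.get(s, 0), N) for s, N in pools.stage_totals.items()}
    tpm_cell = {c: tpm(counts.get(c, 0), N) for c, N in pools.cell_totals.items()}
    low_conf = {c for c, N in pools.cell_totals.items() if N < pool_min}
    return SpatioTemporalProfile(
        cluster_id=gene.cluster_id,
        counts=dict(counts),
        pools=pools,
        tpm_tissue=tpm_tissue,
        tpm_stage=tpm_stage,
        tpm_cell=tpm_cell,
        low_confidence_cells=low_conf,
        pool_min=pool_min,
    )


def write_profile_tsv(profile: SpatioTemporalProfile, path: str | Path) -> Path:
    """Write the flat cell table, with cluster id and pool_min in a header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# cluster_id: {profile.cluster_id}\n")
        fh.write(f"# pool_min: {profile.pool_min}\n")
        # 17 significant digits so TPM values re-ingest bit-exactly
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_profile_tsv(path: str | Path) -> SpatioTemporalProfile:
    """Re-ingest a profile TSV written by :func:`write_profile_tsv`.

    The cell table fully determines the profile: marginal pools and TPM
    values are recomputed by summing cells (every corpus record carries
    a normalized label on both axes, so cell pools partition the corpus).
    Axis order is taken from row order, which preserved vocabulary order.
    """
    path = Path(path)
    cluster_id, pool_min = "unknown", DEFAULT_POOL_MIN
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            if key.strip() == "cluster_id":
                cluster_id = value.strip()
            elif key.strip() == "pool_min":
                pool_min = int(value.strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    cell_totals: dict[Cell, int] = {}
    counts: dict[Cell, int] = {}
    t_order: list[str] = []
    s_order: list[str] = []
    for _, row in df.iterrows():
        cell = (str(row["tissue"]), str(row["stage"]))
        if row["pool"]:
            cell_totals[cell] = int(row["pool"])
        if row["count"]:
            counts[cell] = int(row["count"])
        if cell[0] not in t_order:
            t_order.append(cell[0])
        if cell[1] not in s_order:
            s_order.append(cell[1])
    tissue_totals: Counter[str] = Counter()
    stage_totals: Counter[str] = Counter()
    for (t, s), n in cell_totals.items():
        tissue_totals[t] += n
        stage_totals[s] += n
    pools = PoolSizes(
        tissue_totals=dict(tissue_totals),
        stage_totals=dict(stage_totals),
        cell_totals=cell_totals,
        tissue_order=t_order,
        stage_order=s_order,
    )
    t_counts: Counter[str] = Counter()
    s_counts: Counter[str] = Counter()
    for (t, s), n in counts.items():
        t_counts[t] += n
        s_counts[s] += n
    return SpatioTemporalProfile(
        cluster_id=cluster_id,
        counts=counts,
        pools=pools,
        tpm_tissue={t: tpm(t_counts.get(t, 0), N) for t, N in pools.tissue_totals.items()},
        tpm_stage={s: tpm(s_counts.get(s, 0), N) for s, N in pools.stage_totals.items()},
        tpm_cell={c: tpm(counts.get(c, 0), N) for c, N in cell_totals.items()},
        low_confidence_cells={c for c, N in cell_totals.items() if N < pool_min},
        pool_min=pool_min,
    )


def render_profile(
    profile: SpatioTemporalProfile,
    tsv_path: str | Path,
    figure_path: str | Path | None = None,
):
    """Write the profile TSV and, when there is signal, a 3-D columnar figure.

    Bars sit on the tissue x stage grid in vocabulary order with height =
    cell TPM.  An all-zero profile yields the TSV only.
    """
    write_profile_tsv(profile, tsv_path)
    if figure_path is None:
        return None
    if not any(profile.counts.values()):
        logger.warning("%s: all-zero profile, figure skipped", profile.cluster_id)
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tissues = profile.pools.tissue_order
    stages = profile.pools.stage_order
    t_pos = {t: i for i, t in enumerate(tissues)}
    s_pos = {s: i for i, s in enumerate(stages)}
    xs, ys, zs = [], [], []
    for (t, s), value in sorted(profile.tpm_cell.items()):
        if profile.counts.get((t, s), 0) > 0:
            xs.append(t_pos[t])
            ys.append(s_pos[s])
            zs.append(value)
    fig = plt.figure(figsize=(max(6, len(tissues) * 0.45), max(5, len(stages) * 0.3)))
    ax = fig.add_subplot(projection="3d")
    ax.bar3d(xs, ys, [0] * len(zs), 0.6, 0.6, zs, shade=True)
    ax.set_xticks(range(len(tissues)))
    ax.set_xticklabels(tissues, rotation=75, fontsize=6, ha="right")
    ax.set_yticks(range(len(stages)))
    ax.set_yticklabels(stages, fontsize=6)
    ax.set_zlabel("TPM")
    ax.set_title(f"{profile.cluster_id} spatio-temporal expression")
    fig.savefig(figure_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(figure_path)
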