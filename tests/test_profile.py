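"""Spatio-temporal profiles: pool sizes, TPM arithmetic, rendering round-trip."""

from collections import Counter

import pytest

from estprofile.est_io import ESTCorpus, ESTRecord
from estprofile.profile import (
    build_profile,
    pool_sizes,
    read_profile_tsv,
    render_profile,
    tpm,
    write_profile_tsv,
)
from estprofile.synthgen import GeneratorConfig, generate_expression_dataset
from estprofile.unigene import GeneESTSet, extract_gene
from estprofile.vocab import Vocabulary, cross_tally


@pytest.fixture(scope="module")
def tv():
    return Vocabulary.default("tissue")


@pytest.fixture(scope="module")
def sv():
    return Vocabulary.default("stage")


class TestTpm:
    @pytest.mark.parametrize(
        "n,N,expected",
        [(0, 1000, 0.0), (1000, 1000, 1_000_000.0), (5, 50_000, 100.0), (2, 10_000, 200.0)],
    )
    def test_formula(self, n, N, expected):
        assert tpm(n, N) == expected

    def test_empty_pool_is_undefined_not_zero(self):
        with pytest.raises(ValueError, match="undefined pool"):
            tpm(0, 0)

    def test_count_exceeding_pool_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            tpm(5, 4)

    def test_monotone_in_n_for_fixed_pool(self):
        values = [tpm(n, 500) for n in range(0, 501, 50)]
        assert values == sorted(values) and len(set(values)) == len(values)


class TestPoolSizes:
    def test_simple_totals(self, tv, sv):
        corpus = ESTCorpus(
            [ESTRecord("A", tissue_raw="ovary", stage_raw="pupa"),
             ESTRecord("B", tissue_raw="ovary", stage_raw="egg"),
             ESTRecord("C", tissue_raw="MSG", stage_raw="pupa")]
        )
        pools = pool_sizes(corpus, tv, sv)
        assert pools.tissue_totals == {"ovary": 2, "middle silk gland": 1}
        assert pools.stage_totals == {"pupa": 2, "egg": 1}
        assert pools.cell_totals[("ovary", "pupa")] == 1
        assert pools.corpus_size == 3

    def test_empty_corpus(self, tv, sv):
        pools = pool_sizes(ESTCorpus([]), tv, sv)
        assert pools.tissue_totals == {} and pools.cell_totals == {}

    def test_totals_equal_cross_tally_marginals(self, tv, sv):
        config = GeneratorConfig(seed=21, n_genes=10, n_background=400)
        corpus, _, _ = generate_expression_dataset(config)
        pools = pool_sizes(corpus, tv, sv)
        table = cross_tally(corpus, "tissue", "stage", tv, sv)
        assert pools.tissue_totals == table.sum(axis=1).to_dict()
        assert pools.stage_totals == table.sum(axis=0).to_dict()


def _uniform_corpus(tissues, stages, per_cell):
    records = []
    i = 0
    for t in tissues:
        for s in stages:
            for _ in range(per_cell):
                records.append(ESTRecord(f"U{i:05d}", tissue_raw=t, stage_raw=s))
                i += 1
    return ESTCorpus(records)


class TestBuildProfile:
    def test_cell_tpm_formula(self, tv, sv):
        corpus = _uniform_corpus(["fat body"], ["5th instar day 3 larva"], 9998)
        gene_recs = [
            ESTRecord(f"G{i}", tissue_raw="fat body", stage_raw="5th instar day 3 larva")
            for i in range(2)
        ]
        corpus = ESTCorpus(corpus.records + gene_recs)
        pools = pool_sizes(corpus, tv, sv)
        gene = GeneESTSet("Bmo.x", gene_recs, [])
        prof = build_profile(gene, pools, tv, sv)
        cell = ("fat body", "5th instar day 3 larva")
        assert prof.tpm_cell[cell] == 200.0
        assert prof.tpm_tissue["fat body"] == 200.0
        assert prof.support == 2

    def test_missing_metadata_routes_to_unknown_stage(self, tv, sv):
        corpus = ESTCorpus(
            [ESTRecord("A", tissue_raw="head", stage_raw=""),
             ESTRecord("B", tissue_raw="head", stage_raw="pupa")]
        )
        pools = pool_sizes(corpus, tv, sv)
        gene = GeneESTSet("g", [corpus.records[0]], [])
        prof = build_profile(gene, pools, tv, sv)
        assert prof.counts == {("head", "uncharacterized"): 1}
        assert prof.tissue_counts() == {"head": 1}

    def test_zero_record_gene_is_valid_all_zero(self, tv, sv):
        corpus = _uniform_corpus(["head"], ["pupa"], 5)
        prof = build_profile(GeneESTSet("g", [], []), pool_sizes(corpus, tv, sv), tv, sv)
        assert prof.support == 0
        assert all(v == 0.0 for v in prof.tpm_cell.values())
        assert prof.argmax_cell() is None

    def test_gene_not_from_corpus_rejected(self, tv, sv):
        corpus = _uniform_corpus(["head"], ["pupa"], 2)
        alien = [ESTRecord("X", tissue_raw="ovary", stage_raw="egg")]
        with pytest.raises(ValueError, match="same corpus"):
            build_profile(GeneESTSet("g", alien, []), pool_sizes(corpus, tv, sv), tv, sv)

    def test_low_confidence_flagging(self, tv, sv):
        corpus = _uniform_corpus(["head", "ovary"], ["pupa"], 10)
        pools = pool_sizes(corpus, tv, sv)
        prof = build_profile(GeneESTSet("g", [], []), pools, tv, sv, pool_min=30)
        assert prof.low_confidence_cells == {("head", "pupa"), ("ovary", "pupa")}
        prof2 = build_profile(GeneESTSet("g", [], []), pools, tv, sv, pool_min=5)
        assert prof2.low_confidence_cells == set()

    def test_hotspot_recovery_of_designed_genes(self, tv, sv):
        """Count-argmax of each synthetic gene's profile is its designed hotspot."""
        config = GeneratorConfig(seed=13, n_genes=40)
        corpus, clusters, truth = generate_expression_dataset(config)
        pools = pool_sizes(corpus, tv, sv)
        for row in truth.itertuples():
            gene = extract_gene(corpus, clusters, row.cluster_id)
            prof = build_profile(gene, pools, tv, sv)
            top = max(prof.counts, key=lambda c: (prof.counts[c], c))
            assert prof.counts[top] == prof.counts[(row.hotspot_tissue, row.hotspot_stage)]

    def test_infection_peaked_gene_recovers_its_hotspot_by_tpm(self, tv, sv):
        """A gene seeded to peak in microbe-infected fat body at 5th instar
        is recovered with that cell as its TPM argmax."""
        tissues = ["fat body", "microbe-infected fat body", "pheromone gland"]
        stages = ["5th instar larva", "5th instar day 3 larva", "pupa day 5"]
        corpus = _uniform_corpus(tissues, stages, 100)
        gene_recs = (
            [ESTRecord(f"C{i}", tissue_raw="microbe-infected fat body",
                       stage_raw="5th instar larva") for i in range(6)]
            + [ESTRecord("C6", tissue_raw="fat body", stage_raw="5th instar day 3 larva"),
               ESTRecord("C7", tissue_raw="fat body", stage_raw="5th instar day 3 larva"),
               ESTRecord("C8", tissue_raw="pheromone gland", stage_raw="pupa day 5")]
        )
        corpus = ESTCorpus(corpus.records + gene_recs)
        prof = build_profile(
            GeneESTSet("Bmo.1023-like", gene_recs, []), pool_sizes(corpus, tv, sv), tv, sv
        )
        assert prof.argmax_cell() == ("microbe-infected fat body", "5th instar larva")


class TestInvariants:
    def test_partition_conservation_sums_to_one_million(self, tv, sv):
        """When every EST in a pool belongs to exactly one gene, per-gene
        TPM values over that pool sum to 1e6."""
        config = GeneratorConfig(seed=4, n_genes=24, n_background=0)
        corpus, clusters, _ = generate_expression_dataset(config)
        pools = pool_sizes(corpus, tv, sv)
        profiles = [
            build_profile(extract_gene(corpus, clusters, cid), pools, tv, sv)
            for cid in sorted(clusters)
        ]
        for cell in pools.cell_totals:
            total = sum(p.tpm_cell[cell] for p in profiles)
            assert total == pytest.approx(1e6, rel=1e-6)
        for t in pools.tissue_totals:
            assert sum(p.tpm_tissue[t] for p in profiles) == pytest.approx(1e6, rel=1e-6)

    def test_scale_invariance_under_corpus_duplication(self, tv, sv):
        corpus = _uniform_corpus(["head", "ovary"], ["pupa", "egg"], 25)
        gene_recs = [ESTRecord(f"G{i}", tissue_raw="ovary", stage_raw="pupa")
                     for i in range(5)]
        corpus = ESTCorpus(corpus.records + gene_recs)
        prof1 = build_profile(GeneESTSet("g", gene_recs, []),
                              pool_sizes(corpus, tv, sv), tv, sv)
        doubled_recs = corpus.records + [
            ESTRecord(r.accession + "b", r.tissue_raw, r.stage_raw) for r in corpus
        ]
        gene2 = gene_recs + [ESTRecord(r.accession + "b", r.tissue_raw, r.stage_raw)
                             for r in gene_recs]
        prof2 = build_profile(GeneESTSet("g", gene2, []),
                              pool_sizes(ESTCorpus(doubled_recs), tv, sv), tv, sv)
        assert prof1.tpm_cell == prof2.tpm_cell
        assert prof1.tpm_tissue == prof2.tpm_tissue
        assert prof1.tpm_stage == prof2.tpm_stage

    def test_counts_equal_brute_force_recount(self, tv, sv):
        config = GeneratorConfig(seed=31, n_genes=8, n_background=300)
        corpus, clusters, _ = generate_expression_dataset(config)
        assert len(corpus) <= 1000
        pools = pool_sizes(corpus, tv, sv)
        for cid in sorted(clusters):
            gene = extract_gene(corpus, clusters, cid)
            prof = build_profile(gene, pools, tv, sv)
            oracle = Counter()
            member = set(clusters.members[cid])
            for rec in corpus:
                if rec.accession in member:
                    oracle[(tv.normalize(rec.tissue_raw), sv.normalize(rec.stage_raw))] += 1
            assert prof.counts == dict(oracle)


class TestRenderRoundTrip:
    def _profile(self, tv, sv):
        corpus = _uniform_corpus(["head", "ovary", "midgut"], ["pupa", "egg"], 12)
        gene_recs = [ESTRecord(f"G{i}", tissue_raw="ovary", stage_raw="pupa")
                     for i in range(4)]
        corpus = ESTCorpus(corpus.records + gene_recs)
        return build_profile(GeneESTSet("Bmo.7", gene_recs, []),
                             pool_sizes(corpus, tv, sv), tv, sv)

    def test_tsv_reingestion_reproduces_profile(self, tmp_path, tv, sv):
        prof = self._profile(tv, sv)
        path = write_profile_tsv(prof, tmp_path / "p.tsv")
        back = read_profile_tsv(path)
        assert back.cluster_id == prof.cluster_id
        assert back.counts == prof.counts
        assert back.pools.cell_totals == prof.pools.cell_totals
        assert back.tpm_cell == prof.tpm_cell
        assert back.tpm_tissue == prof.tpm_tissue
        assert back.tpm_stage == prof.tpm_stage
        assert back.low_confidence_cells == prof.low_confidence_cells

    def test_axis_order_follows_vocabulary(self, tv, sv):
        prof = self._profile(tv, sv)
        df = prof.to_frame()
        tissues_seen = list(dict.fromkeys(df["tissue"]))
        order = [t for t in tv.canonical_terms if t in set(tissues_seen)]
        assert tissues_seen == order

    def test_render_writes_figure_and_tsv(self, tmp_path, tv, sv):
        prof = self._profile(tv, sv)
        fig = render_profile(prof, tmp_path / "p.tsv", tmp_path / "p.png")
        assert (tmp_path / "p.tsv").exists()
        assert fig is not None and fig.stat().st_size > 0

    def test_all_zero_profile_skips_figure(self, tmp_path, tv, sv):
        corpus = _uniform_corpus(["head"], ["pupa"], 3)
        prof = build_profile(GeneESTSet("g", [], []), pool_sizes(corpus, tv, sv), tv, sv)
        fig = render_profile(prof, tmp_path / "z.tsv", tmp_path / "z.png")
        assert (tmp_path / "z.tsv").exists() and fig is None
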