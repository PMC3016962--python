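import pytest

from estprofile.synthgen import GeneratorConfig, generate_blast_and_go, generate_corpus
from estprofile.vocab import default_vocabularies


@pytest.fixture(scope="session")
def vocabs():
    return default_vocabularies()


@pytest.fixture(scope="session")
def corpus_fixture(tmp_path_factory):
    """A 1,000-record synthetic corpus (files + truth table)."""
    outdir = tmp_path_factory.mktemp("corpus")
    config = GeneratorConfig(seed=11, n_records=1000)
    est_source, fasta, rules, truth = generate_corpus(config, outdir)
    return {
        "est_source": est_source,
        "fasta": fasta,
        "rules": rules,
        "truth": truth,
        "config": config,
        "dir": outdir,
    }


@pytest.fixture(scope="session")
def blast_go_fixture(tmp_path_factory):
    """BLAST tabular + OBO + protein2go files with truth tables (500 queries)."""
    outdir = tmp_path_factory.mktemp("blastgo")
    config = GeneratorConfig(seed=5, n_queries=500)
    out = generate_blast_and_go(config, outdir)
    out["config"] = config
    return out
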