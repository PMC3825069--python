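import pytest

import codonforge as cf


@pytest.fixture(scope="session")
def code():
    return cf.default_code()


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA from (id, seq[, description]) tuples."""

    def make(entries, name="test.fa"):
        path = tmp_path / name
        lines = []
        for entry in entries:
            header = entry[0] if len(entry) < 3 else f"{entry[0]} {entry[2]}"
            lines.append(f">{header}\n{entry[1]}\n")
        path.write_text("".join(lines))
        return path

    return make


def _valid_cds(n_codons=100, body="GAA", start="ATG", stop="TAA"):
    return start + body * n_codons + stop


@pytest.fixture
def valid_cds():
    return _valid_cds


# -- session-scoped synthetic genomes (study conditions; reused) ---------

@pytest.fixture(scope="session")
def mutation_genome():
    spec = cf.mutation_dominated_spec(n_genes=400, seed=5)
    records, truth = cf.generate_genome(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def mutation_results(mutation_genome):
    _, records, truth = mutation_genome
    model = cf.CodonUsageAnalysis(
        records, reference_ids=cf.make_reference_set(truth)
    )
    return model.fit()


@pytest.fixture(scope="session")
def selection_genome():
    spec = cf.selection_dominated_spec(n_genes=500, seed=11)
    records, truth = cf.generate_genome(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def selection_results(selection_genome):
    _, records, truth = selection_genome
    model = cf.CodonUsageAnalysis(
        records, reference_ids=cf.make_reference_set(truth)
    )
    return model.fit()
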