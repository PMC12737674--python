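import numpy as np
import pytest

from viroscreen import make_dataset, run_pipeline_data


def random_contig_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_dataset():
    """Zero-noise labeled dataset shared across test modules (4 per class)."""
    return make_dataset(seed=7, n_per_class=4, mutation_rate=0.0)


@pytest.fixture(scope="session")
def small_report(small_dataset):
    ds = small_dataset
    return run_pipeline_data(ds.contigs, ds.protein_hits, ds.nucleotide_hits, ds.segment_groups)


@pytest.fixture()
def write_text(tmp_path):
    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
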