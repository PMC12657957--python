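import numpy as np
import pytest

from ribodwell.core_io import CodonSequence, Sample
from ribodwell.model import DwellModel, ModelConfig
from ribodwell.preprocess import PreprocessConfig, preprocess_dataset
from ribodwell.simulate import SimulationConfig, records_to_samples, simulate_dataset


@pytest.fixture(scope="session")
def tiny_model64():
    """Small float64 model for numeric checks."""
    return DwellModel(ModelConfig(d_model=16, n_layers=2, n_heads=2, d_ff=32, dtype="float64", seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A small preprocessed synthetic dataset (fast to build, reused widely)."""
    cfg = SimulationConfig(n_genes=24, length_range=(60, 120), seed=11)
    seqs, records, sim = simulate_dataset(cfg)
    ds, report, manifest = preprocess_dataset(seqs, records_to_samples(seqs, records), PreprocessConfig())
    return ds, sim


def make_sample(codons, cond="VAL", y_ctrl=None, y_dc=None, gene="gX"):
    seq = CodonSequence(gene, tuple(codons))
    n = seq.n
    if y_ctrl is None:
        y_ctrl = np.ones(n)
    if y_dc is None:
        y_dc = np.ones(n)
    return Sample(seq, cond, np.asarray(y_ctrl, float), np.asarray(y_dc, float))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
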