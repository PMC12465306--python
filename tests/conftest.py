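import numpy as np
import pytest

from salmotx.pipeline import run_synthetic_study
from salmotx.synthetic import SimulationConfig, simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at default conditions, run end to end."""
    return run_synthetic_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def module_study_3():
    """Three pure latent-factor modules, no tissue-specific planting."""
    cfg = SimulationConfig(
        seed=2, n_modules=3, module_size=50, n_tissue_specific_per_tissue=0,
        module_tissue_shift=0.0, n_background_loci=150, n_divergent_pairs=0,
    )
    reference, assembled, truth = simulate_annotation(cfg)
    counts, samples = simulate_counts(cfg, truth)
    return cfg, truth, counts, samples


@pytest.fixture(scope="session")
def module_study_4tissue():
    """Four tissue-driven modules, one per tissue."""
    cfg = SimulationConfig(
        seed=3, n_modules=4, module_size=50, n_tissue_specific_per_tissue=0,
        n_background_loci=300, n_divergent_pairs=0,
    )
    reference, assembled, truth = simulate_annotation(cfg)
    counts, samples = simulate_counts(cfg, truth)
    return cfg, truth, counts, samples


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_transcript(rng, tid="t", contig="c1", lo=1, hi=20_000, strand=None,
                      max_exons=4):
    """Random multi-exon transcript for oracle cross-checks."""
    from salmotx.annotation import Exon, Transcript

    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(lo, hi))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 300))
        exons.append(Exon(contig, pos, pos + length - 1))
        pos += length + int(rng.integers(30, 500))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return Transcript(id=tid, contig=contig, strand=strand, exons=exons)
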