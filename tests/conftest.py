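import numpy as np
import pytest

from ishscreen.pipeline import PipelineConfig, run_pipeline, training_shape_model
from ishscreen.segmentation import train_accept_forest, train_inside_forest
from ishscreen.synthetic_data import SectionParams, generate_cohort, generate_section


@pytest.fixture(scope="session")
def shape_model():
    return training_shape_model(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def default_section():
    """One noise-free section at the default moderate enrichment."""
    params = SectionParams(seed=11, noise_sd=0.0)
    image, truth = generate_section(params)
    return params, image, truth


@pytest.fixture(scope="session")
def noisy_section():
    params = SectionParams(seed=23)
    image, truth = generate_section(params)
    return params, image, truth


@pytest.fixture(scope="session")
def cohort20():
    """The 20-gene training design: 3 positives, 17 negatives."""
    return generate_cohort(3, 17, seed=42)


@pytest.fixture(scope="session")
def qc_forests(cohort20):
    rf_inside = train_inside_forest(cohort20, seed=1)
    rf_accept = train_accept_forest(cohort20, rf_inside, seed=2)
    return rf_inside, rf_accept


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default screen (20 training genes + 30 graded screen genes)."""
    outdir = tmp_path_factory.mktemp("run_a")
    result = run_pipeline(PipelineConfig(seed=1), outdir=outdir)
    return result, outdir


@pytest.fixture(scope="session")
def pipeline_rerun(tmp_path_factory):
    """Second run with the same master seed, for determinism checks."""
    outdir = tmp_path_factory.mktemp("run_b")
    result = run_pipeline(PipelineConfig(seed=1), outdir=outdir)
    return result, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
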