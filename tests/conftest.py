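import pytest

from vesiscope.dls import compute_wave_vector
from vesiscope.pipeline import run_study
from vesiscope.synthetic import StudyConfig, gen_study


@pytest.fixture(scope="session")
def q_173() -> float:
    """Wave vector of a 633 nm backscattering setup in water."""
    return compute_wave_vector(633e-9, 1.33, 173.0)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Full synthetic study (seed 7): data dir, manifest, pipeline report."""
    data_dir = tmp_path_factory.mktemp("study7")
    manifest = gen_study(StudyConfig(seed=7), data_dir)
    report = run_study(data_dir / "study.yaml", data_dir)
    return data_dir, manifest, report
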