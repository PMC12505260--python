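import json
from pathlib import Path

import pytest

from thzmob.pipeline import StudyConfig, run_pipeline
from thzmob.synthetic import make_study_fixture


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory) -> Path:
    """Noiseless four-sample study fixture on disk."""
    out = tmp_path_factory.mktemp("study")
    make_study_fixture(out, seed=1)
    return out


@pytest.fixture(scope="session")
def ground_truth(study_dir) -> dict:
    return json.loads((study_dir / "ground_truth.json").read_text())


@pytest.fixture(scope="session")
def study_report(study_dir) -> dict:
    config = StudyConfig.from_file(study_dir / "study_config.json")
    return run_pipeline(config)
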