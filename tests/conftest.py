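import numpy as np
import pytest

import vibrotissue as vt

PAPER_CLASS_COUNTS = {0: 231, 1: 300, 2: 208, 3: 211, 4: 332}


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """Small corrupted corpus with clean references: 5 classes x 5 recordings
    x 2 half-second segments, default periodic interference."""
    out = tmp_path_factory.mktemp("small_corpus")
    manifest = vt.generate_corpus(
        class_counts={c: 10 for c in range(5)},
        recordings_per_class=5,
        segment_s=0.5,
        interference=vt.InterferenceSpec(),
        seed=123,
        out_dir=out,
        write_clean=True,
    )
    return manifest


@pytest.fixture(scope="session")
def paper_counts_manifest(tmp_path_factory):
    """Corpus with the study's per-class segment counts (1282 segments total),
    cut as short segments from 10 recordings per class."""
    out = tmp_path_factory.mktemp("paper_counts")
    return vt.generate_corpus(
        class_counts=dict(PAPER_CLASS_COUNTS),
        recordings_per_class=10,
        segment_s=0.1,
        interference=None,
        seed=7,
        out_dir=out,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
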