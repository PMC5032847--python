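import numpy as np
import pytest

from crowdgrade import (
    AnnotatorProfile,
    BinaryMask,
    CorpusConfig,
    generate_study,
)

MASTER_SEED = 1234


def noise_free_profiles():
    """One perfect annotator profile per group: every label and mask exact."""
    return [
        AnnotatorProfile(group=g, sens=1.0, spec=1.0, p_detect=1.0,
                         jitter_sd=0.0, scale_sd=0.0, fp_rate=0.0)
        for g in ("nonmasters", "masters", "nonmasters_trained")
    ]


@pytest.fixture(scope="session")
def default_bundle():
    """The default study design: 100-image corpus, 84 evaluation images,
    3 groups x 20 annotators with the default error profiles."""
    return generate_study(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast corpus for pipeline-level tests."""
    return CorpusConfig(
        n_severe=2, n_mild=6, n_normal=4, n_training=2, n_training_normal=1,
        width=64, height=64,
        mild_lesion_count=(1, 2), severe_lesion_count=(2, 3),
        mild_lesion_size=(6, 14), severe_lesion_size=(10, 24),
    )


def mask_from_string(art: str) -> BinaryMask:
    """Build a small mask from ASCII art ('#' positive, '.' negative)."""
    rows = [line.strip() for line in art.strip().splitlines()]
    return BinaryMask(np.array([[c == "#" for c in row] for row in rows]))
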