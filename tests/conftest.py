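import numpy as np
import pytest

from fatph import PipelineConfig, fat_config, nonfat_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pipeline_config(tmp_path):
    """1 subject/group, 4 patches of 8x8 — the smoke-test scale."""
    return PipelineConfig(
        fat=fat_config(n_subjects=1, patches_per_subject=4, patch_size=8),
        nonfat=nonfat_config(n_subjects=1, patches_per_subject=4, patch_size=8),
        grid_cols=2,
        output_dir=str(tmp_path / "out"),
        make_plots=False,
    ).with_seed(7)
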