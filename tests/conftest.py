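import numpy as np
import pytest

from qrhythm import DesignSpec, GeneSpec, ZT_PRINTED


@pytest.fixture
def study_design():
    """The daily-cycle sampling design: 9 ZT points, 6 replicates."""
    return DesignSpec(timepoints_h=ZT_PRINTED, n_replicates=6, seed=11)


@pytest.fixture
def clean_gene():
    """Noise-free rhythmic gene peaking at ZT6."""
    return GeneSpec("g1", mesor=10.0, amplitude=2.0, acrophase_h=6.0,
                    noise_sd=0.0, efficiency=2.0)


@pytest.fixture
def design_times():
    return np.repeat(np.array(ZT_PRINTED), 6)
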