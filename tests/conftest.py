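import numpy as np
import pytest

from efptiming import sigproc, synthrec


@pytest.fixture(scope="session")
def template():
    return synthrec.biphasic_template()


@pytest.fixture(scope="session")
def fs():
    return synthrec.DEFAULT_FS


@pytest.fixture()
def single_spike_trace(template, fs):
    """Noise-free trace with one template at 100 ms, trough depth 100 µV."""
    trace = np.zeros(int(0.2 * fs))
    i0 = int(0.1 * fs)
    trace[i0 : i0 + template.samples.size] = 100.0 * template.samples
    return trace, i0 / fs + template.peak_offset
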