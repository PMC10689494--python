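import numpy as np
import pytest

from lowsuite import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 600 s, 3-channel instance of the committed scenario."""
    return generate_dataset(SynthConfig(duration_s=600.0, seed=11))


def write_minimal_edf(path, samples_uV, fs, labels):
    """Hand-rolled minimal EDF writer (test scaffolding only: the package
    reads EDF through MNE but the environment has no EDF writer)."""
    n_ch, n_t = samples_uV.shape
    fs = int(fs)
    assert n_t % fs == 0, "test signals must span whole seconds"
    n_rec = n_t // fs
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    header = b""
    header += b"0".ljust(8)
    header += b"test patient".ljust(80)
    header += b"test recording".ljust(80)
    header += b"01.01.20".ljust(8) + b"00.00.00".ljust(8)
    header += str(256 * (1 + n_ch)).encode().ljust(8)
    header += b"".ljust(44)
    header += str(n_rec).encode().ljust(8)
    header += b"1".ljust(8)
    header += str(n_ch).encode().ljust(4)

    def field(vals, width):
        return b"".join(str(v).encode().ljust(width) for v in vals)

    header += field(labels, 16)
    header += field([""] * n_ch, 80)
    header += field(["uV"] * n_ch, 8)
    header += field([phys_min] * n_ch, 8)
    header += field([phys_max] * n_ch, 8)
    header += field([dig_min] * n_ch, 8)
    header += field([dig_max] * n_ch, 8)
    header += field([""] * n_ch, 80)
    header += field([fs] * n_ch, 8)
    header += field([""] * n_ch, 32)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip((samples_uV - phys_min) * scale + dig_min,
                      dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * fs : (r + 1) * fs].tobytes())
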