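"""Shared fixtures: synthetic EDF files and small annotated recordings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

FS = 178.0


def write_minimal_edf(path, data_uv: np.ndarray, fs: int, labels: list[str]) -> None:
    """Write a minimal synthetic EDF file (one 1-s data record per second).

    Synthetic test fixture only: 16-bit samples over a +/-3276.8 uV physical
    range, enough for byte-level round-trip checks against the CSV reader.
    """
    n_ch = len(labels)
    spr = int(fs)
    n_rec = int(np.ceil(data_uv.shape[1] / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : data_uv.shape[1]] = data_uv
    phys_min, phys_max = -3276.8, 3276.7
    dig_min, dig_max = -32768, 32767

    def f(s, n):
        return str(s).ljust(n)[:n].encode()

    hdr = f("0", 8) + f("X", 80) + f("X", 80)
    hdr += f("01.01.20", 8) + f("00.00.00", 8)
    hdr += f(256 + 256 * n_ch, 8) + f("", 44) + f(n_rec, 8) + f(1, 8) + f(n_ch, 4)
    hdr += b"".join(f(l, 16) for l in labels)
    hdr += b"".join(f("", 80) for _ in labels)
    hdr += b"".join(f("uV", 8) for _ in labels)
    hdr += b"".join(f(phys_min, 8) for _ in labels)
    hdr += b"".join(f(phys_max, 8) for _ in labels)
    hdr += b"".join(f(dig_min, 8) for _ in labels)
    hdr += b"".join(f(dig_max, 8) for _ in labels)
    hdr += b"".join(f("", 80) for _ in labels)
    hdr += b"".join(f(spr, 8) for _ in labels)
    hdr += b"".join(f("", 32) for _ in labels)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                seg = padded[c, r * spr : (r + 1) * spr]
                dig = np.round((seg - phys_min) * scale + dig_min).astype("<i2")
                fh.write(dig.tobytes())


@pytest.fixture
def edf_writer():
    return write_minimal_edf


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
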