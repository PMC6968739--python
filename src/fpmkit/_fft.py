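"""FFT wrappers with a lightweight operation counter.

All Fourier transforms inside the package go through these wrappers so that
the relative computational cost of different refocusing routes (e.g. a single
post-reconstruction propagation versus a full re-reconstruction) can be
compared by counted operations rather than wall time.  The cost of one 2D FFT
of ``n`` samples is tallied as ``n * log2(n)`` (the usual flop proxy).
"""

from __future__ import annotations

import numpy as np

_COUNTER = {"fft_calls": 0, "flops": 0.0}


def _tally(a: np.ndarray) -> None:
    n = float(a.size)
    _COUNTER["fft_calls"] += 1
    _COUNTER["flops"] += n * np.log2(max(n, 2.0))


def fft2(a: np.ndarray) -> np.ndarray:
    _tally(a)
    return np.fft.fft2(a)


def ifft2(a: np.ndarray) -> np.ndarray:
    _tally(a)
    return np.fft.ifft2(a)


fftshift = np.fft.fftshift
ifftshift = np.fft.ifftshift


def reset_counter() -> None:
    _COUNTER["fft_calls"] = 0
    _COUNTER["flops"] = 0.0


def counter() -> dict:
    return dict(_COUNTER)
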