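"""Centered, unitary 2-D Fourier transforms.

All spectra in this package live on grids whose DC bin sits at index
``side // 2`` (``fftshift`` convention), and every transform is unitary
(``norm="ortho"``) so that Parseval's identity holds exactly and the
Hermitian adjoint of the forward transform is its inverse.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ft2", "ift2"]


def ft2(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D Fourier transform."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def ift2(X: np.ndarray) -> np.ndarray:
    """Centered unitary inverse 2-D Fourier transform."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(X), norm="ortho"))
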