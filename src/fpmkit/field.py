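"""Complex optical fields on a sample-plane grid."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ComplexField"]


@dataclass
class ComplexField:
    """2D complex amplitude U(x, y) at axial position ``z``.

    ``pixel`` is the grid pitch in µm, ``wavelength`` in µm and ``z`` the axial
    position in µm relative to the nominal focal plane.
    """

    values: np.ndarray
    pixel: float
    wavelength: float
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel <= 0:
            raise ValueError("pixel must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("field values must be a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def with_values(self, values: np.ndarray, z: float | None = None) -> "ComplexField":
        return replace(self, values=values, z=self.z if z is None else z)

    def check_finite(self) -> "ComplexField":
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        return self
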