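"""Core container for complex dynamic image series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DynamicImage:
    """A complex-valued dynamic 2D image series of shape (Nx, Ny, Nt).

    The Casorati matrix view reshapes the series so that each column is
    one vectorized temporal frame; its rank measures temporal redundancy
    and is the object the nuclear-norm (low-rank) penalty acts on.

    Parameters
    ----------
    data :
        Complex array of shape (Nx, Ny, Nt).
    frame_interval :
        Time between frames in seconds (metadata only).
    """

    data: np.ndarray
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"DynamicImage expects a (Nx, Ny, Nt) array, got shape {self.data.shape}"
            )
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def casorati(self) -> np.ndarray:
        """(Nx*Ny) x Nt matrix; column-major (Fortran) voxel flattening."""
        nx, ny, nt = self.data.shape
        return self.data.reshape(nx * ny, nt, order="F")

    @classmethod
    def from_casorati(
        cls, matrix: np.ndarray, nx: int, ny: int, frame_interval: float | None = None
    ) -> "DynamicImage":
        nt = matrix.shape[1]
        if matrix.shape[0] != nx * ny:
            raise ValueError("Casorati matrix rows do not match nx*ny")
        return cls(matrix.reshape(nx, ny, nt, order="F"), frame_interval)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


def as_series(x) -> np.ndarray:
    """Coerce a DynamicImage or ndarray into a complex (Nx, Ny, Nt) array."""
    if isinstance(x, DynamicImage):
        return x.data
    arr = np.asarray(x)
    if arr.ndim != 3:
        raise ValueError(f"expected (Nx, Ny, Nt) array, got shape {arr.shape}")
    return arr.astype(np.complex128, copy=False)


def casorati(x) -> np.ndarray:
    arr = as_series(x)
    nx, ny, nt = arr.shape
    return arr.reshape(nx * ny, nt, order="F")


def from_casorati(matrix: np.ndarray, nx: int, ny: int) -> np.ndarray:
    return matrix.reshape(nx, ny, matrix.shape[1], order="F")
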