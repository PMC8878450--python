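"""Sparsifying transforms: identity, temporal Fourier, spatial wavelets,
and a Parseval discrete shearlet system.

All transforms are linear with exact inverses, operate on complex
(Nx, Ny, Nt) series, and are selected by short names ``none | tf | wt |
ds`` in configs and on the command line.

The shearlet system is a cone-adapted, band-limited construction
assembled entirely in the frequency plane: Meyer-type radial windows
split the spectrum into a low pass and dyadic annuli, raised-cosine
angular windows split each annulus into sheared directional wedges on
the horizontal and vertical frequency cones, and a final pointwise
normalization enforces the Parseval property sum |W|^2 = 1 exactly.
Because the frame is Parseval with real windows, the adjoint equals the
inverse, and coefficientwise shrinkage sandwiched between forward and
inverse is non-expansive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt


__all__ = [
    "SparsifyingTransform",
    "ShearletSystem",
    "identity_transform",
    "temporal_fourier_transform",
    "wavelet_transform",
    "build_shearlet_system",
    "shearlet_forward",
    "shearlet_inverse",
    "shearlet_transform",
    "get_transform",
]


@dataclass
class SparsifyingTransform:
    """An invertible sparsifying map Phi with its exact inverse."""

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    coeff_shape: str = ""

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def identity_transform() -> SparsifyingTransform:
    """Phi = identity (plain L1 penalty on the image itself)."""
    return SparsifyingTransform(
        name="none",
        forward=lambda x: np.asarray(x),
        inverse=lambda c: np.asarray(c),
        coeff_shape="same as input",
    )


def temporal_fourier_transform() -> SparsifyingTransform:
    """Unitary FFT along the time axis only."""

    def fwd(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim < 1 or x.shape[-1] < 2:
            raise ValueError("temporal Fourier transform needs Nt >= 2")
        return np.fft.fft(x, axis=-1, norm="ortho")

    def inv(c: np.ndarray) -> np.ndarray:
        return np.fft.ifft(np.asarray(c), axis=-1, norm="ortho")

    return SparsifyingTransform(
        name="tf", forward=fwd, inverse=inv, coeff_shape="same as input (x, y, f)"
    )


def wavelet_transform(wavelet: str = "db4", levels: int = 3) -> SparsifyingTransform:
    """Orthogonal 2D DWT applied frame-by-frame (periodized boundaries).

    Periodization keeps the decomposition orthonormal, so energy is
    preserved and the inverse is exact; frame sizes must be divisible by
    2**levels.
    """
    wav = pywt.Wavelet(wavelet)
    slices_cache: dict = {}

    def _check(nx: int, ny: int) -> None:
        f = 2**levels
        if nx % f or ny % f:
            raise ValueError(
                f"frame size ({nx}, {ny}) not divisible by 2**levels = {f}"
            )

    def fwd(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.complex128)
        single = x.ndim == 2
        if single:
            x = x[:, :, None]
        _check(x.shape[0], x.shape[1])
        out = np.empty_like(x)
        for t in range(x.shape[2]):
            coeffs = pywt.wavedec2(x[:, :, t], wav, mode="periodization", level=levels)
            arr, sl = pywt.coeffs_to_array(coeffs)
            slices_cache[(x.shape[0], x.shape[1])] = sl
            out[:, :, t] = arr
        return out[:, :, 0] if single else out

    def inv(c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=np.complex128)
        single = c.ndim == 2
        if single:
            c = c[:, :, None]
        key = (c.shape[0], c.shape[1])
        if key not in slices_cache:
            # rebuild the slice layout from a dummy decomposition
            dummy = pywt.wavedec2(
                np.zeros(key), wav, mode="periodization", level=levels
            )
            _, sl = pywt.coeffs_to_array(dummy)
            slices_cache[key] = sl
        sl = slices_cache[key]
        out = np.empty_like(c)
        for t in range(c.shape[2]):
            coeffs = pywt.array_to_coeffs(c[:, :, t], sl, output_format="wavedec2")
            out[:, :, t] = pywt.waverec2(coeffs, wav, mode="periodization")
        return out[:, :, 0] if single else out

    return SparsifyingTransform(
        name="wt", forward=fwd, inverse=inv, coeff_shape="same as input per frame"
    )


# ---------------------------------------------------------------------------
# Discrete shearlets
# ---------------------------------------------------------------------------


def _meyer_nu(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: 0 below 0, 1 above 1, C^3 in between."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _radial_windows(r: np.ndarray, n_scales: int) -> list[np.ndarray]:
    """Squared-partition radial windows: low pass + n_scales dyadic bands.

    Band j lives on [b_j, 4 b_j] with b_j = 2**(j - n_scales) / 2 scaled so
    the finest band reaches the Nyquist circle and plateaus out to the
    spectrum corners (r is normalized: 1 at the Nyquist edge).
    """
    bounds = [0.5 * 2.0 ** (j - (n_scales - 1)) for j in range(n_scales)]
    windows = []
    b0 = bounds[0]
    # low pass: 1 below b0, Meyer decay to 0 at 2*b0
    low = np.cos(0.5 * np.pi * _meyer_nu(r / b0 - 1.0))
    low[r <= b0] = 1.0
    low[r >= 2 * b0] = 0.0
    windows.append(low)
    for j, bj in enumerate(bounds):
        rise = np.sin(0.5 * np.pi * _meyer_nu(r / bj - 1.0))
        rise[r <= bj] = 0.0
        rise[r >= 2 * bj] = 1.0
        if j < n_scales - 1:
            fall = np.cos(0.5 * np.pi * _meyer_nu(r / (2 * bj) - 1.0))
            fall[r <= 2 * bj] = 1.0
            fall[r >= 4 * bj] = 0.0
        else:
            fall = np.ones_like(r)  # finest band plateaus to the corners
        windows.append(rise * fall)
    return windows


def _angular_window(u: np.ndarray) -> np.ndarray:
    """Raised-cosine bump with sum_s b(u - s)^2 = 1 over integer shifts."""
    out = np.cos(0.5 * np.pi * np.clip(np.abs(u), 0.0, 1.0))
    out[np.abs(u) >= 1.0] = 0.0
    return out


@dataclass
class ShearletSystem:
    """Frequency-domain directional window bank on a fixed grid.

    ``windows`` is a (n_windows, Nx, Ny) real array in unshifted (fft)
    frequency ordering; ``labels`` carries (scale, cone, shear) with
    scale -1 denoting the low pass and cone in {"h", "v"}.
    """

    nx: int
    ny: int
    n_scales: int
    windows: np.ndarray
    labels: list[tuple[int, str, int]]

    @property
    def redundancy(self) -> int:
        return self.windows.shape[0]

    def window(self, scale: int, cone: str, shear: int) -> np.ndarray:
        idx = self.labels.index((scale, cone, shear))
        return self.windows[idx]


def shears_per_scale(j: int) -> int:
    """Half-range of shear indices at scale j (0-based, coarse to fine)."""
    return 2 ** int(np.ceil((j + 1) / 2))


def build_shearlet_system(nx: int, ny: int, n_scales: int = 3) -> ShearletSystem:
    """Build a Parseval cone-adapted shearlet window bank for an nx x ny grid.

    Raises if the grid is too small to resolve the requested scales.
    """
    if nx < 32 or ny < 32:
        raise ValueError("grid must be at least 32 x 32")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if min(nx, ny) < 2 ** (n_scales + 2):
        raise ValueError(
            f"grid {nx}x{ny} too small for n_scales={n_scales}"
        )

    f1 = np.fft.fftfreq(nx)[:, None] / 0.5  # normalized: Nyquist -> 1
    f2 = np.fft.fftfreq(ny)[None, :] / 0.5
    r = np.sqrt(f1**2 + f2**2)
    radial = _radial_windows(r, n_scales)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_h = np.where(f1 != 0, f2 / np.where(f1 != 0, f1, 1.0), np.inf)
        t_v = np.where(f2 != 0, f1 / np.where(f2 != 0, f2, 1.0), np.inf)
    t_h = np.where(f1 != 0, t_h, np.inf)
    t_v = np.where(f2 != 0, t_v, np.inf)

    windows = [radial[0]]
    labels: list[tuple[int, str, int]] = [(-1, "h", 0)]
    for j in range(n_scales):
        band = radial[j + 1]
        n = shears_per_scale(j)
        for s in range(-n, n + 1):
            wh = band * _angular_window(n * np.where(np.isfinite(t_h), t_h, 1e6) - s)
            windows.append(wh)
            labels.append((j, "h", s))
        for s in range(-n, n + 1):
            wv = band * _angular_window(n * np.where(np.isfinite(t_v), t_v, 1e6) - s)
            windows.append(wv)
            labels.append((j, "v", s))

    bank = np.stack(windows, axis=0)
    total = np.sqrt((bank**2).sum(axis=0))
    if np.any(total <= 0):
        raise RuntimeError("shearlet windows do not cover the frequency plane")
    bank /= total[None, :, :]
    return ShearletSystem(nx=nx, ny=ny, n_scales=n_scales, windows=bank, labels=labels)


def shearlet_forward(frame: np.ndarray, system: ShearletSystem) -> np.ndarray:
    """Shearlet coefficients of one frame (or a (Nx, Ny, Nt) stack).

    Returns (n_windows, Nx, Ny[, Nt]); each band is the inverse FFT of
    the windowed spectrum, so coefficients live on the image grid.
    """
    x = np.asarray(frame, dtype=np.complex128)
    if x.shape[0] != system.nx or x.shape[1] != system.ny:
        raise ValueError(
            f"frame shape {x.shape[:2]} does not match system grid "
            f"({system.nx}, {system.ny})"
        )
    spec = np.fft.fft2(x, axes=(0, 1), norm="ortho")
    if x.ndim == 2:
        return np.fft.ifft2(
            spec[None, :, :] * system.windows, axes=(1, 2), norm="ortho"
        )
    # (Nx, Ny, Nt) stack
    out = np.fft.ifft2(
        spec[None, :, :, :] * system.windows[:, :, :, None],
        axes=(1, 2),
        norm="ortho",
    )
    return out


def shearlet_inverse(coeffs: np.ndarray, system: ShearletSystem) -> np.ndarray:
    """Exact inverse (= adjoint, Parseval frame) of :func:`shearlet_forward`."""
    c = np.asarray(coeffs, dtype=np.complex128)
    if c.shape[0] != system.redundancy or c.shape[1:3] != (system.nx, system.ny):
        raise ValueError("coefficient stack does not match system")
    spec = np.fft.fft2(c, axes=(1, 2), norm="ortho")
    if c.ndim == 3:
        acc = (spec * system.windows).sum(axis=0)
    else:
        acc = (spec * system.windows[:, :, :, None]).sum(axis=0)
    return np.fft.ifft2(acc, axes=(0, 1), norm="ortho")


def shearlet_transform(
    nx: int, ny: int, n_scales: int = 3, system: ShearletSystem | None = None
) -> SparsifyingTransform:
    """Frame-wise spatial shearlet transform packaged as a SparsifyingTransform."""
    if system is None:
        system = build_shearlet_system(nx, ny, n_scales)

    def fwd(x: np.ndarray) -> np.ndarray:
        return shearlet_forward(np.asarray(x), system)

    def inv(c: np.ndarray) -> np.ndarray:
        return shearlet_inverse(np.asarray(c), system)

    tr = SparsifyingTransform(
        name="ds",
        forward=fwd,
        inverse=inv,
        coeff_shape=f"({system.redundancy}, Nx, Ny, Nt)",
    )
    tr.system = system  # keep the bank reachable for caching/inspection
    return tr


def get_transform(name: str, nx: int, ny: int, **kwargs) -> SparsifyingTransform:
    """Transform factory keyed by the config/CLI names none|tf|wt|ds."""
    name = name.lower()
    if name in ("none", "id", "identity"):
        return identity_transform()
    if name == "tf":
        return temporal_fourier_transform()
    if name == "wt":
        return wavelet_transform(**kwargs)
    if name == "ds":
        return shearlet_transform(nx, ny, **kwargs)
    raise ValueError(f"unknown transform {name!r}; expected none|tf|wt|ds")
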