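"""Seeded synthetic dynamic-MRI phantoms with ground truth.

Two families are generated, mirroring the two study conditions the
package is evaluated on:

* a DCE abdominal series: procedurally drawn static anatomy (body,
  liver, bowel, right/left heart, aorta, portal vein) whose organs
  enhance according to the extended Tofts model driven by a population
  (Parker-type) arterial input function, converted to spoiled
  gradient-echo signal; 50 frames at 3 s by default;
* a small-bowel series: smooth bowel-loop anatomy deformed by a
  single-frequency periodic respiratory field during the free-breathing
  segment, plus sparse, aperiodic, localized motility events; the
  breath-hold segment (first 20 frames by default) has zero respiratory
  amplitude.

Both generators are bit-deterministic given (config, seed) and return
the series together with a PhantomGroundTruth (label map, kinetic maps,
per-frame true deformation fields, and the binary support of the true
sparse component).

Geometry conventions: arrays are (Nx, Ny, Nt) with axis 0 the image row
and axis 1 the column; displacement fields are stored as (dx, dy) where
dx moves content along columns and dy along rows, in pixels; warping is
bilinear with edge clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import DynamicImage

__all__ = [
    "DCEPhantomConfig",
    "BowelPhantomConfig",
    "PhantomGroundTruth",
    "DCE_LABELS",
    "population_aif",
    "extended_tofts",
    "concentration_to_signal",
    "generate_dce_phantom",
    "generate_bowel_phantom",
    "warp_frame",
]

# ---------------------------------------------------------------------------
# Pharmacokinetics
# ---------------------------------------------------------------------------

# Parker population AIF parameters (bi-Gaussian bolus + sigmoid-gated
# exponential washout); time in minutes, concentration in mM.
_PARKER = dict(
    A=(0.809, 0.330),
    T=(0.17046, 0.365),
    sigma=(0.0563, 0.132),
    alpha=1.050,
    beta=0.1685,
    s=38.078,
    tau=0.483,
)


def population_aif(t_grid: np.ndarray) -> np.ndarray:
    """Population arterial input function Cp(t) in mM, t in minutes.

    Bi-Gaussian bolus plus sigmoid-modulated exponential washout; zero
    before contrast arrival (t < 0).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("time grid is empty")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be non-decreasing")
    p = _PARKER
    cp = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    for a, tc, sg in zip(p["A"], p["T"], p["sigma"]):
        cp[pos] += a / (sg * np.sqrt(2 * np.pi)) * np.exp(-((tp - tc) ** 2) / (2 * sg**2))
    cp[pos] += p["alpha"] * np.exp(-p["beta"] * tp) / (1.0 + np.exp(-p["s"] * (tp - p["tau"])))
    return np.maximum(cp, 0.0)


def extended_tofts(
    ktrans: float, kep: float, vp: float, cp: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """Tissue concentration Ct = Ktrans * (Cp (*) exp(-kep t)) + vp * Cp.

    The convolution is evaluated on the (uniform) time grid with
    trapezoidal weights, accurate to O(dt^2). Parameters are in 1/min
    (ktrans, kep), dimensionless (vp), minutes (t_grid), mM (cp).
    """
    if ktrans < 0 or kep < 0 or vp < 0:
        raise ValueError("pharmacokinetic parameters must be non-negative")
    if vp > 1:
        raise ValueError("vp must not exceed 1")
    cp = np.asarray(cp, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if cp.shape != t.shape:
        raise ValueError("cp and t_grid must have the same shape")
    n = t.size
    if n < 2:
        return vp * cp
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("extended_tofts requires a uniform time grid")
    dt = float(dt[0])
    kernel = np.exp(-kep * (t - t[0]))
    full = np.convolve(cp, kernel)[:n] * dt
    # trapezoid endpoint correction
    full -= 0.5 * dt * (cp * kernel[0] + cp[0] * kernel)
    return ktrans * full + vp * cp


def concentration_to_signal(
    ct: np.ndarray,
    t1_ms: float,
    r1: float = 4.5,
    flip_angle_deg: float = 10.0,
    tr_ms: float = 2.3,
    m0: float = 1.0,
) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal for a concentration curve.

    R1(t) = 1/T1 + r1 * Ct(t); S = m0 sin(a) (1 - E1) / (1 - cos(a) E1)
    with E1 = exp(-TR * R1). r1 is the contrast-agent relaxivity in
    1/s/mM, T1 and TR in milliseconds.
    """
    if t1_ms <= 0 or tr_ms <= 0:
        raise ValueError("T1 and TR must be positive")
    ct = np.asarray(ct, dtype=float)
    r1_total = 1.0 / (t1_ms / 1000.0) + r1 * ct  # 1/s
    e1 = np.exp(-(tr_ms / 1000.0) * r1_total)
    a = np.deg2rad(flip_angle_deg)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


# ---------------------------------------------------------------------------
# Configs and ground truth
# ---------------------------------------------------------------------------

DCE_LABELS = {
    "background": 0,
    "body": 1,
    "liver": 2,
    "bowel": 3,
    "right_heart": 4,
    "left_heart": 5,
    "aorta": 6,
    "portal_vein": 7,
}

# per-label (T1 [ms], Ktrans [1/min], kep [1/min], vp [-], m0 [a.u.]);
# literature-plausible stand-ins, all overridable through the config.
_DEFAULT_TISSUES = {
    "background": (1000.0, 0.0, 0.0, 0.0, 0.0),
    "body": (900.0, 0.0, 0.0, 0.0, 1.0),
    "liver": (800.0, 0.10, 0.50, 0.03, 1.0),
    "bowel": (900.0, 0.15, 0.75, 0.02, 0.9),
    "right_heart": (1600.0, 0.0, 0.0, 1.0, 0.9),
    "left_heart": (1600.0, 0.0, 0.0, 1.0, 0.9),
    "aorta": (1600.0, 0.0, 0.0, 1.0, 0.9),
    "portal_vein": (1600.0, 0.0, 0.0, 0.6, 0.9),
}


@dataclass
class DCEPhantomConfig:
    """Settings for the synthetic DCE abdominal series."""

    nx: int = 64
    ny: int = 64
    nt: int = 50
    frame_interval_s: float = 3.0
    flip_angle_deg: float = 10.0
    tr_ms: float = 2.3
    r1: float = 4.5  # contrast relaxivity, 1/s/mM
    bolus_arrival_s: float = 15.0
    # fraction of the full pharmacokinetic signal change retained; the
    # default reproduces the strongly background-dominated energy budget
    # of the reference abdominal series (dynamic energy ~1e-4 of total,
    # i.e. sigma_2 of the Casorati matrix ~1% of sigma_1)
    enhancement_scale: float = 0.04
    tissues: dict = field(default_factory=lambda: {k: v for k, v in _DEFAULT_TISSUES.items()})
    # optional periodic respiratory motion of the underlying anatomy
    respiratory_amplitude_px: float = 0.0
    respiratory_period_frames: float = 5.0
    noise_sigma: float = 0.0
    smoothing_px: float = 0.8

    def __post_init__(self) -> None:
        for name, (t1, kt, kep, vp, m0) in self.tissues.items():
            if min(t1, kt, kep, vp) < 0:
                raise ValueError(f"negative tissue parameter for {name!r}")
            if vp > 1:
                raise ValueError(f"vp > 1 for {name!r}")
        if self.nt < 1 or self.frame_interval_s <= 0:
            raise ValueError("invalid temporal settings")


@dataclass
class BowelPhantomConfig:
    """Settings for the synthetic small-bowel series.

    The series is n_bh breath-hold frames (respiratory amplitude zero)
    followed by n_fb free-breathing frames with a single-frequency
    sinusoidal respiratory deformation; sparse motility events occur
    throughout.
    """

    nx: int = 64
    ny: int = 64
    n_bh: int = 20
    n_fb: int = 60
    respiratory_period_frames: float = 5.0
    respiratory_amplitude_px: float = 1.0
    motility_rate_per_frame: float = 0.15
    motility_amplitude_px: float = 2.0
    motility_extent_px: float = 3.0
    motility_duration_frames: tuple = (3, 6)
    noise_sigma: float = 0.001
    smoothing_px: float = 3.0

    def __post_init__(self) -> None:
        if self.respiratory_amplitude_px < 0 or self.motility_amplitude_px < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_bh < 0 or self.n_fb < 0 or self.n_bh + self.n_fb < 1:
            raise ValueError("invalid segment lengths")

    @property
    def nt(self) -> int:
        return self.n_bh + self.n_fb


@dataclass
class PhantomGroundTruth:
    """Ground truth accompanying a generated phantom."""

    label_map: np.ndarray
    kinetic_maps: dict | None  # name -> (Nx, Ny) map (DCE only)
    deformation_fields: np.ndarray  # (2, Nx, Ny, Nt): (dx, dy) per frame
    sparse_support: np.ndarray  # boolean (Nx, Ny)
    bh_frames: int = 0


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _ellipse(nx: int, ny: int, cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    """Boolean ellipse mask; all coordinates in grid-normalized units."""
    rr = (np.arange(nx)[:, None] / nx - cr) / ar
    cc_ = (np.arange(ny)[None, :] / ny - cc) / ac
    return rr**2 + cc_**2 <= 1.0


def _dce_label_map(nx: int, ny: int) -> np.ndarray:
    lab = np.zeros((nx, ny), dtype=np.int8)
    L = DCE_LABELS
    lab[_ellipse(nx, ny, 0.52, 0.5, 0.45, 0.42)] = L["body"]
    lab[_ellipse(nx, ny, 0.34, 0.30, 0.15, 0.14)] = L["liver"]
    lab[_ellipse(nx, ny, 0.68, 0.52, 0.17, 0.22)] = L["bowel"]
    lab[_ellipse(nx, ny, 0.14, 0.44, 0.065, 0.05)] = L["right_heart"]
    lab[_ellipse(nx, ny, 0.14, 0.57, 0.065, 0.05)] = L["left_heart"]
    rows = np.arange(nx)[:, None] / nx
    cols = np.arange(ny)[None, :] / ny
    aorta = (np.abs(cols - 0.52) < 0.018) & (rows > 0.24) & (rows < 0.75)
    lab[aorta & (lab > 0)] = L["aorta"]
    lab[_ellipse(nx, ny, 0.40, 0.40, 0.035, 0.035)] = L["portal_vein"]
    return lab


def _bowel_anatomy(nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth bowel-loop anatomy: bright loop walls, darker lumen."""
    img = np.zeros((nx, ny), dtype=float)
    img[_ellipse(nx, ny, 0.5, 0.5, 0.46, 0.43)] = 0.45  # body
    img[_ellipse(nx, ny, 0.28, 0.28, 0.14, 0.13)] = 0.7  # liver-like blob
    loops = [
        (0.42, 0.55, 0.11, 0.13),
        (0.62, 0.38, 0.12, 0.11),
        (0.66, 0.62, 0.10, 0.12),
        (0.48, 0.36, 0.08, 0.08),
    ]
    for cr, cc, ar, ac in loops:
        outer = _ellipse(nx, ny, cr, cc, ar, ac)
        inner = _ellipse(nx, ny, cr, cc, 0.55 * ar, 0.55 * ac)
        img[outer] = 1.0  # wall
        img[inner] = 0.25  # lumen
    texture = gaussian_filter(rng.standard_normal((nx, ny)), 3.0)
    texture = 1.0 + 0.08 * texture / max(texture.std(), 1e-12)
    return img * texture


def _bowel_region_mask(nx: int, ny: int) -> np.ndarray:
    m = np.zeros((nx, ny), dtype=bool)
    for cr, cc, ar, ac in [
        (0.42, 0.55, 0.11, 0.13),
        (0.62, 0.38, 0.12, 0.11),
        (0.66, 0.62, 0.10, 0.12),
        (0.48, 0.36, 0.08, 0.08),
    ]:
        m |= _ellipse(nx, ny, cr, cc, ar, ac)
    return m


def warp_frame(frame: np.ndarray, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Pull-back warp: output(r, c) = frame(r - dy, c - dx), bilinear,
    edge-clamped. Works on real or complex frames."""
    nx, ny = frame.shape
    rows, cols = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.array([rows - dy, cols - dx])
    if np.iscomplexobj(frame):
        re = map_coordinates(frame.real, coords, order=1, mode="nearest")
        im = map_coordinates(frame.imag, coords, order=1, mode="nearest")
        return re + 1j * im
    return map_coordinates(frame, coords, order=1, mode="nearest")


def _static_phase(nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
    """Gentle smooth static phase map (field inhomogeneity stand-in)."""
    u = np.arange(nx)[:, None] / nx
    v = np.arange(ny)[None, :] / ny
    a, b, c = rng.uniform(-0.5, 0.5, size=3)
    return np.exp(1j * (a * u + b * v + c * u * v))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_dce_phantom(
    config: DCEPhantomConfig | None = None, seed: int = 0
) -> tuple[DynamicImage, PhantomGroundTruth]:
    """Generate the DCE abdominal phantom and its ground truth.

    Static anatomy with per-organ extended-Tofts enhancement; the
    ground-truth sparse support is the set of voxels that any enhancing
    organ can influence (enhancing labels dilated by the anatomical
    smoothing kernel).
    """
    cfg = config or DCEPhantomConfig()
    rng = np.random.default_rng(seed)
    nx, ny, nt = cfg.nx, cfg.ny, cfg.nt

    t_min = (np.arange(nt) * cfg.frame_interval_s - cfg.bolus_arrival_s) / 60.0
    cp = population_aif(t_min)

    label_map = _dce_label_map(nx, ny)
    names = list(DCE_LABELS)
    curves = np.zeros((len(names), nt))
    kin_maps = {k: np.zeros((nx, ny)) for k in ("ktrans", "kep", "vp", "t1")}
    enhancing = np.zeros((nx, ny), dtype=bool)
    for name in names:
        idx = DCE_LABELS[name]
        t1, kt, kep, vp, m0 = cfg.tissues[name]
        ct = extended_tofts(kt, kep, vp, cp, t_min)
        full = concentration_to_signal(ct, t1, cfg.r1, cfg.flip_angle_deg, cfg.tr_ms, m0)
        base = concentration_to_signal(
            np.zeros(1), t1, cfg.r1, cfg.flip_angle_deg, cfg.tr_ms, m0
        )[0]
        curves[idx] = base + cfg.enhancement_scale * (full - base)
        region = label_map == idx
        kin_maps["ktrans"][region] = kt
        kin_maps["kep"][region] = kep
        kin_maps["vp"][region] = vp
        kin_maps["t1"][region] = t1
        if kt > 0 or vp > 0:
            enhancing |= region

    texture = gaussian_filter(rng.standard_normal((nx, ny)), 2.5)
    texture = 1.0 + 0.1 * texture / max(texture.std(), 1e-12)
    phase = _static_phase(nx, ny, rng)

    frames = curves[label_map]  # (Nx, Ny, Nt)
    frames = frames * texture[:, :, None]
    if cfg.smoothing_px > 0:
        frames = gaussian_filter(frames, (cfg.smoothing_px, cfg.smoothing_px, 0))
        support = gaussian_filter(enhancing.astype(float), cfg.smoothing_px) > 1e-6
    else:
        support = enhancing
    series = frames * phase[:, :, None]

    fields = np.zeros((2, nx, ny, nt))
    if cfg.respiratory_amplitude_px > 0:
        u = np.arange(nx)[:, None] / nx
        profile = (0.6 + 0.4 * (1.0 - u)) * np.ones((1, ny))
        for t in range(nt):
            a = cfg.respiratory_amplitude_px * np.sin(
                2 * np.pi * t / cfg.respiratory_period_frames
            )
            fields[1, :, :, t] = a * profile
            fields[0, :, :, t] = 0.3 * a * profile
            series[:, :, t] = warp_frame(series[:, :, t], fields[0, :, :, t], fields[1, :, :, t])

    if cfg.noise_sigma > 0:
        noise = rng.normal(scale=cfg.noise_sigma, size=(nx, ny, nt, 2))
        series = series + noise[..., 0] + 1j * noise[..., 1]

    image = DynamicImage(series.astype(np.complex128), cfg.frame_interval_s)
    gt = PhantomGroundTruth(
        label_map=label_map,
        kinetic_maps=kin_maps,
        deformation_fields=fields,
        sparse_support=support,
        bh_frames=0,
    )
    return image, gt


def generate_bowel_phantom(
    config: BowelPhantomConfig | None = None, seed: int = 0
) -> tuple[DynamicImage, PhantomGroundTruth]:
    """Generate the small-bowel phantom and its ground truth.

    The breath-hold segment has zero respiratory amplitude; the
    free-breathing segment is deformed by one sinusoidal respiratory
    mode. Motility events are seeded, local, aperiodic Gaussian-bump
    displacements inside the bowel region; the ground-truth sparse
    support is the set of voxels whose noiseless intensity is changed by
    the motility events at any time.
    """
    cfg = config or BowelPhantomConfig()
    rng = np.random.default_rng(seed)
    nx, ny, nt = cfg.nx, cfg.ny, cfg.nt

    anatomy = _bowel_anatomy(nx, ny, rng)
    if cfg.smoothing_px > 0:
        anatomy = gaussian_filter(anatomy, cfg.smoothing_px)
    phase = _static_phase(nx, ny, rng)
    bowel_mask = _bowel_region_mask(nx, ny)
    bowel_idx = np.argwhere(bowel_mask)

    # --- respiratory component (single temporal frequency)
    u = np.arange(nx)[:, None] / nx
    resp_profile = (0.25 + 0.75 * (1.0 - u)) * np.ones((1, ny))
    resp_dy = np.zeros(nt)
    for t in range(cfg.n_bh, nt):
        resp_dy[t] = cfg.respiratory_amplitude_px * np.sin(
            2 * np.pi * (t - cfg.n_bh) / cfg.respiratory_period_frames
        )

    # --- motility events
    n_events = rng.poisson(cfg.motility_rate_per_frame * nt)
    events = []
    rows, cols = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for _ in range(n_events):
        cx_r, cx_c = bowel_idx[rng.integers(len(bowel_idx))]
        start = int(rng.integers(0, nt))
        dur = int(rng.integers(cfg.motility_duration_frames[0], cfg.motility_duration_frames[1] + 1))
        theta = rng.uniform(0, 2 * np.pi)
        amp = cfg.motility_amplitude_px * rng.uniform(0.6, 1.0)
        bump = np.exp(
            -((rows - cx_r) ** 2 + (cols - cx_c) ** 2) / (2 * cfg.motility_extent_px**2)
        )
        env = np.sin(np.pi * (np.arange(dur) + 0.5) / dur)  # smooth on/off
        events.append((start, dur, env, amp, theta, bump))

    fields = np.zeros((2, nx, ny, nt))
    fields_resp = np.zeros((2, nx, ny, nt))
    for t in range(nt):
        fields_resp[1, :, :, t] = resp_dy[t] * resp_profile
        fields_resp[0, :, :, t] = 0.25 * resp_dy[t] * resp_profile
    fields[:] = fields_resp
    for start, dur, env, amp, theta, bump in events:
        for k in range(dur):
            t = start + k
            if t >= nt:
                break
            d = amp * env[k] * bump
            fields[0, :, :, t] += d * np.cos(theta)
            fields[1, :, :, t] += d * np.sin(theta)

    series = np.empty((nx, ny, nt), dtype=np.complex128)
    resp_only = np.empty((nx, ny, nt), dtype=float)
    base = anatomy * phase
    for t in range(nt):
        series[:, :, t] = warp_frame(base, fields[0, :, :, t], fields[1, :, :, t])
        resp_only[:, :, t] = warp_frame(anatomy, fields_resp[0, :, :, t], fields_resp[1, :, :, t])

    # motility support: voxels whose noiseless intensity differs from the
    # respiration-only series at any time
    diff = np.abs(np.abs(series) - resp_only)
    support = (diff > 1e-3 * anatomy.max()).any(axis=2)

    if cfg.noise_sigma > 0:
        noise = rng.normal(scale=cfg.noise_sigma, size=(nx, ny, nt, 2))
        series = series + noise[..., 0] + 1j * noise[..., 1]

    image = DynamicImage(series, frame_interval=1.0)
    gt = PhantomGroundTruth(
        label_map=bowel_mask.astype(np.int8),
        kinetic_maps=None,
        deformation_fields=fields,
        sparse_support=support,
        bh_frames=cfg.n_bh,
    )
    return image, gt
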