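"""Estimation of T2, B1, B0, T2*, T1 and PD maps from the simulated series.

The chain follows the classical relaxometry recipe: repeats are averaged,
T2 comes from a voxel-wise exponential fit over the echo train, B1 from the
cosine of the measured preparation angle, B0 from the phase difference of a
dual-TE pair, T2* from a two-point log ratio, T1 from the two-point
variable-flip-angle line (slope exp(-TR/T1), flip angles scaled by B1), and
PD from the low-angle VFA image after compensating T2*, T1 and flip-angle
weighting, removing the receive-coil profile, and calibrating the CSF
reference to 100 percent units.

Invalid voxels (background, noise floor, non-physical ratios) carry NaN plus
an explicit boolean validity mask, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquire import EchoSeries

__all__ = [
    "FittedMap",
    "QuantitativeMaps",
    "average_repeats",
    "fit_t2",
    "fit_b1",
    "fit_b0",
    "fit_t2star",
    "fit_t1_vfa",
    "fit_pd",
]


@dataclass
class FittedMap:
    """A fitted parameter volume: data (NaN where invalid), mask, units."""

    data: np.ndarray
    valid: np.ndarray
    units: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape != self.valid.shape:
            raise ValueError("data and validity mask must share a grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def masked_mean(self, mask: np.ndarray) -> float:
        sel = mask & self.valid
        if not np.any(sel):
            raise ValueError("no valid voxels under the requested mask")
        return float(np.mean(self.data[sel]))


@dataclass
class QuantitativeMaps:
    """The full set of fitted maps plus a processing provenance log."""

    t1: FittedMap
    t2: FittedMap
    t2star: FittedMap
    pd: FittedMap
    b1: FittedMap
    b0: FittedMap
    provenance: dict = field(default_factory=dict)

    def parameter(self, name: str) -> FittedMap:
        return {"t1": self.t1, "t2": self.t2, "pd": self.pd, "t2star": self.t2star}[name]


def average_repeats(series: EchoSeries) -> EchoSeries:
    """Average volumes acquired with identical TE (and flip angle) over repeats."""
    keys: list[tuple[float, float]] = []
    for i in range(len(series.volumes)):
        flip = series.flip_per_volume[i] if series.flip_per_volume else 0.0
        key = (series.te_per_volume[i], flip)
        if key not in keys:
            keys.append(key)
    volumes, tes, flips = [], [], []
    for te, flip in keys:
        group = [
            series.volumes[i]
            for i in range(len(series.volumes))
            if series.te_per_volume[i] == te
            and (series.flip_per_volume[i] if series.flip_per_volume else 0.0) == flip
        ]
        volumes.append(np.mean(group, axis=0))
        tes.append(te)
        flips.append(flip)
    out = series.copy()
    out.volumes = volumes
    out.te_per_volume = tes
    out.repeat_per_volume = [0] * len(volumes)
    out.flip_per_volume = flips if series.flip_per_volume else []
    out.noise_sigma = series.noise_sigma / np.sqrt(
        max(len(series.volumes) // max(len(volumes), 1), 1)
    )
    return out


def _noise_floor(series: EchoSeries, noise_floor_sigma: float) -> float:
    return noise_floor_sigma * series.noise_sigma


def fit_t2(
    series: EchoSeries,
    noise_floor_sigma: float = 3.0,
    max_iter: int = 30,
    stimulated_echo_correction: bool = False,
    b1_map: np.ndarray | None = None,
    t1_map: np.ndarray | None = None,
) -> FittedMap:
    """Voxel-wise exponential T2 fit over an averaged multi-echo SE series.

    Nonlinear least squares of ``S = A * exp(-TE/T2)`` initialized from the
    log-linear solution; two echoes reduce exactly to the closed-form
    two-point solution.  Voxels whose first-echo signal is below
    ``noise_floor_sigma * sigma`` (or non-positive anywhere) are masked.

    With ``stimulated_echo_correction`` the simulator's EPG stimulated-echo
    factor is inverted before fitting (needs ``b1_map``; ``t1_map`` defaults
    to a WM-like 900 ms); the factor itself depends on T2, so one
    uncorrected pre-fit supplies the T2 estimate.
    """
    tes = np.asarray(series.te_per_volume, dtype=np.float64)
    if len(tes) < 2:
        raise ValueError("T2 fitting needs at least two echoes")
    if np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be strictly increasing; average repeats first")
    shape = series.shape
    signals = np.stack([v.reshape(-1) for v in series.volumes], axis=0)

    if stimulated_echo_correction:
        pre = fit_t2(series, noise_floor_sigma=noise_floor_sigma, max_iter=max_iter)
        signals = _invert_stimulated_echoes(series, signals, pre, b1_map, t1_map)

    floor = _noise_floor(series, noise_floor_sigma)
    valid = np.all(signals > 0, axis=0) & (signals[0] > floor)
    if not np.any(valid):
        raise ValueError("all voxels fall below the noise floor; nothing to fit")

    s = signals[:, valid]
    logs = np.log(s)
    # log-linear init: log S = log A - TE * R2
    g = np.stack([np.ones_like(tes), -tes], axis=1)
    coef, *_ = np.linalg.lstsq(g, logs, rcond=None)
    log_a, r2 = coef
    a = np.exp(log_a)
    r2 = np.clip(r2, 1e-6, 1.0)

    for _ in range(max_iter):
        e = np.exp(-tes[:, None] * r2[None, :])
        model = a[None, :] * e
        resid = model - s
        ja = e
        jr = -a[None, :] * tes[:, None] * e
        # 2x2 normal equations, solved in closed form per voxel
        jaa = np.sum(ja * ja, axis=0)
        jar = np.sum(ja * jr, axis=0)
        jrr = np.sum(jr * jr, axis=0)
        ga = np.sum(ja * resid, axis=0)
        gr = np.sum(jr * resid, axis=0)
        det = jaa * jrr - jar * jar
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (jrr * ga - jar * gr) / det
        dr = (jaa * gr - jar * ga) / det
        a_new = a - da
        dr = np.clip(dr, -0.5 * r2, 0.5 * r2)  # damp R2 steps to stay positive
        r2_new = r2 - dr
        ok = np.isfinite(a_new) & np.isfinite(r2_new) & (a_new > 0) & (r2_new > 0)
        a = np.where(ok, a_new, a)
        r2 = np.where(ok, r2_new, r2)

    t2 = 1.0 / r2
    e = np.exp(-tes[:, None] * r2[None, :])
    rss = np.sum((a[None, :] * e - s) ** 2, axis=0)
    converged = np.isfinite(t2) & (t2 > 1.0) & (t2 < 1e4)

    data = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    quality = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(valid)
    data.reshape(-1)[idx] = np.where(converged, t2, np.nan)
    amp.reshape(-1)[idx] = np.where(converged, a, np.nan)
    quality.reshape(-1)[idx] = np.where(converged, np.sqrt(rss / len(tes)), np.nan)
    mask.reshape(-1)[idx] = converged
    return FittedMap(data=data, valid=mask, units="ms", extras={"amplitude": amp, "rms_residual": quality})


def _invert_stimulated_echoes(
    series: EchoSeries,
    signals: np.ndarray,
    pre: FittedMap,
    b1_map: np.ndarray | None,
    t1_map: np.ndarray | None,
) -> np.ndarray:
    from .epg import stimulated_echo_factors

    if b1_map is None:
        raise ValueError("stimulated-echo correction requires a B1 map")
    protocol = series.protocol
    esp = protocol.echo_spacing or series.te_per_volume[0]
    n_train = max(int(round(max(series.te_per_volume) / esp)), 1)
    t2_est = np.where(pre.valid, pre.data, 80.0).reshape(-1)
    t1_est = (t1_map.reshape(-1) if t1_map is not None else np.full(t2_est.shape, 900.0))
    factors = stimulated_echo_factors(
        t1_est, t2_est, esp, n_train, protocol.refocus_angle * b1_map.reshape(-1)
    )
    corrected = signals.copy()
    for i, te in enumerate(series.te_per_volume):
        k = int(np.clip(round(te / esp) - 1, 0, n_train - 1))
        f = factors[k]
        corrected[i] = np.where(f > 0, signals[i] / np.where(f > 0, f, 1.0), signals[i])
    return corrected


def _nearest_fill(data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid voxels by their nearest valid neighbor (for interpolation)."""
    if np.all(valid):
        return data
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return data[tuple(idx)]


def _upsample(data: np.ndarray, valid: np.ndarray, target_shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear upsampling of a (low-resolution) calibration map."""
    if tuple(data.shape) == tuple(target_shape):
        return data, valid
    filled = _nearest_fill(np.where(valid, data, 0.0), valid)
    zoom = [t / s for t, s in zip(target_shape, data.shape)]
    up = ndimage.zoom(filled, zoom, order=1, mode="nearest", grid_mode=True)
    vup = ndimage.zoom(valid.astype(np.float64), zoom, order=1, mode="nearest", grid_mode=True) > 0.25
    if up.shape != tuple(target_shape):  # guard rounding
        raise ValueError(f"upsampling produced {up.shape}, expected {target_shape}")
    return up, vup


def fit_b1(
    ref: np.ndarray,
    prep: np.ndarray,
    beta0_deg: float,
    target_shape: tuple[int, ...] | None = None,
) -> FittedMap:
    """B1 map from the prepared/reference ratio: B1 = arccos(I_prep/I_ref)/beta_0.

    Ratios outside [-1, 1] (noise-driven) are clipped and counted; voxels with
    no reference signal or a degenerate ratio (>= 1, i.e. preparation angle 0)
    are masked.  If ``target_shape`` is given the low-resolution map is
    upsampled trilinearly.
    """
    if ref.shape != prep.shape:
        raise ValueError("reference and prepared volumes must share a grid")
    if not 0.0 < beta0_deg < 180.0:
        raise ValueError("nominal preparation angle must be in (0, 180) degrees")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref > 0, prep / np.where(ref > 0, ref, 1.0), np.nan)
    n_clipped = int(np.sum((ratio < -1.0) | (ratio > 1.0)))
    clipped = np.clip(ratio, -1.0, 1.0)
    beta = np.arccos(clipped)
    b1 = beta / np.deg2rad(beta0_deg)
    valid = (ref > 0) & np.isfinite(ratio) & (ratio < 1.0 - 1e-12)
    b1 = np.where(valid, b1, np.nan)
    if target_shape is not None:
        b1, valid = _upsample(b1, valid, target_shape)
        b1 = np.where(valid, b1, np.nan)
    return FittedMap(data=b1, valid=valid, units="relative", extras={"n_clipped": n_clipped})


def fit_b0(series: EchoSeries, target_shape: tuple[int, ...] | None = None) -> FittedMap:
    """Off-resonance map from the wrapped phase difference of a dual-TE pair.

    ``delta_f = wrap(phi_2 - phi_1) / (2 pi * delta_TE)`` with wrapping to
    (-pi, pi]; voxels near the wrap boundary are counted in the extras.
    """
    if series.phase_volumes is None or len(series.phase_volumes) != 2:
        raise ValueError("B0 fitting needs a series with two phase volumes")
    te = series.te_per_volume
    dte_s = (te[1] - te[0]) / 1000.0
    if dte_s <= 0:
        raise ValueError("echo times must be increasing")
    raw = series.phase_volumes[1] - series.phase_volumes[0]
    dphi = np.angle(np.exp(1j * raw))
    b0 = dphi / (2.0 * np.pi * dte_s)
    valid = (series.volumes[0] > 0) & (series.volumes[1] > 0)
    n_boundary = int(np.sum(valid & (np.abs(dphi) > np.pi - 0.05)))
    b0 = np.where(valid, b0, np.nan)
    if target_shape is not None:
        b0, valid = _upsample(b0, valid, target_shape)
        b0 = np.where(valid, b0, np.nan)
    return FittedMap(data=b0, valid=valid, units="Hz", extras={"n_wrap_boundary": n_boundary})


def fit_t2star(series: EchoSeries, noise_floor_sigma: float = 3.0) -> FittedMap:
    """Two-point T2* from a dual-echo GE pair: (TE2-TE1)/ln(S1/S2).

    Non-physical voxels (S2 >= S1, or signal at/below the noise floor) are
    masked rather than reported.
    """
    if len(series.volumes) != 2:
        raise ValueError("T2* estimation needs exactly two echoes")
    te = series.te_per_volume
    dte = te[1] - te[0]
    if dte <= 0:
        raise ValueError("echo times must be increasing")
    s1, s2 = series.volumes
    floor = _noise_floor(series, noise_floor_sigma)
    valid = (s1 > max(floor, 0.0)) & (s2 > 0) & (s2 < s1)
    t2star = np.full(series.shape, np.nan)
    t2star[valid] = dte / np.log(s1[valid] / s2[valid])
    return FittedMap(data=t2star, valid=valid, units="ms")


def fit_t1_vfa(
    series: EchoSeries,
    b1: FittedMap | np.ndarray,
    b0: FittedMap | np.ndarray | None = None,
    b0_correction=None,
    noise_floor_sigma: float = 3.0,
) -> FittedMap:
    """Variable-flip-angle T1 from the two-point I/sin vs I/tan line.

    With effective angles ``alpha_i' = B1 * alpha_i``, the points
    ``(I_i/tan(alpha_i'), I_i/sin(alpha_i'))`` lie on a line of slope
    ``exp(-TR/T1)``; slopes outside (0, 1) and degenerate abscissae are
    masked.  ``b0_correction(t1_ms, b0_hz) -> t1_ms`` is an optional hook
    applied after inversion (identity when absent: no off-resonance model is
    assumed by default).
    """
    if len(series.volumes) != 2 or len(series.flip_per_volume) != 2:
        raise ValueError("VFA T1 fitting needs exactly two flip-angle volumes")
    b1_data = b1.data if isinstance(b1, FittedMap) else np.asarray(b1, dtype=np.float64)
    b1_valid = b1.valid if isinstance(b1, FittedMap) else np.isfinite(b1_data)
    if b1_data.shape != series.shape:
        raise ValueError("B1 map must be on the series grid (upsample first)")
    tr = series.protocol.tr
    i1, i2 = series.volumes
    a1 = np.deg2rad(series.flip_per_volume[0]) * b1_data
    a2 = np.deg2rad(series.flip_per_volume[1]) * b1_data
    floor = _noise_floor(series, noise_floor_sigma)
    valid = (i1 > max(floor, 0.0)) & (i2 > max(floor, 0.0)) & b1_valid & (b1_data > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        x1 = i1 / np.tan(a1)
        x2 = i2 / np.tan(a2)
        y1 = i1 / np.sin(a1)
        y2 = i2 / np.sin(a2)
        dx = x2 - x1
        slope = np.where(np.abs(dx) > 0, (y2 - y1) / np.where(dx != 0, dx, 1.0), np.nan)
    valid &= np.isfinite(slope) & (slope > 0.0) & (slope < 1.0) & (np.abs(dx) > 0)
    t1 = np.full(series.shape, np.nan)
    t1[valid] = -tr / np.log(slope[valid])
    # equilibrium-amplitude map from the line's intercept: y = m x + A (1 - m)
    amp = np.full(series.shape, np.nan)
    amp[valid] = (y1[valid] - slope[valid] * x1[valid]) / (1.0 - slope[valid])
    if b0_correction is not None:
        b0_data = b0.data if isinstance(b0, FittedMap) else b0
        t1 = np.where(valid, b0_correction(t1, b0_data), t1)
    return FittedMap(data=t1, valid=valid, units="ms", extras={"amplitude": amp})


def _t1_classes(t1_values: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """1D Lloyd clustering of T1 into k tissue-like classes.

    Clustering runs on the longitudinal rate R1 = 1/T1: the noise of a fitted
    T1 explodes for long-T1 (CSF-like) voxels where the VFA slope approaches
    one, while R1 noise stays comparable across tissues, so rate-domain
    clusters remain separable.  Farthest-point initialization on
    percentile-trimmed rates keeps well-separated clusters distinct even when
    their populations are very unbalanced.
    """
    r1 = 1.0 / np.maximum(t1_values, 1.0)
    lo, hi = np.percentile(r1, [0.5, 99.5])
    trimmed = np.clip(r1, lo, hi)
    centers = [float(trimmed.min())]
    for _ in range(k - 1):
        dist = np.min(np.abs(trimmed[:, None] - np.array(centers)[None, :]), axis=1)
        centers.append(float(trimmed[np.argmax(dist)]))
    centers = np.sort(np.array(centers))
    centers = np.unique(centers)
    t1_values = trimmed
    for _ in range(max_iter):
        edges = (centers[:-1] + centers[1:]) / 2.0
        labels = np.digitize(t1_values, edges)
        new = np.array(
            [t1_values[labels == i].mean() if np.any(labels == i) else centers[i] for i in range(len(centers))]
        )
        if np.allclose(new, centers, rtol=0, atol=1e-9):
            centers = new
            break
        centers = new
    edges = (centers[:-1] + centers[1:]) / 2.0
    return np.digitize(t1_values, edges)


def _polynomial_basis(shape: tuple[int, ...], order: int = 2) -> np.ndarray:
    coords = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij")
    x, y, z = [c.reshape(-1) for c in coords]
    cols = [np.ones_like(x)]
    if order >= 1:
        cols += [x, y, z]
    if order >= 2:
        cols += [x * x, y * y, z * z, x * y, x * z, y * z]
    if order >= 3:
        cols += [x**3, y**3, z**3, x * x * y, x * x * z, y * y * x, y * y * z, z * z * x, z * z * y, x * y * z]
    return np.stack(cols, axis=1)


def _rx_als(
    m: np.ndarray,
    classes: np.ndarray,
    basis: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> np.ndarray:
    """Alternating least squares for M = level_class * smooth_field.

    The receive field is modeled as a low-order spatial polynomial (in the
    linear intensity domain) and the tissue model as one level per T1-derived
    class; the two factors are alternately refit until the field stabilizes.
    """
    n_classes = classes.max() + 1
    pinv = np.linalg.pinv(basis)
    field = np.ones_like(m)
    prev = field
    for _ in range(max_iter):
        sums = np.bincount(classes, weights=m * field, minlength=n_classes)
        norms = np.bincount(classes, weights=field * field, minlength=n_classes)
        levels = np.where(norms > 0, sums / np.where(norms > 0, norms, 1.0), 1.0)
        target = m / levels[classes]
        coef = pinv @ target
        field = basis @ coef
        field = field / np.mean(field)
        if np.max(np.abs(field - prev)) < tol * max(np.max(np.abs(field)), 1.0):
            break
        prev = field
    return field


def fit_pd(
    vfa_series: EchoSeries,
    t1: FittedMap,
    b1: FittedMap,
    t2star: FittedMap,
    csf_mask: np.ndarray,
    rx_method: str = "als",
    rx_sigma_mm: float = 16.0,
    n_t1_classes: int = 4,
    poly_order: int = 2,
    noise_floor_sigma: float = 3.0,
) -> FittedMap:
    """Proton-density map from the PD-weighted (low-angle) VFA image.

    The compensation chain removes T2* decay, T1 saturation and flip-angle
    weighting::

        M = I_1 * exp(TE/T2*) * (1 - E1 cos(B1 a1)) / (sin(B1 a1) (1 - E1))

    leaving ``M = rx * PD``.  The receive profile is then estimated and
    divided out, and the result is calibrated so the CSF reference mean is
    exactly 100 p.u.  Two receive-profile estimators are available:

    - ``"als"`` (default): joint multiplicative model, low-order polynomial
      field times per-tissue-class level (classes derived from the T1 map),
      solved by alternating least squares;
    - ``"smooth"``: heavily Gaussian-smoothed (sigma ``rx_sigma_mm``) ratio of
      M to a per-class tissue-model prediction.
    """
    if len(vfa_series.volumes) != 2 or len(vfa_series.flip_per_volume) != 2:
        raise ValueError("PD estimation needs the two-angle VFA series")
    shape = vfa_series.shape
    for m, name in ((t1, "t1"), (b1, "b1"), (t2star, "t2star")):
        if m.shape != shape:
            raise ValueError(f"{name} map grid does not match the VFA series")
    if csf_mask.shape != shape:
        raise ValueError("csf_mask grid does not match the VFA series")

    low = int(np.argmin(vfa_series.flip_per_volume))
    i1 = vfa_series.volumes[low]
    alpha1 = np.deg2rad(vfa_series.flip_per_volume[low]) * b1.data
    te = vfa_series.te_per_volume[low]
    tr = vfa_series.protocol.tr

    floor = _noise_floor(vfa_series, noise_floor_sigma)
    valid = (
        (i1 > max(floor, 0.0))
        & t1.valid
        & b1.valid
        & t2star.valid
        & (t1.data > 0)
        & (t2star.data > 0)
    )
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        e1 = np.exp(-tr / t1.data)
        m = i1 * np.exp(te / t2star.data) * (1.0 - e1 * np.cos(alpha1)) / (np.sin(alpha1) * (1.0 - e1))
    valid &= np.isfinite(m) & (m > 0)
    if not np.any(valid & csf_mask):
        raise ValueError("no valid CSF reference voxels: cannot calibrate PD")

    mv = m[valid]
    classes = _t1_classes(t1.data[valid], k=n_t1_classes)
    if rx_method == "als":
        basis = _polynomial_basis(shape, order=poly_order)[valid.reshape(-1)]
        rx_est_v = _rx_als(mv, classes, basis)
    elif rx_method == "smooth":
        n_classes = classes.max() + 1
        log_means = np.array(
            [np.log(mv[classes == i]).mean() if np.any(classes == i) else 0.0 for i in range(n_classes)]
        )
        model = np.exp(log_means)[classes]
        ratio = np.zeros(shape)
        ratio[valid] = mv / model
        voxel = (
            np.asarray(vfa_series.voxel_size_mm, dtype=np.float64)
            if vfa_series.voxel_size_mm is not None
            else np.ones(3)
        )
        sigma_vox = rx_sigma_mm / voxel
        num = ndimage.gaussian_filter(ratio * valid, sigma=sigma_vox)
        den = ndimage.gaussian_filter(valid.astype(np.float64), sigma=sigma_vox)
        rx_full = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0), 1.0)
        rx_est_v = rx_full[valid]
    else:
        raise ValueError(f"unknown rx_method {rx_method!r}")

    pd_raw = np.full(shape, np.nan)
    pd_raw[valid] = mv / rx_est_v
    csf_ref = valid & csf_mask
    scale = 100.0 / np.mean(pd_raw[csf_ref])
    pd = pd_raw * scale
    rx_estimate = np.full(shape, np.nan)
    rx_estimate[valid] = rx_est_v
    return FittedMap(
        data=np.where(valid, pd, np.nan),
        valid=valid,
        units="p.u.",
        extras={"rx_estimate": rx_estimate, "csf_scale": float(scale), "rx_method": rx_method},
    )
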