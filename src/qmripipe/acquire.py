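"""Voxel-wise forward simulation of the five quantitative-MRI acquisitions.

Each simulator evaluates the sequence's steady-state signal equation per
voxel on a :class:`~qmripipe.phantom.TissuePhantom`; there is no k-space or
readout-train simulation, since the fitting chain consumes magnitude images
only.  Noise is Rician (complex Gaussian on quadrature channels before the
magnitude operation), matching magnitude MR images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phantom import TissuePhantom
from .protocols import AcquisitionProtocol, default_protocol

__all__ = [
    "EchoSeries",
    "simulate_multiecho_se",
    "simulate_vfa",
    "simulate_b1_pair",
    "simulate_b0_pair",
    "simulate_dualecho_ge",
    "add_noise",
    "spgr_signal",
]


@dataclass
class EchoSeries:
    """A simulated acquisition: magnitude volumes plus protocol metadata.

    ``volumes[i]`` corresponds to echo time ``te_per_volume[i]`` and repeat
    ``repeat_per_volume[i]``; for the VFA pair the per-volume flip angle is in
    ``flip_per_volume``.  ``phase_volumes`` (radians) are present for the B0
    pair only.
    """

    volumes: list[np.ndarray]
    protocol: AcquisitionProtocol
    te_per_volume: list[float]
    repeat_per_volume: list[int] = field(default_factory=list)
    flip_per_volume: list[float] = field(default_factory=list)
    phase_volumes: list[np.ndarray] | None = None
    noise_sigma: float = 0.0
    voxel_size_mm: np.ndarray | None = None
    grid_scale: int = 1  # coarsening factor relative to the phantom grid

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("EchoSeries needs at least one volume")
        shape = self.volumes[0].shape
        for v in self.volumes:
            if v.shape != shape:
                raise ValueError("all volumes must share one grid")
        if len(self.te_per_volume) != len(self.volumes):
            raise ValueError("te_per_volume must match volumes")
        if not self.repeat_per_volume:
            self.repeat_per_volume = [0] * len(self.volumes)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape

    def copy(self) -> "EchoSeries":
        return replace(
            self,
            volumes=[v.copy() for v in self.volumes],
            phase_volumes=None if self.phase_volumes is None else [p.copy() for p in self.phase_volumes],
            te_per_volume=list(self.te_per_volume),
            repeat_per_volume=list(self.repeat_per_volume),
            flip_per_volume=list(self.flip_per_volume),
        )


def _decay(pd_weighted: np.ndarray, relax_ms: np.ndarray, te_ms: float) -> np.ndarray:
    """pd * exp(-TE/relax), zero where the relaxation map is zero (background)."""
    out = np.zeros_like(pd_weighted)
    valid = relax_ms > 0
    out[valid] = pd_weighted[valid] * np.exp(-te_ms / relax_ms[valid])
    return out


def _coarsen(volume: np.ndarray, factor: int) -> np.ndarray:
    """Block-average down-sampling emulating a lower-resolution acquisition."""
    if factor == 1:
        return volume.copy()
    shape = volume.shape
    trimmed = volume[tuple(slice(0, (n // factor) * factor) for n in shape)]
    view = trimmed.reshape(
        shape[0] // factor, factor, shape[1] // factor, factor, shape[2] // factor, factor
    )
    return view.mean(axis=(1, 3, 5))


def simulate_multiecho_se(
    phantom: TissuePhantom,
    protocol: AcquisitionProtocol | None = None,
    stimulated_echoes: bool = False,
) -> EchoSeries:
    """Multi-echo fast spin-echo series for T2 mapping.

    Noiseless voxel signal ``S(TE) = rx * PD * exp(-TE/T2)``.  With
    ``stimulated_echoes`` enabled, a multiplicative B1-dependent factor from
    an EPG evaluation of the CPMG train (refocusing angle scaled by the local
    B1) emulates stimulated-echo contamination; default off, so the baseline
    signal is exactly exponential.
    """
    protocol = protocol or default_protocol("multiecho_se")
    if protocol.sequence_kind != "multiecho_se":
        raise ValueError(f"expected multiecho_se protocol, got {protocol.sequence_kind}")

    pd_rx = phantom.rx_profile * phantom.pd_map
    signals = [_decay(pd_rx, phantom.t2_map, te) for te in protocol.te_list]

    if stimulated_echoes:
        from .epg import stimulated_echo_factors

        esp = protocol.echo_spacing or protocol.te_list[0]
        n_train = max(int(round(protocol.te_list[-1] / esp)), 1)
        factors = stimulated_echo_factors(
            phantom.t1_map.ravel(),
            phantom.t2_map.ravel(),
            esp,
            n_train,
            protocol.refocus_angle * phantom.b1_map.ravel(),
        )
        for i, te in enumerate(protocol.te_list):
            k = int(np.clip(round(te / esp) - 1, 0, n_train - 1))
            signals[i] = signals[i] * factors[k].reshape(phantom.shape)

    volumes, te_per_volume, repeat_per_volume = [], [], []
    for rep in range(protocol.n_repeats):
        for te, s in zip(protocol.te_list, signals):
            volumes.append(s.copy())
            te_per_volume.append(te)
            repeat_per_volume.append(rep)
    return EchoSeries(
        volumes=volumes,
        protocol=protocol,
        te_per_volume=te_per_volume,
        repeat_per_volume=repeat_per_volume,
        voxel_size_mm=phantom.voxel_size_mm,
    )


def spgr_signal(
    pd: np.ndarray,
    t1: np.ndarray,
    t2star: np.ndarray,
    b1: np.ndarray,
    alpha_deg: float,
    tr_ms: float,
    te_ms: float,
) -> np.ndarray:
    """Ideally spoiled gradient-echo signal with effective flip angle B1*alpha."""
    out = np.zeros_like(pd, dtype=np.float64)
    valid = (t1 > 0) & (t2star > 0)
    e1 = np.exp(-tr_ms / t1[valid])
    a = np.deg2rad(alpha_deg) * b1[valid]
    out[valid] = (
        pd[valid]
        * np.exp(-te_ms / t2star[valid])
        * np.sin(a)
        * (1.0 - e1)
        / (1.0 - e1 * np.cos(a))
    )
    return out


def simulate_vfa(phantom: TissuePhantom, protocol: AcquisitionProtocol | None = None) -> EchoSeries:
    """Two-angle spoiled gradient-echo pair for variable-flip-angle T1 mapping."""
    protocol = protocol or default_protocol("vfa_ge")
    if protocol.sequence_kind != "vfa_ge" or len(protocol.flip_angles) != 2:
        raise ValueError("VFA simulation needs a vfa_ge protocol with two flip angles")
    te = protocol.te_list[0]
    pd_rx = phantom.rx_profile * phantom.pd_map
    volumes = [
        spgr_signal(pd_rx, phantom.t1_map, phantom.t2star_map, phantom.b1_map, a, protocol.tr, te)
        for a in protocol.flip_angles
    ]
    return EchoSeries(
        volumes=volumes,
        protocol=protocol,
        te_per_volume=[te, te],
        flip_per_volume=list(protocol.flip_angles),
        voxel_size_mm=phantom.voxel_size_mm,
    )


def _saturation(t1: np.ndarray, tr_ms: float, alpha_deg: float) -> np.ndarray:
    """Generic T1-weighting (saturation) factor of a GE readout."""
    out = np.zeros_like(t1, dtype=np.float64)
    valid = t1 > 0
    e1 = np.exp(-tr_ms / t1[valid])
    a = np.deg2rad(alpha_deg)
    out[valid] = np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return out


def simulate_b1_pair(
    phantom: TissuePhantom,
    protocol: AcquisitionProtocol | None = None,
    grid_scale: int = 2,
) -> EchoSeries:
    """Reference and magnetization-prepared GE pair for B1 mapping.

    The prepared volume is the reference scaled by ``cos(B1 * beta_0)``.  The
    pair is produced on a ``grid_scale``-times coarser grid, emulating the
    low-resolution calibration scan; the fit upsamples back.
    """
    protocol = protocol or default_protocol("b1_pair")
    if protocol.sequence_kind != "b1_pair" or protocol.prep_angle_nominal is None:
        raise ValueError("B1 simulation needs a b1_pair protocol with a nominal prep angle")
    te = protocol.te_list[0]
    weighting = (
        phantom.rx_profile
        * _decay(phantom.pd_map, phantom.t2star_map, te)
        * _saturation(phantom.t1_map, protocol.tr, protocol.flip_angles[0])
    )
    beta = np.deg2rad(protocol.prep_angle_nominal) * phantom.b1_map
    ref = _coarsen(weighting, grid_scale)
    prep = _coarsen(weighting * np.cos(beta), grid_scale)
    return EchoSeries(
        volumes=[ref, prep],
        protocol=protocol,
        te_per_volume=[te, te],
        voxel_size_mm=None if phantom.voxel_size_mm is None else phantom.voxel_size_mm * grid_scale,
        grid_scale=grid_scale,
    )


def simulate_b0_pair(
    phantom: TissuePhantom,
    protocol: AcquisitionProtocol | None = None,
    grid_scale: int = 2,
    phase_offset_rad: float = 0.0,
) -> EchoSeries:
    """Dual-TE GE pair with magnitude and phase export for B0 mapping.

    Phase evolves as ``phi_i = 2*pi*b0*TE_i`` plus a common receiver offset.
    Field amplitudes whose phase difference would reach +/-pi are rejected, as
    they would be ambiguous under wrapping.
    """
    protocol = protocol or default_protocol("b0_pair")
    if protocol.sequence_kind != "b0_pair" or len(protocol.te_list) != 2:
        raise ValueError("B0 simulation needs a b0_pair protocol with two echoes")
    dte_s = (protocol.te_list[1] - protocol.te_list[0]) / 1000.0
    dphi = 2.0 * np.pi * phantom.b0_map * dte_s
    if np.any(np.abs(dphi) >= np.pi):
        raise ValueError(
            "off-resonance too large for the echo spacing: |delta phi| >= pi would wrap ambiguously"
        )
    sat = _saturation(phantom.t1_map, protocol.tr, protocol.flip_angles[0])
    volumes, phases = [], []
    for te in protocol.te_list:
        mag = phantom.rx_profile * _decay(phantom.pd_map, phantom.t2star_map, te) * sat
        phase = 2.0 * np.pi * phantom.b0_map * (te / 1000.0) + phase_offset_rad
        volumes.append(_coarsen(mag, grid_scale))
        phases.append(_coarsen(phase, grid_scale))
    return EchoSeries(
        volumes=volumes,
        protocol=protocol,
        te_per_volume=list(protocol.te_list),
        phase_volumes=phases,
        voxel_size_mm=None if phantom.voxel_size_mm is None else phantom.voxel_size_mm * grid_scale,
        grid_scale=grid_scale,
    )


def simulate_dualecho_ge(
    phantom: TissuePhantom, protocol: AcquisitionProtocol | None = None
) -> EchoSeries:
    """Dual-echo GE pair used to estimate T2* for the VFA compensation."""
    protocol = protocol or default_protocol("dualecho_ge")
    if protocol.sequence_kind != "dualecho_ge" or len(protocol.te_list) != 2:
        raise ValueError("dual-echo simulation needs a dualecho_ge protocol with two echoes")
    sat = _saturation(phantom.t1_map, protocol.tr, protocol.flip_angles[0])
    volumes = [
        phantom.rx_profile * sat * _decay(phantom.pd_map, phantom.t2star_map, te)
        for te in protocol.te_list
    ]
    return EchoSeries(
        volumes=volumes,
        protocol=protocol,
        te_per_volume=list(protocol.te_list),
        voxel_size_mm=phantom.voxel_size_mm,
    )


def add_noise(
    series: EchoSeries,
    snr: float,
    seed: int,
    reference_mask: np.ndarray | None = None,
) -> EchoSeries:
    """Add Rician magnitude (and consistent phase) noise to a series.

    ``snr`` is defined as (mean reference-region signal of the first volume) /
    sigma, with sigma the per-channel Gaussian noise SD.  The reference region
    defaults to all positive voxels of the first volume; pass the phantom's WM
    mask to follow the usual white-matter SNR convention.  Magnitude and phase
    are derived from the same complex perturbation, so background magnitudes
    follow the Rayleigh distribution.
    """
    if np.isnan(snr) or snr <= 0:
        raise ValueError("snr must be positive")
    first = series.volumes[0]
    if reference_mask is None:
        reference_mask = first > 0
    if reference_mask.shape != first.shape:
        # reference defined on the phantom grid; coarsen to the series grid
        if series.grid_scale > 1:
            reference_mask = _coarsen(reference_mask.astype(np.float64), series.grid_scale) > 0.5
        if reference_mask.shape != first.shape:
            raise ValueError("reference_mask grid does not match the series")
    if not np.any(reference_mask):
        raise ValueError("empty reference mask")
    sigma = float(np.mean(first[reference_mask])) / snr

    rng = np.random.default_rng(seed)
    out = series.copy()
    out.noise_sigma = sigma
    for i, mag in enumerate(out.volumes):
        phase = out.phase_volumes[i] if out.phase_volumes is not None else np.zeros_like(mag)
        real = mag * np.cos(phase) + rng.normal(0.0, sigma, mag.shape)
        imag = mag * np.sin(phase) + rng.normal(0.0, sigma, mag.shape)
        out.volumes[i] = np.hypot(real, imag)
        if out.phase_volumes is not None:
            out.phase_volumes[i] = np.arctan2(imag, real)
    return out
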