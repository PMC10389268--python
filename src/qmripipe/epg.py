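"""Extended phase graph (EPG) evaluation of a CPMG echo train.

Used to model the stimulated-echo contamination of fast spin-echo T2 data
when the refocusing angle is below 180 degrees: crushed/stimulated pathways
make the echo amplitudes deviate from the pure exponential exp(-TE/T2).  The
implementation tracks the configuration states (F+, F-, Z) through the usual
relax -> shift -> refocus -> shift -> relax interval, vectorized over voxels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cpmg_echo_amplitudes", "stimulated_echo_factors"]


def cpmg_echo_amplitudes(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    esp_ms: float,
    n_echoes: int,
    refocus_deg: np.ndarray | float,
    excite_deg: float = 90.0,
) -> np.ndarray:
    """Echo amplitudes of a CPMG train (unit equilibrium magnetization).

    Returns an array of shape ``(n_echoes, n_voxels)``.  With a 180-degree
    refocusing angle the amplitudes reduce exactly to ``exp(-k*esp/T2)``.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=np.float64)).ravel()
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=np.float64)).ravel()
    beta = np.deg2rad(np.broadcast_to(np.asarray(refocus_deg, dtype=np.float64), t1.shape).ravel())
    n = t1.size
    if n_echoes < 1 or esp_ms <= 0:
        raise ValueError("need n_echoes >= 1 and positive echo spacing")

    with np.errstate(divide="ignore"):
        e1h = np.where(t1 > 0, np.exp(-0.5 * esp_ms / np.maximum(t1, 1e-12)), 0.0)
        e2h = np.where(t2 > 0, np.exp(-0.5 * esp_ms / np.maximum(t2, 1e-12)), 0.0)

    K = n_echoes + 2
    fp = np.zeros((K, n))
    fm = np.zeros((K, n))
    z = np.zeros((K, n))
    fp[0] = np.sin(np.deg2rad(excite_deg))
    z[0] = np.cos(np.deg2rad(excite_deg))

    c2 = np.cos(beta / 2.0) ** 2
    s2 = np.sin(beta / 2.0) ** 2
    sb = np.sin(beta)
    cb = np.cos(beta)

    def relax_half() -> None:
        fp[...] *= e2h
        fm[...] *= e2h
        z[...] *= e1h
        z[0] += 1.0 - e1h

    def shift() -> None:
        # gradient dephasing by one configuration order
        fp_old = fp.copy()
        fp[1:] = fp_old[:-1]
        fp[0] = fm[1]
        fm[:-1] = fm[1:].copy()
        fm[-1] = 0.0

    amps = np.zeros((n_echoes, n))
    for k in range(n_echoes):
        relax_half()
        shift()
        fp_new = c2 * fp + s2 * fm + sb * z
        fm_new = s2 * fp + c2 * fm - sb * z
        z_new = -0.5 * sb * fp + 0.5 * sb * fm + cb * z
        fp, fm, z = fp_new, fm_new, z_new
        shift()
        relax_half()
        amps[k] = fp[0]
    return amps


def stimulated_echo_factors(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    esp_ms: float,
    n_echoes: int,
    refocus_deg: np.ndarray | float,
) -> np.ndarray:
    """Multiplicative deviation of each echo from pure exponential decay.

    ``factor[k] = amplitude_epg[k] / exp(-(k+1)*esp/T2)``; identically one for
    an ideal 180-degree train.  Shape ``(n_echoes, n_voxels)``.
    """
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=np.float64)).ravel()
    amps = cpmg_echo_amplitudes(t1_ms, t2, esp_ms, n_echoes, refocus_deg)
    k = np.arange(1, n_echoes + 1, dtype=np.float64)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ideal = np.exp(-k * esp_ms / np.maximum(t2[None, :], 1e-12))
        factors = np.where(ideal > 0, amps / ideal, 1.0)
    factors[:, t2 <= 0] = 1.0
    return factors
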