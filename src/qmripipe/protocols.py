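"""Acquisition protocol descriptions and the default 3 T protocol set.

Defaults follow the study protocol the package emulates: four fast spin-echo
datasets for T2 mapping (TE = 13/67/93/106 ms, TR = 10 s, acquired twice for
averaging), a two-angle spoiled gradient-echo pair for T1/PD (alpha = 4/24
deg, TR = 16.4 ms, TE = 6.7 ms), a magnetization-prepared/reference pair for
B1 (nominal preparation angle 45 deg), a dual-TE gradient-echo pair with
phase export for B0 (TE = 4.89/7.35 ms), and a dual-echo gradient-echo pair
for T2* compensation (TE = 4.3/11 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

SEQUENCE_KINDS = ("multiecho_se", "vfa_ge", "b1_pair", "b0_pair", "dualecho_ge")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and flip-angle parameters of one acquisition."""

    sequence_kind: str
    te_list: tuple[float, ...]  # ms
    tr: float  # ms
    flip_angles: tuple[float, ...] = ()  # degrees
    prep_angle_nominal: float | None = None  # degrees, B1 preparation only
    n_repeats: int = 1
    echo_spacing: float | None = None  # ms, effective echo train spacing
    refocus_angle: float = 180.0  # degrees, spin-echo refocusing

    def __post_init__(self) -> None:
        if self.sequence_kind not in SEQUENCE_KINDS:
            raise ValueError(f"unknown sequence_kind {self.sequence_kind!r}")
        te = tuple(float(t) for t in self.te_list)
        if len(te) == 0 or any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError(f"te_list must be strictly increasing, got {te}")
        if any(t <= 0 for t in te):
            raise ValueError("echo times must be positive")
        if self.tr <= max(te):
            raise ValueError(f"tr ({self.tr} ms) must exceed max TE ({max(te)} ms)")
        for a in self.flip_angles:
            if not 0.0 < a < 180.0:
                raise ValueError(f"flip angle {a} out of (0, 180) degrees")
        if self.prep_angle_nominal is not None and not 0.0 < self.prep_angle_nominal < 180.0:
            raise ValueError("prep_angle_nominal out of (0, 180) degrees")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        object.__setattr__(self, "te_list", te)
        object.__setattr__(self, "flip_angles", tuple(float(a) for a in self.flip_angles))

    def with_updates(self, **kwargs) -> "AcquisitionProtocol":
        return replace(self, **kwargs)


_DEFAULTS: dict[str, AcquisitionProtocol] = {
    "multiecho_se": AcquisitionProtocol(
        sequence_kind="multiecho_se",
        te_list=(13.0, 67.0, 93.0, 106.0),
        tr=10_000.0,
        flip_angles=(90.0,),
        n_repeats=2,
        echo_spacing=13.3,
        refocus_angle=160.0,
    ),
    "vfa_ge": AcquisitionProtocol(
        sequence_kind="vfa_ge",
        te_list=(6.7,),
        tr=16.4,
        flip_angles=(4.0, 24.0),
    ),
    "b1_pair": AcquisitionProtocol(
        sequence_kind="b1_pair",
        te_list=(5.0,),
        tr=11.0,
        flip_angles=(11.0,),
        prep_angle_nominal=45.0,
    ),
    "b0_pair": AcquisitionProtocol(
        sequence_kind="b0_pair",
        te_list=(4.89, 7.35),
        tr=560.0,
        flip_angles=(60.0,),
    ),
    "dualecho_ge": AcquisitionProtocol(
        sequence_kind="dualecho_ge",
        te_list=(4.3, 11.0),
        tr=1336.0,
        flip_angles=(50.0,),
    ),
}


def default_protocol(sequence_kind: str) -> AcquisitionProtocol:
    """Return the default protocol for one of the five acquisitions."""
    try:
        return _DEFAULTS[sequence_kind]
    except KeyError:
        raise ValueError(f"unknown sequence_kind {sequence_kind!r}") from None


def default_protocol_set() -> dict[str, AcquisitionProtocol]:
    return dict(_DEFAULTS)
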