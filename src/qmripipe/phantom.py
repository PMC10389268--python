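"""Digital brain phantoms and two-group cohorts with known ground truth.

The phantom is a parametric concentric-shell brain: an outer CSF envelope, a
cortical gray-matter ribbon (at least three voxels thick), a white-matter
interior containing bilateral deep gray-matter blobs and small CSF ventricles.
Every voxel carries ground-truth T1, T2, T2* (ms) and proton density (percent
units, CSF = 100), together with smooth second-order B1, B0 and receive-coil
field maps.  Cohorts emulate a two-group study (default 27 vs 27 subjects)
with per-subject tissue-parameter variation and an optional injected group
effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "TISSUE_LABELS",
    "TissueParams",
    "FieldSpec",
    "MetadataSpec",
    "TissuePhantom",
    "CohortSpec",
    "default_tissue_table",
    "default_between_subject_sd",
    "make_phantom",
    "sample_subject_tables",
    "make_cohort",
]

#: integer label conventions used by every module in the package
TISSUE_LABELS: dict[str, int] = {
    "background": 0,
    "csf": 1,
    "cortex": 2,
    "wm": 3,
    "deep_gm": 4,
}

#: labels that belong to the brain proper (CSF envelope included)
BRAIN_LABELS = (1, 2, 3, 4)

PARAM_NAMES = ("t1", "t2", "t2star", "pd")


@dataclass(frozen=True)
class TissueParams:
    """Relaxation times (ms) and proton density (p.u.) of one tissue class."""

    t1: float
    t2: float
    t2star: float
    pd: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"tissue parameter {name} must be positive, got {value!r}")
        if self.pd > 100.0:
            raise ValueError(f"pd must be <= 100 p.u., got {self.pd}")
        if self.t2 >= self.t1:
            raise ValueError(f"t2 ({self.t2}) must be smaller than t1 ({self.t1})")

    def shifted(self, shifts: Mapping[str, float]) -> "TissueParams":
        values = {name: getattr(self, name) for name in PARAM_NAMES}
        for name, delta in shifts.items():
            if name not in values:
                raise KeyError(f"unknown tissue parameter {name!r}")
            values[name] = values[name] + float(delta)
        return TissueParams(**values)


def default_tissue_table() -> dict[str, TissueParams]:
    """Default 3 T tissue parameter table.

    T1/T2/PD of cortex, WM and deep GM are set to the patient-group compartment
    means of the study the phantom emulates, so that recovery tests target
    those values directly; T2* and the CSF entries are generic 3 T literature
    values.
    """
    return {
        "csf": TissueParams(t1=4000.0, t2=500.0, t2star=200.0, pd=100.0),
        "cortex": TissueParams(t1=1556.79, t2=80.97, t2star=40.0, pd=80.74),
        "wm": TissueParams(t1=894.07, t2=62.15, t2star=45.0, pd=66.24),
        "deep_gm": TissueParams(t1=1249.95, t2=58.6, t2star=35.0, pd=75.79),
    }


def default_between_subject_sd() -> dict[str, dict[str, float]]:
    """Between-subject SDs per tissue/parameter (reported patient-group SDs)."""
    return {
        "cortex": {"t1": 51.14, "t2": 2.82, "pd": 2.00},
        "wm": {"t1": 57.08, "t2": 12.99, "pd": 3.41},
        "deep_gm": {"t1": 158.94, "t2": 12.47, "pd": 5.93},
        "csf": {},
    }


@dataclass(frozen=True)
class FieldSpec:
    """Amplitudes of the smooth instrumental field inhomogeneities.

    ``b1_amplitude`` is the relative transmit-field deviation (0.2 means B1 in
    [0.8, 1.2]); ``b0_amplitude_hz`` the peak off-resonance; ``rx_amplitude``
    the relative receive-profile deviation.  The B0 default keeps the phase
    difference of the B0 protocol within (-pi, pi), avoiding unwrapping
    ambiguity by construction.
    """

    b1_amplitude: float = 0.2
    b0_amplitude_hz: float = 60.0
    rx_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.b1_amplitude < 0 or self.rx_amplitude < 0 or self.b0_amplitude_hz < 0:
            raise ValueError("field amplitudes must be non-negative")
        if self.b1_amplitude > 0.3:
            raise ValueError("b1_amplitude above 0.3 leaves the supported [0.7, 1.3] range")


@dataclass(frozen=True)
class MetadataSpec:
    """Distributions for the subject metadata table (age, sex, seizures, ASM)."""

    age_mean_a: float = 33.1
    age_sd_a: float = 14.2
    age_mean_b: float = 33.0
    age_sd_b: float = 13.8
    female_fraction: float = 12.0 / 27.0
    seizure_free_fraction: float = 8.0 / 27.0
    seizure_rate: float = 4.0  # median seizures in the last 3 months
    asm_rate: float = 2.0  # median current antiseizure medications


@dataclass
class TissuePhantom:
    """Labeled 3D volume with ground-truth parameter and field maps."""

    label_volume: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    t2star_map: np.ndarray
    pd_map: np.ndarray
    b1_map: np.ndarray
    b0_map: np.ndarray
    rx_profile: np.ndarray
    voxel_size_mm: np.ndarray
    tissue_table: dict[str, TissueParams] = field(default_factory=default_tissue_table)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_volume.shape

    def mask(self, tissue: str) -> np.ndarray:
        return self.label_volume == TISSUE_LABELS[tissue]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def parameter_map(self, name: str) -> np.ndarray:
        return {
            "t1": self.t1_map,
            "t2": self.t2_map,
            "t2star": self.t2star_map,
            "pd": self.pd_map,
        }[name]


def _ellipsoid_distance(shape: tuple[int, int, int], center: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Anisotropy-normalized radius scaled back to voxels of the shortest axis."""
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    u = [(g - c) / h for g, c, h in zip(grids, center, half)]
    r = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    return r * float(np.min(half))


def _blob_mask(
    shape: tuple[int, int, int],
    center_offset_vox: np.ndarray,
    radius_vox: float,
    center: np.ndarray,
    half: np.ndarray,
) -> np.ndarray:
    hmin = float(np.min(half))
    blob_center = center + center_offset_vox * half / hmin
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    # isotropic in normalized units so blobs follow the head's aspect ratio
    d2 = sum(((g - c) / h * hmin) ** 2 for g, c, h in zip(grids, blob_center, half))
    return d2 <= radius_vox**2


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Random smooth second-order polynomial field, normalized to max |f| = 1."""
    grids = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij")
    x, y, z = grids
    basis = [x, y, z, x * x, y * y, z * z, x * y, x * z, y * z]
    coeffs = rng.standard_normal(len(basis))
    f = sum(c * b for c, b in zip(coeffs, basis))
    peak = np.max(np.abs(f))
    if peak == 0:
        return np.zeros(shape)
    return f / peak


def make_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    tissue_params: Mapping[str, TissueParams] | None = None,
    field_spec: FieldSpec | None = None,
    seed: int = 0,
    voxel_size_mm: float | tuple[float, float, float] = 2.0,
    partial_volume: bool = False,
) -> TissuePhantom:
    """Build a concentric-shell digital brain phantom.

    Parameters
    ----------
    shape
        Grid shape; every axis must be at least 16 voxels so the cortical
        ribbon can be at least three voxels thick.
    tissue_params
        Per-class :class:`TissueParams`; defaults to :func:`default_tissue_table`.
    field_spec
        Amplitudes of the B1/B0/receive inhomogeneities; amplitude zero gives
        perfectly homogeneous fields.
    seed
        Seeds the random low-order field realizations; the anatomy itself is
        deterministic.
    partial_volume
        If set, the parameter maps (not the labels) are blurred across class
        boundaries to emulate partial volume effects in boundary voxels.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError(f"shape must be 3D with every axis >= 16, got {shape}")
    table = dict(tissue_params) if tissue_params is not None else default_tissue_table()
    missing = set(TISSUE_LABELS) - {"background"} - set(table)
    if missing:
        raise ValueError(f"tissue_params missing classes: {sorted(missing)}")
    for params in table.values():
        if not isinstance(params, TissueParams):
            raise TypeError("tissue_params values must be TissueParams")
    spec = field_spec if field_spec is not None else FieldSpec()

    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,)).copy()
    if np.any(voxel_size <= 0):
        raise ValueError("voxel sizes must be positive")

    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    half = np.asarray(shape, dtype=np.float64) / 2.0
    hmin = float(np.min(half))

    outer_r = 0.92 * hmin
    csf_th = max(1.0, 0.06 * hmin)
    ctx_th = max(3.0, 0.16 * hmin)
    wm_r = outer_r - csf_th - ctx_th
    if wm_r < 0.2 * hmin or ctx_th < 3.0:
        raise ValueError(f"shape {shape} too small for a >=3-voxel cortical ribbon")

    rho = _ellipsoid_distance(shape, center, half)
    labels = np.zeros(shape, dtype=np.int16)
    labels[rho <= outer_r] = TISSUE_LABELS["csf"]
    labels[rho <= outer_r - csf_th] = TISSUE_LABELS["cortex"]
    labels[rho <= wm_r] = TISSUE_LABELS["wm"]

    deep_r = max(0.22 * wm_r, 1.2)
    vent_r = max(0.15 * wm_r, 1.2)
    for sign in (-1.0, 1.0):
        deep = _blob_mask(shape, np.array([sign * 0.5 * wm_r, 0.0, 0.0]), deep_r, center, half)
        labels[deep & (labels == TISSUE_LABELS["wm"])] = TISSUE_LABELS["deep_gm"]
        vent = _blob_mask(shape, np.array([0.0, sign * 0.3 * wm_r, 0.0]), vent_r, center, half)
        labels[vent & (labels == TISSUE_LABELS["wm"])] = TISSUE_LABELS["csf"]

    for tissue, lab in TISSUE_LABELS.items():
        if tissue == "background":
            continue
        if not np.any(labels == lab):
            raise ValueError(f"shape {shape} too small: tissue class {tissue!r} is empty")

    maps = {name: np.zeros(shape, dtype=np.float64) for name in PARAM_NAMES}
    for tissue, lab in TISSUE_LABELS.items():
        if tissue == "background":
            continue
        sel = labels == lab
        for name in PARAM_NAMES:
            maps[name][sel] = getattr(table[tissue], name)

    if partial_volume:
        from scipy.ndimage import gaussian_filter

        brain = labels > 0
        for name in PARAM_NAMES:
            blurred = gaussian_filter(maps[name], sigma=0.8)
            norm = gaussian_filter(brain.astype(np.float64), sigma=0.8)
            maps[name][brain] = blurred[brain] / norm[brain]

    rng = np.random.default_rng(seed)
    b1 = 1.0 + spec.b1_amplitude * _smooth_field(rng, shape)
    b0 = spec.b0_amplitude_hz * _smooth_field(rng, shape)
    rx = 1.0 + spec.rx_amplitude * _smooth_field(rng, shape)

    return TissuePhantom(
        label_volume=labels,
        t1_map=maps["t1"],
        t2_map=maps["t2"],
        t2star_map=maps["t2star"],
        pd_map=maps["pd"],
        b1_map=b1,
        b0_map=b0,
        rx_profile=rx,
        voxel_size_mm=voxel_size,
        tissue_table=table,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-group phantom cohort.

    ``effect`` holds per-tissue additive shifts (e.g. ``{"cortex": {"t2": 8.0}}``)
    applied to group A only; an empty effect defines the null cohort.
    ``between_subject_sd`` gives the SD of subject-level tissue means; the
    default uses the reported patient-group compartment SDs.
    """

    n_group_a: int = 27
    n_group_b: int = 27
    effect: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    between_subject_sd: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float | tuple[float, float, float] = 2.0
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    tissue_table: Mapping[str, TissueParams] | None = None
    metadata_spec: MetadataSpec = field(default_factory=MetadataSpec)

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("group sizes must be positive")
        sds = self.between_subject_sd
        if sds is not None:
            for tissue, entries in sds.items():
                for name, sd in entries.items():
                    if sd < 0:
                        raise ValueError(f"negative SD for {tissue}/{name}: {sd}")

    def resolved_sd(self) -> dict[str, dict[str, float]]:
        if self.between_subject_sd is None:
            return default_between_subject_sd()
        return {t: dict(v) for t, v in self.between_subject_sd.items()}

    def resolved_table(self) -> dict[str, TissueParams]:
        if self.tissue_table is None:
            return default_tissue_table()
        return dict(self.tissue_table)


def _draw_table(
    base: Mapping[str, TissueParams],
    sds: Mapping[str, Mapping[str, float]],
    shifts: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
) -> dict[str, TissueParams]:
    table: dict[str, TissueParams] = {}
    for tissue, params in base.items():
        values = {name: getattr(params, name) for name in PARAM_NAMES}
        for name, sd in sds.get(tissue, {}).items():
            if sd > 0:
                values[name] += rng.normal(0.0, sd)
        for name, delta in shifts.get(tissue, {}).items():
            values[name] += float(delta)
        # guard physical plausibility for extreme draws
        values["t1"] = max(values["t1"], 50.0)
        for name in ("t2", "t2star"):
            values[name] = float(np.clip(values[name], 5.0, 0.9 * values["t1"]))
        values["pd"] = float(np.clip(values["pd"], 1.0, 100.0))
        table[tissue] = TissueParams(**values)
    return table


def sample_subject_tables(
    spec: CohortSpec,
) -> list[tuple[str, dict[str, TissueParams], dict]]:
    """Draw per-subject tissue tables and metadata without building volumes.

    Returns a list of ``(group, tissue_table, metadata)`` with groups "A"
    (n_group_a subjects, effect applied) and "B".
    """
    base = spec.resolved_table()
    sds = spec.resolved_sd()
    meta = spec.metadata_spec
    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = ss.spawn(spec.n_group_a + spec.n_group_b)
    out = []
    for idx, sseed in enumerate(subject_seeds):
        group = "A" if idx < spec.n_group_a else "B"
        rng = np.random.default_rng(sseed)
        shifts = spec.effect if group == "A" else {}
        table = _draw_table(base, sds, shifts, rng)
        if group == "A":
            age = rng.normal(meta.age_mean_a, meta.age_sd_a)
            seizure_free = bool(rng.random() < meta.seizure_free_fraction)
            seizures = 0 if seizure_free else int(rng.poisson(meta.seizure_rate))
            asm = 1 + int(rng.poisson(max(meta.asm_rate - 1.0, 0.0)))
        else:
            age = rng.normal(meta.age_mean_b, meta.age_sd_b)
            seizure_free, seizures, asm = True, 0, 0
        metadata = {
            "subject": f"sub-{idx + 1:03d}",
            "group": group,
            "age": float(np.clip(age, 18.0, 90.0)),
            "sex": "F" if rng.random() < meta.female_fraction else "M",
            "seizure_free": seizure_free,
            "n_seizures_3mo": seizures,
            "n_asm": asm,
            "phantom_seed": int(sseed.generate_state(1)[0] % (2**31)),
        }
        out.append((group, table, metadata))
    return out


def make_cohort(spec: CohortSpec) -> list[tuple[TissuePhantom, dict]]:
    """Generate the full cohort of phantoms with subject metadata.

    All subjects share the grid and anatomy; tissue parameters and the field
    realizations vary per subject.  Reproducible from ``spec.seed``.
    """
    cohort = []
    for _group, table, metadata in sample_subject_tables(spec):
        phantom = make_phantom(
            shape=spec.shape,
            tissue_params=table,
            field_spec=spec.field_spec,
            seed=metadata["phantom_seed"],
            voxel_size_mm=spec.voxel_size_mm,
        )
        cohort.append((phantom, metadata))
    return cohort
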