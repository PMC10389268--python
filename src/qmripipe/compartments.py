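"""Tissue compartments and qMRI summary statistics.

Re-scopes the surface-based workflow of the emulated study onto volumes: a
three-class intensity segmentation of the synthetic anatomy stands in for
surface reconstruction, the cortical "middle 20%" is realized as a
normalized volumetric depth fraction of 0.4-0.6 between the WM and CSF
boundaries, and WM / deep-GM means are taken after removing voxels with
T1 > 2,000 ms (CSF partial-volume exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .anatomy import SyntheticAnatomy
from .fitting import FittedMap, QuantitativeMaps
from .phantom import TISSUE_LABELS

__all__ = [
    "CompartmentMasks",
    "segment_from_anatomy",
    "cortical_depth",
    "exclude_csf_pve",
    "derive_masks",
    "summarize_compartments",
]

#: T1 threshold (ms) above which WM / deep-GM voxels are considered CSF partial volume
CSF_PVE_T1_MS = 2000.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CompartmentMasks:
    """Voxel sets of the analysis compartments plus the cortical depth map."""

    cortex_full: np.ndarray
    cortex_mid20: np.ndarray
    wm: np.ndarray
    deep_gm: np.ndarray
    csf: np.ndarray
    depth_map: np.ndarray

    def __post_init__(self) -> None:
        masks = [self.cortex_full, self.cortex_mid20, self.wm, self.deep_gm, self.csf]
        shape = masks[0].shape
        if any(m.shape != shape for m in masks) or self.depth_map.shape != shape:
            raise ValueError("all masks must share one grid")
        if np.any(self.cortex_mid20 & ~self.cortex_full):
            raise ValueError("cortex_mid20 must be a subset of cortex_full")

    def compartment(self, name: str) -> np.ndarray:
        return {
            "cortex": self.cortex_mid20,
            "cortex_full": self.cortex_full,
            "wm": self.wm,
            "deep_gm": self.deep_gm,
            "csf": self.csf,
        }[name]


def _kmeans_1d(values: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's algorithm on scalars with quantile init (scale-equivariant)."""
    centers = np.quantile(values, np.linspace(0.15, 0.85, k))
    if np.unique(centers).size < k:
        raise ValueError("degenerate intensity histogram: cannot form distinct classes")
    for _ in range(max_iter):
        edges = (centers[:-1] + centers[1:]) / 2.0
        labels = np.digitize(values, edges)
        new = np.array(
            [values[labels == i].mean() if np.any(labels == i) else centers[i] for i in range(k)]
        )
        if np.array_equal(new, centers):
            break
        centers = new
    edges = (centers[:-1] + centers[1:]) / 2.0
    return np.digitize(values, edges), centers


def segment_from_anatomy(
    anatomy: SyntheticAnatomy | np.ndarray,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Three-class intensity segmentation of a T1-weighted anatomy.

    K-means on intensity with classes ordered by mean intensity (CSF < GM <
    WM, the T1-weighted ordering), then gray matter is split into the
    cortical ribbon (largest connected component, the shell) and deep GM
    (interior components).  Returns labels in the phantom convention
    (0 background, 1 CSF, 2 cortical GM, 3 WM, 4 deep GM).
    """
    volume = anatomy.volume if isinstance(anatomy, SyntheticAnatomy) else np.asarray(anatomy)
    if brain_mask is None:
        brain_mask = volume > 0
    if not np.any(brain_mask):
        raise ValueError("empty brain mask: nothing to segment")
    values = volume[brain_mask]
    if np.ptp(values) == 0:
        raise ValueError("degenerate intensity histogram: single intensity value")
    classes, _ = _kmeans_1d(values.astype(np.float64), k=3)

    labels = np.zeros(volume.shape, dtype=np.int16)
    class_vol = np.full(volume.shape, -1, dtype=np.int16)
    class_vol[brain_mask] = classes
    labels[class_vol == 0] = TISSUE_LABELS["csf"]
    labels[class_vol == 2] = TISSUE_LABELS["wm"]

    gm = class_vol == 1
    if np.any(gm):
        comp, n_comp = ndimage.label(gm, structure=_STRUCT_26)
        sizes = np.bincount(comp.ravel())[1:]
        largest = int(np.argmax(sizes)) + 1
        labels[gm] = TISSUE_LABELS["deep_gm"]
        labels[comp == largest] = TISSUE_LABELS["cortex"]
    return labels


def cortical_depth(
    labels: np.ndarray,
    voxel_size_mm: float | np.ndarray = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cortical depth and the middle-20% ribbon mask.

    Depth is ``d_wm / (d_wm + d_out)`` from Euclidean distance transforms to
    the WM boundary and to the CSF/background boundary (0 at the WM side, 1
    at the pial side); the middle-20% mask selects depth fractions in
    [0.4, 0.6], the layer sampled to avoid WM and CSF partial volume.
    """
    cortex = labels == TISSUE_LABELS["cortex"]
    if not np.any(cortex):
        raise ValueError("no cortex voxels in the label volume")
    wm_like = (labels == TISSUE_LABELS["wm"]) | (labels == TISSUE_LABELS["deep_gm"])
    outside = (labels == TISSUE_LABELS["csf"]) | (labels == TISSUE_LABELS["background"])
    if not np.any(wm_like) or not np.any(outside):
        raise ValueError("cortical depth needs both a WM interior and a CSF/background exterior")
    sampling = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,))
    d_wm = ndimage.distance_transform_edt(~wm_like, sampling=sampling)
    d_out = ndimage.distance_transform_edt(~outside, sampling=sampling)
    depth = np.full(labels.shape, np.nan)
    denom = d_wm + d_out
    bad = cortex & (denom == 0)
    if np.any(bad):
        raise ValueError(f"{int(bad.sum())} cortex voxels have zero distance to both boundaries")
    depth[cortex] = d_wm[cortex] / denom[cortex]
    mid20 = cortex & (depth >= 0.4) & (depth <= 0.6)
    return depth, mid20


def exclude_csf_pve(
    mask: np.ndarray,
    t1_map: FittedMap | np.ndarray,
    threshold_ms: float = CSF_PVE_T1_MS,
) -> np.ndarray:
    """Remove voxels with T1 above the CSF partial-volume threshold (2,000 ms).

    Strictly a subset of the input mask; voxels with undefined T1 are removed
    as well (their partial-volume status cannot be established).
    """
    t1 = t1_map.data if isinstance(t1_map, FittedMap) else np.asarray(t1_map, dtype=np.float64)
    if t1.shape != mask.shape:
        raise ValueError("mask and T1 map must share a grid")
    return mask & np.isfinite(t1) & (t1 <= threshold_ms)


def derive_masks(
    labels: np.ndarray,
    t1_map: FittedMap | np.ndarray | None = None,
    voxel_size_mm: float | np.ndarray = 1.0,
) -> CompartmentMasks:
    """Build all compartment masks from a label volume.

    WM and deep GM receive the CSF partial-volume exclusion when a T1 map is
    supplied; cortical sampling uses the middle-20% depth ribbon.
    """
    cortex = labels == TISSUE_LABELS["cortex"]
    wm = labels == TISSUE_LABELS["wm"]
    deep = labels == TISSUE_LABELS["deep_gm"]
    csf = labels == TISSUE_LABELS["csf"]
    depth, mid20 = cortical_depth(labels, voxel_size_mm=voxel_size_mm)
    if t1_map is not None:
        wm = exclude_csf_pve(wm, t1_map)
        deep = exclude_csf_pve(deep, t1_map)
    return CompartmentMasks(
        cortex_full=cortex, cortex_mid20=mid20, wm=wm, deep_gm=deep, csf=csf, depth_map=depth
    )


def summarize_compartments(
    maps: QuantitativeMaps,
    masks: CompartmentMasks,
    subject: str = "sub-001",
    group: str = "A",
    parameters: tuple[str, ...] = ("t1", "t2", "pd"),
    compartments: tuple[str, ...] = ("cortex", "wm", "deep_gm"),
) -> pd.DataFrame:
    """Per-compartment mean/SD/voxel-count table of the fitted parameter maps.

    Cortical values are sampled from the middle-20% ribbon; WM and deep GM
    are expected to carry the CSF partial-volume exclusion already (see
    :func:`derive_masks`).  Sample SD uses the n-1 denominator.  Empty
    compartments raise instead of producing NaN rows.
    """
    rows = []
    for compartment in compartments:
        region = masks.compartment(compartment)
        for parameter in parameters:
            fitted = maps.parameter(parameter)
            sel = region & fitted.valid
            n = int(sel.sum())
            if n == 0:
                raise ValueError(f"empty compartment {compartment!r} for parameter {parameter!r}")
            values = fitted.data[sel]
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "compartment": compartment,
                    "parameter": parameter,
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if n > 1 else 0.0,
                    "n_voxels": n,
                }
            )
    return pd.DataFrame(rows)
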