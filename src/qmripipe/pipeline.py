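"""End-to-end orchestration: cohort simulation, fitting, compartments, stats.

``run_pipeline`` executes the stage order simulate -> average/fit ->
synthesize -> segment -> compartments -> group statistics for a whole
two-group cohort, with one global seed fanning out deterministically to the
cohort, per-subject noise, and the permutation engine.  Stage failures abort
with the failing stage named.
"""

from __future__ import annotations

import contextlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nifti_io
from .acquire import (
    add_noise,
    simulate_b0_pair,
    simulate_b1_pair,
    simulate_dualecho_ge,
    simulate_multiecho_se,
    simulate_vfa,
)
from .anatomy import MprageProtocol, synthesize_mprage
from .compartments import derive_masks, segment_from_anatomy, summarize_compartments
from .fitting import (
    QuantitativeMaps,
    average_repeats,
    fit_b0,
    fit_b1,
    fit_pd,
    fit_t1_vfa,
    fit_t2,
    fit_t2star,
)
from .inference import GroupDesign, GroupStatsResult, permutation_inference, ttest_two_sided
from .phantom import CohortSpec, FieldSpec, TissuePhantom, make_cohort

__all__ = ["PipelineConfig", "PipelineError", "SubjectResult", "CohortResult", "fit_subject", "run_cohort_study", "run_pipeline"]

PARAMETERS = ("t1", "t2", "pd")
COMPARTMENTS = ("cortex", "wm", "deep_gm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage '{name}' failed: {err}") from err


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable configuration of one cohort run.

    ``seed`` drives cohort generation and acquisition noise; ``stats_seed``
    (derived from ``seed`` when None) drives only the permutation engine, so
    changing it leaves the fitted maps untouched.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    n_group_a: int = 27
    n_group_b: int = 27
    effect: dict = field(default_factory=dict)
    between_subject_sd: dict | None = None
    b1_amplitude: float = 0.2
    b0_amplitude_hz: float = 60.0
    rx_amplitude: float = 0.3
    snr: float | None = None
    segmentation_mode: str = "intensity"  # or "oracle"
    stimulated_echoes: bool = False
    rx_method: str = "als"
    b1_grid_scale: int = 2
    n_permutations: int = 500
    voxelwise_threshold: float = 0.001
    clusterwise_alpha: float = 0.05
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    smoothing_fwhm_mm: float = 10.0
    stats_mode: str = "tfce"
    seed: int = 0
    stats_seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.segmentation_mode not in ("intensity", "oracle"):
            raise ValueError("segmentation_mode must be 'intensity' or 'oracle'")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "shape" in payload:
            payload["shape"] = tuple(payload["shape"])
        return cls(**payload)

    def to_yaml(self, path) -> Path:
        return nifti_io.save_yaml(path, self.to_dict())

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(nifti_io.load_yaml(path))

    def field_spec(self) -> FieldSpec:
        return FieldSpec(
            b1_amplitude=self.b1_amplitude,
            b0_amplitude_hz=self.b0_amplitude_hz,
            rx_amplitude=self.rx_amplitude,
        )

    def cohort_spec(self, tissue_table=None) -> CohortSpec:
        return CohortSpec(
            n_group_a=self.n_group_a,
            n_group_b=self.n_group_b,
            effect=self.effect,
            between_subject_sd=self.between_subject_sd,
            seed=int(np.random.SeedSequence(self.seed).generate_state(1)[0] % (2**31)),
            shape=self.shape,
            voxel_size_mm=self.voxel_size_mm,
            field_spec=self.field_spec(),
            tissue_table=tissue_table,
        )


@dataclass
class SubjectResult:
    maps: QuantitativeMaps
    labels: np.ndarray
    masks: object
    summary: pd.DataFrame


@dataclass
class CohortResult:
    subject_summaries: pd.DataFrame
    roi_table: pd.DataFrame
    #: voxelwise[parameter][compartment] -> GroupStatsResult (each compartment
    #: is analyzed within its own mask, as in the emulated workflow)
    voxelwise: dict[str, dict[str, GroupStatsResult]]
    config: PipelineConfig
    significant: bool

    def parameter_significant(self, parameter: str) -> bool:
        return any(res.significant for res in self.voxelwise[parameter].values())

    def report(self) -> dict:
        roi = [
            {k: rec[k] for k in ("compartment", "parameter", "mean_a", "mean_b", "t", "p", "significant")}
            for rec in self.roi_table.to_dict("records")
        ]
        voxelwise = {}
        for name, per_comp in self.voxelwise.items():
            voxelwise[name] = {
                "significant": self.parameter_significant(name),
                "n_clusters": sum(len(res.clusters) for res in per_comp.values()),
                "min_corrected_p": min(res.min_corrected_p for res in per_comp.values()),
                "per_compartment": {
                    comp: {
                        "significant": bool(res.significant),
                        "n_clusters": len(res.clusters),
                        "min_corrected_p": res.min_corrected_p,
                    }
                    for comp, res in per_comp.items()
                },
            }
        return {"roi": roi, "voxelwise": voxelwise, "significant": bool(self.significant)}


def fit_subject(
    phantom: TissuePhantom,
    config: PipelineConfig,
    noise_seed: int | None = None,
    subject: str = "sub-001",
    group: str = "A",
) -> SubjectResult:
    """Run the acquisition + fitting + segmentation chain for one subject."""
    shape = phantom.shape
    with _stage("simulate"):
        se = simulate_multiecho_se(phantom, stimulated_echoes=config.stimulated_echoes)
        vfa = simulate_vfa(phantom)
        b1_pair = simulate_b1_pair(phantom, grid_scale=config.b1_grid_scale)
        b0_pair = simulate_b0_pair(phantom, grid_scale=config.b1_grid_scale)
        dualecho = simulate_dualecho_ge(phantom)
        if config.snr is not None:
            wm = phantom.mask("wm")
            seeds = np.random.SeedSequence(noise_seed or 0).generate_state(5) % (2**31)
            se = add_noise(se, config.snr, int(seeds[0]), reference_mask=wm)
            vfa = add_noise(vfa, config.snr, int(seeds[1]), reference_mask=wm)
            b1_pair = add_noise(b1_pair, config.snr, int(seeds[2]), reference_mask=wm)
            b0_pair = add_noise(b0_pair, config.snr, int(seeds[3]), reference_mask=wm)
            dualecho = add_noise(dualecho, config.snr, int(seeds[4]), reference_mask=wm)

    with _stage("fit"):
        averaged = average_repeats(se)
        b1 = fit_b1(
            b1_pair.volumes[0],
            b1_pair.volumes[1],
            b1_pair.protocol.prep_angle_nominal,
            target_shape=shape,
        )
        b0 = fit_b0(b0_pair, target_shape=shape)
        t2 = fit_t2(
            averaged,
            stimulated_echo_correction=config.stimulated_echoes,
            b1_map=b1.data if config.stimulated_echoes else None,
        )
        t2star = fit_t2star(dualecho)
        t1 = fit_t1_vfa(vfa, b1, b0)

    with _stage("synthesize"):
        anatomy = synthesize_mprage(t1, protocol=MprageProtocol())

    with _stage("segment"):
        if config.segmentation_mode == "oracle":
            labels = phantom.label_volume.copy()
        else:
            labels = segment_from_anatomy(anatomy)

    with _stage("fit"):  # PD needs the CSF reference from the segmentation
        csf_mask = labels == 1
        pd_map = fit_pd(vfa, t1, b1, t2star, csf_mask, rx_method=config.rx_method)
        maps = QuantitativeMaps(
            t1=t1,
            t2=t2,
            t2star=t2star,
            pd=pd_map,
            b1=b1,
            b0=b0,
            provenance={"subject": subject, "group": group, "snr": config.snr},
        )

    with _stage("compartments"):
        masks = derive_masks(labels, t1_map=t1, voxel_size_mm=phantom.voxel_size_mm)
        summary = summarize_compartments(maps, masks, subject=subject, group=group)

    return SubjectResult(maps=maps, labels=labels, masks=masks, summary=summary)


def _roi_table(summaries: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    for compartment in COMPARTMENTS:
        for parameter in PARAMETERS:
            sel = summaries[
                (summaries["compartment"] == compartment) & (summaries["parameter"] == parameter)
            ]
            a = sel.loc[sel["group"] == "A", "mean"].to_numpy()
            b = sel.loc[sel["group"] == "B", "mean"].to_numpy()
            t, p = ttest_two_sided(a, b)
            rows.append(
                {
                    "compartment": compartment,
                    "parameter": parameter,
                    "mean_a": float(a.mean()),
                    "mean_b": float(b.mean()),
                    "t": t,
                    "p": p,
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def run_cohort_study(config: PipelineConfig) -> CohortResult:
    """Simulate, fit and statistically compare a full two-group cohort."""
    ss = np.random.SeedSequence(config.seed)
    _, noise_root, stats_fallback = (int(s) for s in ss.generate_state(3) % (2**31))
    stats_seed = config.stats_seed if config.stats_seed is not None else stats_fallback

    with _stage("cohort"):
        cohort = make_cohort(config.cohort_spec())

    noise_seeds = np.random.SeedSequence(noise_root).generate_state(len(cohort)) % (2**31)
    summaries = []
    subject_maps: dict[str, list[np.ndarray]] = {p: [] for p in PARAMETERS}
    analysis_masks: dict[str, np.ndarray] = {}
    groups = []
    for i, (phantom, metadata) in enumerate(cohort):
        result = fit_subject(
            phantom,
            config,
            noise_seed=int(noise_seeds[i]),
            subject=metadata["subject"],
            group=metadata["group"],
        )
        summaries.append(result.summary)
        groups.append(metadata["group"])
        for p in PARAMETERS:
            fitted = result.maps.parameter(p)
            subject_maps[p].append(np.where(fitted.valid, fitted.data, np.nan))
        masks = result.masks
        for comp in COMPARTMENTS:
            region = masks.compartment(comp)
            analysis_masks[comp] = (
                region if comp not in analysis_masks else (analysis_masks[comp] & region)
            )

    subject_summaries = pd.concat(summaries, ignore_index=True)

    with _stage("stats"):
        roi_table = _roi_table(subject_summaries, config.clusterwise_alpha)
        design = GroupDesign(
            group_labels=tuple(groups),
            n_permutations=config.n_permutations,
            seed=stats_seed,
            voxelwise_threshold=config.voxelwise_threshold,
            clusterwise_alpha=config.clusterwise_alpha,
            tfce_e=config.tfce_e,
            tfce_h=config.tfce_h,
            smoothing_fwhm_mm=config.smoothing_fwhm_mm,
        )
        # each compartment is analyzed within its own mask so the in-mask
        # smoothing never mixes tissue classes (surface-like for the ribbon)
        voxelwise = {
            p: {
                comp: permutation_inference(
                    np.stack(subject_maps[p]),
                    design,
                    mode=config.stats_mode,
                    mask=analysis_masks[comp],
                    voxel_size_mm=config.voxel_size_mm,
                )
                for comp in COMPARTMENTS
            }
            for p in PARAMETERS
        }

    significant = bool(
        roi_table["significant"].any()
        or any(res.significant for per_comp in voxelwise.values() for res in per_comp.values())
    )
    return CohortResult(
        subject_summaries=subject_summaries,
        roi_table=roi_table,
        voxelwise=voxelwise,
        config=config,
        significant=significant,
    )


def run_pipeline(config: PipelineConfig) -> CohortResult:
    """Run the cohort study and persist artifacts when an output directory is set."""
    result = run_cohort_study(config)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        with _stage("write"):
            config.to_yaml(out / "config.yaml")
            nifti_io.save_table(out / "subject_summaries.tsv", result.subject_summaries)
            nifti_io.save_table(out / "roi_table.tsv", result.roi_table)
            nifti_io.save_json(out / "report.json", result.report())
            for p, per_comp in result.voxelwise.items():
                # compartment masks are disjoint: merge into one volume per map
                stat = np.zeros(config.shape)
                corrp = np.ones(config.shape)
                clusters = []
                for comp, res in per_comp.items():
                    stat[res.mask] = res.stat_map[res.mask]
                    corrp[res.mask] = res.corrected_p_map[res.mask]
                    clusters += [{"compartment": comp, **c} for c in res.clusters]
                nifti_io.save_volume(out / f"stat_{p}.nii.gz", stat, config.voxel_size_mm, units="t")
                nifti_io.save_volume(out / f"corrp_{p}.nii.gz", corrp, config.voxel_size_mm, units="FWE-corrected p")
                if clusters:
                    nifti_io.save_table(out / f"clusters_{p}.tsv", pd.DataFrame(clusters))
    return result
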