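# qmripipe

Multiparametric quantitative MRI (qMRI) analysis — T1, T2, T2\* and proton
density (PD) mapping with B1/B0/receive-field corrections, synthetic
MP-RAGE anatomies for segmentation, tissue-compartment statistics, and
voxel-wise permutation inference with threshold-free cluster enhancement
(TFCE) — packaged together with a digital brain phantom so the whole chain
can be validated against known ground truth.

It is aimed at researchers who work with value-based relaxometry (rather
than contrast-weighted images) and want either (a) a transparent, tested
reference implementation of the classical mapping recipes, or (b) a
simulation harness to answer "could a study of this design have detected an
effect of size X?" for two-group qMRI comparisons.

## The science in brief

- **T2** from four fast spin-echo datasets: voxel-wise nonlinear fit of
  S(TE) = A·exp(−TE/T2) over TE = 13/67/93/106 ms (repeats averaged first).
- **B1** (transmit field) from a magnetization-prepared/reference GE pair:
  B1 = arccos(I_prep/I_ref)/β₀ with β₀ = 45°.
- **B0** from the wrapped phase difference of a dual-TE GE pair:
  Δf = wrap(φ₂−φ₁)/(2π·ΔTE).
- **T2\*** from a dual-echo GE pair: (TE₂−TE₁)/ln(S₁/S₂).
- **T1** by the variable-flip-angle method: the points
  (Iᵢ/tan αᵢ′, Iᵢ/sin αᵢ′) at effective angles αᵢ′ = B1·αᵢ (α = 4°, 24°,
  TR = 16.4 ms) lie on a line of slope exp(−TR/T1).
- **PD** from the PD-weighted (α = 4°) image after compensating T2\*, T1
  and flip-angle weighting, estimating and removing the receive-coil
  profile, and calibrating CSF to 100 percent units.
- **Segmentation** on synthetic MP-RAGE volumes computed from the T1 map
  (TR/TI = 1900/900 ms, α = 9°, echo spacing 8.1 ms); cortical values are
  sampled on the middle 20 % of the ribbon (depth fraction 0.4–0.6), WM and
  deep-GM means after excluding voxels with T1 > 2,000 ms (CSF partial
  volume).
- **Group statistics**: two-sided unpaired pooled t tests on compartment
  means, and voxel-wise permutation inference (max-statistic FWE, TFCE with
  E = 0.5, H = 2, 26-connectivity, 10 mm FWHM smoothing) per compartment.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

Recover the tissue parameters of a noiseless 64³ digital phantom whose
compartments carry realistic patient-group means:

```python
import qmripipe as q
from qmripipe.pipeline import PipelineConfig, fit_subject

phantom = q.make_phantom(shape=(64, 64, 64), seed=20)   # 2 mm isotropic
config = PipelineConfig(shape=(64, 64, 64))             # noiseless default
result = fit_subject(phantom, config)
print(result.summary.to_string(index=False))
```

prints (mean/SD over each compartment mask, cortical rows from the
middle-20 % ribbon):

```
subject group compartment parameter        mean           sd  n_voxels
sub-001     A      cortex        t1 1556.758004 2.206091e-02      9584
sub-001     A      cortex        t2   80.970000 1.449060e-14      9584
sub-001     A      cortex        pd   80.731119 1.187161e-02      9584
sub-001     A          wm        t1  894.052285 2.563473e-02     45736
sub-001     A          wm        t2   62.150000 1.425228e-14     45736
sub-001     A          wm        pd   66.234940 5.854228e-03     45736
sub-001     A     deep_gm        t1 1249.924535 3.351925e-02      1008
sub-001     A     deep_gm        t2   58.600000 7.296889e-15      1008
sub-001     A     deep_gm        pd   75.784525 2.779821e-03      1008
```

The recovered means match the assigned ground truths (cortex
1556.79 ms / 80.97 ms / 80.74 p.u., WM 894.07 / 62.15 / 66.24, deep GM
1249.95 / 58.6) to better than 0.05 % — despite ±20 % B1, ±60 Hz B0 and
±30 % receive-field inhomogeneities, because the chain measures and
removes each of them.

A full two-group in-silico study (27 vs 27 subjects, acquisition noise,
permutation statistics) is one call:

```python
from qmripipe.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    shape=(28, 28, 28), n_group_a=27, n_group_b=27, snr=50.0,
    effect={"cortex": {"t2": 8.0}},        # injected group effect; {} = null
    segmentation_mode="oracle", n_permutations=500, seed=1,
    output_dir="results/study",
)
result = run_pipeline(config)
print(result.report()["voxelwise"]["t2"]["per_compartment"]["cortex"])
# {'significant': True, 'n_clusters': 1, 'min_corrected_p': 0.002}
```

With `effect={}` the same call restates a negative result: no significant
ROI t-tests or voxel-wise clusters beyond the nominal 5 % level.

There is also a CLI (`qmripipe simulate|fit|synthesize|segment|summarize|
stats|run-all`); volumes travel between stages as NIfTI files with units in
the header, tables as TSV, configs as YAML.

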