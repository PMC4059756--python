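# dscaif

Automatic arterial input function (AIF) detection for DSC-MRI perfusion by
agglomerative hierarchical clustering, with k-means and fuzzy c-means
baselines, a tracer-kinetics simulator with ground truth, and the clinical
curve-filtering chain.

## The problem

Quantifying cerebral perfusion (CBF, CBV, MTT) from dynamic susceptibility
contrast MRI requires the tracer concentration–time curve in a feeding
artery — the arterial input function. Picking arterial voxels by hand is
slow and operator-dependent. Clustering-based detection groups the voxelwise
time–concentration curves and selects the cluster whose mean curve is most
arterial — tall, early and narrow — by the score

    M = H_P / (T_P × FWHM)

(peak height over time-to-peak times full width at half maximum). The
iterative baselines (k-means, fuzzy c-means) depend on their random
initialisation and can return different AIFs on identical data; the
agglomerative hierarchy with average linkage is deterministic, so repeated
detections are bit-identical — its across-run variance ("robustness") is
exactly zero.

The package is aimed at perfusion-imaging researchers who want a tested,
reproducible reference implementation of clustering-based AIF detection and
of the standard synthetic benchmark for it (gamma-variate bolus with
recirculation, residue-function tissue kinetics, partial-volume mixtures,
magnitude-MR noise).

## Worked example

```python
from dscaif import compare_methods

df = compare_methods(snrs=(20.0,), seed=0)
print(df.round(4).to_string(index=False))
```

```
 snr method    pve    h_p  t_p   fwhm     auc   rmse      m  n_selected
20.0     ah 0.0000 4.4592 31.0 6.2958 55.3101 0.0000 0.0228           6
20.0 kmeans 0.7143 3.8552 33.0 7.4571 54.5084 0.4521 0.0157          21
20.0    fcm 0.7143 3.8552 33.0 7.4571 54.5084 0.4521 0.0157          21
 0.0   true 0.0000 4.4592 31.0 6.2958 55.3101 0.0000 0.0228           6
```

One SNR-20 realisation of the standard 1902-voxel benchmark (6 true
arterial, 16 false arterial, 1480 tissue, 400 partial-volume voxels). Each
row is one detector: `pve` is the fraction of non-arterial curves in the
cluster selected as arterial, `rmse` the error of the detected AIF against
the noise-free truth, and `h_p`/`t_p`/`fwhm`/`m` the shape of the detected
curve. Here the hierarchy isolates exactly the six true arterial voxels
(PVE 0, RMSE 0 — its curve coincides with the true AIF row), while both
baselines select the broader 22-curve arterial family, yielding a lower,
later, wider AIF. On other seeds the hierarchy's selection can include a few
delayed arterial look-alikes; see `docs/methods.md` for the across-seed
picture.

The estimators compose with scikit-learn idioms:

```python
from dscaif import AifDetector, build_dataset
from dscaif.evaluate import dataset_concentration

ds = build_dataset(seed=0)                    # synthetic signals + truth
conc = dataset_concentration(ds)              # −ln(S/S0)/TE, AIF units
det = AifDetector(method="ah").fit(conc.values)
det.aif_           # detected AIF curve
det.selected_mask_ # curves in the arterial cluster
```

A command-line interface wraps the same pipeline: `dscaif simulate`
(write a dataset or 4D NIfTI phantom), `dscaif detect` (curves CSV or a
4D NIfTI slice; clinical mode applies the AUC/roughness/partial-volume
filter chain first), `dscaif evaluate` (the comparison table above),
`dscaif repro` (repeated-detection robustness). Run any subcommand with
`--help` for options.

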