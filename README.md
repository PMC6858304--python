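# netquant

CNN-based classification and quantitation of neutrophil nuclear
morphologies in fluorescence microscopy, with spatial-clustering and
dose-response analysis, saliency visualisation, and a classical rule-based
baseline — validated end-to-end on a synthetic image generator with exact
ground truth.

## The problem

NETosis (cell death by Neutrophil Extracellular Traps) starts with
chromatin decondensation: a resting neutrophil's bright, multilobulated
nucleus swells into a sphere with a diffuse SYTOX stain. Quantifying a
treatment's NETotic response means classifying thousands of nuclei per
well into non-NETotic (class 1), NETotic (class 2) and everything else
(class 0), while *not* confusing NETosis with necrosis, whose hallmark is
the opposite change — chromatin condensed into bright clumps in a dim,
swollen body. netquant is for researchers who need those per-image counts
programmatically: fraction-NETotic readouts, EC50s of NETosis agonists,
and clustering statistics that distinguish signalling pathways
(ROS-driven, PMA-induced NETosis disperses; calcium-ionophore/PAD4-driven,
A23187-induced NETosis clusters).

## What is in the box

| module | contents |
| --- | --- |
| `netquant.synth` | synthetic 16-bit fields/patches with per-nucleus ground truth, a `difficulty` dial, treatment-subtype and point-process controls, 4PL dose-series simulation |
| `netquant.fieldio` | annotated-field container, TIFF+CSV round-trip, grid tiling |
| `netquant.patches` | 32x32 pixel-level patch extraction, morphological object detection, nearest-annotation labelling, stratified splits with a leakage guard, rotation/flip augmentation |
| `netquant.nn` | a small, deterministic numpy CNN engine and the four architectures: stage-1 patch classifier, stage-2 count regressor, phenotype classifier, densely connected object-level classifier |
| `netquant.quantify` | stride-1 class-score maps ((H-32) x (W-32) x 3), map-based counting, object-level counting |
| `netquant.evaluate` | confusion matrices, one-vs-rest precision/recall, Pearson count correlation with Fisher-z CIs |
| `netquant.spatial` | average nearest neighbor distance (ANND), Clark-Evans expectation, cell-count marginal matching, repeated two-sample KS comparison |
| `netquant.dose` | response normalisation, 4PL fitting, EC50 CIs and confidence bands |
| `netquant.baseline` | Isodata segmentation, area/border filtering, shape-threshold classification |
| `netquant.saliency` | guided backpropagation and guided Grad-CAM |

The core statistic for clustering is the **ANND**: the mean over cell
centres of the Euclidean distance to the nearest other centre, with CSR
expectation 1/(2&radic;&lambda;). Dose-response fits use the 4-parameter
logistic y = bottom + (top-bottom)/(1 + 10^((log10 EC50 - log10 x)·h)).

## Worked example

Counting nuclei in held-out synthetic fields with the object-level route
(`examples/03_count_nuclei_in_fields.py`, abridged):

```python
import numpy as np
import netquant as nq
from netquant.nn import TrainConfig, build_pl_stage1, train
from netquant.patches import extract_pl_patches
from netquant.quantify import count_by_objects

field = nq.render_field(nq.FieldSpec(height=128, width=160, n_nuclei=12,
                                     phenotype_fractions=(0.5, 0.5, 0.0),
                                     hardcore_distance=26.0, seed=2000))
# ... train `model` on patches from other fields, then:
result, objects = count_by_objects(field, model)
```

Running the full example prints, per field, lines like

```
synth_2003: predicted (5.0, 6.0) (truth (6, 6)), 55% NETotic
Pearson r (non_netotic): 0.919  95% CI (0.423, 0.991)
Pearson r (netotic): 1.000  95% CI (1.0, 1.0)
```

i.e. the detected-and-classified tallies per field, the NETotic
percentage, and across fields the correlation between predicted and true
counts per phenotype. The other scripts in `examples/` walk through field
rendering, patch-classifier training, spatial clustering (the clustered
condition's ANNDs are flagged with mean p = 3.9e-22 in the example run),
EC50 fitting (fitted 2.10 nM, 95% CI 1.82-2.43, truth 2.1 nM), saliency
maps and the rule-based baseline, each printing what its numbers mean.

A thin CLI mirrors the library for shell use:

```bash
netquant simulate --out well0 --seed 7 --n-nuclei 50
netquant annd --tiles tiles.csv --min-cells 20 --replicates 10 --seed 0 --out annd.json
netquant ec50 --csv doses.csv --out fit.json
```

Every command accepts `--seed` and a TOML `--config`.

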