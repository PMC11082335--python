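# csfpulse

Quantification of cerebrospinal-fluid (CSF) pulsation in the 4th ventricle
from conventional resting-state EPI fMRI, for neuroimaging researchers
studying CSF dynamics and brain clearance in neurodegeneration
(e.g. Parkinson's disease dementia risk).

## The measurement

In interleaved multislice 2D-EPI, anatomically adjacent slices are excited
a short interval apart — the *interTR* — rather than a full repetition
time TR. CSF that moves between the two excitations carries the
neighbouring slice's saturation history, so the signal ratio of an
adjacent slice pair placed on the 4th ventricle encodes the pulsed CSF
volume at every measurement *n*:

    CSFpulse(n) = (1/α − 1) · (S_i(n) / S_{i−1}(n) − 1) · ROIvolume

where `S_i`, `S_{i−1}` are the CSF ROI signals of the upper/lower target
slice, `ROIvolume` the CSF ROI volume, and α the saturation ratio —
the steady signal of CSF re-excited every interTR over that of static CSF
re-excited every TR:

    α = (1 − e^(−interTR/T1)) / (1 − e^(−TR/T1))

For the protocol this package targets (TR/TE/flip = 2000 ms/30 ms/90°,
31 × 4 mm slices, 2.75 mm in-plane, 160 dynamics, Philips interleaved
ascending order) the interleave step is `1 + ⌊√31⌋ = 6`, giving interTR =
322 ms for lower target slices 8–10 and 387 ms for 6–7, a captured
velocity range of 0–2.48 cm/s (or 0–2.06 cm/s), and α = 0.194 at
T1(CSF) = 4300 ms. Negative CSFpulse values (flow outside the capture
range, or descending) are clamped to zero; per subject the package reports
the mean clamped pulse (strength), the mean absolute z-score
(variability), and the positive ratio.

The package contains, as importable modules mirroring the analysis stages:
the excitation-schedule model (`acquisition`), a matrix-driven Bloch
spin-column simulator and the α calibration (`bloch`), intensity-threshold
ROI segmentation (`roi`), the pulsation metric (`metric`), group
statistics (`stats`), a 4D phantom and cohort generator (`synthetic`), and
a manifest/config pipeline with a `csfpulse` CLI (`pipeline`, `cli`).

## Worked example

Calibrate the pair, synthesise a pulsating phantom, and run the analysis:

```python
import numpy as np
from csfpulse import (AcquisitionProtocol, TissueParams,
                      interslice_interval, calibrate_alpha)
from csfpulse.synthetic import PhantomSpec, VelocityWaveform, generate_phantom
from csfpulse.roi import BoundingBox, segment_csf_roi
from csfpulse.metric import SliceSignals, compute_csfpulse_series

protocol = AcquisitionProtocol()          # TR 2000 ms, 31 slices, 160 dynamics
pair = interslice_interval(protocol, 8)   # target slices 8/9
cal = calibrate_alpha(protocol, TissueParams(), pair)

spec = PhantomSpec(
    waveform=VelocityWaveform(kind="sinusoid", amplitude_mm_s=5.0),
    noise_sd=0.01, seed=7,
)
img, truth = generate_phantom(spec)
data = np.asarray(img.dataobj, dtype=np.float64)
bbox = BoundingBox.parse(truth["suggested_bbox"])
rois = {i: segment_csf_roi(data[:, :, i - 1, 5:].mean(axis=-1), bbox,
                           voxel_volume_mm3=truth["voxel_volume_mm3"])
        for i in (8, 9)}
signals = SliceSignals(
    s_lower=data[:, :, 7, :][rois[8].mask].mean(axis=0),
    s_upper=data[:, :, 8, :][rois[9].mask].mean(axis=0),
)
series = compute_csfpulse_series(signals, cal, rois[9].roi_volume_mm3)
```

Printing the calibration, ROI and series fields gives:

```
interTR = 322 ms, capture range 0-2.48 cm/s
alpha = 0.1940 (closed_form)
ROI: 13 voxels = 393.25 mm^3
mean CSFpulse  = 49.91 mm^3 over 155 measurements
mean |z|       = 0.923
positive ratio = 0.503
ground truth   = 49.70 mm^3
```

The pair is excited 322 ms apart; the 13-voxel CSF ROI (30.25 mm³ voxels)
gives a 393 mm³ reference volume; over the 155 retained measurements the
estimated mean pulsed volume, 49.9 mm³, recovers the generator's ground
truth (49.7 mm³) to well within the noise level, with roughly half the
measurements ascending-positive, as expected for a zero-mean sinusoidal
waveform.

The same analysis is available from the shell:

```sh
csfpulse simulate --out cohort/ --seed 1          # 52-subject synthetic study
csfpulse run --manifest cohort/manifest.tsv --out results/
csfpulse calibrate --lower-slice 8                # alpha JSON
csfpulse response-curve --lower-slice 8 --out curve.tsv
```

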