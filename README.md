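# optofmri

Analysis tools for **block-design optogenetic fMRI (ofMRI)** experiments and
the electrophysiology that accompanies them. The package targets the
workflow used to map frequency-dependent recruitment of forebrain networks
by central thalamus stimulation in rat: light pulse trains delivered in a
fixed block design while whole-brain BOLD, zona incerta field potentials,
cortical spike trains and frontal EEG are recorded.

It provides, as importable library modules plus a thin `ofmri` command line:

- **`optofmri.fmri`** — per-voxel Fourier **coherence/phase** detection of
  block-locked BOLD responses, positive/negative polarity classification,
  ROI activation volumes, empirical HRF extraction, group averaging and
  paired volume comparisons.
- **`optofmri.ephys`** — field-potential preprocessing, the
  **spindle-like-oscillation (SLO)** amplitude-threshold detector,
  inter-event statistics, pulse- and train-aligned **PSTHs**, per-bin
  firing-rate change tests, and EEG band-power fractions.
- **`optofmri.optics`** — the fiber **light-cone model**: in-tissue beam
  divergence, intensity decay with depth (conical spread × Kubelka-Munk
  scattering), opsin-threshold penetration depth and excited frustum volume.
- **`optofmri.simulate`** — a seeded synthetic-data generator for all of the
  above, with ground truth, so every stage is testable without animal data.
- **`optofmri.stats`** — exact Wilcoxon signed-rank / rank-sum wrappers and
  family-wise corrections shared by the pipelines.

## The statistics at the core

For a voxel time series `x(t)` spanning `N` cycles of period `T` (six 60 s
cycles, TR = 0.75 s), expressed as percent modulation about a 30 s
pre-stimulation baseline and boxcar-detrended with a 1 min window, the
detection statistic is the **coherence** with the block frequency
`f0 = 1/T`:

    C = |X(f0)| / sqrt( Σ_{f>0} |X(f)|² )

where `X` is the DFT of the series (DC excluded). Voxels with `C > 0.35`
are significantly synchronized to stimulation; under Gaussian noise with
~470 degrees of freedom the Bonferroni-corrected p-value of that threshold
over a 128×128×23 imaging volume is below 10⁻⁹. The **phase**
`φ = −arg X(f0) mod 2π` encodes the temporal lag of the response: phases in
`[0, π/2] ∪ [3π/2, 2π)` are positive (activation) responses, the complement
negative (suppression). Activation volume in an ROI is the significant-voxel
count of one polarity times the voxel volume (0.125 mm³ at 0.5 mm
isotropic).

An **SLO** is counted at sample `i` of a 2 Hz high-pass-filtered field
potential when `|x(i)|` reaches `mean(|x|) + 6·SD`, no sample in the
preceding 500 ms did, and at least 2% of the samples in the following
500 ms do.

Light intensity below a fiber tip of core radius `r` diverging at half-angle
`θ = arcsin(NA/n)` in tissue of refractive index `n` is

    I(z) = P/(π r²) · ρ² / ((S z + 1)(z + ρ)²),   ρ = r/tan θ,

with Kubelka-Munk scattering `S = 11.2 mm⁻¹`; the penetration depth solves
`I(z) = I_thr` (1 mW/mm² for ChR2, 5 mW/mm² for eNpHR) and the excited
volume is the frustum `V = (π/3) d (R₁² + R₁R₂ + R₂²)`.

## Worked example

```python
import numpy as np
from optofmri import simulate, fmri, ephys, optics
from optofmri.protocol import make_protocol

protocol = make_protocol(10.0, 0.30)          # 10 Hz, 30% duty cycle
print("pulse width:", protocol.pulse_width_ms, "ms")

scene = simulate.GroundTruthScene(
    shape=(32, 32, 8),
    rois=(
        simulate.RoiSpec("thalamus", ((4, 12), (4, 12), (2, 6)), 2.0),
        simulate.RoiSpec("sensory_cortex", ((20, 28), (20, 28), (2, 6)), -1.5),
    ),
    noise_sd_percent=0.5,
)
ds, truth = simulate.gen_bold_dataset(scene, protocol, seed=1)
coh, phase, labels = fmri.analyze_bold(ds)
pos = fmri.activation_volume(labels, truth == 1, fmri.POSITIVE, ds.voxel_size_mm)
print(f"positive volume: {pos.volume_mm3:.3f} mm^3 ({pos.n_voxels} voxels)")

rec, events = simulate.gen_lfp(
    n_channels=1, n_trials=20,
    slo_spec=simulate.SloSpec(n_per_train=3, spacing_s=6.6, spacing_jitter_s=0.3),
    seed=2)
filt, fs = ephys.preprocess_lfp(rec.traces, rec.fs_hz, mode="slo")
det = ephys.detect_slos_recording(simulate.LfpRecording(fs, filt, rec.stim_window_s))
iv = ephys.slo_interval_stats(det)
print(f"SLOs: {len(det)} detected / {len(events)} injected; "
      f"interval {iv.mean_s:.2f} +/- {iv.sem_s:.2f} s")

fiber = optics.FiberSpec(core_radius_mm=0.03125, half_angle_deg=11.7, power_mw=2.5)
d = optics.penetration_depth(fiber)
print(f"light cone: depth {d:.2f} mm, volume {optics.excited_volume(fiber, d):.3f} mm^3")
```

prints

```
pulse width: 30.0 ms
positive volume: 32.000 mm^3 (256 voxels)
SLOs: 60 detected / 60 injected; interval 6.57 +/- 0.04 s
light cone: depth 1.05 mm, excited volume 0.078 mm^3
```

The 2% responder block occupies 256 voxels × 0.125 mm³ = 32 mm³ and is
recovered exactly at 0.5% noise; the three injected spindles per 20 s train
are all found, and their spacing matches the configured 6.6 s; the ChR2
fiber's 1 mW/mm² contour sits ≈1.05 mm below the tip, exciting ≈0.078 mm³
of tissue.

The same operations are available from the shell:

```sh
ofmri simulate --kind bold --config scene.json --seed 1 --out run/
ofmri analyze-fmri --bold run/bold.nii.gz --masks roi.nii.gz --out results/
ofmri optics --radius 0.03125 --half-angle 11.7 --power 2.5 --threshold 1.0
```

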