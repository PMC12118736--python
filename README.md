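# ironmap

Quantification toolchain for iron-sensitive molecular cardiac MRI with
MPIO (micron-sized iron-oxide particle) contrast agents, built around a
digital left-ventricle phantom.

Targeted molecular contrast agents — MPIOs functionalized against
P-selectin — bind in injured myocardium after ischemia/reperfusion and
locally shorten the effective transverse relaxation time T2*. The bound
iron is therefore quantified through the relaxation-rate increase
R2\* = 1/T2\*. `ironmap` implements the complete analysis chain used in such
experiments, for methodologists who want to validate the statistics on
ground-truth data before applying them to scanner output:

* **Phantom simulation** (`ironmap.phantom`) — a ring-shaped short-axis LV
  myocardium split into three angular coronary territories (LCX / LAD /
  RCA), ground-truth S0/T1/T2/R2\* maps, an MPIO-induced R2\* increment
  confined to one territory, and magnitude image series with Rician noise
  under multi-echo (TE = 2.4, 6.0, 9.5, 13.0 ms in vivo; 3.4, 9.8, 17.1 ms
  ex vivo), inversion-recovery (TI = 100…4500 ms) and T2-prepared
  (τ = 0, 30, 40 ms) schedules. Also: two-channel immunofluorescence
  images, particle track tables and bright-field spot fields.
* **Relaxometry** (`ironmap.relaxometry`) — pixel-wise parameter maps. The
  core fit is the offline T2\* computation: ordinary least squares of
  ln S against TE, R2\* = −slope; plus magnitude-IR T1 (signed model
  A(1 − 2e^(−TI/T1)) with polarity restoration) and log-linear T2-prep T2.
* **Territory statistics** (`ironmap.territory`) — per-territory
  ΔR2\* = R2\*(post) − R2\*(pre), the proxy for the amount of bound
  contrast, and the ex vivo count-ratio statistic: fit a normal
  distribution N(μ, σ²) to the histogram of R2\* over the whole LV
  myocardium, count pixels with R2\* > μ + 2σ per region, normalize by
  region area, and form the lesion/reference ratio.
* **Microscopy** (`ironmap.microscopy`) — P-selectin coverage with a
  remote-calibrated threshold (the 95th percentile of nonzero stain
  intensities in uninjured sections), MPIO spot counting per high-power
  field, and the incubation proximity binding rule.
* **Flow chamber** (`ironmap.flowchamber`) — dwell-time binding rule: a
  tracked particle is bound when it stays stationary ≥ 10 s within a 60 s
  observation of a 450 × 350 µm field.
* **CLI / pipeline** (`ironmap.cli`, `ironmap.pipeline`) — `ironmap`
  subcommands for every step plus seeded end-to-end runs with
  content-hash manifests.

## Worked example

Simulate a pre/post contrast experiment with a 40 s⁻¹ MPIO-induced R2\*
increase in the LCX territory, at noise σ/S0 = 0.02:

```python
import numpy as np
from ironmap import phantom, relaxometry, territory

schedule = phantom.AcquisitionSchedule(
    "multi_echo", times=(2.4, 6.0, 9.5, 13.0), noise_sigma=2.0)

pre = phantom.make_phantom((64, 64), seed=0)          # before MPIO injection
post = phantom.apply_mpio(pre, 40.0, "LCX")           # bound contrast in LCX

fit = relaxometry.fit_t2star
pre_map = fit(phantom.simulate_series(pre, schedule, seed=1),
              mask=pre.myocardium_mask)
post_map = fit(phantom.simulate_series(post, schedule, seed=2),
               mask=post.myocardium_mask)

report = territory.delta_r2star(pre_map, post_map, pre.territory_labels)
print(report.to_frame().round(2))
```

```
       pre   post  delta    n
LCX  33.57  72.97  39.40  556
LAD  33.50  33.55   0.05  556
RCA  33.36  33.19  -0.17  556
```

The baseline R2\* of 1000/30 ≈ 33.3 s⁻¹ corresponds to the phantom's
T2\* = 30 ms. The injected increment of 40 s⁻¹ is recovered in the lesion
territory (ΔR2\* = 39.4 s⁻¹ here), while the perfused-but-uninjured LAD and
the non-perfused RCA act as controls with ΔR2\* ≈ 0.

The same analysis from the shell:

```bash
ironmap run-invivo --seed 0 --out run/      # delta_r2star_report.json
ironmap run-exvivo --seed 0 --out exvivo/   # count_ratio_report.json
```

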