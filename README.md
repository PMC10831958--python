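# wavescan

Modular analysis of propagating slow-wave activity (< 1 Hz) on grid
recordings — multi-electrode arrays (ECoG) and wide-field calcium
imaging alike.  Slow waves are alternations between low-activity (down)
and high-activity (up) cortical states seen under anesthesia and in deep
sleep; they sweep across the cortical surface as travelling wavefronts.
`wavescan` is for experimenters and modellers who want comparable,
quantitative wave characterizations (velocity, direction, planarity,
interwave interval, wave modes) from heterogeneous recordings, plus a
synthetic-data generator with exact ground truth so every analysis stage
can be validated end to end.

## The analysis in brief

The pipeline has five stages, each built from interchangeable blocks:

1. **Data entry** — recordings live on a rectangular integer grid with a
   sampling rate (Hz) and inter-site spacing (mm); `check_input`
   validates the contract, HDF5 and CSV-bundle I/O round-trip it.
2. **Processing** (choose any, in any order) — detrend, zero-phase
   Butterworth band-pass, z-score, background subtraction, ROI
   selection, spatial downsampling, and logMUA estimation: the log ratio
   of 200–1500 Hz band power to full-spectrum power in a 0.3 s moving
   window (Welch PSD), a proxy for population firing.
3. **Trigger detection** (choose one) — per-channel down→up transition
   times via amplitude thresholds (fixed, two-Gaussian fit with the
   threshold at the central minimum, or low-state fit with
   mean + σ·SIGMA_FACTOR), via the analytic-signal phase crossing −π/2,
   or via local minima preceding a dominant peak.
4. **Wave detection** — triggers are clustered into wavefronts with
   DBSCAN in (x, y, t·ratio) space, where the TIME_SPACE_RATIO
   `v0 / (sampling_rate · spatial_scale)` makes a wave at the expected
   velocity isotropic; Horn–Schunck optical flow on the phase field
   supplies per-site propagation vectors; optional k-means on the
   trigger-delay matrix groups waves into modes.
5. **Characterization** — per channel and wave: velocity from the delay
   map T(x, y) as `v = 1/‖∇T‖` (mm/s, distributions capped at
   120 mm/s), direction from the flow vectors, planarity
   `P = ‖Σ v_i‖ / Σ ‖v_i‖ ∈ [0, 1]`, interwave intervals, Hedges'
   effect sizes and KDE summaries; emitted as a tidy CSV table.

## Worked example

```python
import numpy as np
import wavescan as wsc
from wavescan import workflows as wf

# five planar waves, 15 mm/s at 45 deg, on a 20x20 grid of 0.05 mm
# pixels sampled at 25 Hz, with additive noise
m = wf.planar_recovery_run(v0=15.0, theta=np.pi / 4, seed=1, noise_sd=0.05)
print(m["n_waves"], round(float(np.median(m["velocities"])), 2),
      round(float(np.median(m["planarity"])), 3))
```

prints

```
5 14.64 1.0
```

i.e. all five simulated waves are detected, the median channel-wise
velocity recovers the true 15 mm/s to within a few percent, and the
planarity of each planar wave is at the top of its 0–1 scale (a radial
wave from the grid centre instead yields P ≈ 0.04, because its outward
flow vectors cancel).

The same analysis from the shell:

```sh
wavescan simulate --pattern planar --v0 15 --n-waves 5 --seed 1 --out rec.h5
wavescan process rec.h5 --blocks detrend,band_pass_filter,zscore --out proc.h5
wavescan triggers proc.h5 --method hilbert --out trig.h5
wavescan waves trig.h5 --v0 15 --out waves.h5
wavescan characterize waves.h5 --variant channel --out table.csv
```

or as one configured run with profile-based config resolution and QC
plots: `wavescan run --config pipeline.yaml --profile mydata --out out/`.

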