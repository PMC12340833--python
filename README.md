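# adhesiondyn

Quantification of cell–substrate adhesion turnover from live-cell
fluorescence microscopy. Migrating amoeboid cells such as *Dictyostelium*
build transient, punctate adhesions that assemble, mature and disassemble
within tens of seconds; tagged adhesion components (e.g. GFP-paxillin)
make each adhesion visible as a diffraction-limited puncta whose intensity
time course reports its turnover. This package implements the full analysis
chain used to measure that turnover — per-frame puncta detection, particle
tracking with QC filters, kinetic curve fitting, two-channel colocalization
classification, FRAP (fluorescence recovery after photobleaching) analysis,
whole-cell migration speed, and the population statistics layer — together
with a synthetic-data generator that produces image stacks and FRAP traces
with known ground truth, so every stage is validated by parameter recovery.

It is written for microscopists and image analysts who want a scriptable,
reproducible replacement for interactive point-and-click pipelines.

## The quantities it measures

For each tracked adhesion with mean fluorescence intensity series
*I(t)* (baseline-subtracted, 3-frame running average):

- **Duration** — total number of frames the puncta is detected.
- **Assembly rate** *r_a* — steepness of the logistic fit
  *I(t) = A / (1 + e^(−r_a (t − t_a)))* over the rising half.
- **Disassembly rate** *r_d* — rate of the exponential-decay fit
  *I(t) = D·e^(−r_d (t − t_d))* over the falling half.
- **Lifetime** — the time the fitted intensity stays above half-maximum,
  *(t_d + ln 2 / r_d) − t_a*, in seconds.

For each FRAP trace, with relative fluorescence intensity
*RFI_t = (I_t − I_bg,t) / (I_pre − I_bg,pre)*:

- the exponential-plateau fit *RFI(t) = Y₀ + (P − Y₀)(1 − e^(−kt))* over a
  fixed postbleach window,
- the **recovery halftime** *t_1/2 = ln 2 / k*, and
- the **immobile fraction** *IMf = 1 − (FRFI_f − FRFI₀)/(1 − FRFI₀)*,
  with *FRFI₀*, *FRFI_f* the fitted curve at t = 0 and at the window end.

Track QC removes tracks touching the first or last frame and tracks of 8
frames or fewer; FRAP QC removes halftimes greater than the 45-s
acquisition and robust (ROUT, Q = 1%) outliers. Group comparisons use the
two-sided Wilcoxon rank-sum test (exact for small tie-free samples),
correlations use simple linear regression, and summaries are reported at
both the measurement level (n) and the biological-replicate level (N).

## Worked example

```python
import numpy as np
from adhesiondyn.simulate import SimConfig, FrapSimConfig, simulate_timelapse, simulate_frap_trace
from adhesiondyn.detect import detect_stack
from adhesiondyn.track import link_tracks, filter_tracks, duration
from adhesiondyn.kinetics import analyze_tracks
from adhesiondyn.coloc import classify_tracks
from adhesiondyn.frap import compute_rfi, fit_recovery, halftime, immobile_fraction

cfg = SimConfig(rng_seed=1)          # 240 frames, 0.75 s apart, 30 punctae
stack, truth = simulate_timelapse(cfg)
dets = detect_stack(stack.channel(0))
tracks = link_tracks(dets, max_disp_px=5.0)
kept, removed = filter_tracks(tracks, cfg.n_frames, min_frames=9)

table = analyze_tracks(kept, cfg.frame_interval_s)
ok = table[table.fit_ok]
labels = classify_tracks(kept, stack.channel(1))

trace, true = simulate_frap_trace(FrapSimConfig(k_true=0.35, immobile_fraction_true=0.6, rng_seed=1))
fit = fit_recovery(trace.times_s, compute_rfi(trace), window_s=20.0)
```

Output of the accompanying print statements:

```
45 tracks -> 30 kept after QC filters
kinetic fits ok for 17/30 tracks
mean duration   : 25.7 frames
median lifetime : 11.3 s
median assembly rate    : 0.734 1/s
median disassembly rate : 0.243 1/s
colocalization: 15/30 tracks channel-2 positive
FRAP: k = 0.376 1/s, t1/2 = 1.84 s (true 1.98), IMf = 0.602 (true 0.600)
```

The 45 raw tracks shrink to 30 after removing first/last-frame touchers and
short tracks; 15/30 channel-2-positive matches the simulated 50%
colocalized fraction exactly. The FRAP halftime and immobile fraction land
within a few percent of the generative truth. Note that rates fitted to
*detected* tracks are conditioned on the detection window — a track only
begins once the puncta clears the detection floor, exactly as with real
microscopy — so they are not expected to equal the generative rates
one-for-one; the recovery tests quantify the agreement that is achievable
(see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
adhesiondyn simulate timelapse --out stack.tif --truth truth.csv
adhesiondyn detect --stack stack.tif --out punctae.csv
adhesiondyn track --punctae punctae.csv --n-frames 240 --out tracks.csv
adhesiondyn kinetics --tracks tracks.csv --interval 0.75 --out kinetics.csv
adhesiondyn coloc --tracks tracks.csv --stack stack.tif --out tracks_coloc.csv
adhesiondyn simulate frap --k 0.35 --imf 0.6 --seed 1 --out trace.csv
adhesiondyn frap --traces trace.csv --window 20 --out frap.csv
adhesiondyn stats compare --table kinetics.csv --value lifetime_s --group fit_ok --out report.json
```

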