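# specklight

Wide-field, label-free imaging of tissue *stiffness* from dynamic laser
speckle, built for the tumour-localisation setting: a coherent source
illuminates the tissue surface, a camera records the reflected speckle
movie (e.g. 60 s at 100 fps, 9500 µs exposure), and the temporal
statistics of every pixel report how fast the underlying scatterers move.
Stiffer tissue (a tumour, or a locally fixed region used as a tumour
proxy) moves more slowly than healthy tissue, so the dynamics map is a
stiffness map.

`specklight` implements the three standard pixel-wise read-outs plus the
synthetic ground-truth machinery needed to validate them without any
experimental data:

- **DCS (diffuse correlation spectroscopy).** The normalized intensity
  autocorrelation of each pixel series,
  `g2(τ) = ⟨I(t)I(t+τ)⟩ / ⟨I(t)⟩²`, and the speckle decorrelation time
  τc read off as the 1/e point: `τc = argmin_τ |g2(τ) − [1 + (g2(0)−1)/e]|`.
  Slow (stiff) tissue → large τc.
- **ML-DCS.** A regressor trained on synthetic noiseless Brownian-motion
  speckle windows (10 s at 100 fps, τc ~ U(0, 2] s, 90:10
  train/validation split with a MAPE-based stopping rule) maps a single
  10 s window to τc; a 60 s stack yields six predictions per pixel which
  are averaged. Compared to the 1/e read-out at equally short
  acquisitions, the learned estimator trades a shrinkage bias for a much
  smaller per-pixel variance, improving lesion SNR.
- **Temporal LSCI (laser speckle contrast imaging).** The speckle
  contrast `K = σ/⟨I⟩` over a sliding 7-frame temporal window, averaged
  over all window positions. At short exposure, slow (stiff) tissue
  varies little within a window → *low* K.
- **Phantom simulator.** Per-pixel complex-Gaussian speckle with
  Ornstein–Uhlenbeck field dynamics, calibrated so that the 1/e read-out
  of the ideal curve returns exactly the requested τc
  (`g2 − 1 = β·exp(−τ/τc)`), with elliptical lesions, static-pixel
  support and an optional camera-noise model (shot noise, read noise,
  quantization).
- **ROI statistics.** Tumour ROI (polygon or mask), mirrored control ROI
  in the contralateral hemisphere, per-ROI summaries, single-image
  `SNR_T = μ_T/σ_T`, Welch's t with Satterthwaite degrees of freedom,
  and pre/post difference maps.

The library is the primary interface (`import specklight as sl`); a thin
CLI (`specklight simulate|dcs|lsci|lsci-sweep|mldcs-train|mldcs|stats|run`)
wraps it for shell use.

## Worked example

`examples/05_roi_statistics.py` simulates the standard lesion phantom
(64×64 pixels, 60 s at 100 fps; a 0.67 s-τc ellipse of ≈1000 pixels on a
0.39 s background), processes it with all three pipelines and compares
tumour vs mirrored-control ROIs:

```
tumour ROI: 1033 px; control (mirrored): 1033 px
modality   mu_C  sigma_C   mu_T  sigma_T  SNR_T      t          p
     dcs 0.3796   0.0996 0.6381   0.2003  3.186  37.11 9.933e-215
   mldcs 0.6625    0.116  0.962   0.1286  7.478  55.56          0
    lsci 0.3049  0.01607 0.2462  0.01797   13.7 -78.32          0
```

Reading the table: the DCS and ML-DCS maps are in seconds and place the
lesion *above* the control (slower, stiffer); the LSCI contrast is
dimensionless and places it *below* (less intra-window variation). Every
separation is overwhelmingly significant, and the single-image SNR
ranking (LSCI > ML-DCS > DCS) matches the experimentally reported
ordering for this contrast regime. The ML-DCS values sit above the
ground truth — the prior-informed regressor shrinks noisy short-window
estimates toward the middle of its training range, which costs accuracy
but buys per-pixel stability (hence its SNR advantage over DCS).

The other examples each demonstrate one capability: phantom simulation
and noise (`01`), DCS recovery and the ~100·τc acquisition-length rule
(`02`), the LSCI window-length sweep (`03`), and ML-DCS training with its
honest validation error (`04`).

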