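# hospect

Quantitative holmium-166 SPECT is the imaging backbone of ¹⁶⁶Ho-PLLA
radioembolization (TARE/SIRT) dosimetry, and its weak point is scatter:
roughly half of the counts in the 80.6 keV photopeak window come from the
downscattered 1.38 MeV gamma, which punches through any collimator, plus
the photopeak's own phantom scatter and a small bremsstrahlung floor.
`hospect` is a toolkit for studying how the two practical projection-space
corrections — the dual-energy-window (DEW, subtract `k`·W4 with `k = 1`)
and triple-energy-window (TEW, subtract the two narrow flanking windows
W1 + W3) methods — behave end to end: from a simulated multi-window
Jaszczak-phantom acquisition, through OSEM reconstruction, to contrast
recovery (CRC), contrast-to-noise (CNR) and local-dose-deposition (LDD)
compartment dosimetry with paired statistics.

It is aimed at medical physicists evaluating ¹⁶⁶Ho scatter-correction
protocols without access to a Monte-Carlo transport chain or a camera.

## The models in brief

* **Spectrum.** Each acquisition window (Table below) carries four
  components — 80.6 keV photopeak + associated scatter, high-energy
  scattered gammas, X-ray peak, bremsstrahlung — with configurable
  per-window fractions (packaged defaults reproduce a GATE-style
  decomposition, e.g. 48.7% high-energy share in W2 and 96.9% in W4).

  | window | bounds (keV) | definition |
  |---|---|---|
  | W1 | 68.56–74.56 | 71.56 keV ± 8.39% |
  | W2 | 74.56–86.65 | 80.6 keV ± 15.0% |
  | W3 | 86.65–92.65 | 89.65 keV ± 6.69% |
  | W4 | 112.0–124.0 | 118.0 keV ± 10.2% |

* **CRC (per sphere i)**: `CRC_i = (m_i/a_i) / (m_bg/a_bg)` with `m` the
  mean reconstructed value and `a` the true concentration; CRC curves over
  `x = diameter/FWHM` are fitted with `S(x) = 1/(1+e^{-b(x-c)}) - d`
  (plateau fixed at 1).
* **CNR (per sphere j)**: `|mean_j - mean_bg| / sd_bg`.
* **OSEM**: 10 iterations, 8 subsets, matched-adjoint rotation projector
  with attenuation; Butterworth (0.25 cycles/pixel, order 1.5) available
  for visualization.
* **LDD dose**: `D_v = A·(n_v/Σn)·κ/m_v` with κ = 15.87 J/GBq for ¹⁶⁶Ho.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from hospect.pipeline import run_phantom_study, StudyConfig

result = run_phantom_study(seed=1, cfg=StudyConfig(n_projections=64))
for method in ("scatter_free", "tew", "dew", "uncorrected"):
    print(method, round(result.mean_crc(method), 3), round(result.mean_cnr(method), 2))
```

prints (64³ grid, 4 mm voxels, 341 MBq phantom, 64 projections × 30 s):

```
scatter_free 0.252 8.46
tew 0.224 3.12
dew 0.176 3.62
uncorrected 0.115 3.15
```

Reading: the scatter-free reference recovers the most contrast; TEW gets
closest to it; DEW lands between TEW and no correction; and TEW pays for
its accuracy with the lowest contrast-to-noise ratio (its narrow 6 keV
side windows inject extra Poisson noise), exactly the qualitative
trade-off that motivates preferring TEW for quantification while watching
its noise penalty. The same pipeline is scriptable from the shell
(`hospect simulate|correct|reconstruct|metrics|dose|stats|run-all`, each
stage writing NIfTI/CSV/JSON artifacts with provenance sidecars).

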