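# quickdwi

Synthetic diffusion-weighted MRI (DWI) simulation and deep-learning-based
denoising, end to end on CPU with no deep-learning framework required.

The package simulates fast, noisy single-acquisition DWI (NOA 1) of
known-ground-truth phantoms, reproduces the clinical averaging scheme
(geometric mean over three orthogonal diffusion-encoding directions, then
arithmetic mean over repeated acquisitions → NOA 9), trains a U-Net-style
regression network (pure NumPy: analytic backprop, Adam, He init,
max-norm ≤ 3 constraint, MAE / MSE / combined MAE-SSIM losses) to map a
normalized NOA 1 image to the clinical-standard image, and quantifies the
result via monoexponential ADC fitting, ROI statistics (mean ADC, CoV,
RDM, MAVD), image-quality metrics (MSE / SSIM / PSNR) and paired Wilcoxon
signed-rank tests with Benjamini–Hochberg correction.

## Layout

| module | role |
| --- | --- |
| `quickdwi.phantom` | parametric 2D phantoms with true S0/ADC maps and lesion ROI masks |
| `quickdwi.acquisition` | Rician-noise acquisition, trace-weighted + NOA averaging, normalization |
| `quickdwi.dnif` | the denoising network: layers, losses (incl. SSIM with analytic gradient), training |
| `quickdwi.quantify` | log-linear least-squares ADC maps, ROI stats, RDM, MAVD |
| `quickdwi.evaluate` | MSE/SSIM/PSNR, Wilcoxon signed-rank + BH correction |
| `quickdwi.interface` | YAML config, NIfTI I/O, pipeline orchestration, CLI |

## CLI

Each stage is individually invocable on the previous stage's outputs;
`run` is their composition:

```bash
quickdwi simulate --config cfg.yaml --out work/
quickdwi average  --data work/
quickdwi train    --config cfg.yaml --data work/ --out work/model.ckpt.npz
quickdwi denoise  --model work/model.ckpt.npz --data work/
quickdwi quantify --data work/
quickdwi evaluate --data work/ --out work/report.json
quickdwi run      --config cfg.yaml --out work/   # everything, plus manifest.json
```

Configs are YAML (see `quickdwi.interface.config`); the `desk` profile is
a CPU-sized schedule (≤ 128×128, ≤ 5 epochs), the `paper` profile pins
the full-scale recipe (batch 36, 15 epochs, Adam lr 0.001).

## Notes

- All arrays are NumPy; training runs in float32 and is bit-reproducible
  for a fixed seed on a given platform.
- ADC is stored in mm²/s (multiply by 10³ for the usual display scale).
- NIfTI I/O via nibabel; stacks are exploded per (b, direction,
  acquisition) with a JSON protocol sidecar.
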