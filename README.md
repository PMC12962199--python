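# lungshim

Automated 2D lung B0 shimming toolkit. It simulates TR-shifted multi-echo
gradient-echo acquisitions of a coronal thorax phantom with ultra-short lung
T2* and structured off-resonance, and implements the full shimming chain:

1. **phantom** — ground-truth thorax phantom (proton density, T2*, ν, φ₀,
   lung mask, respiratory deformations) and the forward acquisition model
   `s_j = M0·exp(−TE_j/T2*)·exp(i(2πν·TE_j + φ₀)) + noise` with
   `TE_j = (j−1)·ΔT + TE₁`.
2. **preprocess** — non-rigid registration of all echo/repetition magnitude
   images to the reference frame (pyramidal TV-L1 optical flow), warping of
   the complex data (real/imaginary channels, never wrapped phase), and
   complex averaging across repetitions.
3. **segmentation** — classical lung segmentation (Otsu thresholds, hole
   filling, morphology, two largest dark components inside the body) with
   the same contract as a learned segmenter; external masks can be plugged
   in via `--mask`.
4. **fieldmap** — voxel-wise off-resonance from incremental echo phases
   `arg(s_j/s_1)` by linear least squares, plus per-voxel precision,
   residual RMS and a wrap guard; T2* estimation from log-magnitude decay.
5. **shim** — zeroth-to-second-order spherical-harmonic basis at y = 0
   (columns 3, 6, 8 identically zero and excluded), mask-restricted
   least-squares shim currents, residual-field prediction, and a
   plain-text shim configuration file (write → read → write is
   byte-identical).
6. **evaluate** — masked field statistics/histograms and the bSSFP
   steady-state off-resonance response with banding at ±n/(2·TR), odd n.
7. **pipeline/CLI** — `calcshim` (register → average → segment → map →
   solve → write config) and `adjustshim` (read config back).

## CLI

```bash
# simulate a phantom acquisition (NIfTI magnitude/phase pairs + JSON sidecar)
lungshim simulate --out sim/ --seed 1

# compute shim currents (from a simulated or user-supplied series)
lungshim calcshim --input sim/ --out shim/
lungshim calcshim --out shim/                 # simulate internally
lungshim calcshim --input sim/ --mask my_mask.nii --out shim/

# read a shim configuration file back
lungshim adjustshim shim/shim_config.txt

# field statistics + bSSFP banding report (JSON + PNG)
lungshim evaluate --field shim/fieldmap_nu_hz.nii --mask shim/lung_mask.nii \
    --residual shim/residual_nu_hz.nii --out eval/
```

All commands accept `--config config.yaml` (see `lungshim.PipelineConfig`
for the schema) and `--seed` for deterministic runs.

User-supplied data: a directory of `repNN_mag.nii`/`repNN_phase.nii` (or
`repNN_real.nii`/`repNN_imag.nii`) volumes plus a `series.json` sidecar with
`te_list_us`, `delta_t_us`, `n_reps` and the geometry block.

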