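# gliopred

How good does MRI data have to be before a mechanistic tumor-growth model
calibrated to it can be trusted? `gliopred` answers this question in
silico for a mechanically coupled, two-species reaction-diffusion model of
glioma growth and angiogenesis. It simulates coupled tumor/vasculature
dynamics in a synthetic two-tissue brain, degrades the resulting "imaging"
data to chosen signal-to-noise (SNR), spatial-resolution (SR) and
temporal-resolution (TR) levels, re-estimates the model parameters from
the degraded data by Levenberg-Marquardt, predicts forward to day 10, and
scores parameter recovery (percent error) and prediction accuracy (Dice,
Lin's concordance correlation coefficient) over the full 6 SNR x 3 SR x
3 TR experiment grid. It is written for computational-oncology and
image-based-modelling groups planning pre-clinical imaging protocols.

## The model

Tumor (N_t) and vasculature (N_v) volume fractions evolve with logistic
growth, self-diffusion and nonlinear cross-diffusion under a shared,
vasculature-dependent carrying capacity θ:

    ∂N_t/∂t = ∇·[D_t((1 − N_v/θ)∇N_t + (N_t/θ)∇N_v)] + k_t N_t (1 − N_t/θ)
    ∂N_v/∂t = ∇·[D_v((1 − N_t/θ)∇N_v + (N_v/θ)∇N_t)]
              + k_v N_v (1 − N_v/θ) d(x) − k_dv N_v (1 − d(x))

    θ(x,t) = θ_min + N_v (θ_max − θ_min)/N_v,thresh   (capped at θ_max)

Angiogenesis acts at the tumor rim and vessel regression in the core
through the normalized distance-to-periphery map d(x); the loss of core
vasculature collapses the local capacity and produces the necrotic core.
Tissue mechanics feed back on growth: the tumor-cell gradient loads the
brain as a linear elastic solid (∇·σ = λ_f ∇N_t, white matter G = 800 Pa,
gray 466 Pa) and the von Mises stress suppresses diffusion,
D = D_0 exp(−γ σ_vm). Four parameters are calibrated per tumor: D_t0,
D_v0, k_t, k_v. See `docs/methods.md` for assumptions, defaults and
numerical choices.

## Worked example

One in silico experiment at the middle resolution (0.063 mm³ voxels),
SNR 20, with imaging days 1/3/5 available for calibration:

```python
from dataclasses import replace
from gliopred import (central_parameters, ExperimentCondition, degrade,
                      calibrate, predict, dice, ccc)
from gliopred.study import StudyConfig, ground_truth_course

study = StudyConfig()
params = central_parameters()

truth, domain = ground_truth_course(params, voxel_volume=0.063, study=study)
cond = ExperimentCondition(snr=20, voxel_volume=0.063, tr_days=(1, 3, 5),
                           replicate_seed=7)
observed = degrade(truth, cond, replicate=0)

config = replace(study.calibration, true_parameters=params)
result = calibrate(observed, params, domain, config=config, seed=7)
forecast = predict(result, (observed.tumor(1), observed.vasculature(1)),
                   domain, horizon=10, solver=study.solver)
```

This prints (via the comparison loop in `analysis/`-style scripts):

```
D_t: true 0.0263  estimated 0.0266  error 0.99%
D_v: true 0.0100  estimated 0.0105  error 4.92%
k_t: true 0.4500  estimated 0.4468  error 0.71%
k_v: true 0.2500  estimated 0.2497  error 0.11%
day-10 tumor Dice: 1.000
day-10 tumor CCC:  1.000
day-10 vasc CCC:   0.997
```

Despite 5% multiplicative noise on every voxel of every imaging day, the
three well-identified parameters (k_t, k_v, D_t) return within 1% of
truth, and the ten-day forecast overlaps the noiseless ground truth almost
perfectly — the central finding this pipeline exists to quantify. D_v is
the model's known blind spot (its output sensitivity is negligible), so
its error runs higher at every noise level.

## The analysis

Numbered drivers under `analysis/` reproduce the study end to end; each
writes tidy CSV tables under `results/`:

| script | what it does |
|---|---|
| `01_build_cohort.py` | synthetic brain, seed lesion, 13-tumor parameter cohort |
| `02_ground_truths.py` | noiseless 10-day ground truths at the three resolutions |
| `03_degradation_checks.py` | noise-model and resampling sanity checks |
| `04_central_tumor_grid.py` | central tumor x 54 conditions x 5 replicates (~6 min) |
| `05_cohort_grid.py` | adds the high/low-proliferation corner variants (~17 min) |
| `06_summarize.py` | median ± IQR summary tables, trends by SNR |

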