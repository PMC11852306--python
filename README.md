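# bpci — cuff-less blood pressure with per-subject confidence intervals

`bpci` estimates systolic and diastolic blood pressure (SBP/DBP) from
synchronized photoplethysmogram (PPG) and electrocardiogram (ECG) waveforms,
and — unlike a point-estimate regressor — attaches a per-subject confidence
interval to every reading. It is aimed at researchers in physiological
monitoring who work with bedside-monitor waveform data (PPG, ECG and an
invasive arterial-pressure reference, typically at 125 Hz) and who need both
an accuracy figure *and* a calibrated statement of how uncertain each
subject's estimate is.

## The method

The pipeline runs in the order the data flows:

1. **Windowing** — a 20 s analysis window is cut from each record after a
   60 s settling period (2500 samples at 125 Hz). Records with reference
   pressures outside 70 < SBP < 200 and 40 < DBP < 150 mmHg are excluded.
2. **Dual-stage preprocessing** — stage 1: undecimated db8 wavelet
   decomposition to level 10, empirical-Bayes posterior-median shrinkage of
   details d1–d6 under a quasi-Cauchy prior, zeroing of d7–d10 and the
   approximation, then a zero-phase 0.5 Hz IIR high-pass. Stage 2: R peaks
   from a sym4 level-4 reconstruction keeping only d2+d3; PPG pulse feet,
   systolic peaks, max-slope and dicrotic-inflection points; 1.4 s
   beat-anchored segmentation (10–13 segments per window).
3. **Signal-quality index (SQI)** — three rhythm rules (extrapolated heart
   rate in 40–180 bpm, no inter-beat gap over 3 s, max/min interval ratio
   below 2.2) followed by adaptive template matching: each beat is
   correlated with the window's average beat; the window is `trusted` only
   if the mean PPG-pulse/QRS correlation reaches the threshold (0.8).
4. **Features** — 47 per-beat features: pulse arrival times
   (PAT1/2/3 = R peak → PPG peak / max-slope / foot, the transit-time
   proxies that carry the pressure signal, since higher pressure stiffens
   arteries, speeds the pulse wave and shortens transit), systolic and
   diastolic times and areas, widths at six amplitude fractions,
   derivative landmarks, intensity ratios, and spectral/statistical
   descriptors. Reference SBP/DBP come from per-beat ABP extrema.
5. **Weighted feature decision (WFD)** — a minimum-redundancy
   maximum-relevance (MRMR) ranking by mutual information, then 5-fold
   cross-validated gradient boosting (50 regression-tree stages, exact
   greedy splits minimising the weighted two-sided squared error) over
   every top-*n* prefix of the ranking; the prefix with the lowest mean CV
   MSE is the selected feature set.
6. **Gaussian-process regression (GPR)** — y = β(x)ᵀw + f(x) + ε with
   f ~ GP(0, k), k(x,x′) = σ_f² exp(−‖x−x′‖/η) (exponential kernel,
   standardized inputs). Θ = {η, σ², σ_f²} is fit by multi-restart
   quasi-Newton ascent of the log marginal likelihood with the basis
   weights profiled in closed form; predictions carry a posterior mean and
   variance.
7. **Per-subject intervals** — from each subject's ~10 segment-level
   estimates: the GPR predictive interval; a parametric bootstrap
   (Gaussian MLE redraws, column means, percentile interval); GUM-style
   expanded uncertainty U = K·√(u_α² + u_β² + u_γ²) with u_α = σ̂/√n and
   K = 2; and the central-limit interval μ̂ ± z·s/√n.
8. **Grading** — mean error (ME), SD, MAE; the AAMI/ESH pass rule
   (|ME| ≤ 5, SD ≤ 8 mmHg); BHS cumulative-percentage grades (A/B/C/D);
   Bland–Altman limits ME ± 2·SD.

Everything is testable offline: `bpci.synth` generates three-channel
records with known per-beat R times, pulse feet, SBP/DBP and a
PTT↔SBP coupling SBP = a − b·PTT, plus injectable artifacts.

## Worked example

```python
import numpy as np
from bpci import synth, pipeline

records = synth.generate_cohort(50, seed=7, bp_noise_sd=2.0)
result = pipeline.run_pipeline(records, pipeline.PipelineConfig(), seed=7)

s = result.sbp.stats
print(f"SBP  ME {s.me:+.2f}  SD {s.sd:.2f}  MAE {s.mae:.2f} mmHg  "
      f"AAMI {'pass' if result.sbp.aami_pass else 'fail'}  "
      f"BHS {result.sbp.bhs.grade}")
iv = result.sbp.subject_cis["subj-000"]["boot"]
print(f"subj-000 bootstrap 95% CI: {iv.lower:.1f}–{iv.upper:.1f} mmHg "
      f"(width {iv.width:.1f})")
```

prints

```
SBP  ME +0.48  SD 2.94  MAE 1.73 mmHg  AAMI pass  BHS A
subj-000 bootstrap 95% CI: 137.3–138.8 mmHg (width 1.5)
```

ME and SD are the bias and spread of the held-out-test errors against the
ABP reference (both well inside the AAMI limits of 5 and 8 mmHg); the BHS
grade summarises how many absolute errors fall within 5/10/15 mmHg; the
bootstrap interval is one subject's 95% CI built from that subject's
segment-level estimates.

The same flow is available from the shell:

```bash
bpci --seed 3 synth --subjects 10 --duration 85 --out recs
bpci --seed 3 features --in recs --out features.csv
bpci --seed 3 select  --features features.csv --target sbp --out sel.json
bpci --seed 3 train   --features features.csv --select sel.json --target sbp --out model.json
bpci predict --model model.json --features features.csv --out pred.csv
bpci ci --pred est.csv --out ci.csv        # per-subject intervals
bpci evaluate --pred ev.csv --out report.json
```

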