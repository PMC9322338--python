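# hp13c

Simulation and quantification tools for **hyperpolarized [1-¹³C]pyruvate
MRI** of the pyruvate → lactate / bicarbonate system, built around a
question that matters for sequence design in the brain: *what does exciting
(or saturating) the lactate resonance cost you in bicarbonate signal?*

Hyperpolarized magnetization is a non-renewable budget. Each
metabolite-selective excitation at flip angle α reads out `Mz·sin α` and
leaves `Mz·cos α`; T1 relaxation consumes the rest. When a
lactate→bicarbonate exchange route exists (as expected if glial lactate is
shuttled to neurons for oxidation), repeatedly saturating lactate with 90°
pulses also starves the downstream bicarbonate pool and biases the apparent
pyruvate→bicarbonate rate `kPB` low. The package is written for MR
physicists and kinetic modelers who want to simulate these trade-offs,
optimize flip-angle schemes, and test quantification pipelines on synthetic
paired experiments with known ground truth.

## Model

Longitudinal magnetization of the three detectable pools evolves between
excitations as a linear compartment system

```
dP/dt = u(t) − (1/T1P + kPL + kPB,direct)·P
dL/dt = kPL·P − (1/T1L + kLB)·L
dB/dt = kLB·L + kPB,direct·P − (1/T1B)·B
```

with `u(t)` the pyruvate supply (instantaneous bolus or gamma-variate) and
RF applied as discrete per-TR events (`signal = Mz·sin α`, `Mz ← Mz·cos α`),
which is exact at all flips including 90° saturation. Reference constants:
`kPL = 0.012 s⁻¹`, `kLB = 0.001 s⁻¹`, `T1(P/L/B) = 35/30/10 s`, TR 1 s,
240 excitations.

On top of the simulator:

* **flip_optimizer** — SNR surfaces and own-flip sweeps (SNR = summed noisy
  signal / SD of the final 10 noisy samples), plus a constrained scheme
  recommendation (maximize bicarbonate SNR subject to pyruvate/lactate SNR
  retention).
* **kinetics** — time-to-peak, gamma-variate bolus fits, and
  precursor–product rate fits (`dX/dt = k·P_meas(t) − r_eff·X`, with
  `r_eff = 1/T1 − ln(cos α)/Δt`), gated at SNR > 3.
* **synthetic_data** — paired 0°/90° lactate-flip image series (brain:
  16×16, 40 mm FOV, single slice, 40 points at 1.5 s, lactate→bicarbonate
  route on; body: 20×20, 80 mm, 3 slices, 1.95 s, route off) with
  per-subject bolus variability and recorded ground truth.
* **analysis_pipeline** — AUC maps, organ ROI AUC-SNR, gated kinetic fits,
  and paired crossover statistics (mean difference, t-based 95% CI,
  p-value).

## Worked example

Run a full synthetic brain crossover study (8 subjects, both arms each,
alternating order) and the matching body study:

```bash
hp13c run-study --protocol brain --n-subjects 8 --seed 11 --out report.json
```

prints

```
   brain    bicarbonate_auc_snr: diff +2.014 [+1.682, +2.347] p=1.92e-06 (n=8)
   brain                    kPB: diff +0.0008103 [+0.0007253, +0.0008954] p=4.09e-07 (n=7)
   brain                  ttp_s: diff -0.1875 [-0.6309, +0.2559] p=0.351 (n=8)
```

Read: sparing lactate (0° instead of 90°) raises the bicarbonate ROI
AUC-SNR by about 2 points (from ≈3.6 to ≈5.6 here) and the apparent kPB by
≈8×10⁻⁴ s⁻¹, while pyruvate delivery (time-to-peak) is unchanged — the
saturation effect is metabolic, not hemodynamic. One of the eight
saturated-arm subjects fell below the SNR-3 gate, hence `n=7` for kPB. The
same command with `--protocol body --n-subjects 5` gives null results in
heart, kidney and liver (all CIs cover 0), e.g.

```
   heart    bicarbonate_auc_snr: diff -0.04431 [-0.6451, +0.5564] p=0.848 (n=5)
```

because the body phantom has no lactate→bicarbonate route.

Library use mirrors the CLI:

```python
from hp13c import KineticParams, AcquisitionScheme, simulate_pools, summed_signal

params = KineticParams()                      # kPL 0.012, kLB 0.001, T1 35/30/10
scheme = AcquisitionScheme(TR=1.0, n_steps=240, flip_P=10, flip_L=15, flip_B=60)
tc = simulate_pools(params, scheme)           # unit bolus at t = 0
summed_signal(tc, "bicarbonate")              # -> 0.004722
```

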