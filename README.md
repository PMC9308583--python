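# medastac

Kinetic quantification of dynamic [11C]MeDAS brain PET — a tracer whose
binding to intact myelin basic protein makes its uptake a quantitative index
of myelin density, of interest for monitoring remyelination therapies in
multiple sclerosis.

The package implements the full quantification chain for a 60-min dynamic
scan with arterial sampling:

* **Arterial input function** — cross-calibration of the continuous
  whole-blood detector curve against manual samples, a Hill-type parent
  fraction PF(t) = 1 − a·tᵇ/(tᵇ + c) fitted to the measured fraction of
  unmetabolized tracer, and the metabolite-corrected plasma input
  C_p(t) = C_wb(t)·R(t)·PF(t).
* **Compartment models** — the reversible one-tissue model (1T2k) and the
  irreversible (2T3k) / reversible (2T4k) two-tissue models, each with a
  fractional blood volume V_B, fitted by bounded weighted nonlinear least
  squares.  The measured signal is C_pet = (1−V_B)·C_t + V_B·C_wb, with C_t
  the exact exponential-convolution solution evaluated as frame averages.
  Macroparameters: net influx rate K_i = K₁k₃/(k₂+k₃), volume of
  distribution V_T, binding potential BP_ND = k₃/k₄, each with delta-method
  %SE; AIC = n·ln(WRSS/n) + 2m for model preference.
* **Simplified estimators** — Patlak and Logan graphical analysis, the
  multilinear estimators MLAIR1 (K_i = −P₄/P₅) and MLAIR2 (K_i read directly
  as a regression coefficient), SUV over 40–50 and 50–60 min windows, and
  voxelwise parametric maps.
* **Study statistics** — %SE>25 reliability filtering, AIC preference
  tables, Pearson/OLS method comparison, GM-vs-WM t-tests with
  Kolmogorov–Smirnov and Levene gates, Mann–Whitney U lesion-vs-NAWM tests,
  and MRI-based lesion classification into black holes, demyelinated,
  partially myelinated, and remyelinated lesions.
* **Synthetic studies** — a generator producing complete cohorts (blood
  curves, manual samples, region and lesion TACs, lesion descriptors) with
  known ground truth, so every stage is testable without patient data.

## Worked example

```python
import medastac as m

schedule = m.parse_frame_schedule(m.DEFAULT_FRAMING)   # 26 frames, 60 min
inp = m.true_input_function()                          # synthetic arterial input

truth = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.02)
tac = m.model_tissue_curve("2T3k", truth, inp, schedule)

fit = m.fit_model(tac, inp, "2T3k")
print(f"Ki = {fit.macro.Ki:.4f} mL/min/cm3  (%SE {fit.se_percent['Ki']:.2f})")
print(f"MLAIR2 Ki = {m.mlair2(tac, inp).estimate:.4f}")
print(f"Patlak Ki = {m.patlak(tac, inp, tstar=20).estimate:.4f}")
```

prints

```
Ki = 0.1136 mL/min/cm3  (%SE 0.00)
MLAIR2 Ki = 0.1110
Patlak Ki = 0.1114
```

The nonlinear fit recovers the generating K₁k₃/(k₂+k₃) = 0.1136 exactly on
noiseless data; the two linearizations land within ~2% low because their
apparent K_i absorbs the (1−V_B) factor (here 0.98) plus a small residual
linearization bias.

A full synthetic study from the shell:

```bash
medastac simulate --seed 42 --out study/
medastac run --seed 42 --out results/
medastac sweep-tstar --tstar 15 --tstar 20 --tstar 30 --out sweep.csv
```

`medastac run` emits tidy CSV tables: per-region fits (rate constants,
macroparameters, %SE, WRSS, R², AIC), the AIC preference table, the
method-comparison table (r/slope/intercept per cohort), the GM-vs-WM test,
and the lesion-class-vs-NAWM statistics.

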