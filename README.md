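# fluorbind

Analysis of protein–ligand binding by steady-state fluorescence
spectroscopy, for spectroscopists and pharmacology groups who titrate a drug
into a protein solution and need the standard chain of derived quantities:

* **Stern-Volmer analysis** — F₀/F = 1 + Ksv[Q]; quenching rate constant
  k_q = Ksv/τ₀ (τ₀ = 10⁻⁸ s) and the static/dynamic mechanism call against
  the diffusion limit 2×10¹⁰ M⁻¹s⁻¹, with optional two-regime (two
  binding-site-class) fitting.
* **Modified Stern-Volmer** — F₀/(F₀−F) = 1/f_a + 1/(f_a·k_a[Q]): accessible
  fraction f_a and effective constant k_a, with an explicit flag (never a
  clamp) for unphysical parameters.
* **Double-log (Hill-type) plot** — log((F₀−F)/F) vs log[Q]: number of
  binding sites n and association constant K_A.
* **Conformation probes** — red-edge excitation shift (REES, 295/305-nm
  pair), synchronous-fluorescence F/F₀ slopes at Δλ = 15/60 nm
  (tyrosine/tryptophan channels), per-point red-shift tracking, and CD
  mean-residue-ellipticity plus secondary-structure deltas.
* **Resonance light scattering** — hinge regression locating the critical
  induced aggregation concentration (C_CIAC) with an F-ratio acceptance gate.
* **FRET** — overlap integral J, Förster radius R₀
  (R₀⁶ = 8.8×10⁻²⁵K²n⁻⁴φJ), efficiency E = 1 − F/F₀ and donor–acceptor
  distance r = R₀((1−E)/E)^(1/6).

A seeded synthetic-spectra generator (Gaussian emission bands that quench,
red-shift and carry configurable noise; acceptor absorption bands; RLS hinge
curves) makes every stage testable without instrument data, and a `click`
CLI (`fluorbind generate|fit|conformation|rls|fret|run|compare`) wraps the
library for shell use. Spectra are two-column CSVs; titrations are described
by a manifest CSV; see `docs/methods.md` for the models, assumptions and
numerical choices.

## Worked example

Fit a noiseless synthetic titration (protein band at 340 nm, drug titrated
0–8.33×10⁻⁶ mM, generating Ksv = 2.4×10⁵ mM⁻¹ with a linear red shift),
then detect an RLS onset and run the FRET chain:

```python
import numpy as np
import fluorbind as fb

cfg = fb.GeneratorConfig(
    band=fb.BandModel(shift_rate=2.4e5),          # nm per mM
    quencher_grid=np.linspace(0, 8.33e-6, 11),    # mM, first point 0
    mechanism="simple_static", ksv=2.4e5, unit="mM", seed=1,
)
series = fb.gen_quenching_titration(cfg)

sv = fb.stern_volmer_fit(series)
print("Ksv =", f"{sv.ksv:.6g}", sv.unit + "^-1",
      "| kq =", f"{sv.kq:.6g}", "| mechanism:", fb.quenching.classify_fit(sv))
dl = fb.double_log_fit(series)
print("n =", f"{dl.n:.4f}", "| log10 KA =", f"{dl.log_ka:.4f}")
print("lam_max shift =", f"{fb.red_shift_track(series).total_shift:.3f}", "nm")

curve = fb.gen_rls_series(3.7e-7, 100.0, 5e8, np.linspace(0, 1e-6, 21))
print("C_CIAC =", f"{fb.detect_cciac(curve).cciac:.4g}", "mM")

donor = fb.gen_emission_band(fb.BandModel(), (280.0, 420.0, 1.0))
acc = fb.gen_absorption_spectrum(
    "gaussian", dict(center=330.0, width=25.0, eps_max=2000.0), (250, 450, 1.0))
r = fb.fret_analysis(donor, acc, f=50.0, f0=100.0,
                     constants=fb.FretConstants(phi=0.14))
print(f"J = {r.j:.4g} cm^3 M^-1 | E = {r.e:.3f} | R0 = {r.r0:.3f} nm | r = {r.r:.3f} nm")
```

prints

```
Ksv = 240000 mM^-1 | kq = 2.4e+13 | mechanism: static
n = 1.0000 | log10 KA = 5.3802
lam_max shift = 1.999 nm
C_CIAC = 3.7e-07 mM
J = 2.113e-15 cm^3 M^-1 | E = 0.500 | R0 = 1.947 nm | r = 1.947 nm
```

The fit recovers the generating constant exactly (240000 mM⁻¹); k_q =
Ksv/τ₀ = 2.4×10¹³ mM⁻¹s⁻¹ = 2.4×10¹⁶ M⁻¹s⁻¹ is far above the diffusion
limit, so the quenching is static (ground-state complex formation); n ≈ 1
means one binding-site class, and for simple Stern-Volmer data K_A equals
Ksv (10^5.3802 ≈ 2.4×10⁵). The band red-shifts by ~2 nm over the titration
(a more hydrophilic tryptophan microenvironment). The RLS onset is recovered
at the generating 3.7×10⁻⁷ mM, and with E = 0.5 the donor–acceptor distance
equals the Förster radius exactly.

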