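# scatterkin

Global kinetic analysis of femtosecond time-resolved gas-phase x-ray
scattering, built around the 200-nm photofragmentation of 1,2-dithiane
(DT, C4H8S2) — the prototypical cyclic disulfide. A UV pump breaks the
S–S bond; a hard x-ray probe records difference scattering as the molecule
ring-opens, equilibrates between the open biradical and vibrationally hot
cyclic forms, and fragments into one-sulfur (FA) and two-sulfur (FB)
products over femtoseconds to nanoseconds.

The central observable is the percent-difference scattering map

    %ΔI(q, t) = 100 · [I_on(q, t) − I_off(q)] / I_off(q)
              = γ Σ_α S_α(q) F_α(t),

with q the momentum transfer, t the pump-probe delay, F_α(t) the relative
population of species α from a first-order reaction network, S_α(q) the
species-associated difference pattern, and γ the optical excitation
fraction. The package provides each stage as a library:

- **iam / structures** — rotationally averaged scattering of molecules and
  fragment mixtures via the Debye equation with Cromer–Mann atomic form
  factors; built-in approximate geometries for the dithiane reaction
  transients; percent differences.
- **kinetics** — the dithiane reaction network (and arbitrary first-order
  networks), solved analytically with Gaussian instrument-response
  convolution; equilibrium ratios and asymptotic product fractions.
- **globalfit** — `KineticGlobalFit`, a scikit-learn-style estimator doing
  multi-start variable projection: nonlinear search over rates (and γ)
  with patterns solved per-q by weighted linear least squares under a
  theory-informed prior that resolves the separable model's gauge
  degeneracies.
- **anisotropy** — simplified detector images with pump-induced P2
  alignment and their isotropic/anisotropic decomposition.
- **ensembles** — ensemble-averaged scattering of vibrationally hot species
  from geometry pools (multi-frame XYZ or a toy thermal sampler).
- **synthetic_data** — seeded end-to-end generator of %ΔI(q, t) maps with
  sealed ground truth, for parameter-recovery benchmarks.

It targets researchers analysing pump-probe x-ray (or electron) difference
scattering who want a transparent, testable reference implementation of
the species-associated-pattern global fit.

## Worked example

Generate a synthetic map under the nominal experimental conditions
(reference rates, γ = 4.5%, 238 fs cross-correlation, 0.1-point noise) and
fit it back:

```python
import warnings
from scatterkin import (ScenarioConfig, generate_map, default_dt_network,
                        KineticGlobalFit, FitConfig, CollinearityWarning,
                        asymptotic_fractions)

net = default_dt_network()
data, truth = generate_map(ScenarioConfig(network=net, noise=0.1, seed=1))
theory = {g: truth.patterns[m[0]] for g, m in net.groups().items()}
with warnings.catch_warnings():
    warnings.simplefilter("ignore", CollinearityWarning)
    fit = KineticGlobalFit(network=net, irf=truth.irf,
                           config=FitConfig(n_restarts=20, seed=0),
                           theory_patterns=theory).fit(data)
print(fit.result().summary())
print(asymptotic_fractions(net, fit.rates_))
```

prints

```
global kinetic fit
    k1 = (4.123e+12 +- 2.9e+04) /s   (1/k = 242.5 fs)
    k2 = (9.313e+11 +- 1.5e+04) /s   (1/k = 1074 fs)
   km2 = (3.063e+11 +- 4.6e+04) /s   (1/k = 3265 fs)
    k3 = (2.797e+12 +- 4e+04) /s   (1/k = 357.5 fs)
    k4 = (2.743e+12 +- 3.6e+04) /s   (1/k = 364.6 fs)
    k5 = (1.584e+10 +- 1.4e+04) /s   (1/k = 6.311e+04 fs)
    k6 = (2.588e+09 +- 1.8e+02) /s   (1/k = 3.864e+05 fs)
    k7 = (2.396e+09 +- 2.8e+02) /s   (1/k = 4.174e+05 fs)
  gamma = 4.493 % +- 0.000 %
  chi2/dof = 1.047  (20 converged restarts)
{'FA-2': 0.390..., 'FB': 0.610...}
```

Reading the output: the ring-opening step is recovered at 242.5 fs
(generated with 240 fs) and the excitation fraction at 4.49% (generated
4.5%); the ± values are spreads over the 20 random restarts, which all
converged to the same optimum (χ²/dof ≈ 1 at the injected noise). The
fitted rates imply ~61% of molecules end in the two-body C4H8 + S2 channel
and ~39% in the three-body channel.

The same pipeline is available from the shell:

```bash
scatterkin simulate --seed 5 --out map.txt
scatterkin fit --map map.txt --seed 1 --out report.txt
scatterkin patterns --xyz my_structure.xyz --reference --out pattern.txt
```

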