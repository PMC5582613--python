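# meiqxkin

Kinetic ensemble modeling of the balance between **bioactivation** and
**detoxification** of MeIQx (2-amino-3,8-dimethylimidazo[4,5-f]quinoxaline,
the most abundant heterocyclic aromatic amine in cooked meat) in human
hepatocytes.

MeIQx is metabolised in the liver along competing routes: CYP1A2 either
C8-hydroxylates it (detoxification) or N-hydroxylates it into the reactive
HONH-MeIQx intermediate (bioactivation, toward DNA-adduct-forming esters),
while UGT glucuronidates both the parent and the intermediate.  The package
implements an 8-species ODE model with Michaelis–Menten kinetics in which
the limited CYP1A2 and UGT pools are *partitioned* between their competing
reactions by distribution coefficients α and β — either constants
("saturation" hypothesis) or decreasing sigmoids of the instantaneous
MeIQx concentration, φ(a,b,θ,n,S) = a·θⁿ/(θⁿ+Sⁿ) + b with n = 5
("dose-dependent" hypothesis).

The model is calibrated to a published hepatocyte experiment (metabolite
concentrations 24 h after 1, 10 and 50 µM MeIQx) by multistart
trust-region χ² minimisation on log concentrations.  Because the data
constrain the parameters only up to a family of equally good fits, all
fits passing the goodness gate (p ≥ 0.999) and biological plausibility
filters form an **ensemble**, and predictions — dose sweeps,
bioactivation/detoxification ratio curves, metabolism times, CYP1A2
perturbations, parameter sensitivities — are made with the whole family.

Audience: systems-toxicology and pharmacokinetics researchers studying
procarcinogen metabolism, and anyone needing a worked example of ODE
ensemble modeling with enzyme-pool competition.

## Worked example

```python
import meiqxkin as mk

# 1. the packaged HL-1 calibration table -> 48 records
obs = mk.hl1_dataset()

# 2. the balance quantities implied by the measurements alone
from meiqxkin.dataset import balance_records_from_observations
for r in balance_records_from_observations(obs):
    print(f"dose {r.dose_uM:>4} µM: detox {r.detoxification_uM:g} µM, "
          f"bioactivation {r.bioactivation_uM:g} µM, ratio {r.rounded_ratio()}")
```

prints

```
dose  1.0 µM: detox 0.69 µM, bioactivation 0.26 µM, ratio 0.377
dose 10.0 µM: detox 6.1 µM, bioactivation 2.5 µM, ratio 0.41
dose 50.0 µM: detox 16 µM, bioactivation 5 µM, ratio 0.313
```

i.e. at every tested dose roughly a quarter to a third as much MeIQx ends
in the potential-genotoxic pool as in excretable conjugates, with the
worst (highest) ratio at the intermediate 10 µM dose.

Fitting both hypotheses and predicting with the accepted ensemble
(≈13 min on one CPU at the 200-start study profile):

```python
from meiqxkin.fitting import fit_multistart, filter_fits
from meiqxkin.analysis import dose_sweep, perturb_cyp1a2

sat = fit_multistart("saturation", obs, n_starts=200, seed=1000003)
dd  = fit_multistart("dose_dependent", obs, n_starts=200, seed=1)
print(sat[0].chi2, sat[0].p_value)   # 15.663  0.985  -> gate failed
print(dd[0].chi2, dd[0].p_value)     #  7.393  0.9999 -> gate passed

ensemble = filter_fits(dd, obs)      # 30 accepted models
sweep = dose_sweep(ensemble)         # 12 doses x 180 h
pert = perturb_cyp1a2(ensemble, 0.1) # CYP1A2 knocked down 10-fold
print(pert.summary["percent_bioactivated_mean"].round(1).tolist())
# [9.6, 8.4, 2.8]   at 1, 10, 100 µM
```

Only the dose-dependent partition law explains the measurements — fixed
α, β cannot reconcile the dose-dependent product pattern — reproducing the
model-selection verdict of the source analysis.  The fitted ensemble
predicts detoxification dominating (>50 % of dose) at every dose from
0.05 to 100 µM, a non-monotone bioactivation/detoxification ratio peaking
at intermediate doses (median argmax ≈ 5 µM at 24 h), and a collapse of
bioactivation to under 10 % of the dose when CYP1A2 is reduced 10-fold —
CYP1A2 abundance is the key lever on the balance.

A command-line interface mirrors the library
(`meiqxkin prepare|fit|filter|sweep|perturb|sensitivity|synth|run-all`);
`meiqxkin run-all --seed 7 --n-starts 200 --out-dir out/` writes ensemble
JSON, balance/ratio CSV tables, a model-selection report and a manifest
with config hash and per-stage seeds.

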