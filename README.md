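# gutpkpd

Population pharmacokinetic/pharmacodynamic modelling of how intravenous
antibiotics perturb the diversity of the human gut microbiota.

Antibiotic residues reaching the colon disturb the resident bacterial
community.  This package links, within one nonlinear mixed-effects
framework, (i) plasma and fecal antibiotic kinetics in healthy volunteers
on a 5-day IV course (ceftriaxone, piperacillin/tazobactam,
ceftazidime/avibactam, plus oral moxifloxacin), (ii) the kinetics of an
activated-charcoal adsorbent (DAV132) that binds antibiotic in the distal
gut, and (iii) the loss and recovery of 16S Shannon diversity, and then
uses the fitted models in Monte-Carlo trial simulations to rank
antibiotics by their impact on the microbiota.  It is written for
pharmacometricians and microbiome researchers who want a fully scripted,
reproducible version of this analysis chain with a synthetic-trial
generator standing in for the clinical data.

## Models

**Antibiotic PK.**  Two-compartment disposition (one-compartment with
first-order absorption for oral moxifloxacin) with first-order
elimination.  Central elimination is split: a fraction `f_gut` feeds a
chain of `n` transit compartments (rate `k_t`, n = 3–4) emptying into a
fecal compartment (rate `k_f`).  With stool production fixed at
F_w = 200 g/day, the measured fecal concentration is the excretion flux
per unit stool:

    C_fecal(t) = k_f · A_fecal(t) / F_w        [µg/g]

**Charcoal and adsorption.**  DAV132 reaches the distal gut through an
Erlang chain, dAf_charc/dt = kt·Aa3 − kf·Af_charc; free antibiotic is
bound at rate `k_ads · Af_charc · A_free` and removed from the free pool.

**Diversity PD.**  The Shannon index SI = −Σ pᵢ log₂ pᵢ (singletons
removed) follows an indirect-response model whose loss rate is stimulated
by the free fecal concentration C_f:

    dSI/dt = R_in − k_out·(1 + Emax·C_f/(EC50 + C_f))·SI,   R_in = SI0·k_out

**Statistics.**  y_ik = f_k(θ_i, t) + ε, θ_i = µ·exp(b_i), b_i ~ N(0, Ω)
diagonal, residual sd σ_inter + σ_slope·f, and left-censored (BLOQ)
observations contribute Φ((LLOQ − f)/sd) to the likelihood.  Estimation is
SAEM (Metropolis-within-SAEM, simulated-annealing variance caps, Louis-
identity standard errors); the marginal likelihood is computed by
importance sampling, model choice by corrected BIC, and model checking by
IWRES/NPDE/VPC.  PK is fitted first; empirical-Bayes fecal predictions are
carried into the diversity fit (fecal concentration 0 in controls).

## Worked example

Simulate 1000 virtual subjects on a 5-day piperacillin/tazobactam course
(parameters drawn from the asymptotic distribution of the population
estimates, plus interindividual variability) and summarize the
pharmacodynamic impact indices:

```bash
gutpkpd simulate --drug TZP --duration 5 --n 1000 --seed 7 --out results/demo
```

prints

```
TZP 5d (n=1000): nadir 21.5% | AUC0-42 -11.8 SI.day | t95 15.7 d
wrote simulation outputs to results/demo
```

i.e. the median virtual subject loses 21.5% of baseline Shannon diversity
at the nadir, accumulates −11.8 Shannon-unit·days of diversity change over
the 42 days after treatment start, and (among subjects whose diversity
drops below 95% of baseline) needs 15.7 days after the last dose to
recover to 95% of baseline.  `summary_TZP_5d.csv` adds quartiles and
10th/90th percentiles per index — e.g. fecal C_max median 30.3 µg/g
[IQR 15.9; 60.7] — and `per_subject_TZP_5d.csv` holds every virtual
subject, from which all summaries can be recomputed.

The same library surface is scriptable: `generate_trial` creates a
synthetic trial with known ground truth, `SAEMFitter` /
`fit_sequential_pkpd` estimate the PK and PD models, `npde`/`vpc` check
them, and `run_scenarios` sweeps drugs × treatment durations.

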