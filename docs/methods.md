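# Methods

## Structural model

Six states describe one subject: SC depot, central and peripheral drug
amounts (nmol), free IL13 concentration (nM, central reference space),
and central and peripheral complex amounts (nmol). With
C = A_c/V2 and Ccx = A_cx/Vcx:

    dA_depot/dt = −Ka·A_depot
    dA_c/dt     = Ka·A_depot − (CL'/V2)·A_c − (Q/V2)·A_c + (Q/V3)·A_p
    dA_p/dt     = (Q/V2)·A_c − (Q/V3)·A_p
    dC_il13/dt  = Kin − Kout·C_il13 − Kon·C·C_il13            [+ Koff·A_cx/V2]
    dA_cx/dt    = Kon·C·C_il13·V2 − CL'·Ccx − Q·Ccx + Q·A_cxp/V3   [− Koff·A_cx]
    dA_cxp/dt   = Q·Ccx − Q·A_cxp/V3

with CL' = CL·(1 + θ_ADA·ADA). The complex is produced centrally, cleared
with the drug's apparent clearance referenced to its own volume Vcx, and
distributes with the drug's Q and V3. Drug equations ignore mass loss to
binding: the model is fitted sequentially and the target is in vast molar
deficit (~0.1 pM baseline against nM-range drug), so consumption is
negligible. Bioavailability is fixed at 1; all parameters are apparent (/F).

**Dissociation terms (bracketed) are off by default.** This was the one
genuinely open structural choice: the schematic fixes the compartments but
not the volume bookkeeping of the binding fluxes. With the published rate
constants, a fully reversible mass-action formulation leaks the accumulated
complex back through the fast-degrading free pool (Kout = 180/day destroys
most of what Koff releases whenever Kon·C is not ≫ Kout), and the single-dose
105 mg simulation then peaks at only ≈37 pM total complex with free IL13
bottoming at ≈0.006 pM. The irreversible "mass transfer" capture instead
reproduces all three published simulation behaviours simultaneously — total
complex approaching the balance value Kin·V2/CL ≈ 0.11 nM (≈100 pM), a
detected-assay rise of a few pM at FR ≈ 4.3%, and free IL13 suppressed below
0.01 pM — and is the default. KD = Koff/Kon is retained as the affinity
summary, and `dissociation=True` switches the reversible variant on (it is
exercised by the mass-balance and equilibrium-limit tests; the free/bound
ratio converges to KD/C only in that variant). Mole conservation of the
binding subsystem holds in both.

The no-drug steady state C_il13 = Kin/Kout (all other states zero) is the
initial condition: healthy volunteers, no prior drug.

Single-dose mean profiles are presented as population means: with log-normal
IIV of 46–154 %CV the mean curve runs well above the typical-subject
(median) curve — ≈90 pM vs ≈76 pM peak total for 105 mg — and mean-over-IIV
is the form in which such model predictions are overlaid on pooled
dose-group data.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| Ka | 0.156 | 1/day | SC absorption rate |
| CL/F | 0.441 | L/day | apparent clearance (drug and complex) |
| V2/F, V3/F | 2.83, 8.03 | L | central / peripheral drug volumes |
| Q/F | 0.825 | L/day | intercompartmental clearance |
| Kin | 0.0173 | nM/day | IL13 production (central reference) |
| Kout | 180 | 1/day | IL13 degradation (t½ ≈ 5.5 min) |
| Kon, Koff | 138.24, 0.69 | 1/(nM·day), 1/day | binding constants (fixed; KD ≈ 5 pM) |
| Vcx/F | 13.6 | L | apparent central complex volume |
| FR | 0.0429 | — | fraction of complex the PD assay detects |
| θ_ADA | 0.717 | — | fractional CL increase, ADA-positive |

IIV (%CV, log-normal): CL 53.3, V2 72.7, V3 46.2, Q 69.6, Kout 57.1,
FR 154. Residual error: PK proportional 13% + additive 0.0546 µg/L
(= 3.64·10⁻⁴ nM at 150 kDa; the µg/L reading of the printed value is
adopted and documented in the fixture); PD proportional 6.9% *of the
log-prediction* — the observation equation multiplies the natural log of
the detected concentration by (1+ε), which is unusual (error magnitude
grows with |log y|) but is followed as specified. CV% for log-normal
quantities uses 100·√(exp(ω²)−1).

All of these live in `src/il13pkpd/data/medi7836_reference.json` together
with their bootstrap 95% intervals.

## Synthetic trials

`generate_trial` emulates the first-in-human single-ascending-dose design:
cohorts of 6 at 30/105/300/600 mg SC plus 8 placebo (randomised 6:2 per
dose level), 281-day follow-up. Sampling days — the exact inpatient
schedule is not machine-readable from the protocol figure — are fixed at
PD {0,1,3,6,8,10,15,29,43,57,85,113,169,225,281} and PK
{1,2,3,6,8,10,15,29,43,57,85,113,169,225}, giving exactly 15 PD samples
per subject and 14 PK samples per active subject, matching the reported
per-subject averages (14.9 and 13.9). Persistent post-baseline ADA
positivity is Bernoulli(2/3) in active subjects and 1/8 on placebo;
baseline ADA status is generated (50%/25%) but, like in the source
analysis, unused by the model. Weight is log-normal matched to the
reported median and IQR (76.5 kg, σ_log = 0.337), age uniform on 18–50,
race drawn at the reported overall frequencies. FR draws above 1 (≈0.2%
of subjects at 154 %CV) are capped at 1. Individual trajectories are
integrated with the full ODE system; residual errors are then applied at
the sampling days. Everything is driven by one seeded generator:
a seed reproduces the dataset byte-for-byte.

What the generator does **not** emulate: dropout, dosing-time deviations,
assay LLOQ censoring (none was reported; a hook exists but defaults off),
time-varying ADA titres, and any model misspecification — so passing
recovery tests demonstrates estimator correctness under the stated model,
not robustness to real-data pathologies. The `corrupt_swap` utility
re-creates the one pathology the source data did show (two subjects'
PD series apparently exchanged) for exercising outlier workflows.

## Estimation

Sequential: the PK data fix the disposition model, then the PD stage runs
with each subject's empirical-Bayes PK parameters as the forcing function
(the "IPP" variant of sequential fitting). Kon and Koff stay at their
in-vitro values throughout.

The estimator is MAP-EM (iterative two-stage) with a Laplace marginal
likelihood:

* E-step: per-subject MAP ηᵢ (BFGS for the 4-dim PK problem; a nested 1-D
  search for the 2-dim PD problem, exploiting that the basis solve depends
  only on η_Kout), finite-difference curvature H, posterior covariance
  2H⁻¹, and the Laplace −2 log marginal contribution.
* M-step: typical values of IIV parameters by re-centring the η ensemble
  (clearance re-centred per ADA group, which also updates θ_ADA); variances
  by the shrinkage-corrected moment ω² = mean(η̂² + V_post); fixed effects
  without IIV (Ka; Kin and Vcx) and residual SDs by nested conditional
  searches. If a variance collapses to its floor (noise-free data) the
  η-re-centring channel freezes, so the typical values are then updated by
  direct conditional optimisation instead.

OFV values are internal to this approximation; only differences between
nested fits are interpreted (χ², p<0.05 → 3.84 at df 1).

Two numerical hazards are handled explicitly:

* **Flip-flop optima.** SC antibody data admit local optima in which Ka
  trades places with a disposition rate constant and Q collapses; these fit
  the pooled curve deceptively well but bias V2 badly, which would corrupt
  the PD stage. The PK EM therefore runs from two deliberately different
  generic starts and keeps the lower-OFV solution.
* **The (Kin, Kout, FR) ridge.** The data pin the baseline Kin/Kout and the
  detected-complex scale FR·Kin strongly, but the absolute level along
  (s·Kin, s·Kout, FR/s) only through the weak competition between capture
  (Kon·C) and degradation (Kout) at moderate drug levels. The PD stage
  searches this direction explicitly each iteration (conditional on the
  etas) and, after convergence, refines it by a profile over the full
  Laplace OFV with per-subject MAP re-optimisation at each candidate scale.

PD-stage cost stays desk-scale because the PD subsystem is linear in Kin
(one unit-production solve per (subject, Kout, Vcx) serves every candidate
Kin and FR) and FR enters only the observation equation. The FR typical
value is estimated on the log scale; if an estimate escaped [0,1] a
logit-bounded reparameterisation is engaged and logged (not observed in
practice).

The nonparametric bootstrap resamples subjects with replacement, stratified
by dose group to preserve the design balance (a choice; unstratified is
available), refits the PK stage and reports percentile intervals; replicate
failures are dropped and the result is flagged if they exceed 20%.

## Numerical choices

ODE integration: LSODA, rtol 1e-8 / atol 1e-12 for reference trajectories
(states span 1e-5 nM to 1e3 nmol and Kout = 180/day against complex
turnover ≈ 0.03/day is genuinely stiff); the estimation path integrates the
3-state PD subsystem against the closed-form (triexponential) drug
concentration at rtol 1e-6, verified against the full system to ~5e-4
relative. Doses are instantaneous depot additions with solver restarts.
The triexponential guards the degenerate Ka ≈ α,β case by a relative 1e-7
perturbation. Monte-Carlo population means use antithetic η pairs.
Variance floors: ω² ≥ 1e-6, residual SDs ≥ 1e-4 (proportional) — degenerate
noise-free fits stay finite. Eta excursions during line searches are
clipped at |η| ≤ 20.

Problem sizes in the shipped tests and the acceptance script (chosen to
keep a laptop run comfortable): population means over 400–1000 subjects,
VPCs with 150–500 replicates, recovery studies over 3–5 synthetic trials
of the full 32-subject design with EM capped at 20 (PD) / 60 (PK)
iterations.

## Known limitations

* The irreversible-capture default means the model is not thermodynamically
  closed at the dissociation step; it is the formulation that reproduces the
  published fitted behaviour, not a micro-kinetic claim. The reversible
  variant is one flag away and its single-dose peak is ≈2.7× lower.
* TV(Kout) — and through the ridge, Kin and FR — is weakly identified by
  design-sized data; single-trial estimates scatter ±40% even at the truth,
  which is why recovery is assessed by medians over replicate trials
  against the published bootstrap intervals.
* OFV magnitudes are not comparable with other estimators' likelihood
  approximations, and the reported shrinkage (1 − SD(EBE)/ω) is one of
  several conventions.
* ADA is a time-constant binary; transient titre dynamics are out of scope.
* Sequential fitting with empirical-Bayes PK forcing (the IPP variant)
  propagates PK EBE shrinkage into the PD stage: with true per-subject PK
  the FR estimator is unbiased to within a few percent, while EBE forcing
  attenuates it by roughly ten percent relative on design-sized trials.
  This is a recognised trade-off of sequential methods; replicate-trial
  medians are used wherever FR recovery is summarised.
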