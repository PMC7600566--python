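# Methods

This note documents the model as implemented: its structure, assumptions,
the provenance of defaults, numerical choices, and the boundaries of what a
green test establishes.

## Compounds and units

Four monoprotic bases are modelled: selegiline (SEL, the dosed parent),
methamphetamine (MAP) and desmethylselegiline (DMS) as primary metabolites,
and amphetamine (AMP), formed from both. Hydroxy-amphetamine (the other 60%
of MAP's hepatic clearance) is a tracked sink, not a modelled compound.
Bookkeeping is molar throughout — amounts in nmol, volumes in L, time in h —
with pg/mL conversion (numerically `nmol/L × MW`) only at the reporting
boundary. All kinetics are linear; dose linearity and superposition are
exact properties of the equations and are used as regression oracles.

## Plasma protein binding

SEL binds two proteins with one site each in the non-saturable regime
(therapeutic concentrations are pg/mL, many orders below K_D):

    fu = 1 / (1 + [MG]/2.2 µM + [Alb]/95 µM)

The macroglobulin dissociation constant 2.2 µM and albumin 95 µM are fitted
literature values; the default healthy albumin of 624 µM (≈41.5 g/L at
66.5 kDa) is a package constant chosen so that healthy fu ≈ 0.107, matching
the tabulated 0.10. Metabolites use their tabulated fu by default; an
explicit albumin-binding option (used in special-population runs) derives a
single-protein K_D from the healthy fu and recomputes fu from the sampled
albumin, reproducing the direction and approximate magnitude of the
tabulated impaired-population fu shifts (e.g. DMS 0.47 → ≈0.62 in severe
cirrhosis).

## Dermal absorption

The patch releases by a first-order law (default k = 0.04 h⁻¹, the fitted
in-vivo rate; zero-order and Higuchi laws are available for model
discrimination). Released drug enters the stratum corneum (SC), discretised
into 12 sublayers of a two-phase composite: a continuous lipid "mortar"
(10% volume) through which longitudinal diffusion occurs with effective
diffusivity D_SC,Lip/τ², and corneocyte "bricks" whose aqueous phase
equilibrates instantaneously with the lipid (partition = K_lip:v) and binds
keratin with finite rates (k_on = 78.8 h⁻¹, k_off = 0.93 h⁻¹, so K_b ≈ 85).
Viable epidermis and dermis are single well-stirred layers with
binding-corrected diffusivities; a parallel sebum conduit carries the
follicular fraction (0.001 of area). Dermis-to-blood transfer is
Q_dermis·(C_dermis/K_D:b − C_venous,blood), i.e. blood-flow-limited with
back-partitioning when coupled to the systemic model; local dermal blood
flow apportions 5% of cardiac output over 1.8 m² of skin to the patch area.

Every absorption parameter comes from QSARs on logP, MW and pKa. Three
transcription ambiguities in the source QSARs were resolved as follows and
verified against the reference estimates for SEL:

* dermis:blood — the 0.9993 exponent applies to K_ow in numerator **and**
  denominator (reproduces 2.44);
* molecular radius — sphere-equivalent radius at effective density 1 g/cm³
  in Å (4.20 Å for SEL), which reproduces D_SC,Lip = 3.22×10⁻⁵ cm²/h
  within 1%;
* the keratin off-rate formula cannot be reconciled with its own reference
  value, so k_off is formula-pluggable with default 0.93 h⁻¹ and
  k_on = k_off·K_b always; at the default SC surface pH of 6.8 the K_b QSAR
  then reproduces k_on = 78.8 h⁻¹ within 1%.

Site physiology (SC 17 µm, VE 100 µm, dermis 1.2 mm, back of torso, surface
pH 6.8) are design constants: the source model's values are unpublished.
The single calibrated constant is the SC tortuosity, set once to 5.9 so that
a 20 mg/20 cm² patch worn 24 h delivers 30% of its load systemically (the
labelled ≈6 mg/24 h), and frozen. Sublayer count 12 is convergence-tested
(<1% change at 24). No vehicle evaporation, cutaneous metabolism, or
wash-off at removal (the skin depot keeps absorbing; unreleased patch
residual is discarded and ledgered on replacement).

## Clearance

Hepatic clearance is enzyme-resolved by retrograde IVIVE: the tabulated
systemic clearance net of renal (CL_iv − CL_R) is inverted through the
well-stirred model at the healthy reference physiology (Q_H 89.30 L/h, liver
1650 g, MPPGL 40 mg/g, reference CYP abundances) into per-pmol intrinsic
clearances per enzyme pathway; the percent not assigned to any CYP (0.02%
for SEL, 100% for AMP whose enzymology is not tabulated) is carried as a
residual intrinsic clearance scaling with liver weight × MPPGL only. Each
virtual subject's whole-liver CLint re-sums these against their own
abundances, making the fraction metabolized by pathway — and hence
metabolite formation — genotype- and population-dependent.

Basis convention: the printed retrograde equation normalises terms by the
blood:plasma ratio, but the tabulated forward clearances only reproduce with
the plasma-basis well-stirred form. CLint is therefore stored on the plasma
basis by default (the round trip then recovers CL_iv − CL_R to 1e-9); the
blood-basis form is available. Renal clearance scales proportionally with
the subject's GFR ratio against the healthy reference ratio 0.99.

## Distribution and the whole-body system

SEL and MAP use full perfusion-limited PBPK (venous/arterial blood, lung and
12 tissues); DMS and AMP use one-compartment disposition at their tabulated
Vss (they sit near 4–5 L/kg where full PBPK adds nothing). Tissue:plasma
partition coefficients for the bases follow the standard mechanistic
composition method (extracellular water; intracellular water with the
ionized fraction at pH 7.0; acidic-phospholipid binding of the cation with
an association constant back-calculated from blood-cell partitioning via
B/P, fu and hematocrit; neutral lipid/phospholipid partition of the neutral
species). The embedded composition table is the conventional published set,
not the proprietary simulator's; predicted SEL Vss is 9.72 L/kg vs the
tabulated 9.26 (+5%), and a global Kp scalar pins Vss exactly for runs.

Hepatic and renal elimination are implemented as extraction of organ inflow
(E_H = CL_H/(B:P·Q_H)), which makes the systemic plasma clearance equal the
well-stirred value exactly, independent of the partition coefficients — so
AUC = Dose/CL and AUC_met = fm·Dose/CL_met hold analytically and anchor the
engine tests. Formed metabolites enter their systemic pool mole-for-mole
with **no sequential hepatic first pass**; this is the convention the
metabolite AUC identity requires. Its one visible consequence: the secondary
metabolite needs two conversions and so has the smallest first-day exposure
under repeated dosing, giving AMP the *largest* accumulation ratio
(AR(AMP) > AR(MAP) > AR(DMS) > AR(SEL)); a simulator that first-passes
liver-formed metabolites orders MAP first instead. The steady-state
metabolite-to-parent ratios are unaffected.

## Virtual populations (the synthetic-data generator)

Each subject is a reproducible draw (population, n, seed) of: sex, age, body
weight (log-normal, sex-specific); cardiac output and liver weight scaling
allometrically (exponent 0.75) with extra log-normal variability; MPPGL and
GFR ratio; macroglobulin (sex-specific tabulated means/CVs per population);
albumin (mean with a mild age decline, matching the assumption that the
macroglobulin age/sex shape follows albumin's); and per-enzyme CYP
abundances, log-normal around phenotype-multiplied means (CYP2D6: 89% EM,
8% PM with zero expression, 3% UM at 2×). All log-normals are
mean-parameterised so sample means converge to preset means.

Population presets carry the tabulated physiology means exactly (healthy CO
350.19 L/h, Q_H 89.30; SRI 268.79/71.82; CP-C 299.67/70.88; adolescent
333.70/89.59; GFR ratios 0.99/0.16/0.47/1.05). CYP abundance means, CVs,
phenotype frequencies and the impairment multipliers are *not* published for
the source simulator; the shipped values are package defaults, with
impairment multipliers set from the tabulated intrinsic-clearance ratios
(e.g. SRI ≈ 0.31–0.36× across the enzymes driving SEL/MAP/DMS). What a
green population test establishes is therefore directional and scale
fidelity (ratios, orderings, windows), not agreement with the proprietary
population library; tabulated population-mean CLint values for MAP/AMP are
additionally not recoverable from the printed inputs at all (they are
nonlinear population averages self-consistent only with the printed forward
clearances) and are never asserted.

The generator also synthesises observed-like profiles (multiplicative
log-normal error of chosen CV, mean 1, plus an optional additive floor) for
parameter-recovery tests. It does not emulate: assay quantification limits,
sparse clinical sampling schedules, dropout, or inter-occasion variability.

## Trials and statistics

A simulation is 10 virtual trials of n subjects; the reported prediction is
the mean of trial means and the predicted SD is the SD across trial means.
NCA uses the linear trapezoid on the dense grid (no log-tail — profiles are
simulator output); accumulation ratio is AUC(last interval)/AUC(first);
%Fe is the cumulative urinary amount as a percent of the molar dose. The
evaluation statistics are SD ratio = √(CV_obs²+CV_pred²)·(mean_pred/mean_obs),
AFE = 10^mean(log₁₀ ratio) (bias) and AAFE = 10^mean(|log₁₀ ratio|)
(precision), with 0.5–2 and 0.67–1.5 fold windows. For
population-vs-population comparisons (both arms simulated) the SD-ratio
formula is applied symmetrically with the reference arm in the "observed"
slot. Metabolite-to-parent AUC ratios use a 168 h window so the slow
metabolites' AUC is essentially complete; at 48 h the MAP ratio is
truncation-dominated.

The patch release-rate fit minimises squared residuals of the predicted
parent profile over log₁₀k ∈ [−4, 0] (bounded scalar search), using a
reduced simulator (parent-only one-compartment disposition + the dermal
model at 6 SC sublayers) for speed; a relative RMSE above 10% of the
observed peak flags a poor fit, which is how non-first-order release data
are discriminated.

## Numerics

Stiff-capable LSODA with rtol 1e-8, atol 1e-10 nmol, output grid 0.1 h
(0.25 h in scaled-down tests). Because the whole system is linear with
piecewise-constant switching (infusion on/off, patch wear/removal,
replacement), integration proceeds per dosing segment with the constant
Jacobian extracted once per segment by probing the right-hand side with unit
vectors; the solver then holds linear invariants to roundoff, which is why
molar mass balance closes to ~1e-14 relative (asserted at 1e-6).
Concentrations are clipped at zero only at the reporting boundary.
Degenerate inputs (zero CV, empty metabolism scheme, zero follicular
fraction) are supported and tested; infeasible inputs (systemic clearance
exceeding hepatic blood flow, organ extraction ≥ 1) raise validation errors
naming the offending values.

## Known limitations

* No oral route or gut first pass; no drug–drug interactions; no
  pharmacodynamics (MAO-B inhibition).
* Metabolism is exclusively hepatic; no extrahepatic or cutaneous
  metabolism.
* No sequential first pass of liver-formed metabolites (see above).
* Dermal constants beyond the QSARs are calibration-backed design constants;
  absolute dermal layer concentrations should not be over-interpreted.
* Population constants are re-implemented defaults, not the proprietary
  library; absolute special-population exposures carry that uncertainty even
  where directional contracts hold.
* No pediatric (<12 y) ontogeny, pregnancy, or ethnicity-specific
  populations; geriatric physiology is healthy physiology with age-declined
  cardiac output and GFR.
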