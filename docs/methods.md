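# Methods

This note documents the models implemented in `doxopbpk`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the package's numerical conventions and known limitations.

## 1. Middle-out derivation (`doxopbpk.derive`)

The derivation inverts a training cohort's clinical summaries into the
drug-specific inputs of a PBPK simulation.

**Blood/plasma referencing.** The blood:plasma concentration ratio is
stored as R_B:P = 1.15 (blood:plasma). Binding and clearances are mapped
between references by division: fu_b = fu_p / R_B:P = 0.25/1.15 ≈ 0.2174
and CL_b = CL_p / R_B:P. The same ratio converts simulated blood
concentrations to the reported plasma concentrations.

**Renal clearance.** refCL_R = CL_R · GFR_ref / eGFR with GFR_ref
defaulting to 121 mL/min (a healthy 20–30 y.o. male). eGFR comes from
either (A) a decade table of expected GFR per 1.73 m², scaled by the
subject's BSA — the shipped table (121, 114, 106, 97, 89, 79, 68 mL/min
per decade from 20 to 90 y) is editable and pinned by unit tests — or
(B) the creatinine formula (6580 − 38.8·age)·BSA·(1 − 0.168·SEX)/SCr with
SCr in µmol/L; unknown sex averages the male and female values. At
simulation time the inverse mapping individualises renal clearance,
CL_R,subject = refCL_R · GFR_subject / GFR_ref, applied as a linear
elimination pathway. Active tubular secretion of DOX is deliberately not
modelled, so renal clearance scales purely with GFR.

**Hepatic clearance.** The well-stirred liver model
CL_H,b = Q_H · fu_b · CLu_int / (Q_H + fu_b · CLu_int) is inverted
per patient with Q_H = 0.2675 · CO (sex-averaged hepatic fraction of
cardiac output; 0.255 male / 0.280 female when sex is known) and
CO = BSA·60·(3 − (age − 20)/100) L/h. The inversion is exact (property-
tested to 1e-10) but undefined for extraction ratios ≥ 1: such patients
are excluded from the cohort with a logged reason, mirroring the
exclusion rule of the source analysis.

**Route split and IVIVE.** Whole-liver intrinsic clearance is split as
f_bile/(1 − f_e) = 0.40/(1 − 0.11) ≈ 44.94 % biliary, remainder
metabolic. (f_e is fixed at the published 11 %; the derivation also
reports the cohort's mean per-patient CL_R/CL_P ratio, which in general
differs slightly because a mean of ratios is not a ratio of means.)
Scaling between whole-liver L/h and in vitro units is
CLu_int,whole = CLu_int,per-unit × LW × {HPGL | MPPGL | CPPGL} × 6e-5,
an exact round trip. Metabolic clearance is either kept per 10⁶
hepatocytes (method C) or distributed 37 % microsomal / 60 % cytosolic /
3 % hepatocyte (method D), reflecting that the two-electron reductases
(AKR/CBR) are cytosolic and the one-electron pathway microsomal; methods
C and D rescale to identical whole-liver totals by construction.

**Averaging.** All quantities are derived per patient and then averaged;
the report carries mean, SD and CV%. Applying the cohort-mean model back
to heterogeneous patients carries a systematic bias (Section 6).

## 2. Virtual population (`doxopbpk.population`)

Subjects are sampled per trial group from seeds spawned off the study
seed (group-level parallelism cannot change results). Ages are uniform in
the study range; sex is Bernoulli(female fraction); weight is log-normal
(mean 70 kg, CV 15 %); height is normal per sex (176 ± 7 / 162 ± 6 cm);
BSA follows Du Bois. All continuous covariates are truncated at ±3 SD.
CO and Q_H follow the formulas above; subject GFR uses the decade table
with the subject's BSA; blood volume is 70 mL/kg.

**Liver scaling factors.** Defaults are liver weight 18.3 g/kg body
weight, HPGL 99×10⁶ cells/g, MPPGL 35 mg/g, CPPGL 78 mg/g. All are
within literature ranges for adult (and notably cancer) populations, and
they are chosen as a mutually consistent set: the population-mean IVIVE
products (LW×HPGL ≈ 1.25×10⁵, LW×MPPGL ≈ 4.4×10⁴) equal the products
implied by the reference drug's own paired whole-liver and per-unit
clearances, so that scaling down during derivation and back up during
simulation is an unbiased round trip for a typical subject. They are
ordinary configurable constants in `PopulationConstants`.

## 3. Distribution models (`doxopbpk.partition`, `doxopbpk.engine`)

**Minimal PBPK (method E).** Systemic pool ⇄ single adjusting
compartment (SAC) at flow Q_sac, liver in series on Q_H with well-stirred
elimination, renal elimination from the systemic pool. The systemic pool
is 0.5 L/kg — blood plus rapidly equilibrating extracellular water — not
blood alone: the fitted V_sac values of the reference configuration
(≈31.3–31.5 L/kg against Vss 31.923 L/kg) imply a systemic pool of
≈0.4–0.5 L/kg, and the identity V_sac ≈ Vss − (systemic + liver) volumes
only holds with this choice. V_sac and Q_sac are plasma-referenced
configuration values (converted internally to the blood reference).

**Full PBPK (method F).** Venous blood → lung → arterial blood feeding
13 perfusion-limited tissues in parallel; gut and spleen drain into the
liver together with the hepatic artery (6.5 % CO artery, 3 % CO spleen,
portal remainder of the subject's hepatic flow). Tissue volumes are a
standard L/kg table; the residual "rest" compartment absorbs leftover
flow and volume (muscle composition). Tissue:plasma partition
coefficients use the mechanistic composition-based model for ionisable
drugs: partitioning into extra-/intracellular water with pH-dependent
ionisation (pH 7.4 plasma, 7.0 cells, 7.22 blood cells), neutral
lipid/phospholipid terms, and — because DOX carries a basic centre with
pKa 8.94 — electrostatic association of the cation with tissue acidic
phospholipids, with the association constant back-calculated from the
blood:plasma ratio (haematocrit 0.45). A single fitted Kp scalar (5.3119
in the reference configuration) multiplies every tissue Kp; with the
shipped composition table this yields Vss ≈ 22.4 L/kg. The published
configuration reports 34.8 L/kg from a proprietary composition baseline,
so the scalar is carried as reference configuration rather than refit,
and predicted exposures are insensitive to this difference at the
windows used (AUC changes <3 % across Vss 15–35 L/kg).

**Dosing.** "IV bolus" doses are zero-order infusions over the stated
administration time (2 min for the training dose, 1 min for the
validation bolus, 8 h for the infusion arm), avoiding Dirac artefacts.

## 4. Numerics

The compartmental systems are linear and time-invariant between infusion
edges, so the engine propagates them segment-by-segment with augmented
matrix exponentials — exact to machine precision, unconditionally
stable, and deterministic. Propagators are cached per (step, input-rate)
pair; a 100-subject trial on the default 10,000-point/168 h grid runs in
a few seconds. Mass balance (compartments + elimination sinks vs
delivered dose) is checked at every output time with a 1e-6 relative
tolerance (observed closure is ~1e-12); a test cross-checks the
propagator against an adaptive stiff integrator (LSODA, rtol 1e-10).
AUC uses the linear trapezoid (on a 10,000-point grid the log-linear
variant differs negligibly, and the linear rule is deterministic and
additive); window endpoints are interpolated. Cmax is the grid maximum;
the default grid step (~1 min) resolves the shortest infusion.
Population summaries are pointwise means and empirical (linearly
interpolated) 5th/95th percentiles; population AUC and Cmax are means of
per-subject values, not metrics of the mean curve.

## 5. Estimation and synthetic data

`estimate.fit` minimises squared residuals between the simulated and an
observed profile over V_sac/Q_sac (minimal model) or the Kp scalar (full
model), in log-parameter space within bounds, from several log-uniform
starts (the first start is the deterministic mid-bounds point). The
default objective is log-residual SSE because concentrations span more
than two orders of magnitude over a week; a linear objective is
available. Non-convergence is reported, never silent. The representative
fitting subject has population-mean covariates, since one parameter set
is fitted per model, not per subject.

The synthetic training study draws cohorts in the source ranges (ages
42–72, mean CL_P 51.75 L/h CV 18 %, mean f_e 11 %) and generates
profiles from a three-compartment mammillary model (V1 0.5, V2 3 L/kg,
Vss 31.923 L/kg; Q 150/40 L/h), i.e. tri-exponential curves whose
closed-form AUC equals Dose/CL exactly. The validation studies use a
two-compartment model (V1 0.3 L/kg, Vss 20 L/kg — the validation study's
reported steady-state volume) with rich 5–240 min sampling plus
peak/trough samples, three daily doses, and exact zero-order-infusion
kinetics for the 8-h arm. Noise is proportional log-normal (default CV
15 %); samples below the 1 ng/mL quantification limit are censored and
counted. A flag appends an engineered patient with hepatic extraction
1.05 to exercise the exclusion path.

What the generator does **not** emulate: assay-specific error structure
(additive + proportional), sparse/irregular real-world sampling times,
covariate correlations beyond height/weight/BSA, disease effects on
binding or secretion, and metabolite kinetics. Passing recovery tests
therefore demonstrates internal consistency of the pipeline, not
fidelity to any real patient data.

## 6. Design choices and limitations

- **Mean-model bias.** The well-stirred inversion is convex in hepatic
  clearance, so the cohort-mean intrinsic clearance over-weights
  high-extraction patients; applying the mean model to a heterogeneous
  cohort under-predicts the mean AUC by ~5–10 % at CL CV ≈ 18 %. The
  derivation/simulation inverse property is exact per patient and is
  tested per patient.
- **Minimal-model Cmax.** The predicted peak after a 1–2 min injection
  is controlled almost entirely by the systemic pool volume, which is a
  topology convention; minimal-model Cmax values are therefore
  indicative only. The robust qualitative feature — full-PBPK peaks
  exceed minimal-PBPK peaks under these regimens — is asserted in tests.
- **Renal transport.** Observed DOX renal clearance exceeds GFR,
  implying active secretion; the GFR-only scaling used here knowingly
  ignores it, matching the source analysis.
- **B:P ratio** originates from rat data; human values may differ.
- **Metabolic split** (37/60/3 %) quantifies qualitative enzymology and
  is configurable.
- **Problem sizes.** Simulated trials use 10 groups × 10 subjects on a
  10,000-point grid, the study design the package reproduces; tests use
  smaller cohorts and coarser grids where the property under test does
  not require the full design.
- Out of scope: metabolite (doxorubicinol/doxorubicinone) kinetics,
  liposomal/nano-formulations, drug–drug interactions with
  co-administered agents, permeability-limited or intracellular-binding
  distribution submodels, and population (mixed-effects) estimation.
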