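# osmosim: model description and design notes

## Scope and intent

osmosim is a reduced-order, deterministic model of short-term (minutes to
~36 h) water and sodium homeostasis in a resting adult.  It trades the
breadth of large integrative physiology engines for a state vector small
enough to audit by hand (23 states, of which 7 are bookkeeping
accumulators), an analytically constructed steady state, and bitwise
reproducible runs.  It is not a chronic blood-pressure model: pulsatile
hemodynamics, autonomic heart-rate control, regional circulations,
potassium and acid–base balance, and renal pressure–natriuresis beyond the
TGF/aldosterone pathway are out of scope.

## Body-fluid compartments

Total body water (fraction 0.60 of body mass; 44.4 L at 74 kg) is split
into intracellular (2/3 of TBW), interstitial and plasma water (plasma is
20.3% of extracellular water), plus a gastrointestinal lumen.  Sodium is a
single extracellular pool; intracellular osmoles are a fixed lumped
quantity (potassium and organic osmolytes), so cell volume responds to
extracellular tonicity only — no transmembrane solute fluxes are modelled.
Serum osmolality is `2[Na] + osm_offset` with `osm_offset = 8 mOsm/kg`
fixed non-sodium osmoles, calibrated so 140 mmol/L maps to 288 mOsm/kg;
none of the packaged protocols perturb urea or glucose.  mOsm/kg and
mOsm/L are treated as numerically identical (plasma water ≈ 1 kg/L).
Red-cell volume is constant, making hematocrit a pure plasma-volume proxy,
which is exactly how the dehydration literature uses it.

Water exchange:

* **Cell membrane** — `J = k_osm (Osm_icf − Osm_ecf)` with
  `k_osm = 0.01 L/min per mOsm/kg`, giving an intracellular equilibration
  time constant of ~3.5 min.
* **Capillary** — Starling relation with `K_f = 1 mL/min/mmHg`, σ = 0.9.
  Oncotic pressure uses the Landis–Pappenheimer cubic rescaled to
  25 mmHg at 7 g/dL; interstitial protein is fixed at 2 g/dL.
  One capillary bed at one gravitational level suffices because all
  packaged protocols are non-orthostatic.
* **Lymph** — zero at or below an interstitial pressure threshold
  (−6 mmHg), rising exponentially toward a 4 mL/min ceiling.  The pressure
  scale is *solved at calibration* so that baseline filtration minus lymph
  exactly equals the insensible loss (see "Baseline as a fixed point").

Hemodynamics eliminate cardiac output as an explicit variable:
`MAP = 93 mmHg · (1 + ΔBV/BV₀) · tpr_mult`, with the resistance multiplier
the product of the AVP pressor effect (saturating, EC50 30 pg/mL — only
~0.2% above 1 at baseline AVP) and an angiotensin-II term.  Capillary
pressure is affine in MAP and blood volume; interstitial pressure affine
in interstitial volume (compliance 2 L/mmHg); right-atrial pressure
4 mmHg per litre of blood volume.  Baroreceptor activities are logistic
curves normalized to 1 at the anchors (MAP 93, P_ra 0 mmHg), bounded in
(0, 2).  One deliberate sign decision: AVP secretion here is stimulated by
baroreceptor *unloading* (hypovolemia/hypotension), the classical
convention, even though one reading of the source literature ties AVP
release to increased cardiac-baroreceptor activity during hypervolemia;
we flag rather than silently adopt that reversed sign.

## Kidney

A single nephron scaled by a nephron multiplier (1 = intact mass; scaling
resistances by 1/m and glomerular Kf by m makes GFR and all urine outputs
exactly proportional to m at fixed signals).

* **Glomerulus** — ohmic two-resistor network with no compliance.
  Baseline anchors: GFR 125 mL/min, renal plasma flow 600 mL/min,
  P_glom 52 mmHg, Bowman 10 mmHg, renal venous 4 mmHg; afferent/efferent
  resistances and Kf are solved from these at calibration.  The afferent
  arteriole carries three multipliers: TGF, a myogenic response, and (via
  the efferent side) angiotensin II.  The myogenic multiplier is affine in
  MAP, `(MAP − 52)/(93 − 52)` (floored at 0.2), which makes P_glom — and
  hence GFR — *exactly* independent of perfusion pressure at baseline
  multipliers.  A pure ohmic network would pass ~80% of a 20-mmHg MAP
  change into GFR; the affine form is the simplest that satisfies
  glomerular pressure autoregulation, and TGF then handles everything the
  myogenic response misses (oncotic shifts, efferent tone).
* **TGF** — afferent multiplier is a rising sigmoid of macula-densa sodium
  delivery, bounded [0.3, 3], slope 3 /(mmol/min), centred at calibration
  so it equals 1 at the baseline delivery of 1.4 mmol/min.  The algebraic
  loop (multiplier → GFR → delivery → multiplier) has loop gain ≈ −3.6, so
  plain fixed-point iteration diverges; it is closed by *damped*
  fixed-point iteration (damping 0.25, ≤50 iterations), warm-started from
  the previous integration step.  The tolerance is 10⁻⁹ on the
  multiplier — stricter than needed for accuracy — so the converged output
  is insensitive to the initial guess to <10⁻⁶ mL/min.
* **Tubule** — fractional reabsorption per segment: proximal 0.67 of
  water and sodium (glomerulotubular balance); loop of Henle 0.25 of
  filtered sodium but only 0.15 of filtered water, so macula-densa inflow
  is dilute; distal tubule water fraction 0.42 and sodium fraction
  0.95·(1 + 0.3(aldo−1))·(1 − 0.5(anp−1)), clamped below 0.998; the
  collecting duct moves urine a fraction `cd_perm(AVP)` of the way from
  its inflow toward osmotic equilibration with a *static* 1200 mOsm/kg
  medullary gradient (no washout dynamics — the protocols span ≤36 h and
  nothing constrains a washout time constant).  `cd_perm` is a Hill
  function of AVP with coefficient 3; its constant is solved at
  calibration so baseline urine flow is exactly 0.58 mL/min at baseline
  AVP (2.5 pg/mL), which lands baseline urine osmolality at 560 mOsm/kg.
  A constant obligate non-sodium osmolar excretion (0.185 mOsm/min,
  ~270 mOsm/day of urea etc.) keeps dehydrated urine concentrating rather
  than shutting off.  Reported urine osmolality is clamped to
  [50, 1200] mOsm/kg; at extreme water diuresis the excreted-osmole
  bookkeeping can imply a value slightly below 50, and the clamp then
  introduces a small reporting inconsistency (the flow itself is never
  clamped).  A `hummod-like` preset raises the dilution floor to
  324 mOsm/kg to mimic the limited post-water-load dilution reported for
  the large reference engine; the default dilutes correctly.

## Endocrine control

* **AVP** — secretion is expressed through a target concentration: the
  steady plasma level the current stimuli would sustain,
  `0.1 + 0.3·max(0, Osm − 280)` pg/mL, times a baroreceptor multiplier
  `1 + 2(1 − mean baro activity)` and a store-limitation factor.  The
  threshold (280 mOsm/kg) and the linear supra-threshold gain are the
  classical osmoregulation line; the baseline of 2.5 pg/mL at 288 mOsm/kg
  is a packaged choice — source studies disagree severalfold on basal AVP.
  Clearance is first-order with a 20-min half-life, the midpoint of the
  10–35-min physiologic range.  The neurohypophyseal store (capacity
  12 µg) is filled at 1.5× the baseline secretion rate and clamped at
  capacity; 36 h of dehydration drains <10% of it, so secretion never
  becomes store-limited in any packaged protocol.
* **Oropharyngeal reflex** — drinking hypotonic fluid suppresses AVP
  secretion and thirst *before* any osmotic change, via an accumulated
  drive `u` (du/dt = 10/L × drinking rate − u/30 min) that multiplies
  secretion and thirst by `exp(−u)`.  The effect scales with the
  hypotonicity of the ingested fluid, `max(0, 1 − [Na]/150 mmol/L)`, so
  water triggers it fully and 180 mmol/L saline not at all.  This reflex
  is ON by default: the rapid post-drinking AVP fall seen in every
  rehydration experiment is faster than osmotic dilution plus a 20-min
  clearance can produce, so a purely osmotic model cannot halve AVP
  within the first post-drink hour.  The exponential form keeps the state
  equation linear and non-stiff (stable at the coarse 0.5-min step used
  for multi-day runs).  Background (food) water intake does not trigger
  the reflex.
* **ANP** — relaxes with a 10-min time constant toward
  `exp(g·P_ra)`; the atrial gain g = 0.0943 /mmHg is the one parameter
  calibrated against a protocol outcome: it is set so the acute water
  load peaks at +33% ANP.
* **RAAS** — renin drive `exp(−4 ΔMAP/MAP₀ − 0.5 ΔNa_MD/Na_MD₀ +
  0.5(1 − baro))` with a 20-min time constant; angiotensin II tracks renin
  (5 min); aldosterone tracks angiotensin II (4 h).  Gains are small by
  design — the reference experiments saw no significant renin changes —
  and all packaged protocols keep renin within ±50% of baseline.

## GI tract, thirst and losses

Gastric emptying and intestinal absorption are lumped into one first-order
stage, half-time 12 min for water and sodium; this aggregate rate is the
single degree of freedom the source literature itself flags (absorption
"overpaced" relative to experiments).  IV infusions bypass the gut.
Insensible loss is fixed at 0.625 mL/min (~0.9 L/day; resting, indoor, no
sweating), drawn from the interstitium.  Deprivation is purely the absence
of intake; food water during protocol windows is zero.  Thirst is
`2·max(0, Osm − 290) + 50·(fractional ECF deficit)`, and drinking during
an open ad-libitum window is `200 mL/min · drive/(drive + 2) ·
satiation(gut fill)` with satiation halving at 0.4 L of gastric content.
Together with the oropharyngeal quench this front-loads drinking: in the
hypertonic-infusion protocol ~62% of the ad-libitum intake falls in the
first 10 of the 30 available minutes, with ~1 L total.

## Baseline as a fixed point

`calibrate()` does not search for a steady state — it constructs one.
Anchors (serum Na 140 mmol/L, osmolality 288 mOsm/kg, hematocrit 0.43,
protein 7 g/dL, MAP 93 mmHg, GFR 125 mL/min, urine flow 0.58 mL/min, AVP
2.5 pg/mL) determine the compartment volumes and all derived parameters:
the lymph pressure scale is solved so filtration − lymph = insensible
loss; basal oral intake equals urinary + insensible water loss and basal
sodium intake equals urinary sodium excretion (0.07 mmol/min); every
hormone multiplier is normalized to 1 at its anchor.  Every time
derivative therefore vanishes at the constructed state to machine
precision, and `find_baseline` (which integrates with basal intake until
the largest relative derivative is <10⁻⁶/min) terminates immediately and
is idempotent.  Overriding any anchor re-solves the dependent parameters.

## Integration and numerics

Classical RK4 with a fixed step (default 0.05 min), chosen over adaptive
solvers for bitwise reproducibility and trivial event alignment.  Event
schedules contribute piecewise-constant rates; all switching times are
forced to be step boundaries by integrating between the union of event
edges, sample times and the regular recording grid, each interval in equal
substeps ≤ dt.  Halving dt changes every sampled observable of the acute
water-load run by <10⁻⁷ relative.  State invariants (positive plasma and
cell volumes, non-negative gut content) are checked after every step and
violations raise an error naming the time and variable.  Conservation
accumulators (cumulative intake, infusion, urine, insensible loss, sodium
fluxes) are integrated with the same quadrature as the state, so
whole-body water and sodium audits close to ~10⁻¹³ relative.

Problem sizes: the packaged tests integrate the acute water-load protocol
at dt = 0.05 min and the multi-day protocols at dt = 0.5 min — the
stiffest surviving time constant is ~3.5 min, so the coarse step remains
well inside the RK4 stability region, and the two steps agree to <0.1% on
all sampled observables.

## Protocols

All six schedules use a 74-kg subject and constant-rate intake events.
5% NaCl maps to 50 g/L ÷ 58.44 g/mol = 855.6 mmol/L.  The
hypertonic-infusion rate is 0.06 mL/kg/min for 120 min (a published
per-kilogram table entry of "0.7 mL/kg" lacks a time unit and cannot be
reconciled dimensionally; the rate form is used).  "Overnight fast" is
10 h without intake.  The NaCl "pill" is an oral load of 1 mL water
carrying 80 mmol NaCl at minute 720.  The acute-load protocol samples
before the load and one hour after it ends (t = 80 min).

## Validation harness

z-scores are `|model − mean|/SD` with SEM·√n conversion; bins Z<1, 1≤Z≤2,
Z>2 with boundary values in the middle bin; RMSE per (protocol, variable)
at matched (linearly interpolated) times.  Published experimental time
courses exist only as figures, so no digitized experimental values are
packaged; the harness ships the reference CSV schema and a synthetic
generator that places reference means a chosen number of SDs away from a
model run, giving analytically known tallies for end-to-end testing.
Synthetic references are exactly that — labelled synthetic, never
experimental data.

## What the packaged tests do and do not show

Passing tests demonstrate internal consistency (conservation, convergence,
determinism), the calibrated operating point, and the qualitative response
repertoire: water diuresis with ≥20-fold flow rise and ~85% urinary sodium
dilution; monotone hyperosmolality and AVP rise under deprivation; faster
AVP suppression by water than by hypertonic saline after dehydration;
lower final serum sodium with drinking than without after salt loading;
stable renin.  They do not show agreement with digitized experimental time
courses (not packaged), nor chronic regulation beyond ~36 h.

## Known limitations

* ICF osmole content and red-cell volume are constant; severe or chronic
  electrolyte disturbances are outside the model's validity.
* The medullary gradient is static; urine-concentration dynamics during
  prolonged diuresis (gradient washout) are absent, and at extreme
  dilution the reported urine osmolality clamp is slightly inconsistent
  with the excreted-osmole bookkeeping.
* Obligate osmolar excretion is constant, so osmolar clearance during
  water diuresis is lower than in real subjects.
* Aldosterone acts only on distal sodium fraction; no potassium coupling.
* The oropharyngeal reflex parameters (gain 10 /L, decay 30 min) are
  behavioural calibrations to the rehydration and ad-libitum-drinking
  response shapes, not measured quantities.
* Baseline AVP, hematocrit and osmolality anchors are conventional values;
  the source studies themselves disagree on basal AVP severalfold.
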