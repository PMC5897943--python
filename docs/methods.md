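# Methods

## Expression metrics

Every molecule readout is a percent change `((D/C) − 1) × 100` of the
patient-specific disease steady state `D` over the non-tumorigenic baseline
`C` (both in µM). The baseline must be strictly positive; the metric is
unbounded and unclamped, so deletions can drive it to −100% and strong
activation far above +100% (the reference cohort spans −32.2% to +229.9%).

The dendritic-cell (DC) infiltration index summarises the 9 chemokine
percent changes (CCL2, CCL3, CCL4, CCL5, CCL7, CCL11, CCL20, CX3CL1,
CXCL14) as `Σᵢ pctᵢ·wᵢ` with nonnegative weights summing to 1 (validated to
1e-9; configuration files are renormalised when within 1e-6). The weight
vector used to produce the reference cohort's per-patient indices was never
published; the package defaults to uniform weights (1/9 each). For patient
SA97V5 the uniform reconstruction gives 24.3 against a recorded 23.81, so
the original weights were non-uniform and are unrecoverable from the single
published example — estimating nine weights from one equation is
under-determined, and we do not attempt it. This affects only synthetic
cohorts: the classifier consumes each record's stored DC index.

## The decision tree

The classifier is deterministic with four parameters: `pdl1_cut` = 29.0,
`dc_low` = 20.0, `dc_high` = 60.0, `ism_margin` = 5.0 (all percent).
Ordering of tests and boundary semantics:

1. non-responder iff `PDL1 < pdl1_cut`; equality proceeds.
2. non-responder iff `DC < dc_low`; responder iff `DC > dc_high`;
   equality with either bound proceeds to step 3.
3. non-responder iff any of the 14 ISMs satisfies
   `ism − PDL1 > ism_margin` (all such molecules are recorded as
   triggering); otherwise responder.

Step 3 needs care: stated as two symmetric clauses ("higher than PD-L1 by
more than the margin" → non-responder, "lower by more than the margin" →
responder) the rule would be undefined for profiles inside the ±margin
band. The implemented rule — non-responder iff any excess exceeds the
margin, else responder — is the only completion consistent with the
reference labels (patient L8MTGU has an IL6 excess of +3.63 inside the band
and is a recorded responder). Negative ISM values (FASLG for most patients)
participate unchanged; they simply never trigger.

The equivalent closed form, used as an independent test oracle, is:
responder ⟺ `PDL1 ≥ pdl1_cut` ∧ `DC ≥ dc_low` ∧ (`DC > dc_high` ∨
max excess ≤ `ism_margin`). The tree is monotone in PD-L1 (raising PD-L1
never turns a responder into a non-responder) and antitone in each ISM.

The estimator wrapper (`ResponseTreeClassifier`) is stateless — `fit` only
validates the feature table — so `clone`/`set_params` support threshold
sensitivity scans; at cutoffs 25.0/29.0/35.0 the step-1 tally over the
reference cohort is 6/9/14.

## Concordance statistics

Match score = 100 × (label agreements) / n; responder rate =
100 × responders / n. Values are kept at full float precision internally.
Reported rounding follows the source's conventions, which are not a single
rule: match scores round ties to even (81.25 → 81.2) while responder rates
round ties up (56.25 → 56.3); both conventions are needed to reproduce the
printed summaries and the choice is documented here rather than hidden.

The 2×2 comparisons use Pearson's chi-square (1 df, optional Yates
correction, zero-margin tables rejected) and two-sided Fisher's exact under
the point-probability rule (sum hypergeometric masses ≤ the observed
table's), delegating to scipy.stats; the test suite checks Fisher against
an explicit hypergeometric enumeration. Degenerate Fisher tables return
p = 1, flagged. The report assigns tests per comparison as the published
values imply: clinical responder rates by uncorrected chi-square
(p = 0.9577 on [[5,8],[6,10]]), predicted responder rates by Fisher
(p = 0.2642 on [[4,9],[9,7]]), and match/mismatch counts by Fisher
(p = 0.6059 on [[12,1],[13,3]]). A fixed rule such as "Fisher iff an
expected cell < 5" reproduces none of the first two, so no auto-policy is
offered.

## Reference cohort fixture

The packaged 29-patient table (13 discovery, 16 validation; 11 clinical
responders) stores study ID, dataset, clinical response, the 16 numeric
columns, and two metadata columns — the recorded predicted response and
MATCH/MISMATCH call — that serve exclusively as validation oracles; the
classifier never reads them. The loader accepts Unicode minus signs and
thin spaces (as typeset in the source) and normalises molecule-name
synonyms (CX3CL → CX3CL1, PD-L1 → PDL1, …). Writing uses full float
precision so load/write/load round trips are exact.

## Signaling network simulator

The simulator stands in for the proprietary whole-cell network that
generated the original profiles; it is a reduced, documented
reconstruction, not a transcription, and no attempt is made to reproduce
any patient's numeric profile from their mutations.

**Model.** Species obey `dXᵢ/dt = sᵢ − dᵢXᵢ + Σ ν r(X)` with basal
synthesis `sᵢ`, first-order degradation `dᵢ = 1` (so steady concentrations
equal total production), and reaction rates of two kinds:
Michaelis–Menten `Vmax·S/(Km+S)` over a consumed substrate (or a pure
regulated synthesis when no substrate is declared) and mass action
`k·ΠS`. Every rate is multiplied by saturating activator factors
`A/(Ka+A)` and inhibitor factors `Ki/(Ki+I)`. Time units are arbitrary
since only steady states are read out.

**Topology.** ~44 species: the ERK arm (EGFR→KRAS→BRAF→MEK→ERK→AP1), the
PI3K arm (EGFR→PIK3CA→AKT→MTOR→STAT3, with STK11→AMPK feeding MTOR and
KEAP1 boosting the STAT3 arm), the IFN-γ arm (IFNG→IFNGR1→STAT1→IRF1),
TP53 inhibition of all three PD-L1 transcription reactions with CDKN2A
restraining TP53, and the 23 non-PD-L1 readouts as lumped transcriptional
targets of the activation factors (GM3 and GD2 share a driver, matching
their near-identical columns in the reference table; FASLG and CXCL14 are
ERK-repressed, giving the negative changes those columns show). The
AMPK→MTOR and KEAP1 links are encoded as *positive* PD-L1 regulation —
that is what the co-mutation phenomenology requires of the reduced model,
and loss of CDKN2A raises TP53-mediated inhibition — rather than as a full
account of their biology.

**Perturbations** transform the specification, never solver state. Gain of
function multiplies the rate constant of every reaction the gene drives (as
substrate or activator) by the magnitude and divides its inhibition
constants by it; loss of function applies the reciprocals; amplification
scales basal synthesis; deletion zeroes it. Defaults: ×5 for gain and
amplification, ÷10 for loss — unpublished, chosen once for clearly
separated effects. With these defaults the packaged parameters give the
PD-L1 percent-change ordering KRAS+TP53 > KRAS > KRAS+STK11+KEAP1 >
KRAS+CDKN2A/B (the KP/K/KL/KC subgroups); the first parameterisation
satisfying the ordering was frozen as the versioned fixture.

**Solver.** scipy's implicit Radau integrator advances the stiff system in
windows of 500 time units (rtol 1e-8, atol 1e-10) until max |dX/dt| <
1e-9 µM/time or the relative state change over a window < 1e-8, up to a
horizon of 5×10⁴; non-convergence is reported via a flag, not an
exception. Tiny negative excursions are clipped at 0; excursions beyond
solver tolerance raise. Halving tolerances moves steady concentrations by
< 1e-4 relative.

## Synthetic cohorts

The generator produces cohorts with known ground truth. Parametric mode
draws per-molecule percent changes from Gaussians; defaults (location/scale
50/45 for PD-L1, 20/25 for ISMs, −4/4 for FASLG, 30/60 for chemokines)
spread patients across all five tree terminals. PD-L1, TGFB1 and IL6 are
drawn as a correlated block (ρ = 0.6 with PD-L1, ρ² between the two
targets, consistent with a shared driver) so step-3 decisions are
non-trivial. The DC index is computed from the drawn chemokines with
uniform weights. Mechanistic mode samples driver mutations from a weighted
panel (KRAS, BRAF, MEK, EGFR, PIK3CA, MTOR gains; TP53, STK11, KEAP1,
CDKN2A losses), rejecting empty profiles, and runs the simulator with a
cached baseline.

Each patient's true label is the tree applied to the noiseless profile;
the recorded clinical response flips that label independently with
probability `label_flip_rate` (default 4/29, the reference cohort's
mismatch fraction) — the simplest generative account of all unmodeled
biology separating prediction from outcome. Observation noise (default
0) perturbs stored values only, so with noise the classifier's match score
can fall below 100(1 − flip) through boundary crossings. The
moment-matched preset sets each molecule's location/scale to the fixture
column's mean/SD; chemokines get the DC-index mean and 3× its SD so the
uniform-weight index reproduces the DC moments. Under this preset the
step-1 fraction at large n lands within a few points of the reference 9/29
because the PD-L1 column is roughly Gaussian there — passing tests show
distributional, not per-patient, realism; real profiles are heavier-tailed
(e.g. CD47 = 175.2 for one patient) and correlated beyond the single block
modeled. All randomness flows from one seeded numpy Generator; identical
configurations produce byte-identical cohort files.

## Problem sizes

The test suite and acceptance script run at desk scale: the 29-patient
fixture, 10,000 random profiles for the tree/oracle equivalence check,
synthetic cohorts up to n = 2000 (parametric) and n = 3 (mechanistic), and
a few dozen steady-state solves of the ~44-species network (well under a
second each).
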