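# Methods

## Scope

`aaflux` implements the tracer calculus for postprandial protein handling
experiments that combine a primed continuous intravenous infusion of
stable-isotope amino acid tracers with ingestion of intrinsically labeled
dietary protein: plasma phenylalanine kinetics (total, exogenous and
endogenous rates of appearance and disappearance), whole-body protein
synthesis/oxidation/net balance via the phenylalanine-hydroxylation method,
precursor-product fractional synthesis rates (FSR) of muscle and plasma
protein fractions, de novo incorporation of dietary amino acids, and the
planning calculations for producing the labeled protein itself. A forward
simulator with known ground truth closes the loop: every estimator is
validated by parameter recovery.

## Enrichment conventions

All file formats and user-facing values carry enrichments as mole percent
excess (MPE). Internally every kinetic equation consumes mole-fraction
excess (MPE/100). A tracer-to-tracee ratio (TTR = E/(1−E)) conversion is
provided for interoperability with TTR-based workflows but is not used by
the pipeline; because every equation here is a ratio of enrichments sharing
one scale, switching the pipeline to TTR would be a localized change in the
table builders. Times are minutes since drink ingestion; negative times are
infusion-equilibration samples and are excluded from postprandial
integration.

## Plasma kinetics (single-pool, non-steady state)

Between consecutive samples the Steele single-pool model gives

    total_Ra = [F_iv − pV·C(t)·ΔE_iv/Δt] / E_iv(t)
    exo_Ra   = [total_Ra·E_p,oral(t) + pV·C(t)·ΔE_p,oral/Δt] / E_oral
    endo_Ra  = total_Ra − exo_Ra − F_iv          (whole-body breakdown)
    total_Rd = total_Ra − pV·ΔC/Δt
    exo_Rd   = [total_Rd·E_p,oral(t) + pV·C(t)·ΔE_p,oral/Δt] / E_oral
    endo_Rd  = total_Rd − exo_Rd

with F_iv the IV tracer infusion rate (μmol·kg⁻¹·min⁻¹), pV the
phenylalanine distribution volume (default 0.125 L·kg⁻¹, configurable; the
same default is used for tyrosine in the absence of a separate literature
value), C plasma concentration (μmol·L⁻¹) and E_oral the enrichment of the
ingested protein. Interval statistics are arithmetic means of the two
bounding samples; slopes are forward differences. The first two identities
above hold to 1e-10 on every computed interval by construction and are
emitted as check columns.

Cumulative exogenous availability integrates the interval-mean exogenous Ra
(equivalent to trapezoidal integration of the underlying curve). Negative
interval values — possible under measurement noise, unphysical as
instantaneous appearance — are retained in the rate tables but clamped to 0
for the reported cumulative-availability numbers. Recovery and Monte-Carlo
studies instead integrate the unclamped rates, because zero-clamping is
upward-biased by construction and those studies exist to diagnose bias.
No smoothing or splining is applied to any series.

## Whole-body rates

Phenylalanine's only disposal routes are protein synthesis and irreversible
hydroxylation to tyrosine. With a ring-deuterated phenylalanine infusion the
hydroxylation product carries a distinguishable tyrosine label, giving

    oxidation = Tyr_Ra · [E_D4tyr/E_phe,iv] · [Rd/(F_phe,iv + Rd)]

where Tyr_Ra is the total tyrosine flux measured with its own IV tracer
(same Steele form) and the final factor is the tracee fraction of
phenylalanine disposal, correcting for the infused tracer's own
contribution to the flux. Then synthesis = total_Rd − oxidation, breakdown
= endo_Ra, net balance = synthesis − breakdown. If noise drives oxidation
above total Rd, synthesis is floored at 0 with a warning rather than
reported negative. Interval rates are aggregated to reporting windows
(default 0–4, 4–8, 8–12 and 0–12 h) by time-weighted means. Gram-scale
conversions use MW(Phe) = 165.19 g·mol⁻¹ and a configurable phenylalanine
mass fraction of the dietary protein (default 0.048 g·g⁻¹, typical of
bovine milk protein; leucine 0.098 g·g⁻¹). These two fractions are not
measured quantities of any particular batch and only affect gram-scale
fate summaries.

## Incorporation

FSR follows the precursor-product equation, FSR(%·h⁻¹) =
ΔE_bound/(E_precursor·t)·100. The "weighted mean" precursor enrichment over
an incorporation window is implemented as the trapezoidal time-average of
the plasma free enrichment (sub-window endpoints linearly interpolated).
For the muscle-free precursor only the two bounding biopsies exist, so
their free-pool values are averaged. De novo incorporation scales the
oral-tracer bound-enrichment gain by the oral protein enrichment and the
product pool size: skeletal muscle protein = SMM × 0.20; circulating plasma
protein = BM × 0.07 (blood fraction) × 0.55 (plasma fraction of blood) ×
70 g·L⁻¹. The exogenous contribution to synthesis normalizes the oral- and
IV-tracer bound gains by their respective free precursor enrichments and
reports the ratio as a percentage (capped to [0, 100] with a warning if
noise pushes it outside); the endogenous share is its complement, exactly.
Both the full-window (0–12 h) and per-biopsy-pair FSRs are reported for
every fraction, tracer and precursor pool.

## The simulator

One well-mixed plasma pool per amino acid (phenylalanine, tyrosine,
leucine), each with constant basal endogenous appearance, constant
fractional clearance k, its IV tracer infusion, and — after t = 0 — an
exogenous appearance wave shaped as dose × bioavailability ×
Gamma(shape, scale) density. Labeled sub-pools obey the same clearance;
D4-tyrosine is produced by hydroxylation of the D5-phenylalanine sub-pool
at the configured fraction of phenylalanine disposal. Protein-bound
enrichment accrues from the plasma precursor at the configured true FSR.
The linear ODE system is solved with LSODA at rtol 1e-10 from −150 min
(priming bolus as initial tracer pool; any plateau mismatch decays during
equilibration) to 720 min, sampled by default every minute.

Default study conditions: 75 kg subject; infusions 0.060 / 0.018 / 0.12
μmol·kg⁻¹·min⁻¹ (D5-phe / D2-tyr / 13C-leu) with primes 3.60 / 1.10 / 7.19
μmol·kg⁻¹; dietary protein labeled at 31.6 MPE 13C-phenylalanine and
8.0 MPE 13C-leucine; basal endogenous Ra 0.60 (phe), 1.38 (leu) and 0.216
(tyr, sized so total basal tyrosine flux including hydroxylation inflow is
0.30) μmol·kg⁻¹·min⁻¹; clearances sized for ~60/55/120 μM plasma
phenylalanine/tyrosine/leucine; hydroxylation fraction 0.10 of
phenylalanine disposal. Absorption of 25 g is largely complete by ~5 h
(gamma shape 2, scale 70 min; bioavailability 0.66 by 12 h) while 100 g is
still being absorbed at 12 h (scale 280 min, bioavailability 0.75); these
are simulation settings chosen for qualitative realism, not reproduction
targets. True simulator FSRs default to 0.045/0.050/0.030 %·h⁻¹ for
mixed/myofibrillar/connective muscle fractions and 0.25 %·h⁻¹ for plasma
protein. Observation noise is multiplicative Gaussian, default CV 2% for
enrichments and 4% for concentrations, drawn from a seeded generator;
identical configurations give byte-identical output.

Because the simulator realizes exactly the model the estimators assume,
noise-free recovery error measures discretization alone: on the 1-min grid
the exogenous-appearance curve, cumulative release, breakdown and Rd are
recovered to ≲0.01% and FSR to ~1e-9; coarser grids degrade monotonically
(grid-refinement property tests). The oxidation estimator is consistent
with the simulator's tracee hydroxylation flux only to O((F/Rd)²) because
of the tracee-fraction factor, observed as ~0.7% at default settings.

What the simulator does not emulate — and hence what green recovery tests
do not certify on real data: splanchnic first-pass extraction, insulin and
exercise effects, inter-organ exchange, diurnal drift in basal rates,
tracer recycling from protein breakdown, and intracellular precursor
compartments. The muscle-free enrichment series is a fixed-dilution proxy
of plasma (default 0.65), so the simulator's bound label accrues from the
plasma precursor and muscle-free-based FSR estimates exceed plasma-based
ones by the reciprocal dilution — the direction seen in real data, but not
a mechanistic intracellular model. An optional tissue-exchange mode
(`tissue_exchange_k12 > 0`) adds a slowly exchanging extravascular
phenylalanine pool to quantify the bias a single-pool estimator incurs
under model mismatch.

## Statistical behaviour of the estimators

The Steele forms are ratio estimators: with multiplicative noise of CV c on
each enrichment sample, E[1/Ē] over a two-sample interval mean exceeds 1/E
by ≈ c²/2, so cumulative-release estimates carry a positive relative bias
of order 2×10⁻⁴ at c = 0.02. On a 1-min grid this is detectable by a
200-replicate Monte-Carlo study (standard error of the mean ≈ 1.4×10⁻⁴
relative) even though it is far below any physiological relevance; the
bundled unbiasedness test documents this honestly rather than hiding it.
FSR estimates show no resolvable bias at the same noise level. The
`monte_carlo_study` helper reports mean, spread, Monte-Carlo s.e. and
z-score per quantity, reusing one forward solve across replicates.

## Numerical choices and degenerate inputs

Enrichment/concentration series validate monotone time grids, nonnegative
values and matched lengths at construction; trial configuration validates
positivity and MPE ranges at construction (never downstream). Kinetics
requires exactly aligned postprandial grids and lists offending times
otherwise. Placebo arms (dose 0) force exogenous rates identically to zero
and make the release percentage undefined (raises). Zero precursor
enrichments raise rather than return infinities. Mixture planning rejects
targets outside the feasible blend range. CSV output uses %.17g floats and
reading uses round-trip parsing, so write→read is lossless.

## Known limitations

* Single-pool Steele kinetics: no two-pool (intracellular) correction, no
  splanchnic-extraction estimate.
* The 67:33 blend of the production batches reproduces the reported
  leucine enrichment (8.0 MPE) but, applied to the reported phenylalanine
  batch enrichments (38.3/7.7 MPE), linear blending yields ≈28.2 MPE, not
  the 31.6 MPE reported for the production batch. Per-amino-acid profile
  weighting differing between batches could account for this; a profile
  weighting hook exists, but no batch composition data are available to
  resolve it, so the discrepancy is documented rather than forced.
* Oxidation is derived from the hydroxylation route only; breath-CO₂-based
  oxidation is out of scope.
* Aminoacyl-tRNA, the true precursor, is not modeled; plasma and
  muscle-free pools bracket it, and FSRs inherit that precursor-choice
  uncertainty exactly as in real experiments.
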