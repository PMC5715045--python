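# Methods

## The model and its assumptions

`cnmfa` performs steady-state ¹³C metabolic flux analysis: intracellular
reaction rates are assumed constant (metabolic steady state, S·v = 0 for
every balanced metabolite) and the labelling of proteinogenic amino acids
is assumed to have reached isotopic steady state, so the measured mass
isotopomer distributions (MIDs) are algebraic functions of the flux vector
and the substrate labelling.  Amino acid fragments report on the labelling
of their biosynthetic precursors (pyruvate, 3-phosphoglycerate,
α-ketoglutarate, oxaloacetate, phosphoenolpyruvate, erythrose-4-phosphate,
ribose-5-phosphate); the packaged model encodes those precursor-to-product
carbon maps explicitly as amino-acid synthesis reactions, so fragments are
ordinary EMUs of amino-acid metabolites.

### The packaged *C. necator* H16 network

The default model has 72 reactions covering: fructose uptake to
fructose-6-phosphate; glycerol uptake via glycerol-3-phosphate to DHAP;
the Entner–Doudoroff route (this organism lacks phosphofructokinase and
6-phosphogluconate dehydrogenase, so G6P → 6PG → KDPG → pyruvate + GAP is
the only sugar-catabolic route, with the oxidative step lumped into `zwf`);
the non-oxidative pentose phosphate pathway (two transketolases and a
transaldolase); CBB carboxylation (phosphoribulokinase + RuBisCO,
RU15P + CO₂ → 2× 3-PG, with the fixed CO₂ entering as the upper 3-PG C1);
lower glycolysis/gluconeogenesis with reversible steps; the TCA cycle; the
glyoxylate shunt; anaplerosis (PEP carboxylase, PEP carboxykinase,
pyruvate carboxylase, malic enzyme); PHB synthesis via acetoacetyl-CoA;
fifteen amino-acid synthesis reactions with literature atom mappings
(valine from two pyruvates, phenylalanine/tyrosine from two PEP + E4P,
methionine C5 from the serine-derived C1 pool, glycine cleavage closing
the C1 balance); and one constrained biomass drain per amino acid.

Atom transitions use 1-based numbering with C1 at the carboxyl/aldehyde
end, one lowercase letter per carbon; carbon released by decarboxylation is
written explicitly against the CO₂ pool, so conservation is checked
reaction by reaction at parse time.  Succinate and fumarate are
rotationally symmetric: every reaction producing them contributes both atom
orientations at weight ½.

The exact reaction list is configuration (`src/cnmfa/data/cnecator_core.csv`
plus a YAML companion for roles, labellings and conditions), not code.
Biomass precursor demands are uniform placeholder drains (0.012–0.05
mmol/g DW/h depending on condition, scaled with growth) because the source
genome-scale coefficients are not reproduced here; they are
`constrained`-class fluxes and can be overridden per run.

### Flux-space parameterization

Measured fluxes (substrate uptake) and constrained fluxes (demands) are
substituted into the steady-state system; the remaining unknowns split into
pivot (dependent) and non-pivot (free) columns by Gaussian elimination with
a column order that prefers reactions marked `free` in the model file as
the free coordinates.  For the default model all three conditions yield
seven free fluxes: `pyk`, `rbc`, `ppc`, `pck`, `pyc`, `mae`, `phaA` — the
glycolysis/anaplerosis split, the CBB flux, the four anaplerotic routes and
the PHB drain.  Free-flux bounds in the file are deliberately physiological
(0–5 mmol/g DW/h, PHB 0–2) rather than generic: they define the region the
multi-start sampler explores, and the heterotrophic landscape is strongly
multimodal, so generic ±20 bounds would waste nearly all restarts on an
attractor with SSR two orders of magnitude above the optimum.

Reversible reactions carry a net flux (sign = direction) plus an optional
exchange flux (forward = max(v,0)+exch, backward = max(−v,0)+exch).  The
default model fixes exchanges at zero; the machinery supports them and they
are exercised in the tests.

### CO₂ handling

The CO₂ pool is treated as an unbalanced input at a fixed 1% ¹³C
enrichment: decarboxylation reactions dump into it, carboxylation reactions
draw from it at the fixed enrichment.  This mirrors the two-source model
behind the R-value statistic and is appropriate when headspace CO₂
dominates the intracellular pool (mixotrophic bottles at 10% CO₂).  A
balanced-CO₂ mode (`balance_co2` in the model config) is available, in
which CO₂ becomes an ordinary balanced metabolite; it is not the default
because under heterotrophic growth in ambient air the balanced pool's
labelling would be dominated by re-fixed decarboxylation CO₂ with no
exchange term to dilute it, which overstates label recycling.

## EMU simulation and its oracle

Target fragment MIDs are computed by EMU decomposition: tracing target
atom sets backward through the atom maps produces, per EMU size, a linear
system A·X = B·Y whose right-hand side collects substrate EMUs and
convolutions (Cauchy products) of smaller EMUs from condensation
reactions; systems are solved dense (LU) in ascending size.  The default
model's 24 fragment targets decompose into ~330 EMUs across sizes 1–9 and
simulate in under 2 ms, which is what makes multi-start fitting and
profile confidence intervals affordable.

EMUs of inactive branches (for example the fructose-uptake chain when the
condition feeds glycerol, so every producing flux is zero) receive a
placeholder unlabelled MID; if such an EMU feeds any balance with positive
flux the system is genuinely singular and an error names the EMU.

The independent oracle (`brute_force_mids`) solves the full positional
isotopomer balance — the complete 2ⁿ state distribution per metabolite —
by fixed-point iteration, with condensation handled through joint
distributions of the reactant pools (the same independence assumption the
EMU framework makes).  It is exponential in carbon count and refuses
networks above 32 total carbons; simulator and oracle agree to 10⁻⁸ on
toy networks covering branching, condensation, decarboxylation with
refixation, symmetric scrambling and reversible exchange.

## Natural-abundance correction

Each detected fragment carries a full elemental formula of the derivatized
ion ([M-57] = TBDMS-derivatized amino acid − C₄H₉; [M-85] additionally
− CO, losing the C1 carboxyl).  The packaged formulas reproduce the
reported nominal M₀ masses exactly (Ala 260 … His 440), which is the only
cross-check available since the original correction configuration is not
published.  Isotope abundances are IUPAC 2013 values; envelopes are built
by exponentiation-by-squaring of per-element distributions, truncated at
mass depth 8 and renormalized.

The correction matrix maps a tracer-carbon MID (length C+1) to the
observed envelope: column j convolves the residue envelope (formula minus
backbone carbons) with the tracer-purity smear Binomial(j, 0.99) and the
natural-¹³C distribution Binomial(C−j, 1.07%) of the unlabelled backbone
carbons.  Column 0 therefore equals the full natural envelope and a
natural-abundance-only spectrum corrects to M₀ = 1 (SFL < 10⁻³).  The
inverse problem is solved by non-negative least squares with
renormalization, which tolerates envelopes truncated by the instrument's
scan window.  Note the R-value statistic separately uses the stated 1% CO₂
abundance; the 1.07% elemental constant and the 1% mixing-model constant
coexist deliberately.

## Labelling statistics

SFL is implemented as Σᵢ i·Mᵢ / Σᵢ Mᵢ, i.e. the ratio form with an
explicit normalization, because the average-atom-count convention (range
0…C, not 0…1) is what the observed magnitudes imply (up to 5.8 for a
9-carbon fragment).  The R-value inversion
R = (f − 0.01)/(0.99·n − m·f), f = SFL/C, is defined only on
0.01 < f < 0.66; outside that window the fragment's labelling is
inconsistent with the two-source model and a domain error is raised rather
than a clamped value returned.  The printed mixotrophic table contains one
internal inconsistency: the Tyr and His rows do not invert from their own
SFLs but exactly reproduce each other's R-values, consistent with a row
transposition; the package flags these two rather than silently "fixing"
them, and the validation suite asserts the transposition explicitly.

Growth rate is the least-squares slope of ln OD₆₀₀ vs time (exact on
noise-free exponentials); the uptake rate is the regression slope of
substrate concentration on the trapezoidal time-integral of OD, reported
in the experimentally natural unit g L⁻¹ OD⁻¹ h⁻¹.  Conversion to
mmol/g DW/h uses a configurable biomass density (default 0.4 g DW L⁻¹ per
OD unit).

## Flux estimation

The objective is Σ ((sim − meas)/SD)² over included isotopologue
fractions.  Measurement SDs are user-supplied per entry (the synthetic
generator writes its own noise SD; 0.01 mole fraction is the default, a
typical GC-MS MID accuracy).  Twelve amino acids' [M-57] and [M-85]
fragments enter the fit; tyrosine and lysine are excluded for low
signal-to-noise and proline for co-elution — as configuration flags in the
fragment table, not hard-coded.

Dependent-flux bound violations are penalized (10⁶ × violation on the
residual scale, 10¹² on the SSR scale) instead of rejected, keeping the
objective finite; restart points are additionally repaired toward
feasibility by seeded resampling, because trust-region steps stall on the
penalty kink when started deep in the infeasible region.  Optimization is
bounded trust-region least squares (TRF) from Latin-hypercube seeded
starts; 100 restarts is the default schedule and is genuinely needed for
the heterotrophic conditions, where a broad suboptimal attractor captures
~95% of random starts.  Everything is deterministic given the seed.

Confidence intervals are profile-likelihood at Δ SSR = 3.84 (χ²₀.₉₅ with
one degree of freedom): the flux is scanned outward from its estimate with
geometric expansion and bisection, re-optimizing the remaining free fluxes
with warm starts.  A scan that reaches a model bound before crossing the
threshold marks that side unidentifiable (flagged, not an exception).
Dependent fluxes are profiled through their affine dependence on the free
fluxes.  Goodness of fit is the one-sided χ² test at
dof = #included isotopologue fractions − #free fluxes.

### The clip-aware measurement model

The synthetic generator adds Gaussian noise to mole fractions, clips at
zero and renormalizes.  Clipping makes the noise on near-zero fractions
positively biased (mean ≈ 0.4·SD), which an unbiased forward model
misreads as isotope dilution — enough to pull a truly-zero CBB flux to
+0.017 mmol/g DW/h with a CI excluding zero.  When the noise process is
known (all synthetic studies), the fit can therefore predict the expected
clipped measurement, E[max(p+ε,0)] = p·Φ(p/σ) + σ·φ(p/σ) renormalized,
instead of p itself (`clip_sd=` in `fit`).  This removes the bias (mean
spurious CBB flux drops to ~0.002) without touching the generator or the
data.  For real data the analogous non-negativity operator is the NNLS
correction step and the option stays off.

## The synthetic study conditions

The generator's defaults are the study conditions: tracer purity 99 atom%,
non-tracer substrate positions at 1.07% natural ¹³C, CO₂ at 1%; noise SD
0.01 mole fraction per isotopologue; growth parameters per condition
(μ = 0.254/0.173/0.23 h⁻¹; uptake 0.189/0.023/0.055 g L⁻¹ OD⁻¹ h⁻¹;
4 g/L fructose or 10 g/L glycerol).  Growth series sample 8 points over
the second half of the run (OD ≈ 0.1–1.2, the measurably exponential
window; a 2-point mode mirrors minimal sampling), with multiplicative
lognormal OD noise (σ = 0.01) and additive concentration noise
(0.02 g/L).  The demo ground-truth flux vectors put the CBB flux at
0.05 / 0.15 / 2.2 mmol/g DW/h for fructose / heterotrophic glycerol /
mixotrophic growth, reproducing the qualitative pattern of a nearly silent
CBB cycle on fructose, a modest one on glycerol, and a dominant one under
mixotrophy with a glycerol-to-CO₂ carbon ratio inside the observed R range
(the generated per-fragment R-values span ≈ 0.24–0.72).

What passing tests do and do not show: the generator draws noise from the
very model family the estimator assumes (plus the clipping operator),
contains no co-elution artifacts, drifting retention times, inaccurate
fragment formulas, metabolic channeling or isotopic non-stationarity from
sub-culturing.  Recovery and coverage results therefore validate the
inference machinery, not the biology; with real spectra the correction
formulas and the SD model become additional hypotheses.

## Numerical choices

* Steady-state residual tolerance 10⁻⁹ (relative); basis elimination pivot
  tolerance 10⁻⁹ relative to the largest stoichiometric coefficient.
* EMU systems solved dense; MIDs clipped at 0 and renormalized after each
  solve (departures are at rounding level).
* Brute-force oracle: fixed-point tolerance 10⁻¹³, cap 50 000 iterations.
* Envelope truncation depth 8 (column sums within 10⁻⁴ of 1).
* TRF tolerances 10⁻¹⁰ (fit) / 10⁻⁹ (profile re-optimization, capped at 60
  residual evaluations per scan point, 12 bisection steps).
* Simulation studies in the test suite use 20 restarts per fit and 20
  replicates (the full 100-restart schedule is reserved for the strongly
  multimodal heterotrophic fits), with problem sizes chosen so the whole
  suite completes comfortably on one CPU.

## Known limitations

* The 72-reaction network is a reconstruction of the central-carbon
  topology from the study's pathway map; the original reaction list was
  not available, so lumping choices (e.g. `zwf` including the lactonase
  step) are this package's own.
* Exchange (reversibility) fluxes are not fitted by default; net-flux signs
  carry directionality.  Profile CIs therefore do not account for exchange
  uncertainty.
* Biomass demands are placeholders; absolute flux values scale with the
  uptake conversion (biomass density), so cross-condition *ratios* are the
  robust quantities.
* The anaplerotic cycle (ppc/pck/pyc/mae) is only partially identifiable
  from amino acid MIDs; expect wide or bound-limited intervals for some of
  these fluxes, which the CI code flags.
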