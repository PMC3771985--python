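# Methods

`cryptabm` simulates a single murine colonic crypt as a population of
semi-autonomous cell agents on an unrolled cylinder, under two contrasting
concepts of crypt organisation, and evaluates each crypt as a
"mature-cell factory" against quantitative performance targets.  This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## Geometry

The crypt epithelium is a monolayer, so the tube is cut open and unrolled
into a 2D rectangle with periodic left/right borders; `y = 0` is the
impenetrable crypt base and `y = height` the orifice, where cells whose
centres cross are removed from the tissue.  Cells are discs at continuous
positions (lattice-free).  The sheet is sized for the murine descending
colon: 22 cells around the circumference, 32 along the axis, 704 cells at
perfect packing.

*Fine-tuning.*  The sheet dimensions are chosen so that exactly 704
*average* cells tile it when packed at the mechanical equilibrium overlap
`delta_eq`: the effective cell diameter is `2 * r_pack - delta_eq` and
width/height are 22 resp. 32 effective diameters.  The packing radius
`r_pack` is not the birth radius: a cycling cell grows linearly in area
from `A0` to `2 A0` over G1 + G2, so its time-averaged area is

    <A>/A0 = [g1 (1 + a/2) + s (1 + a) + g2 (3 + a)/2 + 2 m] / T_c,
    a = g1 / (g1 + g2),

which is 1.63 for the transit-amplifying (TA) parameter set.  Using the
reference composition of the descending-colon crypt (200 proliferative of
704 cells) the number-weighted mean radius is `r_pack = (504 * 5 um + 200
* 5 um * sqrt(1.63)) / 704 = 5.40 um`, giving a 226 x 329 um sheet.
Sizing the sheet with the birth radius instead underfills the crypt by
exactly the average-area factor (~16%), because the simulated population
really does contain cycling cells larger than newborns.  The derivation
treats G1 at its mean duration and ignores the age-structure bias of a
growing population; both corrections are second order at the reported
tolerances.

## Cell cycle

Proliferative cells follow a two-phase stochastic cycle: phase A
(identified with G1) is left with constant probability per unit time —
per step `1 - exp(-dt/g1_mean)`, the exact exponential form, so the
distribution of A durations is step-size invariant — followed by a
deterministic phase B = S + G2 + M.  Completing M divides the cell into
two daughters of half its area, placed symmetrically about the mother
along the division axis (vertical when "vertical division only" is set,
else a uniformly random direction), separated so they just touch.
Durations (hours): TA cells G1 7.0, S 6.2, G2 1.8, M 0.5; stem cells
G1 22.5, S 20.0, G2 6.0, M 1.5.  Mature (G0) cells neither grow nor
divide.

Cells grow in area at the constant rate `A0 / (g1_mean + g2)` during G1
and G2 only, so the average cell doubles per cycle.  Because G1 is
random, sizes vary; two gates keep them bounded: a cell below
`r_min = 6.5 um` cannot leave G1 (it then clears the minimum during G2),
and growth clamps at `r_max = 7.5 um`, slightly above the dividing radius
`sqrt(2) * 5 = 7.07 um`.  The gates do not delay division once a cell is
past G1.  The founding row starts unsynchronised: each cell is assigned a
uniform position within a nominal mean cycle.

## Mechanics

Dynamics are overdamped: drag against the basement membrane balances the
sum of pairwise contact forces at every instant, so velocities follow
directly from the force law and positions advance with an explicit
first-order update at a fixed 10-second step.  All constants are
expressed over the drag coefficient eta.  The pair law in the overlap
`delta = r_i + r_j - d` is a linear (Hookean) spring, `v = k/eta *
(delta - delta_eq)` repulsive above the equilibrium overlap, plus a
constant adhesive pull of magnitude `attr/eta` whenever `delta <
delta_eq` and the gap is within the filopodial reach `attr_distance`.
Equal and opposite contributions guarantee zero net internal momentum.

Parameter defaults and rationale:

- `delta_eq = 0.5 um` — the equilibrium overlap is not an experimentally
  printed quantity; 5% of a cell diameter gives visually contiguous
  sheets and feeds the geometry fine-tuning.  Configurable.
- `k/eta = 0.02 1/s` — chosen so that pair relaxation (time constant
  `1/(2k) = 25 s`) is fast against the hours-scale cell kinetics: packing
  is then quasi-static, which is what the perfect-packing capacity
  argument assumes.  Much softer springs cannot transmit the steady-state
  cell flux (~10 cells/h through 22 columns) without overlap increments
  accumulating cell-over-cell into unphysical compression at the base.
  The literature value printed for this constant (1e-7 1/s) implies
  relaxation times of months and is recorded in configuration provenance
  but not used.
- `attr/eta` in m/s (grid values 0, 0.5e-8, 1.0e-8) and `attr_distance`
  (0, 0.5, 1 um) are the calibrated free parameters of the two model
  variants.
- Active migration, when enabled, adds a constant upward drift of the
  adhesive speed scale to every non-anchored cell — a deliberately
  minimal reconstruction of crypt-directed motility.
- Stem attachment anchors stem-cell centres vertically at their basal
  sites (lateral drift only if lateral migration is on).

*Integration.*  The overdamped equation has no inertia, so the update is
forward Euler on `x' = v(x)`.  Stability requires `lambda dt < 2` where
`lambda ~ (number of contacts) * k/eta`; in transiently crowded
configurations (right after a division) the bound can be violated, so any
step whose displacement would exceed half a micrometre is subdivided with forces
re-evaluated — the integrator then tracks the fast local relaxation
instead of overshooting it.  A cell whose *accumulated* displacement
within one 10-s step exceeds its own radius aborts the run with an
instability diagnostic; this never triggers at the shipped parameters.

## Lineage rules

*Pedigree*: the 22 basal cells are immortal stem cells dividing
asymmetrically (stem + TA generation 1); TA cells divide symmetrically,
daughters of generation `g` carry `g + 1`, and generation-5 daughters are
mature.  Fate is position-independent.  When stems are anchored, the stem
daughter keeps the mother's basal site and the TA child is placed on the
luminal side of it: placing it basally would wedge it permanently between
the immobile stem and the impenetrable base once lateral motion is
disabled.

*Niche*: all divisions are symmetric; fate is positional.  The
proliferative region is the basal fraction (0.2-0.5) of the crypt
height.  Two maturation schemes: "only new cells mature" — daughters
born above the boundary are mature, anything cycling that wanders out
keeps cycling; otherwise any cell still in G1 whose centre crosses the
boundary matures immediately, while cells past G1 (S/G2/M) finish their
cycle and their daughters are caught by the birth rule.  Maturation is
irreversible.

*Adapted variants*: the adapted pedigree removes all cycle stochasticity
(every G1 is exactly its mean; cells stay out of phase because the
founding row starts desynchronised).  The adapted niche replaces the
sharp boundary by a maturation probability evaluated at birth — a linear
ramp centred on the boundary with half-width 0.15 x height, clipped to
[0, 1] (0 deep in the niche, 1 well above, 0.5 at the boundary).
Evaluating the ramp once per cell at birth, rather than per step, keeps
the maturation rate independent of the integration step.  The ramp is the
simplest monotone profile that smooths the labelling-index shoulder.

## Run protocol

Each run starts from one row of 22 cells at the base (stems in the
pedigree model) and advances per 10-s step in fixed order: growth, cycle
advance, positional maturation, divisions (with fate rules), mechanics,
removal at the orifice.  Counts are sampled hourly.  Steady state is
declared from the 12-hour moving-average gradient of total cell number:
the detector arms once the gradient clearly exceeds an arming threshold
(5 cells/h at full size — genuine filling shows 20-30 cells/h, the
initial transient under ~2 — scaled proportionally for smaller sheets)
and fires when the gradient magnitude first drops below 0.5 cells/h.
The run then continues for a 3-day measurement window over which all
quantities are time-averaged.  Results are means over >= 30 replicates
by default (10 in the scaled acceptance protocol); each replicate has
its own child stream of the master seed, so every run is individually
reproducible and replicate results are independent of execution order.

## Measures

Total cell number (target 704), production rate (cells leaving the
orifice per hour; normalisation target 14 cells/h, from complete renewal
of a 704-cell crypt in ~2 days — the murine epithelial turnover time),
mature proportion (target 504/704) and mature-cell order.  The order of
a cell is the unweighted fraction of its contact neighbours (zero reach)
that are mature; cells without neighbours score 1; the crypt statistic is
the mean over mature cells.  This reconstruction satisfies the printed
properties of the original statistic (near 1 for a segregated mature
compartment, strictly below 1 whenever proliferative and mature cells
touch); whether the original weighted neighbours by contact area is not
recoverable from the source, so unweighted fractions are used.

The labelling-index protocol marks every S-phase cell at steady state;
labels are heritable and never cleared; after a 1-h chase the labelled
fraction per crypt row (cell centres binned into 32 rows) is reported,
with empty rows as missing rather than zero.  Clonal experiments mark 4
distinct basal cells with heritable clone identifiers; the gap statistic
of a clone counts, per lateral column the clone occupies, unmarked cells
lying strictly between two of its members — an operational formalisation
of "gaps in the ribbons" that makes the qualitative claims testable.

## Sensitivity analysis

Relative sensitivity of a measure `f` to a parameter `p` at its normal
operating point `p0` is the dimensionless normalised derivative
`(p0/f) df/dp`, estimated by a central finite difference at `p0 (1 +- d)`
with `d = 0.1` by default (the perturbation magnitude behind the
published table is not stated; +-10% is standard practice for empirical
relative-sensitivity estimation and stays near the operating point).
Each evaluation is a replicate mean with seeds paired across the three
evaluation points, and the per-replicate central differences are
averaged, which cancels most common-mode Monte-Carlo noise; quoted
standard errors are replicate spreads.

## Parametric sweep and gating

The free-parameter grids are full Cartesian products of the printed axis
values: 72 pedigree configurations (3 adhesion strengths x 3 reaches x
active x lateral x vertical-division) and 576 niche configurations
(x 2 maturation schemes x 4 region sizes).  Model selection is
sequential gating on replicate-mean normalised measures — cell number
within [0.95, 1.01], production within [0.88, 1.12], then normalised
mature order >= 1 — with survivors ranked by production closest to
nominal, ties broken by higher order.  The gate bounds that were printed
are used verbatim; the lower bounds and the order threshold (0.90 before
normalisation) are package defaults and configurable.

## Problem sizes and numerical choices

Simulations in the shipped tests and the acceptance protocol use the
full-size crypt for the calibrated-scenario check (10 replicates), the
cell-cycle check (100,000 cells) and the sensitivity analysis (two
paired replicates per evaluation point at +-20% perturbation — enough to
resolve the production-rate magnitudes and the larger signs; entries
within a few hundredths of zero are below this protocol's Monte-Carlo
noise).  The stem-loss study runs on a quarter-scale sheet (8 cells
around, 10 high, detector thresholds scaled in proportion), where the
qualitative outcome — complete loss without attachment — completes
within a few simulated weeks.  Relative sensitivities are dimensionless
and transfer across crypt sizes only to first order: in short crypts
transit-amplifying cells exit the orifice while still cycling, which
visibly weakens the coupling between stem-cycle time and production.

Degenerate inputs: coincident cell centres receive a uniformly random
force direction from the run's seeded stream; cells pushed below the
base are clipped to `y = 0`; a crypt with no mature cells reports the
order statistic as missing; rows with no cells report labelling indices
as missing.

## Known limitations

The 2D unrolled cylinder has no hemispherical crypt bottom, so basal
geometry effects are approximated.  The drag coefficient is the same for
all cells regardless of contact area.  Active migration is a minimal
constant-drift reconstruction.  The synthetic crypt emulates cell counts,
spatial ordering and kinetics of the murine descending colon but not
crypt-to-crypt heterogeneity, cell-type diversity (columnar vs goblet),
molecular signalling, or injury dynamics; passing tests demonstrate
internal consistency with the published reference values, not fidelity
to any individual biological crypt.
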