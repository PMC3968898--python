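# Methods

## Model overview

`aneuqs` treats the karyotype — an integer copy-number vector over a fixed
set of chromosome units — as the replicating sequence of quasispecies
theory. The "symbol" is one physically distinct chromosome copy, and the
sequence length c is the total copy number, not the number of unit types
(a diploid cell over 23 units has c = 46). The unit set is frozen at
configuration time; fragments or arms that matter must be declared as
units up front, which matches the observation that most somatic
copy-number alterations involve whole chromosomes or whole arms. Dynamic
fragmentation (creation of new units during a simulation) is not modelled.

## Replication kernel

Each chromosome copy is reproduced exactly once per division with
probability Ā = 1 − E. On error (probability E per copy, i.i.d. across
copies), the daughter inherits either two copies of it (gain, fraction g
of errors) or none (loss, fraction 1 − g). Defaults: g = 0.5, symmetric
missegregation — the minimal completion of an aggregate fidelity
parameter that specifies only E. E is defined *per copy*, not per unit
type; that convention is what makes the precise-reproduction probability
Q = Ā^c an exact identity for the no-error path.

The daughter's copy count for a unit with n parental copies is the sum of
n i.i.d. {0, 1, 2} outcomes, computed by polynomial convolution; the full
karyotype transition probability factorizes over units. Two consequences
worth keeping in mind:

* gains and losses within one unit can cancel, so the diagonal
  P(k → k) exceeds Ā^c — the no-error *path* alone has probability Ā^c;
* on an enumerated space truncated at `max_copy`, daughters exceeding the
  bound constitute *escape mass*. Columns are left sub-stochastic rather
  than renormalized (renormalization would silently inflate fidelity);
  downstream, escaped mass is treated as lethal.

Whole-genome doubling as a distinct event, chromothripsis, and
copy-number-dependent missegregation rates are out of scope.

## Fitness and superiority

`single_peak_landscape` assigns A_master to the master karyotype and
A_mutant everywhere else, with a uniform death rate. A single copy-number
change can have a large phenotypic effect, which is what justifies a
sharply peaked landscape — the regime in which an error threshold exists
at all. By default, states missing every copy of some unit (nullisomy)
get fitness 0: loss of all copies of an essential chromosome is lethal.

The superiority of state m is σ̄_m = A_m / (D_m + Ē_{k≠m}). The
competitor mean Ē_{k≠m} is normalized by the competitors' total frequency
(Σ_{k≠m} E_k x_k / Σ_{k≠m} x_k). The unnormalized form diverges as
competitors vanish; the normalized form is the standard, dimensionally
stable definition and leaves σ̄ invariant under common rescaling of A and
D. Where a scan needs σ̄ at a point with no competitor mass (E = 0), it is
evaluated with competitors weighted uniformly over viable states, which
for a single-peak landscape with D = 0 reduces to A_master / A_mutant.

## Deterministic dynamics and numerics

The replicator–mutator flow is the projectivization of the linear system
y' = W y (x = y / Σy). The integrator exploits this: one matrix
exponential P = exp(W·dt) is computed (default dt = 0.5), the state is
propagated by repeated multiplication, and each step is renormalized —
this implements the mean-excess-production coupling term exactly, keeps
every trajectory point on the simplex to machine precision, and avoids
stiffness entirely. The stationary quasispecies is the normalized
dominant eigenvector of W from a dense deterministic eigensolve (no
randomized or iterative solvers, so results are bit-stable per platform).
Degenerate or complex dominant spectra raise an error rather than
returning a silently wrong state.

On a truncated space the mean excess production used for normalization is
Σ_k x_k (A_k s_k − D_k), where s_k is the column sum of the transition
kernel — i.e. escaped mass counts as dead. With a full-support kernel
(s_k = 1) this is the textbook Ē = Σ (A_k − D_k) x_k, and the simplex is
conserved exactly in both cases.

## Numeric threshold detection

`threshold_scan` rebuilds the kernel over a grid of per-copy error rates
and records the master's stationary frequency. Two operational readouts
are reported, since a finite system has no sharp singularity:

* **detected threshold** (headline): the first grid point where the
  master frequency falls below the neutral expectation 1/(number of
  viable states);
* **steepest-descent point**: the grid midpoint of the largest frequency
  drop.

Two transition models are available, and the distinction is scientific,
not numerical. The exact convolution kernel on a low-dimensional space
(one or two units) does **not** exhibit an error catastrophe: a ±1
copy-number step is easily reversed, back-mutation into the master is
strong, and the master mode merely delocalizes smoothly. The catastrophe
belongs to the high-dimensional regime in which an erroneous copy is
subject to so many further possible alterations that return to the master
configuration is negligible. That regime is realized by the *error-class
model*: states are L1-distance classes from the master, new defects per
division are Binomial(c, E), back-mutation is neglected, and the farthest
class lumps the remaining mutant cloud (retaining itself with probability
1, the classic aggregated-mutant convention). The master class then
self-reproduces with probability exactly (1 − E)^c and the scan shows the
sharp transition at σ̄ (1 − E)^c = 1. With 40 classes (default), the
neutral-crossing readout lands within a few percent of the analytic
bound ln σ̄ / c at c ∈ {10, 20, 46}; the residual deviation is dominated
by the linearization gap between ln σ̄ / c and 1 − σ̄^(−1/c), which
shrinks as c grows.

## Analytic thresholds and the MSI grid

`error_threshold(σ̄, L) = ln σ̄ / L` serves both regimes — nucleotide
(L = v, bases) and aneuploid (L = c, copies) — as two labelled fronts of
one implementation. The default output is the linearized form because
that is the standard printed form; the exact solution
1 − σ̄^(−1/L) of σ̄(1 − E)^L = 1 is available (`--exact` on the CLI), and
the two differ appreciably only near the threshold.

The canonical human parameter set ships as `HUMAN_DEFAULTS`: genome
length 3.2×10⁹, coding fraction 5%, baseline per-nucleotide error rates
10⁻¹⁰–10⁻⁹ per division, mismatch-repair-deficiency (MSI) elevation
10–10³ fold, superiority range 10²–10³, c ≈ 10², and the measured cancer
aneuploidy-rate range 10⁻³–10⁻¹. `msi_viability_report` evaluates the
nucleotide bound over the full Cartesian grid and reports every verdict,
including the corner cases that survive (baseline 10⁻¹⁰ with a ten-fold
elevation sits just under the whole-genome bound at σ̄ = 10³): the grid
is exposed rather than resolved, because the argument's force depends on
which σ̄ one grants, and that is an input, not an inference.

## Stochastic simulator

Wright–Fisher with non-overlapping generations: each generation draws N
parents by fitness-weighted multinomial sampling and replicates each once
through the kernel (vectorized as binomial draws of erring copies and
gains). Wright–Fisher was chosen over Moran because it is cheaper per
generation and nothing in the modelled setting constrains the choice.
Default fitness is flat over viable karyotypes with two lethal
boundaries: nullisomy, and copy counts above a cap (default 8) — excess
is lethal rather than clipped so the kernel is never silently distorted.
All randomness flows from one integer seed through spawned
`SeedSequence`s; identical seed and configuration give byte-identical
output.

### Two-site synthetic dataset

`generate_two_site_dataset` emulates the single-cell design behind the
adaptive-aneuploidy argument: a primary population grows from a founder
clone; one viable aneuploid cell sampled from it seeds a metastatic
population evolving at its own rate; both sites are sampled as integer
copy-number matrices, with the ground truth (rates, seed, seeding cell)
recorded for recovery tests. Default scenario, fixed once: 23 diploid
units (c = 46, human-like), N = 300, 16 generations per site, 100 cells
sampled per site, E_primary = 0.02, E_metastatic = 0.10. The five-fold
elevation keeps both rates inside the measured cancer range; population
size and duration were chosen to give the downstream statistics something
to detect at single-study scale rather than to mimic any particular
tumor's history.

What the generator does *not* emulate: stromal/diploid contamination,
measurement noise in copy-number calling, dissemination-timing structure
(parallel vs linear progression), spatial sampling, and selection beyond
viability. Passing tests on this generator therefore demonstrate that the
statistics detect rate differences under idealized clonal evolution, not
that they are robust to the full noise structure of real single-cell
data.

## Population statistics

* **Distances.** Per-cell Euclidean distance to a common root profile.
  The root defaults to the founder karyotype when known (synthetic data)
  and otherwise to the integer-rounded per-unit median of the pooled
  sample — a stand-in for the tree root we do not build (phylogenetic
  reconstruction is out of scope). Mutual pairwise distances are
  available but the headline test uses root distances.
* **Variance test.** Brown–Forsythe by default: one-way F on absolute
  deviations from the group *medians*, robust to the skewed distance
  distributions karyotype evolution produces. The F-approximation route
  delegates to the standard implementation; the permutation route
  shuffles group labels and recomputes an in-package vectorized statistic
  (cross-checked to 12 digits against the F route's statistic), with
  p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm). If every absolute deviation
  is zero the result is statistic 0, p 1, with a warning.
* **Ploidy tail weight.** The modal total-DNA-content peak is located as
  the highest-count histogram bin (Freedman–Diaconis width, Sturges
  fallback when the IQR vanishes) and the statistic is the fraction of
  cells above (1 + δ)×mode; δ = 0.15 in the shipped analyses.
* **Rate estimator.** Ê = Σ L1(parent, child) / Σ c_parent over lineage
  pairs, with a Wilson 95% interval on the ratio. Offsetting gains and
  losses within one unit cancel in L1, so Ê is a slight lower bound on
  the true per-copy rate (bias O(E²)).

## Known limitations

* **Genealogical correlation inflates the variance test.** Cells from one
  Wright–Fisher site share ancestry, so their root distances are
  positively correlated and the effective sample size is below the cell
  count; under equal rates the Levene/Brown–Forsythe test rejects more
  often than its nominal level on this design (the test itself is
  correctly calibrated on independent observations, as the calibration
  suite verifies). This caveat applies equally to variance comparisons on
  real single-clone tumor data. The end-to-end suite therefore checks
  monotone discrimination across rate ratios rather than nominal
  calibration.
* **Tail-weight ordering is not deterministic.** Under the default
  scenario the metastatic tail weight exceeds the primary's in roughly
  86% of replicates (the acceptance script recomputes this fraction):
  drift-driven clonal sweeps can shift the whole metastatic ploidy
  distribution so that its mode-relative right tail is not thicker, and
  primary subclones occasionally produce bimodal distributions whose
  global mode misplaces the tail threshold.
* The error-class threshold model neglects back-mutation by construction;
  it is the intended high-dimensional idealization, not an approximation
  of the enumerated low-dimensional kernel (which genuinely lacks a
  catastrophe).
* Exactness of transition probabilities is claimed only for the
  enumerated regime; the error-class model is an aggregation.
* No inference of σ̄ from data is attempted anywhere; all superiorities
  are inputs.
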