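# Methods

## Problem setting

`abmkf` addresses dynamic calibration of stochastic agent-based models
(ABMs) to an individual from repeated, partial measurements — the core
mathematical step of building a medical digital twin.  The obstacle is the
gap between what can be measured (a *macrostate*: counts, totals, coverage
fractions) and what the model needs to run (a *microstate*: every agent's
position, energy or category, every lattice value).  The summarization map
micro → macro is many-to-one; Kalman-type filters act naturally on the
macrostate but give no rule for updating microstates.

The package couples an ensemble Kalman filter (EnKF) on transformed
macrostates to microstate-synthesis procedures.  One assimilation cycle:

1. advance every member's microstate with the stochastic model;
2. summarize microstates into a macro ensemble;
3. at measurement times, apply a perturbed-observation ensemble Kalman
   update to obtain a Gaussian posterior over macrostates;
4. draw a fresh macro ensemble from that posterior;
5. synthesize, for each posterior sample, a compatible microstate seeded
   from a nearby predictive member's microstate.

Step 5 rests on a continuity assumption — nearby macrostates have similar
conditional microstate distributions — so each posterior sample is paired
with its closest predictive member (Gale–Shapley stable matching under
mutual distance preferences, posterior side proposing, ties to lower index)
and realized by minimally editing that member's microstate.

## Filter

The update is the classic stochastic (perturbed-observation) EnKF: sample
moments with denominator *n* − 1, gain `K = P Hᵀ (H P Hᵀ + R)⁻¹` from the
sample covariance, each member updated with an independently noised copy of
the observation.  The measurement operator is component selection in
transformed macro space, and `R` is specified in transformed units.  After
each update a Gaussian is fitted to the updated members and a fresh ensemble
is resampled from it, since the synthesis step consumes posterior samples
rather than updated members.  Covariances are symmetrized, eigenvalues
clipped at zero, and a jitter of 1e-8·I is added before sampling; the jitter
matters near absorbing states (species extinction), where ensemble spread
collapses.

Model parameters that vary between individuals are appended to the state
vector and each member is advanced under its own parameter values
(augmented-state filtering).  Process noise is added only to the parameter
block, as independent Gaussian random-walk increments with per-parameter
variance `Q_param`; the simulators supply their own stochasticity for the
state block.  The exact linear Kalman filter is implemented alongside and
serves as the analytic oracle in tests (the ensemble update must reproduce
it on linear-Gaussian problems as the ensemble grows).

## Variable transforms

The Kalman filter is a least-squares estimator and effectively ignores
components orders of magnitude smaller than others, so macro components are
transformed before filtering.  For the predator-prey model: wolf counts
concentrate near zero (extinctions are common) and get the shifted log
`W' = log(ε + W)` with ε = 0.001 and clamped inverse `max(0, exp(W') − ε)`;
sheep counts are scaled by 0.1 and grass counts by 0.01, bringing all
components to the same order as the log-wolf values and the parameters.
For the viral model, field totals get the same shifted log and lattice
counts are scaled by 100/(lattice size).  Filtered values stay real
throughout; rounding to integers happens only inside synthesis, by
largest-remainder rounding so category counts keep their exact total.

## The two example models

**Predator-prey (wolves, sheep, grass).**  A re-implementation of the
classic predator-prey lattice model: wolves and sheep random-walk on a
continuous torus (uniform turn in ±50°, one patch per step, one energy unit
per step), eat at their patch (sheep eat live grass, each wolf eats at most
one co-located sheep, chosen uniformly), reproduce with fixed probability by
halving energy, die below zero energy; grass regrows on a fixed timer.
Substep order is move → eat → reproduce → die → regrow.  Defaults follow the
reference model (reproduction 5%/4%, food gains 20/4, regrowth 30 steps) on
a 51×51 world with 50 wolves, 100 sheep and half grass coverage.  Initial
energies are uniform on (0, 2×gain].  Because all three spatial
distributions are near-uniform, synthesis is uniform resampling: agents
added at uniform positions (energy resampled from survivors, per the
continuity principle), removed uniformly, grass flipped uniformly among
eligible patches.  The macrostate is (wolves, sheep, live-grass count).

**Minimal viral-infection model.**  A deliberately small stand-in for
detailed respiratory-infection ABMs, keeping exactly the state structure
that makes synthesis hard: a categorical epithelial lattice (Healthy,
Infected, Necrosed, Apoptosed, Empty), a categorical endothelial lattice
(Normal, Activated, Dead), molecular fields (virus plus antiviral-like,
proinflammatory-like and damage-signal cytokines) diffusing by an explicit
5-point stencil with zero-flux boundaries (stability bound D ≤ 1/4) and
decaying multiplicatively, and mobile immune agents that chemotax up the
proinflammatory field and kill co-located infected cells.  Healthy sites are
infected with probability 1 − exp(−β·virus); infected sites secrete virus
and cytokines and die by apoptosis (promoted by the antiviral signal, and
counted when caused by virus) or necrosis; necrotic sites emit damage that
activates and eventually kills endothelium.  Infection therefore grows as
contiguous hot-spots around seeding sites — the spatial structure that
uniform-random synthesis destroys.  The macrostate has 14 components: four
field totals, five epithelial and three endothelial counts, the immune-agent
count, and the virus-killed counter.  The default lattice is 51×51; tests
and the shipped experiments use 25×25 or 15×15 to keep desk-scale runtimes.
This model makes no claim of immunological fidelity (no dendritic/NK/
macrophage subtypes, no intracellular virus); it exists to exercise the
synthesis machinery on realistic state *shapes*.

## Spatially aware synthesis

Molecular fields are updated by multiplicative rescaling to the target
total, which preserves spatial correlations exactly (a zero field demanded
to become positive is set uniform).  Categorical lattices cannot be scaled,
so they go through a 3-step pipeline:

1. **One-hot encoding**: category *i* → basis vector e_i, so category counts
   are the componentwise sums over sites.
2. **Rescaling**: every site vector is multiplied componentwise by
   new_count/old_count, making the site-sum equal the target counts (a
   category absent from the seed is spread uniformly).
3. **Quantization with error diffusion**: sites are visited in a seeded
   random permutation (raster order would bias hot-spot edges
   directionally).  At each site the chosen label minimizes

   L(q) = λ₁·|q − s|² + λ₂·(−log(c·q + 1)) + λ₃·(−log p(neighborhood))

   over the categories whose running quota remains positive, where `s` is
   the current (diffused) site vector, `c` counts labels among the 8
   neighbors (assigned labels where available, otherwise the provisional
   argmax), and `p` is an empirical neighborhood model.  The residual
   Δ = q − s is split uniformly (negated) over the unquantized 8-neighbors,
   so total vector mass is invariant mid-pass; a site with no unquantized
   neighbor pushes −Δ onto a global accumulator.  Quota feasibility makes
   the final counts match the target exactly.

A final repair phase applies lowest-delta relabeling *cycles* (negative
cycles over the category graph, found by Floyd–Warshall on cheapest per-site
relabel costs) until no strictly loss-reducing relabeling remains.  Greedy
diffusion alone is order-dependent and can land a few percent above the
count-constrained optimum; with the neighborhood terms off, the repair phase
drives the result to the exact transportation optimum on enumerable
lattices, which is how it is validated.  Costs in the repair phase are
evaluated against the original rescaled field, with neighborhood terms in
the final label context (for active λ₂/λ₃ this is a local polish, not a
global optimum — the loss is then not separable across sites).

The neighborhood model is a histogram over discretized 3×3 configurations
(nine cell categories, off-lattice positions padded, plus a log-binned local
proinflammatory level, 8 bins spanning the training range) with add-one
smoothing that reserves one unit of mass for unseen configurations, so
−log p is always finite.  Default loss weights are λ = (1, 1, 1) when a
model is supplied and (1, 1, 0) otherwise; the smoothing constant in the
λ₂ term is 1.  All of these are configurable.

The geometry-blind alternative (`simple_synthesis_viral`) relabels uniformly
chosen sites, changing exactly half the L1 distance between count vectors —
minimal in edit count but indifferent to geometry, so it fragments hot-spots
by scattering new infected sites; the paired comparison of 8-connected
infected components against the spatial route quantifies this.

Mobile immune agents are removed uniformly or added at sites sampled
proportional to the proinflammatory field (uniformly in the simple route);
cytokine-weighted placement is this package's choice for a quantity whose
conditional spatial law is otherwise unspecified.

## Evaluation

*Surprisal* is reported in nats from the Gaussian closed form above,
evaluated on the full transformed macrostate including parameters (forecast
quality over unobserved components is exactly what assimilation should
improve).  Being a differential quantity it can be negative; only
differences and comparisons are meaningful.  *Wasserstein-2* between
Gaussian cluster summaries uses the closed form with matrix square roots by
symmetric eigendecomposition (negative eigenvalues clipped at zero).
Phenotype discovery flattens each macro trajectory to one vector, reduces by
PCA to 3 components, and k-means clusters (10 restarts, seeded) with k ∈
[2, k_max] chosen by silhouette; a degenerate cohort falls back to a single
cluster.  Tuning sweeps run cohorts of virtual patients across measurement
choices and noise levels (the shipped grid is R ∈ {10, 1, 0.1, 0.01}) and
report pointwise median surprisal.

## Study conditions and problem sizes

The shipped predator-prey twin experiment uses 30 virtual patients, horizon
200 steps, ensemble size 50, sheep measured every 20 steps with R = 0.01
(transformed units, i.e. ±1 sheep at 1 s.d.), on the 51×51 world.  Patient
parameters (the two reproduction probabilities) are drawn from the prior
N(0.05, 0.02²) × N(0.04, 0.015²), held constant along the true trajectory,
and random-walked with Q_param = 10⁻⁶ per step inside the filter only —
per-step drift of ~0.1% of a probability, accumulating to a few percent over
the horizon, which is the scale of individual variation the prior encodes.
The no-measurement baseline is the identical ensemble forecast with an empty
schedule.  Spatial-coherence and clustering experiments use 25×25 and 15×15
lattices with 50 paired trials and 40 trajectories respectively.  These
sizes are the package's standard desk-scale conditions; all of them are
config fields.

## What the synthetic experiments do and do not show

Virtual patients are drawn from the same model family and prior as the
filter ensemble, so twin experiments measure the assimilation machinery
under a well-specified model: no structural model error, no measurement-
procedure effects (assay bias, sampling site), and regular measurement
schedules.  Passing them shows the filter-synthesis loop is internally
consistent and informative, not that any particular clinical model is
identifiable from clinical data.  Known failure modes are retained
deliberately: when an observable cannot distinguish two absorbing basins
(e.g. measuring only an extinct predator while prey may or may not have
collapsed), the unimodal Gaussian belief commits to one basin and further
measurements of that observable cannot correct it; and when a cohort's
phenotypes diverge mid-trajectory, a minimum-mean-square-error estimator
places mass between clusters.  Both are documented behaviors, not bugs; a
stratified filter or multimodal posterior family would be required to remove
them.

## Numerical choices

- Covariance symmetrization at 1e-10 tolerance; eigenvalue clipping at 0;
  sampling jitter 1e-8·I.
- Singular innovation covariance raises rather than pseudo-inverts.
- Largest-remainder rounding breaks ties toward lower index; quantization
  ties resolve to the lower category index; Gale–Shapley ties to the lower
  member index.  All randomness flows through four named seeded streams
  (patient, ensemble, filter, synthesis), making end-to-end runs exactly
  reproducible.
- Posterior macro targets are clamped to valid domains before synthesis
  (counts at 0 and at lattice/patch capacity); parameter values are clamped
  to their declared bounds before being handed to a simulator.
- Filtered grass targets above the patch count are clamped at capacity by
  the driver; `synthesize_wsg` itself treats them as an error.
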