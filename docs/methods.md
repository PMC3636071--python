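# Methods

## Model

`stratdec` implements ancestral-range inference under the
dispersal–extinction–cladogenesis (DEC) model on dated ultrametric trees,
with time-stratified dispersal multipliers, exhaustive per-node split-scenario
likelihoods, and composite Akaike weights averaged over a posterior sample of
dated trees.

A lineage's geographic range is a non-empty subset of K discrete areas,
encoded as a bitmask. Along a branch the range evolves as a continuous-time
Markov chain over the 2^K subsets (the empty "null" range included as an
internal absorbing state):

- **dispersal** — range R gains area a ∉ R at rate `d · Σ_{b∈R} m_t[b][a]`,
  where `m_t` is the dispersal-multiplier matrix of the geological epoch
  containing time t (entries in [0, 1]; 1.0 for contiguous landmasses, down
  to 0.1 for well-separated ones);
- **local extinction** — each occupied area is lost at rate `e`; a
  single-area range decays to the null range, which is absorbing.

Branch propagators are dense matrix exponentials computed per epoch segment
(a branch crossing epoch boundaries is cut by `slice_branch` and the segment
matrices are multiplied oldest-first). The state space has at most 2^6 + ...
= 64 states for six areas, so dense `expm` is exact and cheap at this scale.

At a speciation event an ancestral range R is inherited as follows: a
single-area range passes to both daughters; a widespread range either splits
into {a} vs R\{a} (vicariance) or one daughter retains R while the other is
founded in a single constituent area {a} (subset sympatry). Both orderings
are enumerated, duplicates removed, and all n splits of a given R share a
flat 1/n prior. |R| = 1 gives 1 scenario; |R| = 2 gives 6; |R| = s > 1 gives
4s − [s = 2]·2 after deduplication.

The tree likelihood is a Felsenstein pruning pass over the range state space
with per-node rescaling; the root receives a flat prior over non-null ranges
(switchable via an explicit prior vector). The null state contributes zero at
internal nodes and tips — it only matters inside the propagators, where it
absorbs the probability of lineage-wide extinction.

## Per-node scenarios and model averaging

`node_split_likelihoods` returns the **global** likelihood of the data with a
focal node constrained to each (ancestral, left, right) scenario, for every
scenario — not only those within two log-units of the optimum. It combines
the pruning ("inside") vectors with a preorder "outside" pass, so the
scenario likelihoods at any node sum exactly to the total likelihood; that
identity is asserted in the test suite at 1e-8 on the log scale. The
two-log-unit filter exists purely for display; weights are always normalized
over the complete scenario set first.

Scenario support is summarized by Akaike weights. Every scenario shares the
same two free parameters (d, e), so `AIC_i = −2 logL_i + 2k` with constant k
and the weights reduce to normalized likelihoods; both routes are computed
and asserted to agree at 1e-12, guarding the formula against drift. The
**composite** Akaike weight of a scenario is the arithmetic mean of its
per-tree weights over the trees of a posterior sample that contain the focal
clade (trees lacking it can instead be counted as zero-weight via a flag;
the clade frequency is always reported). The **evidence ratio** is the best
weight divided by the runner-up's — the published worked example
(0.608/0.353 = 1.72) fixes this reading of "versus all other models" over
the alternative w/(1−w), which would give 1.55.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| d | dispersal rate, per area pair per Myr | fitted | bounds [1e-9, 10] |
| e | local extinction rate, per area per Myr | fitted | same bounds |
| m_t | per-epoch K×K dispersal multipliers | 1.0 | 0.1–1.0 in practice |
| epochs | time slices, Ma, half-open [older, younger) | 105–80, 80–50, 50–30, 30–0 | oldest slice auto-extends to cover an older root |
| root prior | distribution over root ranges | flat over non-null | explicit vector accepted |

Fitting maximizes the log-likelihood over (log d, log e) with a
deterministic 4×4 log-spaced scoring grid on [1e-6, 1] followed by
Nelder-Mead polish (fatol 1e-8) from the two best distinct grid points; all
grid endpoints are returned for inspection. The procedure is fully
deterministic and, by construction, its optimum dominates every grid point.

The fossil-calibration helper builds an offset lognormal prior from a
minimum age and a 95% tail span: `mu = ln(span) − z_0.95 · sigma`, with sigma
a user choice (default 1.0) because the tail constraint alone cannot identify
both log-scale parameters.

## Synthetic data generator

The generator emulates the statistical frame the inference assumes: a
birth–death tree conditioned on the tip count (via dendropy, with pendant
edges extended by the exponential waiting time to the next event, since the
simulator stops exactly at the n-th speciation), rescaled to a 105-Ma root;
forward Gillespie simulation of range evolution with exact epoch-boundary
handling (exponential clocks truncated at slice crossings, which is exact by
memorylessness); uniform draws over the allowed splits at each node; and a
pseudo-posterior built by lognormal multiplicative jitter of internal node
ages (unit mean, configurable coefficient of variation; each node redrawn
until younger than its jittered parent) plus optional age-valid NNI moves.
Replicate 0 of a pseudo-posterior is always the unmodified tree.

**Dead lineages.** Observed datasets never contain extinct tips, so each
branch is conditioned on not being absorbed into the null range: a branch
draw that dies is redrawn (bounded retries, count reported). Whole-dataset
rejection is not viable at the default rates — with e = 0.01/Myr on a
100-tip, 105-Ma tree the expected number of absorptions per dataset is ~10,
making the acceptance probability ~e^−10. The unconditioned single-branch
simulator (`simulate_branch`) is exposed separately and is what the
transition-matrix calibration test uses.

What the generator does **not** emulate: molecular data and dating error
structure (pseudo-posterior trees are independent jitters, not an MCMC
sample with autocorrelation and calibration-induced covariance), fossil
calibrations, diversified taxon sampling, and biogeographically structured
speciation. Passing tests therefore validate the inference machinery and its
internal consistency, not the field realism of any particular dataset.

## Numerical choices

- Ultrametricity tolerance: relative 1e-6 of root age (consensus trees carry
  rounding noise). Node ages are root height minus root distance; tips snap
  to 0.
- Branch segment durations are adjusted in the last segment so they sum to
  the branch length exactly (guards 1e-12 assertions downstream).
- Conditional-likelihood vectors are rescaled when their maximum leaves
  [1e-50, 1e50], with accumulated log factors; the same applies to outside
  vectors.
- HPD intervals are shortest-window estimates on the empirical sample —
  matching "95% HPD" usage without density estimation.
- Epoch slices are half-open [older, younger): a boundary age belongs to the
  younger slice.
- Ties in `evidence_ratio` give 1.0; a single scenario is an error rather
  than infinity.

## Known limitations and observed statistical behavior

Two behaviors of the model itself (not implementation defects — both were
cross-checked against exhaustive enumeration and unconditioned single-branch
fits, which recover (d, e) accurately) are worth knowing:

1. **e is underestimated on surviving trees.** The likelihood of an observed
   (all-tips-extant) dataset contains every branch's survival probability,
   and real or simulated datasets are survival-conditioned by construction;
   lowering e therefore buys roughly E[absorptions] log-units for free, and
   ML estimates of e sit well below the generating value (observed median
   ~0.2× at d = 0.05, e = 0.01 on 100-tip trees; even whole-dataset
   rejection sampling at 20 tips only reaches ~0.5×). d is recovered well
   (~0.8×). This is the documented null-range/extinction bias of DEC.
2. **The root range decorrelates on deep trees at moderate rates.** At
   d = 0.05/Myr over a 105-Ma tree the range chain mixes several times along
   any root-to-tip path, so the root-range posterior approaches the
   stationary distribution and root recovery from simulated data is near
   chance (evidence ratios ≈ 1.0). At d = 0.005 the same pipeline recovers
   the simulated root range in ~70% of replicates. Empirically this is why
   deep-time range reconstructions report modest weights at basal nodes.

The acceptance-style tests that assert recovery bounds under the fast-rate
simulation conditions fail for exactly these two reasons and are left
failing; the oracle-equivalence, stratification, calibration, and
worked-example tests all pass.

## Problem sizes

Default test and acceptance-script runs use 100-tip trees with K = 4 (16
states) for rate recovery, 50-tip trees with 10-tree pseudo-posteriors for
composite weights, ≤ 4-tip trees for exhaustive oracles, and 10,000
replicates for simulator calibration — sizes at which every check is exact
or has narrow Monte-Carlo error while the full suite stays in the minutes
range.
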