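# Methods

## Model

Binary units `sigma in {0,1}` are updated asynchronously by thresholding
their summed input (recurrent plus a constant external drive `J_aX m_X`,
minus the threshold `theta_a`).  Connectivity is independent Bernoulli per
ordered pair; weights scale as `J_ab = j_ab / sqrt(N)`.  The balanced-state
weight constants follow from two requirements: `sqrt(K)` excitatory inputs
within one time constant reach threshold (`sqrt(p_aE N_E) J_aE = theta_a`),
and excitation and inhibition cancel row-wise, with surplus inhibition
controlled by `g`:

    j_EE =  theta_E / sqrt(p_EE n_E)          j_IE =  theta_I / sqrt(p_IE n_E)
    j_EI = −g j_EE p_EE n_E / (p_EI n_I)      j_II = −j_IE p_IE n_E / (p_II n_I)

Here `n_a = N_a / N` is the population **fraction**.  Some presentations of
this derivation print `n_E = N / N_E`; that convention breaks the threshold
normalisation (it yields `j_EE = 2.0` instead of `2.5` at the reference
parameters and a 20% residual in the normalisation identity) and we treat it
as a typo.  With fractions, the identities hold to machine precision and the
mean population weight is `Jbar_ab = j_ab p_ab n_b sqrt(N) = N_b p_ab J_ab`.

The population rates follow Gaussian mean-field dynamics
`tau_a dm_a/dt = −m_a + H(−mu_a/s_a)` with
`mu_a = sum_b Jbar_ab m_b + J_aX m_X − theta_a` and
`s_a^2 = sum_b p_ab (1−p_ab) j_ab^2 n_b m_b` (input correlations neglected;
the variance is carried entirely by the Bernoulli variance of the realised
weights).  Cluster multipliers enter `Jbar` linearly and the weight variance
quadratically.

## Reference parameters

All defaults follow the standard configuration of this model family:
`N_E = 4000`, `N_I = 1000`, `Q = 20`, `theta = 1`, `p_EE = 0.2`,
`p_EI = p_IE = p_II = 0.5`, `g = 1.2`, `J_EX = sqrt(p_EE N_E)`,
`J_IX = 0.8 J_EX`, `m_X = 0.03`, `tau_E = 10 ms`, `tau_I = 5 ms`.  The time
constant is nominal — the asynchronous update rule makes all results depend
only on the ratio `tau_I/tau_E`.  `J_EX`/`J_IX` are stored as factors of
`sqrt(p_EE N_E)` so that resizing a spec preserves the scaling (explicitly
given values are kept verbatim).

## Finite-size behaviour (what simulations can and cannot confirm)

The closed-form balanced rates `(0.0589, 0.0741)` are the `N -> infinity`
limit.  At finite `N` the steady state of the full self-consistency equation
`m = H(−mu/s)` sits considerably lower — `(0.0295, 0.0341)` at `N = 5000` —
because the balance cancellation is only enforced up to `O(1/sqrt(N))`
corrections with a large prefactor.  Simulations agree with the *finite-N*
fixed point to within a few percent (residual finite-size correlations
account for the remainder) and drift towards the closed form as `N` grows;
the test suite checks exactly these two statements rather than direct
agreement with the closed form at `N = 5000`, which does not hold.

Two degenerate features of the low-drive regime matter for testing:

* **The all-silent state is absorbing.**  With `J_EX m_X = 0.849 < theta`,
  a network with no active unit stays silent, and the mean-field equations
  have a corresponding `s^2 = 0` fixed point.  It lies outside the
  Gaussian-input theory and is excluded from all fixed-point reports
  (states with `s^2` below `1e-9` are discarded).
* **The oscillatory regime ends in extinction.**  For `tau_I/tau_E` above
  the critical ratio `r2 (~1.5 here)` the balanced fixed point is unstable;
  the flow spirals outward in a large-amplitude oscillation whose troughs
  reach vanishing rates, where the network (and the clipped mean-field
  integration) falls into the silent state.  Tests therefore assert
  departure-plus-extinction at ratio 2 and persistence at ratio 0.5 rather
  than a sustained spectral peak.
* At the reference drive no active fixed point exists below roughly
  `N ~ 3000` (total); small demonstration networks in the tests use a
  stronger drive (`m_X = 0.2`).

## Fixed-point machinery

* **Homogeneous state** (all clusters at one rate): solved on the grouped
  (2- to 4-dimensional) system by damped relaxation with *uniform* clocks
  (fixed-point locations are tau-independent; uniform clocks avoid the
  limit-cycle regime), then a Newton (hybr) polish; several starting levels
  guard against the silent basin.  Lifted to the full system and classified
  there; residual tolerance `1e-9`.
* **Random-restart sampling**: uniform initial rates, 50 `tau_E` of Euler
  pre-integration (`dt = 0.05 min(tau)`), a bounded Nelder–Mead coarsening
  of the squared residual, then the Newton polish.  Pre-integration biases
  the search towards stable states; unstable refinements are discarded by
  default.  Deduplication rounds rates to `1e-4`, sorts the excitatory
  cluster block descending, and counts clusters above the midpoint between
  the largest and smallest cluster rates as *active* (a homogeneous state
  has zero active clusters).
* **Constrained solving**: states with `n` active clusters solved on the
  reduced system (focus clusters / remaining clusters / inhibitory
  partners / remaining inhibition), from a grid of starts, lifted back,
  re-verified and re-classified in the full system.  Finds unstable
  intermediate branches the sampler cannot.
* **Effective response function**: the slave system (everything except the
  focus cluster) is relaxed by short integration plus Newton polish,
  continued along a 201-point grid of imposed focus rates; diagonal
  crossings are bisected to `~1e-12`, slopes estimated by central
  differences, and full-system stability evaluated at the lifted state
  (curve stability — slope < 1 — does not imply global stability).
* **Critical clustering strengths** are reported as the first point of a
  0.1-step scan meeting the criterion (homogeneous state unstable, or more
  than one EFR crossing), matching how such thresholds are read off a
  sweep; `refine=True` bisects to 0.01 instead.  At the reference
  parameters the scan gives 2.9 (E-only), 1.9 (up-state emergence; the
  exact tangency sits at ~1.87) and 4.0 (EI, `R_J = 3/4`).

A subtlety of the EI landscape: targeted *two*-active constrained solving
reveals a stable 2-active branch that creeps slightly above rate 0.7 (up to
~0.72) for `J_E+ ~ 13.5–16` at `R_J = 3/4`.  Its basin is so small that
uniform random-restart sampling never reaches it, which is why sweeps
combining sampling with single-active solving — the procedure used for the
headline "rates stay below 0.7" result — report a maximum of 0.60.

## Simulator

Continuous-time event loop (Gillespie-style): total rate
`Lambda = N_E/tau_E + N_I/tau_I`, exponential waiting times, population
chosen proportional to `N_a/tau_a`, unit uniform within the population.
This realises exponential per-unit inter-update intervals with mean `tau_a`
and the population update-probability ratio `P_UE/P_UI = tau_I/tau_E`; the
discrete one-unit-per-step rule is the equal-tau special case.  Recurrent
inputs are maintained incrementally along outgoing synapses on state flips,
so cost scales with flips, not updates.  Initial states are Bernoulli(0.5)
by default; a spike is a 0 -> 1 transition.  Runs are bit-reproducible from
(matrix seed, simulation seed).

**Rate estimation.**  Per-cluster rates are reported per time bin (default
10 ms) as the *time-averaged occupancy* within the bin — the unbiased mean
of the instantaneous up-fraction — rather than the state sampled at the bin
end, which carries additional binomial noise of `sqrt(m(1−m)/N_c)` per bin
(~0.03 for 200-unit clusters) that inflates both variance baselines and
observed maxima.  Endpoint sampling remains available
(`cluster_rates(..., method="endpoint")`).  The winnerless-competition
statistic `sigma^2_m` is the variance over time of each cluster's binned
rate after a 100 ms transient discard, averaged over clusters; no smoothing
is applied.  Sweeps average `sigma^2_m` over connectivity realisations and
trials (the acceptance protocol uses 5 x 5 at 1000 ms per grid point, which
bounds the run time while leaving the 5x-over-baseline onset criterion far
from its noise floor — at the onset the variance jumps by more than an
order of magnitude).

## Connectivity variants

Besides uniform weight clustering (`E_weights`) and paired EI clustering
(`EI_weights`, with `J_I+ = 1 + R_J (J_E+ − 1)` shared by the EI/IE/II
blocks), the builder supports an unstructured background population
(background units connect everywhere with unmodified weights; the `J_-`
renormalisation applies among clustered units only, so every row keeps its
expected input) and probability clustering (`p_in = R_EE p_out` with the
block mean preserved, plus an optional within-cluster weight factor,
default 1.9, taken from the construction this variant emulates — it plays
no role in any quantitative result here).  Self-connections are excluded;
at `N = 5000` this shifts expected row sums by one synapse (`p J J_+`),
which the tests account for.  Matrices are dense up to 6000 units and
CSR-sparse above, built block-wise from the same per-pair law.

## Known limitations

* Input correlations are neglected in the mean field; the few-percent gap
  between simulated rates and the finite-N fixed point is of that origin.
* The EFR at `J_+ = 1` is flat only up to an intrinsic slope of
  `−1/(Q−1)` (the focus cluster displaces its share of the total
  excitatory rate); "flat" means small against the unit diagonal.
* `sigma^2_m` depends on the binning convention; peak *location* is robust,
  absolute amplitude is not, and only the location is used quantitatively.
* No correlation-corrected or `1/N`-corrected mean field, no spatial or
  overlapping cluster topologies, no spike-interval statistics (binary-unit
  spike trains are artifacts of the update rule).
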