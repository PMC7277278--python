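# Methods

`gravroute` estimates long-distance traffic of potential invasion or
disease vectors ("agents", e.g. trailered boats) through a road network,
from counts collected in roadside surveys.  This note documents the model,
its assumptions, the estimation procedures, the synthetic-data generator
and the numerical choices.

## Observation hierarchy

An agent is recorded in a survey shift only if it (i) makes the trip,
(ii) routes via the survey station, (iii) passes during the shift window,
and (iv) stops and provides complete data.  Each stage has its own
submodel; the observed count in a (shift, origin–destination) cell is
negative binomial with mean

    E[N+] = mu_ij * rho_ijk * tau_t * xi

and a mean-to-variance ratio `p` shared by all cells.

### Gravity model

Mean daily OD flow: `mu_ij = c * m_i * a_j * d_ij^(-alpha_d)` with
repulsiveness `m_i` and attractiveness `a_j` composed from one-covariate
building blocks — power `f0(x) = x^a1` or saturating
`f1(x) = (x/(x+a0))^a1` — multiplied for "and" relations and added for
"or" relations.  The applied composition is

    mu_ij = c * f1(pop_i; pop0) * beta_CA^CA_i * f1(A_j; A0)
              * (1 + beta_camp*camp_j + beta_fac*fac_j + beta_mar*mar_j
                   + beta_lpop * f1(lpop_j; lpop0))
              * d_ij^(-alpha_d)

Units matter: populations in 1e6 persons, near-lake populations in 1e3,
lake areas in km², travel times in 1e4 minutes.  The default parameter
values are the estimates for the British Columbia boater-traffic system
(`c = 3.73e-8`, `p = 0.23`, `alpha_d = 3.45`, `pop0 = 0.16`,
`beta_CA = 14.79`, `A0 = 1236`, `beta_camp = 6.55`, `beta_fac = 4.51`,
`beta_mar = 26.4`, `beta_lpop = 1011`, `lpop0 = 888`; the exponents
`alpha_pop`, `alpha_A`, `alpha_lpop` are fixed at 1).  `c` absorbs the
overall scale; the repulsiveness composition has leading coefficient 1 so
that `c` is identifiable.

### Count law

Counts are negative binomial parametrised by the *success* parameter
`p` (mean `mu`, variance `mu/p`, shape `r = mu p/(1-p)`).  With `p`
shared, independent NB terms add within the family, so predictions are
invariant to how individual origins or destinations are pooled into
regions, and restricting a day to a time window scales the mean by `tau`
while staying in the family.  `p = 1` is handled as the Poisson limit and
`mu = 0` as a point mass at zero.

A caveat documented deliberately: thinning an NB count *per agent*
(binomial thinning by `rho` or `xi`) preserves the NB family but changes
the success parameter.  The fitted observation law keeps the shared `p`
with a thinned mean — exact for window splitting, an approximation for
per-agent thinning.  The package therefore treats `p` as an
observation-level dispersion parameter; see "Synthetic data" below for
the consequence.

### Route choice

Admissible routes are single-via paths (shortest path through one chosen
intermediate vertex) within stretch `gamma` of the shortest travel time
that contain no local detour: every subpath of along-path length at most
`delta * l_P` must itself be a shortest path (relative length tolerance
1e-9).  Defaults `gamma = 1.4`, `delta = 0.2`.  Shortest-path ties are
broken by lexicographic vertex order so enumeration is reproducible;
random-weight networks have no ties.  Correctness of the enumeration is
defined by (and tested against) a brute-force filter over all simple
paths on small graphs.

Conditional on travelling admissibly, a path is chosen with probability
proportional to `length^(-lambda)`.  With probability `eta_c <= 0.05` an
agent instead takes an inadmissible route and then passes any given
station with probability `eta_o` (one shared `eta_o`; the noise model is
location-free, so this flow is never mapped to specific edges).  The
passage probability is
`rho_ijk = (1-eta_c) * (choice mass of admissible paths via k) + eta_c*eta_o`.
Stations at OD endpoints never count as passages (surveys happen en
route).  `eta_c` and `eta_o` are not identifiable from station counts
alone, hence the hard bound on `eta_c`; it is estimated on [0, 0.05] by
clipping, with the bound reported when active.

### Temporal pattern

Daily traffic density is a von Mises distribution rescaled to a 24 h
period: peak time `theta` (hours), concentration `kappa`
(midday/night density ratio `exp(2 kappa)`; `kappa = 0` is uniform).
Defaults `theta = 14.00`, `kappa = 1.34`.  The pattern is assumed
independent of the survey location; weekly and seasonal cycles are out of
scope (their overdispersion is absorbed phenomenologically by the NB
law).  Window probabilities `tau` use the von Mises CDF extended
periodically; windows wrapping midnight are split at 0 h and summed.

### Compliance

A single global rate `xi = xi_p * xi_c`: the participation rate
(stopped / passed) times the complete-data rate among stopped high-risk
agents.  Constant across agents, times and stations by assumption, so
counts pool before estimation.  Exact Clopper–Pearson intervals are
attached.

## Estimation

Fitting is staged in the order inverse to the hierarchy — compliance,
temporal, route choice, gravity — and the gravity stage refuses to run
without the upstream parameters.

* **Temporal**: conditional maximum likelihood; each observed passage
  time contributes `log density(t) - log tau(shift)`, removing the bias
  from uneven survey scheduling.  The log-likelihood reduces to
  sufficient statistics (summed sines/cosines) plus one window term per
  distinct shift window, so evaluation is O(#windows).
* **Route choice**: conditional likelihood given what was monitored: an
  agent with OD (i,j) recorded at station k contributes
  `log[rho_ijk w_k / sum_k' rho_ijk' w_k']` over monitored stations,
  where `w_k` is the station's monitoring effort — by default the
  tau-weighted sum of its shift windows (duration weighting is a config
  option).  `lambda` is flagged unidentifiable when every observed OD
  pair has a single admissible route.
* **Gravity**: composite likelihood treating all (shift, OD) cells as
  independent, including the implicit zero cells.  Cells with identical
  predicted means (same station, same window probability, quantised at
  1e-12 relative precision) are grouped: the all-zero bulk costs one
  closed-form `log P(0) = r log p` evaluation per group, which makes the
  cost independent of the shift count.  The grouped computation is tested
  against a naive double loop.  Optimisation is multi-start L-BFGS-B
  (default 10 restarts, deterministic seed) with positive parameters on
  the log scale and `p` on the logit scale; invalid regions return a
  large finite penalty rather than infinity so numeric gradients stay
  usable.

**Profile confidence intervals.**  Endpoints are where the profile
log-likelihood drops by `chi2_1(0.95)/2 = 1.92`, found by geometric
bracketing plus Brent root-finding; nuisance parameters are re-optimised
at each profile point, warm-started but with a fallback restart from the
MLE (a failed warm start must not poison later evaluations).  Gravity
profiles run on the transformed (log/logit) scale, where the likelihood
is closer to quadratic, and endpoints are mapped back.  A profile that
never reaches the drop before a parameter bound yields an open interval
side.  Because the composite likelihood ignores dependence between
cells, its intervals can undercover; the recovery tests use an 85%
acceptance rate for the gravity stage for this reason.

**Model selection** uses AIC = 2k − 2·(composite log-likelihood) with
stable name-ordered ties.  Two fit metrics are provided: a
variance-corrected R² on midday (11.00–16.00) station means, where
observed and predicted means are normalised by the model-predicted
standard deviation `sqrt(mean/(p m))` over `m` identically distributed
shifts (per-station aggregation); and Nagelkerke's pseudo-R² against a
null model with uniform temporal pattern, route choice carrying no
information (`eta_c = 1`), and constant mean and dispersion — the null is
fitted by its own ML, and `n` in the formula is the number of likelihood
cells (a documented convention choice).

## Synthetic data

The generator emulates a large-scale survey system: a planar road
network (Delaunay triangulation thinned to a spanning tree plus a random
55% of the remaining edges; travel times are Euclidean minutes times a
windiness factor U(1, 1.3)), origins clustered on the eastern edge,
destination lakes elsewhere, and stations on high-betweenness corridor
vertices.  Covariates are drawn on the scales the parameters expect:
origin populations log-normal (median 3 million), lake areas log-normal
(median 100 km², heavy tail), near-lake populations log-normal (median
2 thousand), facility indicators Bernoulli (camp 0.4, fac 0.5,
mar 0.15).  With the default 900×600-minute extent and the default
parameter values this yields a total external inflow of roughly 26
agents/day over 2000 OD pairs — a realistic intensity for a
continental-scale inflow into one province.  The default scenario
(20 origins, 100 destinations, 300 vertices, 12 stations, 500 shifts)
runs the full pipeline in a few minutes on one CPU; the test suite uses
more compact variants (smaller spatial extent, hence shorter trips and
denser traffic) so that fits are well-conditioned at test scale.

Two simulation modes:

* `mode="agents"` — event-level ground truth: daily OD totals are NB
  draws; each agent samples a realised route (or an inadmissible one),
  a von Mises passage time, and Bernoulli compliance.  Station passages
  are actual path events, which validates the marginal `rho`
  computation independently.  Because per-agent binomial thinning
  changes the NB success parameter (see above), the dispersion of these
  counts does *not* equal the latent `p`; this mode is used for the
  Monte-Carlo mean oracle and for the temporal and route-choice
  conditional fits, whose likelihoods are exact under event-level
  sampling.
* `mode="cells"` — draws each (shift, OD) count directly from the fitted
  observation law; used for gravity parameter-recovery studies, where
  the estimator's own distributional assumption must hold exactly.

What passing tests do and do not show: recovery and validation results
on synthetic data demonstrate the estimators are correct under the
model's assumptions; they do not validate those assumptions against real
traffic, and the generator deliberately omits weekly/seasonal cycles,
station-dependent compliance, route-overlap correlations and geographic
realism.

## Known limitations

* Dependence between cells (same day, several stations) is ignored by
  the composite likelihood; estimates stay consistent but intervals and
  AIC are approximate.
* `eta_c`/`eta_o` are bounded, not estimated; inadmissible-route flow is
  reported as an unallocated total.
* Single-via enumeration bounds the admissible set; k-shortest-path
  alternatives, turn restrictions and congestion are out of scope.
* The end-to-end validation R² depends on the between-station
  signal-to-noise of the scenario; sparse designs (few midday shifts per
  station) make it uninformative, which is why the end-to-end test sizes
  its survey programme to the regime of the real deployment.
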