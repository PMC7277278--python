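# gravroute

Hybrid gravity / route-choice model for estimating long-distance vector
traffic in road networks from roadside survey counts.

Human road traffic moves invasive species and disease vectors: trailered
boats carry zebra and quagga mussels to uninvaded lakes, campers move
insects in firewood, anglers move baitfish.  Managers need to know *how
many* potential vectors travel between which origins and destinations and
*which roads* they use, so that inspection stations and early-detection
effort go where the traffic is.  In large-scale systems neither question
can be answered by surveying origins or destinations directly — there are
thousands of them — but most long-distance trips funnel through a few
major roads, where roadside surveys yield plenty of data.  `gravroute`
fits a trip-distribution model to exactly that kind of data and is aimed
at quantitative ecologists, epidemiologists and invasive-species
programme analysts.

## Model

The number of agents surveyed while driving from origin *i* to
destination *j* during shift *t* at station *k* arises hierarchically:

1. **Gravity model** — daily trips are negative binomial with mean
   μ<sub>ij</sub> = c · m<sub>i</sub> · a<sub>j</sub> · d<sub>ij</sub><sup>−α<sub>d</sub></sup>,
   where repulsiveness m<sub>i</sub> and attractiveness a<sub>j</sub> are
   built from power x<sup>α₁</sup> and saturating (x/(x+α₀))<sup>α₁</sup>
   covariate blocks (products = "and", sums = "or"), and d<sub>ij</sub>
   is shortest travel time.  The NB family is parametrised by a constant
   mean-to-variance ratio *p*, which makes it closed under pooling of
   origins or destinations.
2. **Route choice** — agents choose among *admissible* paths: single-via
   paths within stretch γ of the shortest route containing no local
   detour at scale δ; path P is chosen with probability ∝
   l<sub>P</sub><sup>−λ</sup>.  With probability η<sub>c</sub> ≤ 0.05 an
   agent takes an inadmissible route instead and passes any station with
   probability η<sub>o</sub>, giving the passage probability
   ρ<sub>ijk</sub> = (1−η<sub>c</sub>) Σ<sub>P∋k</sub> P(choose P) + η<sub>c</sub>η<sub>o</sub>.
3. **Temporal pattern** — passage times follow a von Mises density on the
   24 h clock (peak θ, concentration κ); τ is its mass inside the shift
   window.
4. **Compliance** — a surveyed agent yields usable data with probability
   ξ = ξ<sub>p</sub> · ξ<sub>c</sub> (stops, and provides complete data).

The observed count is NB with mean μ<sub>ij</sub>ρ<sub>ijk</sub>τξ and
ratio *p*.  Submodels are fitted in stages (compliance → temporal → route
choice → gravity) by conditional and composite maximum likelihood, with
profile-likelihood confidence intervals and AIC model selection.  The
fitted model predicts absolute origin outflows, destination inflows (with
uncertainty quantiles) and directed road-level flows.  See
`docs/methods.md` for assumptions, estimation details and limitations.

## Worked example

Fit the full staged pipeline to a simulated survey programme (240 shifts
at 6 stations in a compact study region):

```python
import gravroute as gr
from gravroute.fitting import (
    GravityFitProblem, fit_gravity, fit_route_choice, monitoring_effort,
)

config = gr.ScenarioConfig(
    n_origins=6, n_destinations=30, n_vertices=90, n_stations=6,
    n_shifts=240, extent=(400.0, 300.0), seed=11,
)
scenario = gr.generate_scenario(config)
counts, compliance_counts, obs_times = gr.simulate_surveys(
    scenario, mode="cells", seed=7
)

comp = gr.estimate_compliance(compliance_counts)
temp = gr.fit_temporal(obs_times, counts.shifts)
effort = monitoring_effort(counts.shifts, temp.params)
rc = fit_route_choice(counts, scenario.path_sets, effort, seed=0)
problem = GravityFitProblem(
    counts, scenario.origin_cov, scenario.dest_cov, scenario.distances,
    scenario.path_sets, rc.params, temp.params, comp,
)
grav = fit_gravity(problem, free=("c", "p", "alpha_d"), seed=0)
```

Output (412 surveyed agents; generating values were ξ = 0.744, θ = 14.00,
κ = 1.34, λ = 7.4, c = 3.73e−8, p = 0.23, α_d = 3.45):

```
compliance xi = 0.742 (participation 0.798 x data quality 0.930)
traffic peak theta = 13.83 h, 95% CI [13.20, 14.58]; kappa = 1.52
route-choice lambda = 9.98, 95% CI [6.87, 13.35]
  c        = 6.24e-08   95% CI [7.53e-09, 5.42e-07]
  p        = 0.211   95% CI [0.163, 0.263]
  alpha_d  = 3.29   95% CI [2.65, 3.91]
composite log-likelihood -1110.3, AIC 2226.6
```

Every generating value lies inside its 95% profile interval.  Flow
prediction then maps the fitted traffic onto the network:

```python
flows = gr.predict_flows(
    scenario.mu_dict(), scenario.path_sets, rc.params, grav.params.p
)
shares = gr.share_table(flows.destination_inflow["mean"])
```

which reports, for this scenario, that the top 4 of 30 lakes receive 50%
of the predicted agent inflow — the concentration pattern that makes
road-based inspection effective.

The same pipeline is available from the shell:

```sh
gravroute simulate --out run/ --seed 4
gravroute fit-all --config run/config.yaml
gravroute predict --config run/config.yaml
```

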