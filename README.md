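# stagedist

Life-stage species distribution modelling for bottom-trawl surveys:
logistic stage ogives, zero-altered Poisson hurdle GAMMs, and
geostatistical aggregation curves with persistence mapping.

Demersal fish such as whiting (*Merlangius merlangus*) shift habitat as
they grow — recruits settle inshore over fine sediments while mature fish
disperse into deeper offshore water — so management questions ("where can
juvenile bycatch be avoided?") need density maps *per life stage*, not per
species. This package builds that workflow for DATRAS-style survey data
(haul records, 1-cm length frequencies, sex-maturity-age-length keys) and
is aimed at fisheries/spatial ecologists who want each step testable in
isolation. Because the real survey extracts cannot be redistributed, a
first-class synthetic survey generator with exported ground truth stands
in for them; every estimator is validated by parameter recovery against
that truth.

## The models

**Stage decomposition.** Per survey, the probability that a fish of
length *L* belongs to stage *s* (age-0, age-1, or mature among age-1+) is
a binomial GLM, logit *p* = α + β₁sex + β₂region + β₃L + β₄year +
interactions, pruned by backward likelihood-ratio elimination (α = 0.05).
L50 is the length where *p* = 0.5 (= −η(0)/slope for a fixed profile).
Haul CPUE (counts standardized to a 30-minute tow, floored) is decomposed
into stage CPUE by multiplying each 1-cm class with its fitted stage
probability at the bin midpoint.

**Hurdle distribution models.** Stage CPUE is zero-inflated, so presence
and abundance are modelled separately and recombined:

    presence:  logit p = α + s(x₁) + te(x₂, x₃) + ... + a_gear
    counts>0:  log λ  = α' + s(x₁) + ...             + a'_gear
    E[CPUE]   = p · λ / (1 − e^(−λ))

with penalized cubic regression splines s(·), tensor-product interactions
te(·,·), a cyclic spline for aspect, and a ridge-penalized survey/gear
random intercept; the count component is a zero-truncated Poisson. The
spline engine (`stagedist.gam`) selects smoothing by GCV on a global
penalty scale. Covariates are screened by VIF (> 3 dropped), terms by
bidirectional stepwise AIC, and performance by 100× stratified 7:3
cross-validation (ROC AUC for presence, Spearman ρ for counts and the
combined prediction).

**Aggregation curves.** Ranking occupied grid cells by predicted density
and accumulating abundance (y) against area (x) yields a curve whose
slope-1 tangent separates aggregated from dispersed space use; for
equal-area cells the tangent density equals the mean occupied density
exactly, which serves as the built-in oracle for the cubic-fit threshold.
Yearly binary maps are summed into persistence grids.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale
(20×30 grid, ~200 hauls, 3 years per season, seed 1) and write their
tables under `results/`. Running them in order prints, among other lines:

```
$ python analysis/01_simulate_survey.py
hauls: 198 ({'SWC_IBTS': 120, 'NIGFS': 78})
catch rows: 582; empty hauls: 84 (42% zero-inflation)

$ python analysis/02_stage_cpue.py
L50 recovery: max |error| = 1.959 cm, mean = +0.074 cm over 162 profiles

$ python analysis/05_validate_models.py
strong AGE1: mean AUC 0.841, mean Spearman(combined) 0.603 (20 iterations)
null   AGE0: mean AUC 0.459, mean Spearman(combined) 0.002 (20 iterations)

$ python analysis/06_aggregation_persistence.py
AGE0: 82% of abundance in 20% of occupied area (mean over 3 years)
MATURE: 54% of abundance in 20% of occupied area (mean over 3 years)
```

Reading these: 42% of hauls are empty (the zero-inflation the hurdle pair
exists for); L50 recovery error at this small SMALK size is ~2 cm and
shrinks below 0.5 cm at 2000 fish per region; cross-validated AUC is well
above chance under the strong-signal truth and at chance under the null
control; and the youngest stage packs ~82% of its abundance into 20% of
the area it occupies while mature fish are far more dispersed — the
coastal-nursery-to-offshore pattern the method is designed to expose.

The same end-to-end run is available as a single call:

```python
from stagedist import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(seed=1, out_dir="runs/demo"))
```

which writes survey tables, layer/prediction/classification grids (ESRI
ASCII), L50 and CV tables, aggregation summaries, persistence maps and a
machine-readable run log; repeated runs at the same seed are
byte-identical.

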