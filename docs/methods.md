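# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with a one-month cycle
over six base health states: DFS on-treatment, DFS off-treatment,
non-metastatic recurrence (NM), remission, metastatic breast cancer (mBC),
and death.  Women enter at diagnosis either in DFS on-treatment (stage
I–III) or in mBC (stage IV); the screening scenario differs from
no-screening *only* in this entry mix (0.924 vs 0.833 entering DFS), which is
how the downstaging effect of CBE is represented.  Both scenarios share
every transition matrix, so scenario differences are attributable to entry
mix and the screening programme's one-off cost alone.

Three states are expanded into tunnels so probabilities can depend on
time-in-state: 12 monthly tunnels each for DFS on-treatment and NM (therapy
lasts at most 12 months; NM discharges to remission automatically after 12
months if alive), and 60 for mBC, whose monthly death probability is
year-specific (0.0324, 0.0446, 0.0492, 0.0511, 0.0541 for years 1–5+); the
60th tunnel month self-loops at the year-5+ rate, absorbing the time
dependence.  With the single-month states and death this gives an 87-state
expanded space.  Death is absorbing.  Row-stochasticity is enforced to 1e-9
as a hard error naming the offending state; rows are never silently
renormalised.

## Transition probabilities

Recurrence from DFS follows a parametric survival curve
S(t) = exp(−(t/scale)^shape) with t = months since diagnosis (DFS is entered
only at diagnosis, so cycle index equals time in DFS and the off-treatment
state needs no tunnel).  The per-cycle event probability 1 − S(t+1)/S(t) is
multiplied by a cure factor: a cured fraction rises linearly from 0 at
diagnosis to 0.95 at month 120 and stays there, so past 10 years only 5% of
the cohort can still recur.  A step-at-threshold variant is available
(`cure_ramp="step"`); the linear ramp is the default because it keeps the
hazard continuous and matches the notion of a maximum cure rate being
*reached at* a month rather than appearing at it.  Recurrences are metastatic
with probability 0.72.

The curve governs recurrence only.  Mortality in the DFS, NM and remission
states is the background life-table rate (trial mortality in these states
sits below background, so a separate on-study death rate would be
double-counting).  Discrete-time competing risks are composed
multiplicatively with death taking precedence: stay = (1−q)(1−p_rec), death
q, recurrence (1−q)·p_rec — outflow can then never exceed 1.  Remission
progresses to mBC at 0.0076/month composed the same way.  Annual life-table
probabilities convert to monthly via 1 − (1−q)^(1/12), constant within each
year of age (floor convention).

## Accrual conventions

Half-cycle correction: cycle t accrues the average of the state occupancy at
its start and end, approximating mid-cycle transitions.  The discount factor
for cycle t is (1+r)^(−t/12) with r = 1.5%/year applied to costs and
outcomes alike.  Life-years and QALYs accrue 1/12 of a year per alive month;
QALYs weight occupancy by state-group utility at the age band containing the
cohort's current age (bands <40, 40–49, 50–59, 60+; NM shares the
on-treatment utilities, remission the off-treatment ones).  Monthly costs by
state: on-treatment/NM months cost a mix-weighted blend of targeted therapy
and chemotherapy (the default mix is 100% targeted for early-stage patients
and 0% for mBC, reflecting reported treatment choices; both fractions are
configurable); off-treatment/remission months accrue follow-up care; mBC
months accrue supportive care plus, for the targeted fraction, the full
targeted course amortised over the average 40-month metastatic survival.
One-off costs at cycle 0 — diagnostic work-up in both arms, plus the CBE
cost per diagnosis (CBE cost per person / 0.0006 detection rate) in the
screening arm — are neither half-cycle corrected nor discounted.

The healthcare-sector perspective is defined as the component-wise sum of
the patient and public-payer inputs, which makes perspective additivity an
identity.  One published cell (monthly chemotherapy, 14.8) differs from the
component sum (9.1 + 5.67 = 14.77) by print rounding; the sum is used.

Internal currency is million VND throughout; USD appears only at reporting
time (divide by 22,759 VND/$, round half-up to whole dollars — this
reproduces the published $ figures from the published VND figures).  ICERs
per QALY are classified against 63.2 / 189.6 million VND (1× / 3× GDP per
capita); a zero QALY difference yields an explicit undefined-ICER flag, and
negative cost with positive effect a dominance flag.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| start DFS fraction, no screening / screening | — | 0.833 / 0.924 | entry mix; the screening effect |
| DFS curve shape, scale | —, months | 0.9, 300 | synthetic stand-in; decreasing hazard, ≈65% event-free at 10 y |
| cure threshold / max cure rate | months, — | 120 / 0.95 | recurrence risk vanishing by 10 y |
| mBC split of recurrences | — | 0.72 | metastatic share of recurrences |
| remission → mBC | /month | 0.0076 | late progression |
| detection rate | — | 0.0006 | diagnostic-positive fraction of screens; divides the CBE cost |
| discount rate | /year | 0.015 | applied to costs and outcomes |
| horizon | months | 672 | lifetime: cohort age 100 |

## Synthetic inputs

The life table is Gompertz–Makeham, h(x) = 4e-4 + 4e-5·exp(0.092x) per year,
integrated in closed form to annual death probabilities for ages 0–100
(q ≈ 0.003 at 44, ≈ 0.06 at 80 — an adult-female mortality profile of the
right scale).  The DFS event generator draws Weibull event times (shape 0.9,
scale 300), independent exponential censoring at 0.0008/month — solved so
that about 20% of subjects are censored, the study condition for the
fitter-recovery checks — and multinomial event types at the 0.72 split.
Both are deterministic given a seed.

What the synthetic inputs do **not** emulate: the real trial curve's exact
level and covariance (so absolute life-years, QALYs and ICERs from the
packaged defaults characterise the model's behaviour, not the published
base-case magnitudes, which depend on privately-held inputs), cohort
heterogeneity beyond age, and any correlation between censoring and event
risk.  Passing tests therefore demonstrate the correctness of the machinery
and the qualitative economics (quadrant, orderings, sensitivity directions),
not the published point estimates.

## Sensitivity analysis

One-way DSA moves a single dot-addressed parameter to the ends of its range
— the reported 95% CI where a source gives one, otherwise ±20% of base —
and records the ICER at each end; the tornado table sorts by bar width with
lexicographic tie-breaks.  At base values the DSA reproduces the base-case
ICER bit-for-bit.

PSA draws all parameters jointly per iteration: beta for probabilities and
utilities, log-normal for costs, and a multivariate normal on the log-scale
Weibull parameters (diagonal covariance, 10% coefficients of variation, the
trial covariance being unavailable).  Hyperparameters are fitted by matching
the mean exactly and minimising the squared distance of the 2.5/97.5%
quantiles from the interval endpoints (±20% ranges are treated as 95%
intervals); a one-dimensional bounded search suffices because the mean pins
one degree of freedom.  The two starting probabilities move as one block:
the no-screening start is drawn from its beta and the screening start
follows at the fixed 9.1-point downstaging gap (capped at 1), because the
gap — not the two starts independently — is the uncertain screening-effect
quantity, and independent draws would occasionally invert the scenarios'
entry mix.  Utilities are varied through their pooled means with age bands
rescaled proportionally (capped at 1).  The CEAC counts iterations with
strictly positive net monetary benefit λ·ΔQALY − ΔCost; ties count as not
cost-effective.  2000 iterations is the default; the CE-plane export carries
the two thresholds as metadata.

## Numerical and testing choices

The per-cycle matrices are cached and shared by both scenarios; a base-case
evaluation at the 672-month horizon takes well under a second.  The
individual-level microsimulation used as an independent check replays the
same per-cycle probabilities one categorical draw at a time, with one RNG
substream per individual spawned from the master seed (reproducible under
any evaluation order), and accrues outcomes under the identical
half-cycle/discounting conventions, so its Monte-Carlo mean estimates the
cohort expectation exactly; agreement is asserted within three standard
errors at 20,000 individuals.  Curve fitting for censored event tables is
delegated to lifelines' Weibull/exponential maximum-likelihood fitters,
which also supply the estimator covariance.  Tests shorten horizons (240–480
months) where only orderings or directions are at stake; full-horizon runs
back the headline checks.

## Known limitations

Only direct medical costs are modelled (no societal perspective or indirect
costs).  Stages I–III are pooled into a single early-disease state.  The
screening programme is a single prevalent screen embodied in the entry mix
and a per-diagnosis cost — no repeat-screening schedule, attendance model or
false-positive pathway.  Treatment-mix fractions are assumptions, published
narrative giving no numeric value.  Background mortality is not subtracted
from the DFS curve before use (the curve is treated as recurrence-only); if
a user supplies a fitted curve whose events include deaths, mortality in DFS
would be double-counted.
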