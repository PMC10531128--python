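# markovcea

Markov cohort cost-utility analysis of **sequential treatment pathways**,
built for health-technology-assessment questions of the form *"is it worth
inserting an extra line of therapy into a standard treatment sequence?"*.
The bundled application is knee osteoarthritis in Vietnam: six regimens
that escalate from acetaminophen through NSAIDs and corticosteroid
injection to total knee arthroplasty (TKA), with crystalline glucosamine
sulfate optionally inserted before or after the NSAID step.

## The model

A closed cohort is distributed over mutually exclusive health states
$s_0, s_1, \dots, s_{K}$ (ordered treatment lines, then surgery, then an
absorbing death state) and redistributed every cycle by a fixed
row-stochastic matrix $P$:

$$x_{t+1} = x_t P, \qquad P_{ij} = 0 \text{ for } j < i \;(\text{no backtracking}),$$

where each treatment row carries $1-p_i$ on itself and the per-cycle
escalation (non-response) probability $p_i$ on the next state. Discounted
totals per strategy are

$$\text{Cost} = \sum_{t=1}^{T} \sum_i x_{t,i}\, c_i \,(1+r)^{-t\ell}, \qquad
\text{QALY} = \sum_{t=1}^{T} \sum_i x_{t,i}\, u_i\, \ell \,(1+r)^{-t\ell},$$

with cycle length $\ell$ (0.5 y), annual discount rate $r$ (3%), per-cycle
state cost $c_i$ (direct medical + direct non-medical + indirect, VND) and
utility $u_i \in [0,1]$. Strategies are compared by the incremental
cost-effectiveness ratio

$$\mathrm{ICER} = \Delta\text{Cost}/\Delta\text{QALY},$$

with dominance labels where the ratio is not meaningful, and classified
against Vietnamese willingness-to-pay thresholds at 1× and 3× GDP per
capita (88,213,416 VND, 2021). One-way sensitivity re-runs the pipeline
with each scalar input at ±20% and ranks ICER excursions into a tornado
table.

## Worked example

```python
from markovcea import CostUtilityModel

results = CostUtilityModel.from_fixture(strategies=["PD", "PGD", "PDG"]).run()
print(results.summary())
```

```
strategies:     PD, PGD, PDG
cohort:         age 40 to 73.6 y, 68 cycles of 0.5 y
discount:       3.0%/year (costs and outcomes)
...
Discounted totals
-----------------
strategy    cost_vnd  cost_usd  qalys
      PD 131241836.0   5588.09 7.0314
     PGD 126211990.0   5373.92 7.5878
     PDG 126220969.0   5374.31 7.5888

Incremental comparisons
-----------------------
strategy comparator  delta_cost_vnd  delta_qalys  icer_vnd_per_qaly ...    label             wtp_class
     PGD         PD      -5029846.0       0.5565                NaN ... dominant highly_cost_effective
     PDG         PD      -5020866.0       0.5574                NaN ... dominant highly_cost_effective
```

On these inputs the glucosamine arms are *dominant*: inserting the cheap
adjunct delays the expensive downstream states (above all the
88.7M-VND arthroplasty), which under discounting and the lifetime horizon
saves more than the adjunct costs while adding quality-adjusted life
years.

The incremental-analysis layer works on any cost/QALY totals. Feeding it
the reference base-case totals bundled with the fixture reproduces the
published pairwise ICERs:

```python
from markovcea import published_base_case, compare_strategies, wtp_classify, EconomyParams

pb = published_base_case()
c = compare_strategies(pb["PGD"], pb["PD"])
# dCost=33,374,824 VND  dQALY=43.8071  ICER=761,859 VND/QALY  -> highly_cost_effective
```

An ICER of ~762k VND/QALY is far below the 1×-GDP threshold: adding
glucosamine before NSAIDs is highly cost-effective.

## Command line

```sh
markovcea run      -c config.yaml        # CEA + comparison tables (CSV/JSON)
markovcea tornado  -c config.yaml --plot # ranked one-way sensitivity per pair
markovcea simulate --seed 3              # synthetic scenario end-to-end
markovcea validate -c config.yaml       # schema + transition-matrix checks
```

`config.yaml` is schema-validated (unknown keys rejected); every field has
a sensible default, so `strategies: [PD, PGD]` alone is a valid file.

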