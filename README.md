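# crcscreen

A cohort-level Markov state-transition model for evaluating **liquid biopsy
(LB)** — blood-based circulating-tumor-DNA testing — as a colorectal cancer
(CRC) screening strategy, with a complete cost-effectiveness apparatus:
incremental frontier analysis with strict and extended dominance, one-way and
threshold sensitivity analyses, scenario analyses, and probabilistic
sensitivity analysis (PSA) with cost-effectiveness acceptability curves.

The package is written for health-economics and screening-policy researchers
who want a transparent, fully reproducible implementation of this class of
model: every input is either a published scalar (test performance, unit
costs) or generated by a synthetic-epidemiology module emulating the
registry data (SEER-like incidence, CDC-life-table-like mortality, CORI-like
polyp prevalence) that such models are calibrated to, so the entire analysis
runs from a clean checkout with no downloads.

## The model

A simulated average-risk cohort enters at age 45 and is followed with annual
cycles until death or age 100. Health states cover the adenoma–carcinoma
sequence (healthy → low-risk polyp → high-risk polyp → cancer), polyp
surveillance tunnels after polypectomy, diagnosed cancer by SEER summary
stage (local/regional/distant, split into first-year and continuing phases),
and death from cancer or other causes. Six strategies are compared:

| Strategy    | First line                  | Interval | Adherence |
|-------------|-----------------------------|----------|-----------|
| NH          | none (natural history)      | —        | —         |
| FIT         | fecal immunochemical test   | 1 y      | 60.6%     |
| Colonoscopy | colonoscopy                 | 10 y     | 60.6%     |
| S-DNA       | stool DNA                   | 3 y      | 60.6%     |
| LB          | liquid biopsy               | 3 y      | 100%      |
| C-LB        | colonoscopy, then LB for the unscreened 39.4% | 10 y / 3 y | 60.6% + 39.4% |

Screening stops at 75; polyp surveillance (colonoscopy every 3 y for
high-risk, 5 y for low-risk polyps) continues to 85. Effectiveness is
life-years gained (LYG) after 45; costs are 2022 USD discounted at 3%/year;
the willingness-to-pay (WTP) threshold is $100 000/LYG. For strategies
`i` on the efficient frontier, the decision statistic is the incremental
cost-effectiveness ratio against the next least costly nondominated
strategy `j`:

    ICER_i = (C_i − C_j) / (E_i − E_j)   [$ per LYG]

The unscreened natural history is calibrated (deterministic nested
least-squares/bisection) so the no-screening arm reproduces a ~5.2% lifetime
CRC incidence and ~1.6% CRC mortality, the pre-screening-era US pattern.

## Worked example

```python
from crcscreen import default_parameter_set, run_all_strategies, incremental_analysis

params = default_parameter_set()          # synthetic epidemiology + calibration
outcomes = run_all_strategies(params)
frontier = incremental_analysis(
    [(n, o.discounted_cost, o.undiscounted_lyg) for n, o in outcomes.items()]
)
print(frontier.to_frame().to_string(index=False))
```

prints (costs $/person, effectiveness in life-years per person from age 45):

```
   strategy        cost  effectiveness  incremental_cost  incremental_effectiveness          icer               status  comparator
         NH 1998.266165      37.092293               NaN                        NaN           NaN            reference        None
        FIT 2811.303707      37.118593        813.037542                   0.026301           NaN extendedly_dominated          NH
Colonoscopy 3057.815371      37.153409       1059.549206                   0.061116  17336.617177         nondominated          NH
      S-DNA 4122.761177      37.124195       1064.945806                  -0.029214           NaN   strictly_dominated Colonoscopy
       C-LB 5591.268931      37.156625       2533.453560                   0.003215 787905.289718         nondominated Colonoscopy
         LB 8428.351343      37.100454       2837.082412                  -0.056171           NaN   strictly_dominated        C-LB
```

Reading the table: colonoscopy is the cost-effective choice at the $100 000
per LYG threshold (ICER ≈ $17 000/LYG); the colonoscopy–LB hybrid buys the
most life-years but at an ICER far above the threshold; stool DNA and
LB-alone cost more while gaining fewer life-years than a cheaper alternative
(strictly dominated); FIT is extendedly dominated — colonoscopy gains
life-years at a lower price per life-year. Lifetime CRC incidence falls from
5.2% (NH) to 2.9–4.7% under the screening arms, and CRC mortality from 1.6%
to 0.9–1.5%. Absolute per-person costs and life-years depend on the
synthetic epidemiology and are not comparable desk numbers; the dominance
structure, decision at the WTP threshold, and all directional results are
the model's substantive output.

The same analyses are available from the command line:

```bash
crcscreen frontier                       # base-case table above
crcscreen threshold costs.lb 0 949       # price at which LB becomes cost-effective
crcscreen scenario lb-polyp              # LB granted polyp sensitivity
crcscreen psa --iterations 500 --seed 1  # acceptability curves
crcscreen run --config my_config.yaml    # config-driven pipeline
```

## Layout

- `src/crcscreen/synthetic_epi.py` — synthetic life table, baseline CRC
  incidence, polyp prevalence, stage inputs
- `src/crcscreen/natural_history.py` — state space, transition matrices,
  calibration
- `src/crcscreen/strategies.py` — the six arms and per-cycle screening and
  surveillance mechanics
- `src/crcscreen/cohort.py` — cohort engine, cost accrual, outcomes
- `src/crcscreen/frontier.py` — dominance and ICER analysis
- `src/crcscreen/sensitivity.py` — one-way/threshold/scenario/PSA
- `src/crcscreen/config.py`, `cli.py` — config document, pipeline, CLI

See `docs/methods.md` for the model's assumptions, parameters, and known
limitations.
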