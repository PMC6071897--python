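# adipersist

Tools for asking a practical question in healthcare delivery research: **is a
patient's current address of record a reasonable measure of their exposure to
neighborhood deprivation, given that people move?** If patients who change
address tend to land in neighborhoods of similar deprivation ("deprivation
persistence"), then a single point-in-time address is a usable proxy for
short-to-intermediate-term neighborhood exposure — which matters to anyone
linking registration-system addresses to area-level social determinants.

The package implements the full analysis pipeline:

* **ADI scoring** (`adipersist.adi`) — an area deprivation index over 17
  census-style block-group indicators: direction-aligned z-scores, weighted
  sum `base + scale·Σ wⱼzⱼ`, quintile assignment (quintile 1 = least
  deprived), urban/rural majority classification. Exposed as a scikit-learn
  transformer (`ADIScorer`).
* **Cohort construction** (`adipersist.cohort`) — two-encounter-window
  eligibility, exclusions (deceased / PO-box address / ungeocodable), and
  address-of-record change detection with conservative string normalization.
* **Persistence statistics** (`adipersist.persistence`) — per-quintile change
  rates, linear pro-rata annualization (×12/w), the mover origin→destination
  quintile transition matrix, and for each origin quintile q:

  | symbol | meaning |
  |---|---|
  | A_q | 1-year probability of an address-of-record change |
  | B_q | P(destination outside q \| change) |
  | D_q | P(destination outside the same-or-neighboring set \| change) |
  | A_q·B_q, A_q·D_q | unconditional leave probabilities |

  with population-weighted headline scalars. The same-or-neighboring set is
  ±1 quintile for origins 2–4 and two inward steps at the edges
  (1→{1,2,3}, 5→{3,4,5}), so every origin has exactly two "outside" quintiles.
* **Odds-ratio models** (`adipersist.risk_models`) — categorical logistic
  regression by IRLS with Wald 95% CIs (`OR = e^β`, `e^{β±1.96·SE}`), a 2×2
  closed-form oracle, and adjusted per-quintile OR reports, optionally
  stratified adult/pediatric.
* **Synthetic cohorts** (`adipersist.synthetic`) — a generator whose defaults
  reproduce the study's published marginal structure (quintile shares,
  per-quintile move rates, destination kernel, demographic mix), including
  the registration-lag mechanism by which late moves go unobserved.

## Worked example

```python
from adipersist import SimConfig, simulate_study, analysis_cohort, PersistenceAnalyzer
from adipersist.pipeline import render_table2

study = simulate_study(SimConfig(n_patients=20_000, seed=1))
cohort = analysis_cohort(study)
print(f"cohort n={len(cohort)}, observed change rate={cohort.changed_address.mean():.3f}")

analyzer = PersistenceAnalyzer(window_months=14).fit(cohort)
print(render_table2(analyzer.report_).to_string())
```

prints

```
cohort n=20000, observed change rate=0.276
                                                             q1    q2    q3    q4    q5
One-year probability of change in address of record (A)    0.20  0.21  0.24  0.27  0.32
P(change outside same ADI quintile | change) (B)           0.43  0.58  0.65  0.66  0.56
P(change outside same ADI quintile) (A×B)                  0.09  0.12  0.16  0.17  0.18
P(change outside same-or-neighboring | change) (D)         0.13  0.24  0.28  0.27  0.19
P(change outside same-or-neighboring quintile) (A×D)       0.03  0.05  0.07  0.07  0.06
```

(row labels abbreviated here; the rendered table spells them out). Reading
it: 27.6% of this simulated cohort changed their address of record over the
14-month window, rising with deprivation (A row, annualized). Among movers,
persistence is strong — e.g. only 13% of quintile-1 movers left the
same-or-neighboring set (D row), so the unconditional chance that a
quintile-1 patient's deprivation context shifted meaningfully in a year is
about 3% (A×D row).

The same analysis runs from the shell on CSV inputs:

```bash
persist simulate --seed 17 --n-patients 20000 --out sim/
persist analyze --cohort sim/patients.csv --blockgroups sim/block_groups.csv \
    --encounters sim/encounters.csv --out run/
persist report --run-dir run/
```

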