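# groomstats

Dominance, friendship and grooming-exchange statistics for focal-sampled
primate groups.

## The problem

Why do female primates groom whom they groom? In species such as Barbary
macaques (*Macaca sylvanus*), grooming may track maternal kinship, run up
the dominance hierarchy (traded for tolerance or reduced aggression), follow
"friendship" (strong affiliative bonds), or simply be reciprocated in kind.
Testing these hypotheses against each other requires a chain of quantitative
machinery that behavioral ecologists usually assemble ad hoc:

1. **Dominance hierarchy** from a displacement matrix: the dyadic dominance
   index corrected for chance, `D_ij = P_ij − (P_ij − 1/2)/(n_ij + 1)`;
   normalized David's scores `NDS = (DS + N(N−1)/2)/N` as a cardinal rank
   value; hierarchy **steepness** (|OLS slope| of NDS on rank position, with
   a wins-resampling randomization test); Landau's linearity `h` and the
   improved **h′** (mean of `h` over random resolutions of unknown and tied
   dyads, with a randomization p-value); and the **directional consistency
   index** `DCI = Σ(H−L)/Σ(H+L)`.
2. **Affiliation measures** from focal event and scan logs: grooming acts
   merged under the ≥ 20 s bout-termination rule, directed grooming rate and
   time per *combined* observation hour, aggression received, contact /
   proximity / co-provisioning time, and the asymmetric **friendship index**
   `F(A,B) = contact(A,B) / mean_C contact(A,C)`.
3. **Dyadic mixed models**: one row per directed dyad per season
   (`N(N−1)` rows per season), log-transformed response, nine fixed effects
   (kinship, relative rank, rank distance, friendship, grooming received,
   co-provisioning, aggression received, season, age difference) and
   **crossed random intercepts** for groomer and groomee identity, with
   exp-scale effect interpretation `(e^b − 1)·100%` and a split analysis by
   rank distance.

`groomstats` implements this whole chain as a tested, reusable library plus
a thin CLI, together with a **focal-sampling simulator** whose ground truth
(latent hierarchy, matriline kin structure, dyadic affinity, log-scale
effect sizes) is known — so every stage has a parameter-recovery test and
the pipeline can be exercised end to end with no field data.

## Worked example

```python
from groomstats import (GroupConfig, EffectConfig, generate_group,
                        simulate_study, analyze_study)
from groomstats.model import report

cfg = GroupConfig(seed=1)               # 17 females, 2 seasons, 15.5 h/female
roster, truth = generate_group(cfg)
events, scans, sessions = simulate_study(roster, truth, EffectConfig(), cfg)
res = analyze_study(events, scans, sessions, roster,
                    n_randomizations=2000, seed=1, responses=("rate",))
s1 = res.dominance["1"]
print(f"season 1: DCI = {s1.dci:.2f}, steepness = {s1.steepness.steepness:.2f}, "
      f"h' = {s1.linearity.h_prime:.2f} (p = {s1.linearity.p_value:.3f})")
print(report({"grooming rate": res.fits["rate"]}))
```

prints

```
season 1: DCI = 0.96, steepness = 0.73, h' = 1.00 (p = 0.000)
== grooming rate (response: grooming_rate, offset 0.016129) ==
term                          estimate      SE   CI low  CI high  sig
Age difference                  -0.005   0.007   -0.019    0.009
Kinship (non-kin)               -0.585   0.115   -0.809   -0.360  *
Rank distance                    0.005   0.011   -0.017    0.027
Relative rank (subordinate)      0.679   0.079    0.525    0.832  *
Friendship                       0.294   0.044    0.208    0.381  *
Groom received                   0.204   0.072    0.063    0.344  *
Co-provisioning                 -0.010   0.170   -0.343    0.323
Aggression received              0.824   0.589   -0.331    1.979
Season (2)                       0.052   0.050   -0.047    0.150
random-effect variances: groomer 0.0834, groomee 0.0258, residual 0.3414
null-model LRT: chi2(9) = 347.49, p = 2.12e-69
  Kinship (non-kin): response 55% lower to 30% lower (per unit)
  Relative rank (subordinate): response 69% higher to 130% higher (per unit)
  Friendship: response 23% higher to 46% higher (per unit)
  Groom received: response 1% higher to 4% higher (per 0.1 unit)
```

The simulated troop grooms kin more (negative non-kin coefficient), directs
grooming up the hierarchy (positive subordinate coefficient), and prefers
high-friendship partners — exactly the structure the generator encodes
(`beta_kin = 0.6`, `beta_sub = 0.6`, `beta_friend = 0.4` on the log scale;
the friendship estimate is attenuated by scan-sampling noise in the measured
index, see `docs/methods.md`). A near-deterministic displacement process
(`consistency = 0.98`) yields the high DCI and significant linearity.

The same chain is exposed as CLI subcommands:

```bash
groomstats simulate --seed 1 --out-dir sim
groomstats dominance --events sim/events.csv --roster sim/roster.csv \
    --season 1 --out-dir results
groomstats affiliation --events sim/events.csv --scans sim/scans.csv \
    --sessions sim/sessions.csv --roster sim/roster.csv --out-dir results
groomstats dyads --events sim/events.csv --scans sim/scans.csv \
    --sessions sim/sessions.csv --roster sim/roster.csv --out-dir results
groomstats fit --table results/dyad_table.csv --response rate \
    --split rank-distance --out-dir results
```

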