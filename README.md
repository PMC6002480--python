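# treemingle

Marked point-pattern analysis of species mingling in stem-mapped forest
plots — for forest ecologists asking whether larger trees are surrounded by
more heterospecific neighbours than smaller ones, a spatial signature of
negative conspecific density dependence.

A census is a table of stems (x, y in metres; species; dbh in cm) inside a
rectangular window. `treemingle` computes:

* the **nearest-neighbour mingling index** M_i — the fraction of a tree's
  k = 4 nearest neighbours of a different species (values 0, 0.25, 0.5,
  0.75, 1; levels 0 and 0.25 pooled) — with pairwise Wilcoxon rank-sum
  comparisons of dbh across mingling levels (Holm-adjusted, compact letter
  display) and a bivariate dbh × mingling density;
* **cumulative mark mingling functions**: the edge-corrected proportion of
  heterospecific ordered pairs within distance r,

      k_m(r) = Σ 1(m_i≠m_j) 1(d_ij≤r) w_ij / Σ 1(d_ij≤r) w_ij,

  with translation edge correction w_ij = ab/((a−|Δx|)(b−|Δy|)), computed
  for the whole pattern or with reference trees restricted to a dbh size
  class (small 5–10 cm, medium 10–25 cm, large > 25 cm), optionally
  normalised by the random-arrangement expectation
  EM_d = Σ_i n_di(n−n_i)/(n_d(n−1)), plus the size-class difference curve
  Δk_v(r) = k_hi(r) − k_lo(r);
* **Monte-Carlo null-model envelopes** (pointwise 2.5%/97.5% quantiles)
  under homogeneous or heterogeneous Poisson location randomisation with
  marks retained, the latter driven by per-species moving-window intensity
  surfaces (20 m radius);
* **simulators**: a two-species dependent-marking construction (Poisson
  locations; species from a second-nearest-neighbour rule with r0 = 2.5 m;
  normal dbh; nearest-neighbour species reassignment around trees
  > 25 cm) and a Thomas-cluster multi-species community emulator.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
import treemingle as tm
from treemingle.pipeline import stacked_class_statistic

pattern = tm.simulate_dependent_marking(seed=1)
print(pattern.n, pattern.species_counts())
# 1001 {'1': 611, '2': 390}

summary = tm.mingling_summary(pattern, k=4)
print(summary.level_counts)
# {'0-0.25': 345, '0.5': 329, '0.75': 241, '1': 86}

tests = tm.dbh_by_mingling_test(pattern, summary)
print({k: round(v, 1) for k, v in tests.medians.items()}, tests.letters)
# {'0-0.25': 20.8, '0.5': 26.1, '0.75': 28.3, '1': 26.4}
# {'0-0.25': 'a', '0.5': 'b', '0.75': 'c', '1': 'bc'}

grid = tm.RGrid(r_max=12, step=0.5)
stat = stacked_class_statistic(
    grid, tm.TWO_CLASS_SCHEME, ("small", "large"), [("large", "small")]
)
env = tm.envelope(pattern, stat, r=np.tile(grid.r, 3), nsim=199, seed=1)
m = grid.r.size
i = list(grid.r).index(5.0)
print(f"small k_m(5) = {env.observed[i]:.3f} (lower envelope {env.lower[i]:.3f})")
print(f"delta(5)     = {env.observed[2*m+i]:.3f} (upper envelope {env.upper[2*m+i]:.3f})")
# small k_m(5) = 0.389 (lower envelope 0.413)
# delta(5)     = 0.178 (upper envelope 0.121)
```

Reading the numbers: trees in the pooled low-mingling level are the
smallest (median dbh 20.8 cm, letter "a") and medians rise with mingling
level; at 5 m range the small-tree mingling curve sits *below* its
homogeneous-Poisson envelope (conspecific small trees are aggregated) while
the large-minus-small difference sits *above* it (large trees have more
heterospecific neighbourhoods than independent marking would produce) —
the dependent-marking signature the simulator builds in.

The same analysis runs from the shell:

```
treemingle simulate --out census.csv --seed 1
treemingle mingle --census census.csv --out out/
treemingle curves --census census.csv --nsim 199 --seed 1 --out out/
treemingle reproduce --out reference/   # full 1000-replicate experiment
```

All numeric results are written as CSV with a JSON manifest recording the
seed and a config digest; reruns with the same config and seed are
byte-identical.

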