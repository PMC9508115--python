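# eggage

Inferring the age class of breeding birds from easily measurable breeding
variables.

In most wild populations the age of a breeder cannot be read off the animal,
yet age structure drives population dynamics: young, newly recruited breeders
and senescent ones both perform worse than middle-aged individuals. In
species where maternal age leaves a measurable trace on breeding output —
in gulls, the volume of the eggs in a clutch — that trace can be turned into
a statistical age assay. `eggage` implements such an assay for colonial
seabirds of the Audouin's gull type, where egg volume follows a concave
(quadratic) function of maternal age:

- **Egg-volume features** per nest: each egg's volume `V (cm³) =
  0.000476 · length · width²` (dimensions in mm), aggregated to the total
  volume `VT`, mean volume `VM` and clutch size of the nest, joined with
  annual covariates (winter/annual NAO indices, fish landings, z-scored food
  per capita, breeding population sizes).
- **GLM age-form selection**: Gaussian linear models of `VM` or `VT` with
  age entered as a linear, quadratic or logarithmic term or as one of four
  class poolings (14 / 6 / 3 / 2 classes), always with clutch size; ranked
  by `AIC = 2k − 2 ln L`.
- **Balanced-bootstrap random-forest ensembles**: because age classes are
  heavily imbalanced, each of many iterations draws a balanced subsample
  (every class downsampled to the minority-class size), fits a random
  forest, and records its out-of-bag (OOB) error, confusion matrix, Gini
  importances and its predictions for every nest of the original table.
  Aggregation over iterations yields accuracy `100·(1 − OOB)`, sensitivity
  and specificity for the 'Young' (age 3–4) class, mean importances, and a
  per-nest mismatch count used to flag nests misclassified in at least half
  of the iterations.
- **Evaluation**: per-year/per-age error rates, learning curves against
  training-set size, hold-out colony prediction, and chi-square comparison
  of young-breeder proportions across colonies.

The field data behind such studies are typically not deposited, so the
package ships a first-class **synthetic colony generator** that inverts the
analysis model (concave quadratic age effect on egg volume, year and
individual random effects, annual covariates, truncated-geometric age
pyramid, modal clutch of 3). Every downstream stage is exercised and tested
against it.

## Worked example

```python
import eggage as eg

# simulate 24 breeding seasons of 100 monitored nests
nests, env = eg.generate_dataset(eg.SimConfig(seed=1))

# nest-level features, two-class labels (Young = 3-4 yr vs Others)
table = eg.build_feature_table(nests, env, version="full", scheme="AGE2")

# which age parameterization best explains mean egg volume?
ranking, best = eg.select_best(table, "age-only")
print(best.spec.age_form, ranking["dAIC"].head(3).tolist())

# balanced-bootstrap ensemble of classification forests
res = eg.run_ensemble(table, eg.EnsembleConfig(n_iterations=100, n_trees=100, seed=2))
print(f"accuracy {res.accuracy:.1f}%  sensitivity {res.sensitivity:.1f}%  "
      f"specificity {res.specificity:.1f}%")
print(res.gini_aggregate.sort_values(ascending=False).head(3))
```

prints

```
QUADRATIC [0.0, 1009.1797332369952, 1046.2490050089]
accuracy 66.4%  sensitivity 66.3%  specificity 66.5%
VM        0.439338
VT        0.307117
Clutch    0.045777
dtype: float64
```

The quadratic age form wins the AIC ranking by a wide margin (the next
candidate is ΔAIC ≈ 1009 behind), the two-class ensemble classifies about
two-thirds of nests correctly under the default noisy-colony conditions, and
the egg-volume aggregates dominate the importance ranking — the qualitative
behaviour expected when egg size is partially, but far from fully, driven by
maternal age.

The same pipeline is available from the shell:

```bash
eggage --seed 1 run-all --out runs/demo --iterations 100 --trees 100
eggage simulate --out data/            # or stage by stage
eggage features --nests data/nests.csv --env data/environment.csv \
       --version M4.1 --scheme AGE2 --out features.csv
eggage fit-glm --features features.csv --stage age-only --out ranking.csv
eggage train --features features.csv --iterations 3000 --trees 500 --out run/
eggage predict --run run/ --train-features features.csv \
       --features new_features.csv --out predictions.csv
eggage evaluate --run run/ --nests data/nests.csv --out report/
```

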