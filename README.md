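# pebkit

Bayesian model reduction (BMR) and parametric empirical Bayes (PEB) for
hierarchical group studies with nonlinear first-level observation models.

Given the posterior of a *full* model (any Gaussian-prior model inverted by
variational Laplace), the posterior and evidence of every *nested* model —
same likelihood, more constrained prior — follow in closed form. This
enables:

- **first-level model comparison** over large nested model spaces from a
  single inversion per subject;
- **empirical Bayes across subjects**: a linear between-subject level
  (Kronecker design `X ⊗ W`, log-precision-weighted covariance components)
  inverted from the subject posteriors alone, yielding group effects,
  empirical shrinkage priors and shrunk subject estimates;
- **model-space operators**: fixed/random-effects Bayesian model
  comparison, Bayesian model averaging (per subject) and parameter
  averaging (per model), exhaustive/greedy search over second-level
  parameter subsets, and joint first×second-level comparison;
- **predictive classification**: estimating unknown design-matrix entries
  (e.g. diagnostic class) for held-out subjects from a trained group model,
  with Savage–Dickey categorical probabilities and leave-one-out
  cross-validation.

A synthetic-data module generates two-group studies (group means plus
Gaussian random effects, per-subject random mixing matrices, smoothed
observation noise) so the entire pipeline is testable offline.

## Library quick start

```python
import numpy as np
from pebkit import (
    SimulationConfig, simulate_group_study, make_model_space,
    invert_laplace, ModelArray, ffx_bmc, SecondLevelModel, peb_invert,
    loo_cross_validation,
)
from pebkit.io_cli import invert_study

study = simulate_group_study(SimulationConfig(seed=1))
subjects = invert_study(study)                       # first-level inversions

models = make_model_space(study.blocks, study.prior) # 8 nested models
arr = ModelArray.from_reduction(subjects, models)    # BMR, no re-inversion
group_F, probs = ffx_bmc(arr.F)                      # fixed-effects BMC

slm = SecondLevelModel.from_subjects(subjects, study.X,
                                     effect_names=study.effect_names)
slp = peb_invert(subjects, slm)                      # PEB: beta, gamma, F2
print(slp.beta.mean, slp.F2)

table = loo_cross_validation(subjects, study.X, unknown_column=1,
                             labels=[-1.0, 1.0])     # predictive labels
```

Free energies are in nats throughout. Parameters with zero prior variance
are represented by an explicit support mask and handled by exact subspace
restriction (a large-precision fallback is provided and tested against it).

## CLI

The `pebkit` console script chains the pipeline; every stage derives its
seed from the master `--seed` by a fixed offset:

```sh
pebkit simulate --seed 1 --out run/study
pebkit invert   --study run/study --out run/subjects
pebkit reduce   --subjects run/subjects --models models.json --out run/scores.csv
pebkit bmc      --scores run/scores.csv --out run/bmc.csv           # or --rfx
pebkit peb      --subjects run/subjects --design run/study/X.csv \
                --hessian consistent --out run/peb.h5
pebkit search   --peb run/peb.h5 --out run/search.csv
pebkit loo      --subjects run/subjects --design run/study/X.csv \
                --unknown group --labels -1,1 --out run/loo.csv
```

Model sets are JSON maps `model name -> {parameter: {mean, var}}` where
`var: 0` switches a parameter off. Designs are CSV with a header row of
effect names and a mandatory constant first column.

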