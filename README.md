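# alm — Anticipated Learning Machine

Multistep-ahead prediction of a single target variable from **short-term but
high-dimensional** time series.

Many systems — gene regulatory networks, plankton communities, climate
fields, traffic networks — are observed as dozens to thousands of variables
over only a handful of time points.  Classical forecasting needs long
records of the target; this package exploits the other axis.  By delay
embedding theory, the delay attractor of any single target variable `x_k`
and the high-dimensional (nondelay) attractor of the full state `X` are
topologically conjugate, so there is a smooth map `Psi` with components

    Psi_i(X(t_j)) = x_k(t_{i+j-1}),    i = 1..L,  j = 1..M,

turning the *spatial* information in one observed state into the *temporal*
evolution of the target.  Written for all observed times, the left side is a
matrix of map evaluations and the right side the L x M Hankel matrix of the
target — whose lower-right anti-diagonals contain the L-1 **unknown future
values**.  A feed-forward network learns `Psi` with input dropout (each
epoch trains a random subset of variables, i.e. one sampled nondelay
attractor), a two-phase scheme that first fits the known Hankel cells and
then enforces the cross-sample consistency constraints
`Psi_i(X(t_j)) = Psi_{i-1}(X(t_{j+1}))`, and a feedback loop that fuses the
anti-diagonal estimates of each future value and feeds the fused value back
as a training label for the next step.  Because the training labels include
the target's future, the scheme is called *anticipated learning*.

See `docs/methods.md` for the model, training stages, parameter defaults
and limitations.

## Worked example

Generate the built-in benchmark — a 90-dimensional time-variant coupled
Lorenz ring sampled at 55 time points — train on the first 30 points, and
predict the next 25 values of one coordinate:

```python
import numpy as np
from alm import ALMConfig, LorenzConfig, simulate_coupled_lorenz, fit_predict
from alm.evaluation import compute_indicators

series = simulate_coupled_lorenz(LorenzConfig(seed=2))   # 90 x 55
train = series.window(0, 30)                             # 30 training points
cfg = ALMConfig(L=26, horizon=25, seed=1)                # anticipate 25 steps
res = fit_predict(train, "x6", cfg)

truth = series.values[series.variable_index("x6"), 30:55]
rep = compute_indicators(truth, res.values)
print(np.round(res.values[:5], 2))
print(np.round(truth[:5], 2))
print(f"pearson={rep.pearson:.3f}  rmse={rep.rmse:.2f}")
```

```
[-4.92 -1.26  2.48  6.92  9.67]
[-4.65 -1.07  2.93  7.25 10.07]
pearson=0.979  rmse=1.51
```

The first line is the start of the 25-step forecast of `x6`, the second the
held-back truth; the network was trained on 30 points of 90 variables and
never saw any future value.  Prediction quality on this benchmark depends
on the dynamical regime of the instance: trajectory segments on the regular
collective attractor are predicted with Pearson above 0.9, while segments
of fully developed synchronized chaos hit the ~2-Lyapunov-time information
limit of 30 samples (see `docs/methods.md`, Known limitations).

The same pipeline is exposed as a command-line tool:

```
alm simulate --seed 2 --out series.csv
alm predict series.csv --target x6 --horizon 25 --seed 1 --out pred.csv
alm evaluate pred_with_truth.csv --out report.csv
alm window-scan series.csv --target x6 --windows 10,20,30,60 --out scan.csv
```

## Tests

```
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end scientific checks (exact
STI matrix structure, combinatorics oracle, linear-system oracle,
coupled-Lorenz reproduction with and without noise, consistency-training
effect, ensemble concentration, window-scan shape).

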