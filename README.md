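# hergfit

Parameter inference for the hERG (I<sub>Kr</sub>) cardiac potassium channel,
warm-started by a neural network.

Fitting a Hodgkin–Huxley channel model to a patch-clamp recording is slow
and prone to local minima, yet it is the workhorse of CiPA-style
proarrhythmia assessment: a drug's effect on hERG kinetics is read off the
fitted parameters. `hergfit` implements a complete in-silico pipeline that
attacks the initialization problem: simulate currents under a staircase
voltage-clamp protocol, generate labelled synthetic training data from a
physiologically constrained prior, train a spectrogram-based regressor that
maps a current trace to approximate channel parameters, and use that
prediction as the starting point for CMA-ES model fitting — benchmarked
against prior-midpoint and random starts, with adaptive-Metropolis MCMC for
posterior exploration.

## Model

The channel carries

$$I_\mathrm{Kr} = g_\mathrm{Kr}\, a\, r\, (V - E_K),\qquad
E_K = \frac{RT}{zF}\ln\frac{[K^+]_o}{[K^+]_i} \approx -85.15\ \mathrm{mV},$$

with an activation gate $a$ and an inactivation gate $r$ relaxing as
$\dot a = (a_\infty - a)/\tau_a$, $\dot r = (r_\infty - r)/\tau_r$, where

$$a_\infty = \frac{k_1}{k_1+k_2},\quad \tau_a = \frac{1}{k_1+k_2},\quad
r_\infty = \frac{k_4}{k_3+k_4},\quad \tau_r = \frac{1}{k_3+k_4},$$

$$k_1 = p_1 e^{p_2 V},\quad k_2 = p_3 e^{-p_4 V},\quad
k_3 = p_5 e^{p_6 V},\quad k_4 = p_7 e^{-p_8 V}.$$

Nine free parameters: $\theta = (g_\mathrm{Kr}, p_1,\dots,p_8)$.
Priors are componentwise uniform ($g_\mathrm{Kr}\in[10^2, 5{\times}10^5]$ pA/V,
prefactors $[10^{-4}, 10^6]$ s⁻¹, sensitivities $[10^{-4}, 400]$ V⁻¹)
subject to four physiological constraints
$0.0167 < p_{2i-1} e^{\pm p_{2i} V_{\mathrm{ext}}} < 10^6$ at
$V_{\min} = -120$ mV, $V_{\max} = +60$ mV.

Because the voltage command is piecewise constant, the gate ODEs are linear
within each step and the simulator evaluates their exact exponential
solution (an adaptive stiff ODE backend is included for cross-checking).

## Worked example

Recover parameters from a noisy synthetic recording
(`examples/05_fit_and_recover.py`):

```
$ python examples/05_fit_and_recover.py
initial objective:   150.49 pA
objective at truth:   11.01 pA (the noise floor)
status: converged after 316 iterations (3161 evaluations)
fitted RMSE: 10.97 pA
relative errors per parameter (g, p1..p8):
   0.44%   0.79%   0.23%   1.25%   0.31%   1.23%   4.18%   1.73%   1.36%
```

The fit starts ×1.5 off per component (objective 150 pA), converges to the
10.84 pA measurement-noise floor, and returns every parameter within a few
percent of the generating value — the staircase protocol carries enough
information to pin down all nine parameters in the physiological regime.

Other examples (`examples/`): staircase simulation, constrained prior
sampling, dataset + spectrogram generation, regressor training, the
three-initializer benchmark, and posterior MCMC. A thin CLI wraps the same
functions:

```
hergfit protocol show
hergfit generate --n 1000 --seed 1 --out data.h5
hergfit train --data data.h5 --out model.bin
hergfit fit --trace cell.csv --init predicted --model model.bin --seed 1 --out fit.json
hergfit run --config examples/demo_config.yaml
```

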