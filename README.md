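# entotaxis

Analysis toolkit for odor-source localization in walking insects —
from raw trajectory and electroantennogram (EAG) recordings to
odor-encounter timings, wind-frame behavioral metrics, and an
information-entropy account of how the search narrows in on the source.
A synthetic plume/moth/EAG generator makes every stage testable without
a tracking robot or live animals.

## The problem

A male silk moth (*Bombyx mori*) walking toward a pheromone source does
not follow a concentration gradient: odor arrives as intermittent pulses
carried on the wind, and the antennal response (EAG) adapts under
repeated stimulation, so the strongest signals occur early in the search
and far from the source.  What the animal reliably has is the *timing*
of its odor encounters.  This package implements the analysis that makes
that idea quantitative.

## The model

Odor detections are modeled as an inhomogeneous Poisson process whose
rate, for a searcher at $r$ and a source at $r_0$, follows an
advection–diffusion plume:

$$R(r\mid r_0) = \frac{aE}{|r-r_0|}\,
  e^{-|r-r_0|/\lambda}\; e^{\,sW/2D},\qquad
  \lambda = \sqrt{\frac{D\tau}{1 + W^2\tau/4D}}$$

with sensor size $a$ = 10 mm, emission rate $E$ = 1, particle lifetime
$\tau$ = 6.3 s, diffusivity $D$ = 0.057 m²/s, wind speed $W$ = 0.6 m/s,
and $s$ the searcher's downwind displacement from the candidate source.
Given the encounter history $\Gamma_t$ (encounter instants $t_i$
separated by silent intervals), the likelihood of a candidate source is

$$L(\Gamma_t \mid r_0) = e^{-\int R(r(t')\mid r_0)\,dt'}
  \prod_i R(r(t_i)\mid r_0),$$

normalized over a grid of candidate source cells (Bayes, uniform prior)
to give a posterior $P_t(r_0)$, its Shannon entropy
$S_t = -\sum p \ln p$, and the relative entropy $S_t/S_0$ that starts at
1 and falls as detections — and silences — accumulate.

Around that core sit the supporting stages: zero-phase 10 Hz low-pass
filtering of the 1 kHz EAG, peak detection for encounter timing,
response metrics (rise time $T_r$, recovery time $T_d$, amplitude),
per-trial intensity normalization, trajectory/EAG fusion, translational
speed, upwind/downwind/crosswind movement fractions, cast detection,
localization outcome against a 10 mm success disc, and spatial intensity
maps.  The generator simulates the standard assay (source at the origin,
1 Hz odor pulses into a 0.6 m/s wind, moth starting 150 mm downwind,
180 s timeout) with a surge/cast/loop agent and an adapting EAG kernel.

## Worked example

```bash
python examples/02_simulate_and_analyze.py
```

```
trial: 6510 samples, 3 true encounters, success=True, time to source = 65.1 s
EAG detection: 3 of 3 encounters recovered
movement fractions: upwind 0.29, downwind 0.20, crosswind 0.51
near-source amplitude ratio = 0.71
```

The simulated moth reaches the 10 mm disc in 65 s after only three odor
encounters; every encounter is recovered from the synthesized voltage
trace; about a third of its moving time points upwind (casting accounts
for the crosswind half); and the EAG amplitude recorded nearest the
source is 71% of the trial maximum — adaptation damps the response
exactly where the odor is strongest.  `examples/01_plume_and_posterior.py`
verifies the Bayesian machinery against a closed form, and
`examples/03_entropy_trace.py` prints the falling $S_t/S_0$ along a
search.

A thin CLI wraps the same functions:

```bash
entotaxis simulate --seed 7 --out run/
entotaxis process-eag --eag run/eag.csv --out run/encounters.csv
entotaxis report --seed 7 --out run_full/
```

## Layout

- `src/entotaxis/plume.py` — encounter-rate model and decay length
- `src/entotaxis/infotaxis.py` — grid posterior, entropy, traces
- `src/entotaxis/eag.py` — filtering, peak detection, response metrics
- `src/entotaxis/kinematics.py` — fusion and behavioral metrics
- `src/entotaxis/synthetic.py` — plume/moth/EAG generator + ground truth
- `src/entotaxis/io.py`, `pipeline.py`, `cli.py` — files, end-to-end
  runs, command line
- `docs/methods.md` — model assumptions, parameter choices, limitations
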