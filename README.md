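# larvascreen

Automated motility phenotyping of mosquito larvae in multi-well video
assays. The toolkit quantifies how much each well of a filmed microplate
moved, turns those measurements into concentration–response potencies, ranks
compound libraries for larvicidal hits, and discriminates
insecticide-susceptible from resistant larval populations by how quickly
their movement decays after exposure — all the analysis that sits between a
camera pointed at a 96-well plate of *Anopheles* or *Aedes* larvae and a
potency or resistance call.

## What it computes

**Movement index.** For each 30-frame sequence (10 ms intervals), frames
1, 11 and 21 are read and the per-pixel temporal variance x computed. Pixels
with

    x_i > mean(x) + 3·std(x)

are scored 1, the rest 0, and each well's movement index is the count of
1-pixels in its region. Indices after compound addition are divided by the
same well's pre-compound baseline (the *normalized movement index* M), and
replicates are aggregated by median. The threshold is scale-free, so the
index is invariant to camera gain and offset.

**Concentration–response.** M is fitted against log10 molar concentration C
with the two-parameter Hill curve

    M(C) = 1 / (1 + 10^((C − I)·H)),   pIC50 = −I

by bounded least squares; mortality fractions use the rising mirror curve
D = 1 − M (midpoint = LC50, reported as logLC50 on the same −log10
convention). Resistance ratios are IC50(resistant)/IC50(susceptible).

**Streaming variance (smartphone pathway).** Per-pixel mean and variance are
maintained online, one frame at a time,

    M_n = M_{n−1} + (P − M_{n−1})/n
    V_n = ((n−1)·V_{n−1} + (P − M_{n−1})(P − M_n))/n

(the population-variance form of Welford's algorithm), exported every
measurement cycle (default 60 frames every 10 s), and averaged per well to
give a motility time series without buffering video.

**Decay-rate resistance calls.** After insecticide addition at time T the
per-well variance trace is fitted with

    V(t) = A + B·exp(−k·(t − T))   (plateau A + B for t < T),

and the decay rate k (= 1/τ, s⁻¹) separates fast-paralysed susceptible
larvae (large k) from resistant ones (small k); groups are compared with a
one-tailed pooled-variance t-test (df = n₁ + n₂ − 2).

A seeded synthetic-data module generates plate videos (drifting, jumping
larvae with dose-scaled motility), dose tables and decay traces with known
ground truth, so every stage is testable without real recordings.

## Worked example

```python
import numpy as np
from larvascreen import (
    SimulationConfig, simulate_series, measure_plate,
    DoseResponsePoint, fit_sigmoid, well_label,
)

# one simulated 96-well plate per replicate: each row dosed at one
# concentration, planted potency pIC50 = 7.0
concs = np.logspace(-8.75, -5.25, 8)
dose_map = {well_label(r, c): concs[r] for r in range(8) for c in range(12)}
plate = SimulationConfig.reduced().plate_map()

by_conc = {c: [] for c in concs}
for rep in range(3):
    cfg = SimulationConfig.reduced(seed=100 + rep)
    series, truth = simulate_series(cfg, dose_map, true_I=-7.0, true_H=1.0)
    for rec in measure_plate(series, plate, replicate=rep + 1):
        if rec.is_defined:
            by_conc[concs[ord(rec.well[0]) - 65]].append(rec.normalized_index)

points = [DoseResponsePoint(c, np.median(v)) for c, v in by_conc.items()]
fit = fit_sigmoid(points)
print(f"pIC50 = {fit.pic50:.2f}  (slope {fit.slope:.2f}, converged={fit.converged})")
```

```
pIC50 = 6.97  (slope 1.10, converged=True)
```

The recovered pIC50 of 6.97 sits within 0.05 log units of the planted 7.0:
the movement index of each dosed row fell in proportion to the planted Hill
factor, and the fit read the potency back off the synthetic videos.

A command-line interface mirrors the library (`larvascreen measure`,
`dose`, `stream`, `decay`, `screen`, `simulate` — see `--help`).

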