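# octflux

Capillary red blood cell (RBC) flux estimation from OCT intensity
time-series.

When a red blood cell passes through an OCT imaging voxel it produces a
transient intensity peak, so the trace of a capillary voxel is a pulse
train whose rate is the RBC flux (cells/second). The classical estimator —
count peaks above a threshold — needs a hand-picked threshold, is fragile
to speckle noise, and systematically underestimates high flux, where
passages are frequent but dim. `octflux` implements the
simulation-and-learning alternative for people who study microvascular
flow with OCT:

- a **trace simulator** with the empirical statistical structure of
  capillary OCT data — Gaussian pulses whose heights follow a two-level
  beta model, widths a two-level gamma model with width × flux ≈ constant,
  gamma inter-peak gaps with mean 1/flux that are overdispersed relative
  to a Poisson process at low flux, coherent speckle noise
  `I = S + |N|² + 2S|N|cos φ`, and a slow sinusoidal baseline — used to
  build flux-balanced labeled training sets of any size;
- **peak analysis**: prominence-ranked detection, FWHM measurement with
  filter-broadening correction, the threshold-counting baseline,
  beta/gamma refitting for calibrating the simulator on labeled data, and
  the noise/width-distortion experiment;
- a **1D inception-style CNN regressor** (kernels 10/20/40, three
  modules, global average pooling) with two outputs — the flux ŷ and a
  learned predictive standard deviation σ — trained with the
  heteroscedastic Gaussian negative log-likelihood
  `ln σ + ½ln 2π + (G−ŷ)²/(2σ²)`, so unreliable traces announce
  themselves through large σ;
- **network mapping**: voxel-wise application to 4D (x, y, z, t) volumes,
  recentering of vessel centerlines onto low-σ voxels, and
  inverse-variance weighted per-vessel flux `F = Σ(f_i/σ_i²)/Σ(1/σ_i²)`.

The network is implemented in numpy with hand-written backpropagation
(verified against finite differences), so the package has no
deep-learning-framework dependency and trains in minutes on a CPU.

## Worked example

```python
import numpy as np
from octflux import (TrainConfig, build_model, evaluate, generate_dataset, train)

train_ds = generate_dataset(per_category=40, rng=1)   # 480 traces, 12 flux bins
test_ds = generate_dataset(per_category=10, rng=2)

model = build_model(seed=0)
history = train(model, train_ds, TrainConfig(epochs=3, seed=0))
met = evaluate(model.predict(test_ds), test_ds.labels)
print(met.slope, met.r2)
```

Running `python examples/03_train_and_evaluate.py` (this script at the
same small scale) prints:

```
trained 10922 parameters; train loss 1.429 -> 0.908
held-out: slope 0.933, R^2 0.790 over 120 traces
keeping the 80% most confident predictions: slope 0.878, R^2 0.719
```

A slope near 1 means no systematic bias across 0–120 RBC/s; R² is the
squared correlation between predicted and true flux (the training loss is
reported in standardized label units). At this toy scale (480 traces,
3 epochs) the model and its uncertainty head are visibly under-trained —
the package's standard reduced protocol (500 traces/category, 10 epochs,
~8 CPU-minutes) reaches slope ≈ 0.98 and R² ≈ 0.84 on held-out simulated
data, with the residual dominated by the hardest regime the generator
deliberately includes (flux above 100 RBC/s at signal-to-noise ratios
below 1); that protocol is what the test suite runs.

The other examples cover the simulator (`01`), the noise/width-distortion
experiment (`02`), the threshold baseline and its high-flux bias (`04`),
and per-vessel flux over a synthetic 4D capillary phantom (`05`). A thin
CLI wraps the same functions:

```bash
octflux simulate --per-category 100 --seed 7 --out data.h5
octflux train --data data.h5 --epochs 10 --out model.npz --seed 0
octflux evaluate --model model.npz --data test.h5 --out metrics.json
octflux predict-volume --model model.npz --volume vol.h5 \
    --centerlines cl.csv --out vessels.csv
```

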