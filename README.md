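# doseup

Super-resolution of 2D dose measurements from a checkerboard
ionization-chamber array, with a dense convolutional network trained on
synthetic data, a bilinear reference chain, gamma-index evaluation, and
radiochromic-film calibration utilities.

## The problem

Planar dose verification compares a measured 2D dose distribution against a
prediction, typically with the gamma index. Ionization-chamber arrays
measure in real time but sample coarsely: the modeled array has 1405
chambers on a 53×53 grid at 5 mm pitch in a checkerboard pattern, so the
nearest chambers sit diagonally at 5·√2 ≈ 7.1 mm and half the grid nodes
are empty, while each 4.4 mm chamber volume-averages the local dose.
`doseup` reconstructs the underlying 159×159 dose map at 1.67 mm from such
a measurement and quantifies the gain over conventional bilinear
interpolation. See `docs/methods.md` for the full model description.

## Worked example

Generate a reduced-geometry dataset (27×27 inputs → 81×81 targets), train
the reduced network, and compare both reconstruction methods on a held-out
measurement — all from Python:

```python
import numpy as np
from doseup import (GammaCriteria, NetworkSpec, TrainConfig, build_network,
                    split_dataset, train)
from doseup.evaluate import evaluate_methods
from doseup.synthetic import generate_dataset, scaled_profile

cfg = scaled_profile(n_sims=200, pairs_per_sim=3)
pairs, _ = generate_dataset(cfg, seed=7)                 # ~3 s
tr, va = split_dataset(pairs, cfg.val_fraction, np.random.default_rng(7))

model = build_network(NetworkSpec.scaled(), seed=7)
model, hist = train(model, tr, va, TrainConfig(epochs=15, batch_size=16,
                                               seed=7))  # ~7.5 min on 1 CPU
print("val MSE", hist.val_loss[0], "->", hist.val_loss[-1])

fields = [p for p in va if p.target.values.max() > 0.05][:50]
crit = GammaCriteria(dose_pct=2, dta_mm=2, local=True, threshold_pct=10)
rep = evaluate_methods(fields, model, crit,
                       training_sim_ids={p.sim_id for p in tr})
print(f"bilinear {rep.bilinear_mean:.2f}+-{rep.bilinear_sd:.2f}  "
      f"network {rep.network_mean:.2f}+-{rep.network_sd:.2f}")
```

Trained on the 510 training pairs this prints validation MSE falling from
2.6e-3 to 1.7e-4 Gy², and on the 50 held-out fields with measurable dose
the mean ± SD gamma passing rate (2 %/2 mm local, 10 % threshold) is

```
bilinear 73.28+-15.11  network 89.06+-15.21
```

a 15.8-point improvement of the learned reconstruction over the
conventional chain.

The same pipeline is scriptable from the command line:

```
doseup generate --scaled --n-sims 200 --seed 7 --out data/
doseup train --scaled --data data/ --seed 7 --out model.npz
doseup upsample --method nn --model model.npz --in data/pair00000.input.grid --out up.grid
doseup gamma --ref data/pair00000.target.grid --eval up.grid --report gamma.json
doseup evaluate --data data/ --model model.npz --report report.json
```

## Package layout

| module | contents |
| --- | --- |
| `doseup.grids` | `DoseGrid` container and coordinate conventions |
| `doseup.detector` | array layout, volume-averaging + noise forward model |
| `doseup.baseline` | hole filling + bilinear upsampling reference chain |
| `doseup.synthetic` | machine-parameter sampling, dose renderer, dataset generation |
| `doseup.network` | dense upsampling network, equivariance loss, training |
| `doseup._autodiff` | minimal reverse-mode autodiff backend (float32, NHWC) |
| `doseup.gamma` | 2D gamma index with local/global criterion |
| `doseup.film` | radiochromic film calibration and scan conversion |
| `doseup.io` | JSON grid containers, CSV export |
| `doseup.evaluate` | network-vs-bilinear comparison on held-out fields |
| `doseup.cli` | `doseup` command-line interface |
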