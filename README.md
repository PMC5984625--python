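# afmring

Analysis toolkit for high-speed AFM (HS-AFM) movies of ring-shaped protein
oligomers — AAA+ disaggregase hexamers of the ClpB/Hsp104 family — and the
equilibrium/kinetic titrations that accompany them.

HS-AFM records nanometer-resolution height maps of single proteins at
video rate. For a ring-forming ATPase this raises two quantitative
questions per frame: is the ring **closed or open**, and if closed, is it
**round or distorted** (spiral / twisted-half-spiral)? `afmring` answers
both with the two shape statistics standard for this problem:

* **Circularity** `4πS/L²` of the particle outline after elliptic Fourier
  smoothing to the 8th harmonic (L = perimeter, S = area; 1 for a circle).
  Rings at or above the threshold 0.68 are closed.
* **SDCH**, the standard deviation of cross-sectional heights sampled
  along the outline shrunk toward the ring center (shrink 0.65). Closed
  rings below 0.3 nm are round; above, distorted.

From the per-frame states the package counts **transition cycles** (one
full round → distorted → round excursion) and their frequency, the
single-molecule counterpart of the ATPase turnover. Around this core it
provides:

* first-order plane flattening and wavelength-parameterized Gaussian
  low-pass filtering of frames;
* ridge-path contour-length measurement of closed rings;
* AFM image simulation from PDB coordinates by grey-scale dilation with a
  sphere-capped cone tip (R = 0.5 nm, half angle 5°);
* curve fits: 1:1 binding `F_max·c/(K_d+c)`, Hill
  `V_max·cⁿ/(K_mⁿ+cⁿ)`, Michaelis–Menten, single-Gaussian histogram
  fits, mant-nucleotide direct (ligand-depletion quadratic) and
  competitive replacement titrations, NADH-coupled ATPase slope
  conversion, and max-window disaggregation slopes;
* a synthetic-data generator producing ring-oligomer movies (round,
  spiral, twisted-half-spiral, open forms; Markov state switching at
  10 fps) and titration curves with known ground truth, used throughout
  the tests.

See `docs/methods.md` for the models, parameter defaults and their
rationale.

## Worked example

Simulate a one-minute two-state movie (round hexamer ↔ spiral, symmetric
switching at 0.6 s⁻¹, 10 fps) and run the full pipeline:

```python
import numpy as np
from afmring import synthgen
from afmring.cli import analyze_frames, PipelineConfig

dyn = synthgen.DynamicsModel(
    states=("round", "distorted"),
    rate_matrix=np.array([[0.0, 0.6], [0.6, 0.0]]),
    frame_rate=10, duration=60, seed=7)
models = {"round": synthgen.make_ring_model("round"),
          "distorted": synthgen.make_ring_model("spiral")}
movie, truth = synthgen.simulate_movie(dyn, models)

report = analyze_frames(movie.frames, movie.frame_interval, PipelineConfig())
print(report.ring_tally["pct_closed"])
print(report.transitions.to_text())
```

```
100.0
transition cycles: 17
total observation time: 60.000 s
cycle frequency: 0.283333 1/s
  round: 17 complete dwells, mean 1.835 s
  distorted: 17 complete dwells, mean 1.465 s
```

All 600 frames classify as closed rings (the chain never visits the open
form), and the measured cycle frequency 0.283 s⁻¹ estimates the expected
rate k/2 = 0.3 s⁻¹ of the symmetric two-state chain from 17 completed
cycles. Fitting a noisy binding titration recovers its constants the same
way:

```python
from afmring import fitkin
c = np.array([10., 50., 100., 500., 1000., 2000.])  # uM ATP
spec = synthgen.TitrationSpec("binding_1to1", c, noise_sd=0.02, seed=11)
print(fitkin.fit_binding_1to1(synthgen.simulate_titration(spec)).report())
```

```
model: binding_1to1
converged: True
  K_d = 8.91103 +/- 1.07
  F_max = 0.599473 +/- 0.00956
  RSS = 0.00124999
```

i.e. K_d = 8.9 ± 1.1 μM against a generator truth of 9.9 μM at this noise
level.

The same stages are available from the shell:

```sh
afmring simulate-movie --duration 60 --rate 0.6 --seed 7 --out movie.tif
afmring analyze-movie movie.tif --outdir results/
afmring simulate-titration --model binding_1to1 \
    --concentrations 10,50,100,500,1000,2000 --seed 11 --out curve.csv
afmring fit-titration curve.csv --model binding_1to1
afmring pdb2afm --pdb structure.pdb --tip-radius 0.5 --half-angle 5 \
    --cutoff 3 --out simulated.tif
```

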