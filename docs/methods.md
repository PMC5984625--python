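# Methods

`afmring` quantifies the conformational states and ATP-driven dynamics of
ring-shaped AAA+ disaggregase oligomers (ClpB/Hsp104-type hexamers) from
high-speed AFM (HS-AFM) height-map movies. Because raw HS-AFM data of this
kind are rarely deposited, the package pairs every analysis stage with a
synthetic-data generator whose ground truth the pipeline must recover; the
generator's defaults define the study conditions.

## Image model and preprocessing

A frame is a calibrated grid of heights in nm (default 0.5 nm/px, 128×128).
Before any metric, each frame is

1. **plane-flattened**: a least-squares plane `a + b·x + c·y` fitted over
   background pixels (or all pixels) is subtracted, removing sample tilt;
2. **low-pass filtered**: an isotropic Gaussian kernel whose transfer
   amplitude is 1/2 at spatial frequency `1/cutoff`, with the cutoff given
   as a *wavelength* (default 3.0 nm, configurable 2–4 nm). A stated
   "cutoff frequency of 3 nm" is dimensionally a length, so the package
   reads it as the attenuated wavelength — the only consistent
   interpretation. A Gaussian (rather than ideal brick-wall) kernel avoids
   ringing at the sharp ring edges; boundary handling is reflective, so the
   DC level is preserved.

## Open/closed classification (circularity)

Each frame is binarized at the Otsu threshold of its height histogram
("optimum threshold" made deterministic), the largest 8-connected component
is selected, and its outer boundary traced by Moore neighbor tracing.
The boundary polygon is smoothed by truncating its Kuhl–Giardina elliptic
Fourier series at the 8th harmonic and resampling 256 points. Circularity
is `4πS/L²` of the smoothed profile (perimeter L, shoelace area S); it is 1
for a circle and scale/rotation invariant by construction. Rings with
circularity ≥ 0.68 are **closed**, below 0.68 **open**; ties classify as
closed. Frames with empty foreground or border-touching particles are
flagged and excluded. Circularity histograms use a fixed 0.02 bin width.

Note on the order-1 elliptic Fourier fit: under the arc-length
parameterization the first harmonic of an eccentric ellipse is *smaller*
than the ellipse itself (≈9 % for 2:1 axes); the identity "ellipse = first
harmonic" holds only near circularity. Tests therefore check the order-1
coefficients against a dense quadrature oracle rather than the naive
identity.

## Contour length

For closed rings, the ridge path is located on 360 rays from the ring
center (the area centroid of the smoothed outline): on each ray the radial
height maximum is found by bilinear interpolation on a quarter-pixel grid.
A ray whose maximum sits at the center, or carries less than 20 % of the
frame's peak height, indicates an open ring and aborts the measurement.
The ridge points are smoothed by the same order-8 truncation and the
perimeter of the reconstruction is the contour length. For the default
wild-type hexamer the ridge circle has circumference 35.2 nm by
construction, and the pipeline recovers it to ≈0.2 %.

## Round/distorted classification (SDCH) and transition cycles

The **SDCH** — standard deviation of cross-sectional heights — is measured
along the smoothed outline shrunk radially toward the ring center by a
factor of 0.65 (the usable range is 0.6–0.7; the midpoint is the default).
The shrunk path is resampled at 64 equal-arc-length positions and heights
read by bilinear interpolation; the population SD is returned. SDCH
< 0.3 nm is the **round** state, ≥ 0.3 nm **distorted** (ties distorted).

Occasional spike frames (transient tip artifacts) are replaced by the
previous frame's value. Spike detection needs a concrete rule: a frame is
a spike when its SDCH exceeds the series median by more than 6 median
absolute deviations *and* jumps more than 0.4 nm above the previous frame.
The MAD gate is robust to the bimodal round/distorted mixture, and the
jump condition protects genuine sustained state changes; both constants
are configurable. The first frame has no predecessor and is never
replaced.

A **transition cycle** is one complete round → distorted → round
excursion, counted at each distorted→round transition preceded by a
round→distorted transition; the frequency divides the cycle count by the
total observation time (`n_frames / frame_rate`). No hysteresis or
minimum-dwell debouncing is applied by default (none is stated for the
original analysis); dwell-time lists report complete (uncensored) visits
only.

## Synthetic generator

Oligomers come in four forms: round closed ring, spiral, twisted-half-
spiral, and open ("worm-like") chain of 3–8 protomers. Each protomer
occupies an arc of the ridge circle (default circumference 35.2 nm) and is
rendered as a Gaussian cap in the *distance to its arc* (lateral width
1.8 nm), with caps combined by max — an AFM topograph is an envelope, not
an additive density. Arc-footprint caps rather than point Gaussians are
essential: point caps at hexamer spacing would corrugate the round form by
several nm and push it far over the 0.3 nm round/distorted threshold,
contradicting the smooth crest (SDCH ≈ 0.2 nm) of real round rings. A
shallow per-protomer bump (0.15 nm) reproduces the barely-resolved
protomer peaks without breaching the threshold.

* **round**: abutting equal-height arcs — a smooth closed crest;
* **spiral**: one 10° seam, crest descending linearly by 1.5 nm over the
  run (a linear ramp of drop D has SD = D/√12 ≈ 0.43 nm, reliably
  distorted);
* **twisted-half-spiral**: two seams ~180° apart with two independently
  descending trimer runs;
* **open**: a 120° missing arc, classifying well below 0.68 circularity.

Crest height (8.0 nm) and width are free generator parameters chosen
inside the 0–9.2 nm color-bar range of typical topographs; no numeric
protomer dimensions are published, so these are plausible-scale choices,
not reproduced claims.

Movies are continuous-time Markov chains over named states (exponential
dwells, Gillespie sampling) discretized at 10 fps; each frame is rendered
from its state's model with i.i.d. Gaussian pixel noise (default
0.1 nm). Noise seeds derive deterministically from (movie seed, frame
index), so re-rendering the ground-truth state table reproduces a movie
bit-for-bit. All stochastic entry points require an explicit seed.

Titrations are evaluated from closed forms plus optional Gaussian noise:

| model | form | wild-type defaults |
|---|---|---|
| 1:1 binding | `F_max·c/(K_d+c)` | K_d 9.9 μM, F_max 0.60 |
| Hill (ATPase) | `V_max·cⁿ/(K_mⁿ+cⁿ)` | V_max 1.0 s⁻¹/hexamer, K_m 0.16 mM, n 2.6 |
| Michaelis–Menten (transition frequency) | Hill, n = 1 | f_max 0.6 s⁻¹, K_m 0.35 mM |
| mant-nucleotide direct | depletion quadratic | K_d 4.0 μM, P_tot 6 μM monomer |
| competitive replacement | `(M/K_M)/(1+M/K_M+A/K_A)` | K_A 9.2 μM, M_tot 12.5 μM |

The mant-nucleotide direct-binding K_d (4.0 μM) is a free generator
parameter (no published value is available to reproduce); it only needs to
be internally consistent between generator and fit. The competitive model
is depletion-free by default; a numerical equilibrium solve
(`competition_bound_fraction_depletion`) is provided and serves as the
cross-check oracle — the closed form agrees within 3 % for protein
concentrations up to about half of K_M.

## Curve fitting

All fits are unweighted nonlinear least squares (trust-region, positivity
bounds) with deterministic initialization: K_d/K_m start at the
concentration nearest half-maximal response, amplitudes at the observed
maximum, Hill n at 1. Standard errors come from the covariance at the
optimum. Fitting with a fixed n = 1 reproduces the 1:1 fit to numerical
precision (tested). ATPase turnover is computed from NADH-coupled
absorbance slopes as `|slope|/(ε·path)/[hexamer]` with ε₃₄₀ = 6220
M⁻¹cm⁻¹ and a 1 cm path (standard assay constants); the disaggregation
rate is the maximum least-squares slope over all 60 s windows inside the
first 300 s of a fluorescence trace.

## AFM simulation from atomic coordinates

Atoms (PDB input, heteroatoms excluded, optional residue-range truncation
and chain selection) become van der Waals spheres (C 0.17, N 0.155,
O 0.152, S 0.18, H 0.12, P 0.18 nm; unknown elements 0.17 nm) resting on
the z = 0 support plane. The molecular surface is the pointwise max of the
sphere caps; the image is its grey-scale dilation by a sphere-capped cone
probe (default R = 0.5 nm, half angle 5°):

    t(r) = R − √(R² − r²)                      r ≤ R·cosθ
    t(r) = (r − R·cosθ)/tanθ + R(1 − sinθ)     r > R·cosθ

(the sphere joins the cone smoothly at the tangent circle). R = 0 denotes
an idealized delta-probe, for which the dilation is the identity. The
dilated image is low-pass filtered at 3 nm like the experimental frames.
Molecule orientation is a configurable rotation with identity default; the
view used for any particular published figure is not parameterized, so
structure-to-image comparisons are qualitative.

## Problem sizes and numerical choices

The bundled acceptance computations run the titration fits at their
experimental design points (6–10 concentrations), the contour pipeline on
one 128×128 noiseless frame, and the transition-frequency recovery on
600 s (6 000 frames) and 3 000 s (30 000 frames) two-state movies at
10 fps, streamed frame-by-frame so memory stays flat. On the slow-cycling
condition (0.022 s⁻¹) roughly 66 cycles are expected, giving a ~12 %
relative sampling SD — the classification itself reproduces the
discretized ground-truth sequence exactly in our checks, so the spread is
Markov realization noise, not detection error.

Degenerate inputs are rejected rather than guessed at: masks with fewer
than three non-collinear pixels, low-pass cutoffs at or below the Nyquist
length, open rings passed to contour length or SDCH, unseeded stochastic
calls, all-equal histograms.

## What the generator does and does not emulate

It emulates ring geometry and its four characteristic forms, two-state
Markov switching at realistic rates, pixel noise, sample tilt, and the
closed-form titration responses. It does **not** emulate scanner drift,
line noise or scars, tip-shape changes, crowded multi-particle fields,
partial assembly/disassembly events, or intermediate conformations between
forms. Passing tests therefore demonstrate that the measurement pipeline
is unbiased and precise under the stated image model — not that the
thresholds (0.68, 0.3 nm) would be optimal for instruments or molecules
with different noise structure.

## Known limitations

* Contour length is defined as a ridge-path perimeter; other conventions
  (e.g. skeletonized center-lines) would differ by a few percent on
  non-circular rings.
* The SDCH spike rule is heuristic; series whose genuine states differ by
  less than the 0.4 nm jump gate rely on the MAD gate alone.
* Transition counting applies no debouncing, so frame-rate-scale flicker
  at the threshold inflates counts for noise levels well above the
  default.
* The open ("worm-like") form is rendered as a circular arc; strongly
  self-crossing worm conformations are out of scope.
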