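# Methods

## Problem and model

canopyscope analyzes per-sample folders of co-registered 8-bit grayscale
frames, one per waveband (blue, green, red, near-infrared), plus a
chlorophyll-fluorescence frame (`cfi`) taken under blue excitation through a
>650 nm long-pass filter. Chlorophyll re-emits above 650 nm while typical
background materials do not, so in the fluorescence frame the plant is
bright and the background dark: the intensity histogram is bimodal, with the
background mode to the left of the plant mode. Segmentation exploits only
this optical property — no training data, no color-space heuristics.

The analysis chain per sample:

1. load the band frames (intensity 0–255 as a reflectance proxy);
2. histogram the fluorescence frame;
3. choose the binarization threshold at the *valley* — the minimum of the
   (smoothed) histogram — between the background and plant modes, searched
   within manual bounds `[lo, hi]` or bounds found automatically as the two
   leftmost sufficiently prominent peaks;
4. binarize (`intensity > t` is plant) and remove connected components
   smaller than a pixel-size cutoff (despeckle);
5. projected canopy area = foreground pixel count × (cm/pixel)²;
6. for each configured normalized-difference index
   `(R_a − R_b)/(R_a + R_b)` (NDVI: a = nir, b = red; NDAI: a = red,
   b = green), evaluate per foreground pixel, render a false-color image,
   and accumulate a 200-bin histogram on [−1, 1];
7. export mean, population standard deviation, pixel count and canopy area
   per sample to `results.csv`.

## Thresholding conventions

The valley position on a raw histogram is noisy, so the argmin runs on a
centered moving average (default window 5 bins, edge bins replicated;
window 1 disables smoothing). Two deliberately fixed conventions make the
threshold deterministic and auditable (both are recorded in
`ThresholdResult`):

* **strict comparison** — the threshold bin itself is background;
* **tie-break low** — equal minima resolve to the lowest intensity, biasing
  toward a larger plant mask.

The argmin ranges over every bin of `[lo, hi]` inclusive, including the
bound bins, whose smoothed value incorporates neighbours outside the
bounds. Automatic bounds take the positions of the two leftmost local
maxima whose prominence is at least 5% of the histogram maximum (the ends
of the histogram may carry a mode, e.g. a clipped dark background, and are
eligible). Fewer than two qualifying peaks raises a "histogram not bimodal"
error that points the user to manual bounds; manual bounds always take
precedence when both are given.

## Despeckling

Size-based filtering of the binary mask: connected components (8-neighbour
by default, 4-neighbour optional) with area below `min_component_px`
(default 50) are discarded. The operation only ever removes foreground and
is idempotent. An optional 3×3 median prefilter on the fluorescence frame
(default off) suppresses salt noise before thresholding; note it also
smooths the plant outline by a pixel, so pixel-exact recovery holds only
without it.

## Index statistics

Pixels where both bands read zero have an undefined ratio and are excluded
from every statistic rather than being scored 0 — an undefined pixel must
not dilute the canopy mean. The standard deviation is the population form
(ddof = 0): the canopy pixels are the entire population of interest, not a
sample. The index histogram uses 200 fixed bins of width 0.01 on [−1, 1];
only the final bin is right-inclusive, so the value 1.0 is counted once.
All valid values of an 8-bit band pair lie in [−1, 1] and negate under band
swap; both facts are verified exhaustively over all 65,536 pairs.

The NDAI band order and sign here — (R_red − R_green)/(R_red + R_green), so
anthocyanin-rich tissue scores positive — is a package convention; the
definition is fully configurable per index (`[[index]]` blocks in the TOML
config), so any published variant can be reproduced.

## Gray-card exposure calibration

Cross-band comparability requires each band's exposure to place a 50%-
reflectance gray card at the 8-bit midpoint (target 127). Under a linear
sensor the card mean is proportional to exposure time, so the update
`exposure ← exposure × target/mean` is a fixed-point iteration that lands in
one step up to quantization; convergence is declared at |mean − target| ≤ 1
intensity level (default), within 10 iterations. A saturated card
(mean 255) breaks the linear model, so the exposure is halved before
resuming; a card mean of 0 is unrecoverable and raises "no signal". The
card region is an explicit user-supplied rectangle — auto-detection is out
of scope. Converged exposures can be persisted as a TOML fragment.

The simulators used in tests dither the card level across pixels so the
region mean resolves below one intensity count, as a real sensor's noise
does; a strictly linear camera then converges in ≤ 2 captures from any
starting exposure that does not saturate, and a mild gamma nonlinearity
(mean ∝ exposure^0.9) still contracts to the target within a few
iterations.

## Synthetic scenes and what they do (not) show

The generator emulates exactly the statistical structure the segmentation
assumes: an elliptical plant of constant per-band reflectance on a constant
background, a bright plant / dark background fluorescence pair (defaults
180 / 10), optional senescence patches with their own reflectance, additive
independent-per-band Gaussian sensor noise (applied last: round, then clip
to [0, 255]), and small bright speckles rejection-sampled strictly outside
the plant so the ground-truth mask stays exact. Defaults: 96×96 px canvas,
0.05 cm/pixel, NDVI bands nir = 180 / red = 36 on the plant (closed-form
NDVI 2/3), noise σ = 5 for the noisy fixture, three 2-px speckles for the
speckled fixture. Generation is bit-deterministic given the seed.

These scenes validate the *computational* chain: threshold optimality,
exact mask/area/index recovery in the noiseless case, and first-order
error-propagated accuracy under noise (with band readings A, B and noise σ,
the per-pixel index deviation is σ_prop = 2σ√(A²+B²)/(A+B)², and the canopy
mean over N pixels concentrates as σ_prop/√N). They do not emulate real
canopies: no within-leaf reflectance texture, no specular highlights, no
uneven illumination, no partial-volume boundary pixels, no 3-D occlusion.
Passing on them shows the arithmetic and bookkeeping are right, not that
any particular camera is calibrated.

## Numerical and design choices

* Intensities stay integer (uint8) until index math; histograms are exact
  tallies.
* 16-bit or color input files are rejected, never rescaled: the instrument
  contract is monochrome 8-bit, and anything else signals an acquisition
  error.
* CSV reals carry 6 significant digits; undefined statistics (empty canopy)
  are empty fields, not zeros.
* Batch runs process folders lexicographically; a failing folder yields an
  error row and never aborts the batch; reruns on unchanged input are
  byte-identical.
* Problem sizes in the verification battery (96×96 scenes, 20-seed noisy
  segmentation, 100-seed noisy-mean coverage, 1,000 random histograms for
  the threshold oracle) were chosen to make the Monte-Carlo checks sharp at
  desk scale while keeping the whole battery under a few seconds.

## Known limitations

Top-view imaging sees one leaf layer only; indices describe the upper
canopy surface. The despeckle cutoff and smoothing window are
device-dependent and exposed in config rather than auto-tuned. The valley
search assumes the background mode sits left of the plant mode — scenes
with a bright background are out of contract. Flat-field (per-pixel)
correction and radiometric calibration beyond the spatial gray-card mean
are not implemented.
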