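# Methods

`cortiplast` re-implements, as a tested pipeline, the quantification chain of
a trigeminal nerve-transection cortical-plasticity experiment: macroscopic
voltage-sensitive-dye (VSD) imaging, cellular two-photon Ca²⁺ imaging, laser
scanning photostimulation (LSPS) excitation mapping, miniature IPSC
statistics, and the group-comparison statistics that tie them together.
Because the raw recordings behind such experiments are typically not public,
every stage is driven by a synthetic-data generator with known ground truth;
this note records the models, parameter choices, numerical details and the
limits of what the synthetic tests demonstrate.

## Wide-field VSD analysis (`vsd_macro`)

Stimulated and blank (no-stimulus) trials are averaged separately; the blank
average is subtracted frame-wise, which cancels any drift common to both —
in practice dye bleaching. The difference is divided by the per-pixel
baseline fluorescence F (mean of the raw stimulated average over the
pre-stimulus window) to give ΔF/F, then smoothed with a 9×9-pixel mean
filter. Significance is ΔF/F > 7 × baseline SD.

Choices the upstream description leaves open, and how they are resolved
here:

* **Baseline window** — all frames before stimulus onset. It is the maximal
  noise sample and needs no extra parameter. The per-pixel SD estimated from
  *n* baseline frames has relative error ≈ 1/√(2n); with a 7×SD threshold
  over ~2×10⁴ pixels, fewer than ~15 baseline frames produces occasional
  spurious suprathreshold pixels, so the generator defaults to a 100-ms
  (25-frame) pre-stimulus epoch.
* **Filter shape** — a 9×9 uniform (box) mean; only the footprint is
  specified upstream.
* **Per-pixel vs pooled SD** — per-pixel SD for maps and areas; the SD of
  the ROI-mean trace for temporal metrics. Both readings appear in the
  reported quantities, so both are implemented.
* **ROI** — a circle of radius 3 px (~0.1 mm) centred on the centroid of
  the suprathreshold pixels in the earliest significant frame. When several
  regions respond simultaneously an optional region polygon restricts the
  centroid (the designated-region rule).
* **Latency / time to peak** — first ROI-trace frame above 7×SD after
  stimulus onset, and the argmax frame, both in ms from onset. Traces that
  are never significant return a flagged "undefined" result rather than
  numbers.
* **Response area** — suprathreshold pixel count in the peak frame times the
  pixel area (6.4/184 mm × 4.8/124 mm for the sensor geometry used). All
  suprathreshold pixels count; a largest-connected-component flag exists but
  is off by default.
* **Cross-animal superposition** — rigid (rotation + translation) alignment:
  the rhinal-fissure direction fixes rotation, the middle-cerebral-artery
  point fixes translation. Two landmarks cannot (and should not) fix scale
  or shear. Maps lacking a landmark are excluded with a warning. The summary
  contour encloses pixels suprathreshold in ≥ ⌈N/2⌉ animals.

## Two-photon Ca²⁺ analysis (`ca_micro`)

Cells are classified from two fluorophores: SR-101-positive somata are
astrocytes (excluded from response analysis); Venus-positive, SR-101-negative
somata are GABAergic (inhibitory) neurons; double-negative somata are
glutamatergic (excitatory) neurons. Positivity is a threshold on the
per-soma mean intensity — Otsu's threshold on the channel image with a
robust background floor (median + 5 MAD) guarding the label-free case;
manual thresholds can override. Somata intersecting a fibre mask are
excluded ("neuropil overlap"), mirroring the practice of dropping
contaminated cells.

ΔF/F is computed per pixel against the pre-stimulus mean, filtered with the
9×9 spatial and 3×3×3 spatiotemporal mean filters, and averaged over each
soma disk (native 10-ms sampling). A cell *responds* when the run of
consecutive samples above 2 × baseline SD **that contains the post-stimulus
maximum** lasts ≥ 100 ms. "The run containing the maximum" is the
deterministic reading of a criterion phrased around the time to peak.

Kinetics (responders only): time to peak = onset→argmax; latency = the
sample after the last sub-threshold sample found walking backward from the
peak; 20–80 % rise time = linear-interpolated crossings of 0.2 and 0.8 of
the peak amplitude on the rising phase (a linear ramp spanning 100 ms gives
60 ms; a saturating exponential gives τ·ln 4); duration = length of the
suprathreshold run. Baseline SD is computed after filtering, since filtering
precedes analysis.

## LSPS excitation mapping (`lsps_map`)

The stimulation lattice defaults to 62.5-µm spacing over 750 µm × 1750 µm —
12 × 28 = 336 sites, the arithmetically consistent triple among the
reported grid figures; all three numbers are parameters. Stimulation order
is a random permutation with consecutive sites ≥ 120 µm apart, built by
greedy randomised construction with restarts (an unsatisfiable constraint,
e.g. two sites 62.5 µm apart, raises).

Per-site sweeps are classified by onset latency, where onset is the first
sample opening a ≥ 0.5-ms run above 3 × baseline SD (the run requirement
rejects single-sample noise excursions; both factors are configurable):

* latency < 5 ms **and** a long decay → **direct** (glutamate acting on the
  recorded cell), excluded from maps as a marker, not a charge;
* latency in [5, 70) ms → **synaptic**; the half-open right edge is a
  convention, and exactly 5 ms counts synaptic since only < 5 ms is direct;
* otherwise **none**. "Long decay" is quantified as > 50 % of
  suprathreshold samples falling beyond 70 ms — a number the upstream
  description does not give; the generator's direct events (τ_decay
  100 ms) and synaptic events (τ_decay 8 ms) sit far on either side of it.

Charge transfer is |∫(I − baseline) dt| over 5–70 ms, trapezoidal, in fC
(pA·ms). Maps are aligned by a rigid change of frame: depth = perpendicular
distance to the pial line (positive into the tissue), lateral = along-pia
distance from the soma's foot point. Cohort maps are averaged per grid cell
(excluded sites omitted from their cell's mean) and profiled as mean charge
in 250-µm depth slabs within a 500-µm-wide strip centred on the soma axis —
the 2-column × 8-row reading of a "16 panels, 250 × 250 µm" strip; the
500–750 and 750–1000 µm slabs carry the headline comparison.

## mIPSC analysis (`mini_events`)

Events are outward (positive) at the +10 mV holding potential. Detection is
a sliding least-squares fit of a unit-peak biexponential template
(τ_rise 1 ms, τ_decay 10 ms by default): the "scale trace"
corr(x, k)/Σk² equals the event amplitude at the event-onset lag. Candidate
onsets are local maxima of that scale trace; a greedy matching pursuit
accepts the largest remaining candidate above threshold, subtracts its
template autocorrelation, and repeats, so the slow tail of one event cannot
spawn spurious detections. Two events closer than the minimum interval
(5 ms default) present a single scale maximum and are reported as one event
— the merging rule. Accepted amplitudes are re-fit jointly (Gram system of
template overlaps), which makes noiseless recovery exact even for
overlapping events; amplitude is therefore the template-fit
baseline-to-peak value. A plain amplitude-threshold mode is kept as a
fallback.

No detection method or threshold is specified upstream; these are free
design choices. The threshold default is 4 × a robust (MAD-based) noise SD
of the scale trace: matched-filter output on event-free noise up-crosses a
3×SD level several times per second, incompatible with the target
false-positive rate of < 0.1 events/s, while 4×SD achieves it with margin
(measured ≈ 0.03 events/s) at no measurable cost in hit rate at the
14.6-pA/2-pA-noise operating point. Interevent interval is the mean of
successive onset differences; it is flagged undefined below two events.

## Statistics (`group_stats`)

* χ² on 2×2 responder tables **always** applies the Yates continuity
  correction, Σ max(|O−E|−0.5, 0)²/E with df = 1 — verified to reproduce
  all four published responder-table statistics (17.933, 20.578, 1.410,
  0.000256) to three decimals, which is itself evidence the original
  analysis used the correction. The clamp at zero makes equal-proportion
  tables give exactly 0.
* Mann–Whitney U is reported as min(U₁, U₂) with midrank ties; p is exact
  (enumeration) when both n ≤ 8 and the pooled sample is tie-free,
  otherwise the normal approximation with tie and continuity corrections.
* Two-sample KS uses the ECDF sup-distance; scipy's method selection
  (exact for small n, asymptotic for large) supplies p.
* Student's t (paired or pooled-variance unpaired) flags zero-variance
  inputs (t = 0 for identical pairs, |t| = ∞ for a constant shift) instead
  of raising.
* Test selection gates on Shapiro–Wilk (both samples) and Brown–Forsythe
  (Levene, median-centred) at α = 0.05: pass all three → t, else
  Mann–Whitney; n < 3 forces Mann–Whitney with a note. The audit trail
  (gate p-values, chosen path) travels in the result object.
* The Bonferroni threshold is base/k rounded to 3 decimals (0.05/3 →
  0.017).

## Synthetic data (`synthetic_data`)

What each generator emulates, and deliberately does not:

* **VSD** — response model A·g(t)·exp(−r²/2σ(t)²) with σ(t) growing
  linearly from onset (the simplest concentric-propagation shape), a linear
  per-frame bleaching decay, and additive Gaussian pixel noise. Defaults:
  peak ΔF/F 0.229, onset 16 ms (4 frames at 250 Hz), σ₀ 500 µm, spread
  10 µm/ms, bleach 5×10⁻⁴/frame, noise SD 0.05·F₀, on the 184×124 sensor.
  Blank trials carry bleach + noise only. No optics (PSF, scattering),
  haemodynamics or movement artefacts.
* **Ca²⁺** — disk somata with class-tagged fluorophore snapshots (Venus,
  SR-101) and a green movie whose responder cells follow a
  difference-of-exponentials transient (τ_rise 50 ms, τ_decay 300 ms,
  onset 170 ms, amplitude 2.2 — chosen to land the kinetic metrics in the
  reported ranges). The movie is emitted trial-averaged, with noise scaled
  by 1/√n_trials (20 by default). Somata are packed with a gap beyond the
  smoothing footprint so one cell's transient cannot bleed into a
  neighbour's ROI; in vivo that contamination exists and is handled by
  exclusion, not simulated. Responder flags are Bernoulli draws; astrocytes
  never respond.
* **LSPS** — one sweep per site; synaptic event amplitudes are normalised so
  the trapezoidal integral of the noiseless sweep over the 5–70 ms window
  equals the planted charge, making noiseless charge recovery exact by
  construction (the planted quantity *is* the windowed charge). Direct-zone
  sites add a < 5-ms-latency, 100-ms-decay component. Sweeps are 300 ms so
  the direct decay criterion is observable.
* **mIPSC** — Poisson event times (exponential gaps) snapped to the sample
  grid, truncated-normal amplitudes, biexponential shapes, Gaussian noise.
  Defaults: rate 1/0.17 Hz, amplitude 14.6 ± 3 pA, noise 2 pA. Fewer than
  ~5 expected events warns (unstable statistics).

Only group-level means are reported upstream; all generator *variances* are
free parameters and are documented as such. Passing recovery tests therefore
shows the pipeline is a consistent estimator of its own generative model at
realistic signal-to-noise — not that the model captures every artefact of
real recordings.

## Problem sizes and tolerances in the test suite

Recovery checks run at sizes chosen to exercise the full pipeline while
staying desk-scale: VSD recovery uses 16 stimulated + 16 blank trials per
seed (the experiment averaged 32) over 20 seeds, 75-frame movies; the
responder-fraction check scores 800 neurons across 32 fields of 144×256 px
(the experimental field is 512×144; multiple fields stand in for multiple
animals); LSPS uses 20 seeds of the full 336-site grid; mIPSC statistics
use 120-s traces over 20 seeds. Tolerances: VSD peak within 10 % and
latency within one frame (4 ms); recovered responder fraction within the
binomial 95 % CI of the planted fraction; depth-bin charge within 15 %;
IEI and amplitude within 15 %. Determinism: every generator is a pure
function of its seed (NumPy `default_rng`), and property tests run
derandomised.

## Known limitations

* The landmark alignment warps binary masks with nearest-neighbour
  sampling; rasterisation nibbles mask edges under rotation (exact only for
  integer translations). Sub-pixel mask interpolation was deliberately
  avoided to keep overlap counts integral.
* The direct/synaptic classifier assigns "none" to a < 5-ms-onset event
  without a long decay; such events fall in neither defined category and
  are treated as non-responses rather than guessed at.
* Template-matching detection assumes a single event shape; strongly
  heterogeneous kinetics would bias amplitude estimates (the fallback
  amplitude mode does not share this assumption).
* Published peak-amplitude units for the Ca²⁺ responses are not stated
  upstream; the package reports ΔF/F on the generator's scale and makes no
  unit claim.
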