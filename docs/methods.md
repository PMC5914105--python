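# Methods

## Background and scope

Fermented *Cordyceps sinensis* products (Jinshuibao capsules, Jinshuibao
tablets, Bailing capsules) are quality-controlled through HPLC fingerprints of
their water-soluble nucleosides.  `cordyqc` implements the combined evaluation
procedure used for these products:

1. **Fingerprint similarity analysis (SA)** — each sample's standardized
   chromatogram is scored against a mean reference chromatogram by the cosine
   of the vector angle and the Pearson correlation coefficient.
2. **Hierarchical cluster analysis (HCA)** — samples are grouped
   agglomeratively from cosine distances with between-groups (unweighted
   average, UPGMA) linkage.
3. **Quantification** — the five named nucleosides (uracil, uridine, adenine,
   guanosine, adenosine) are quantified both by the external standard method
   (ESM, one calibration line per analyte) and by single-marker QAMS:
   with adenosine as internal reference *s*, each analyte *i* carries a
   relative correction factor

       F_i/s = (C_i / C_s) · (A_s / A_i)

   measured on standard solutions, and sample contents follow from
   C_i = F_i/s · (A_i / A_s) · C_s, m_i = C_i · V.  Method agreement is scored
   by the cosine between the QAMS and ESM content vectors across samples.

The raw chromatograms behind the published reference tables were never
deposited, so the package pairs the analysis code with a synthetic
chromatogram generator that reproduces the study design with known ground
truth.  The packaged TSV fixtures under `cordyqc/data/` keep the published
reference values (calibration lines, RCF robustness tables, the 30-sample
QAMS/ESM comparison) for cross-checking the statistics.

## Synthetic data generator

The generator emulates a 30-sample study: 10 samples each of three product
classes on a 0–30 min grid sampled every 0.005 min, carrying 10 common peaks
of which peaks 4/7/8/9/10 are the named nucleosides.

**Peak shape.** Peaks are Gaussian.  No peak-shape data are published for
these separations, and the Gaussian choice makes every peak area available in
closed form (`area = height · σ · √2π`), which is what the integration and
recovery tests are anchored to.  Peak width grows mildly with retention time
(σ = 0.045 + 0.0035·t min), as on a shallow-gradient separation.

**Detector response.** The response factor (area per µg/mL) of each named
nucleoside is the slope of its published area calibration line (41.219,
23.568, 62.462, 22.077, 28.112 for uracil/uridine/adenine/guanosine/
adenosine).  A direct consequence is that the true RCFs of the generator are
the slope ratios k_adenosine/k_i ≈ 0.68, 1.19, 0.45, 1.27 — inside the range
of the published robustness tables — and every QAMS quantity is recoverable
from first principles.  Unknown peaks use nominal response factors (24–30).

**Class profiles.** Mean contents (mg/g) follow the published per-class
orderings and magnitudes: both Jinshuibao-like classes order
adenosine > uridine > guanosine > adenine > uracil, the Bailing-like class
orders adenosine > guanosine > uridine > uracil > adenine.  The Bailing-like
class suppresses the unknown common peaks at 5.3, 13.5 and 20.0 min (the
three "almost no absorption" peaks), and the tablet-like class has the lowest
content of the 3.0 min peak.

**Between-sample variability** (total CV 0.15 by default) is decomposed into
a dominant shared batch-potency factor and a small independent per-analyte
factor (31.2% of the total CV, i.e. ≈0.047).  Commercial batches of a
standardized preparation vary mostly in overall potency while their
composition ratios stay tight; this decomposition keeps the per-class content
orderings valid in every sample, which is what the class-profile contract
promises.  Both factors are lognormal, so contents stay positive.

**Nuisance processes.** White detector noise (SD 1.0 unit), a small baseline
drift (linear ramp + slow sine, amplitude 2 units — small against the
smallest quantified peak so LOD/LOQ remain meaningful), and run-to-run
retention jitter: a shared multiplicative warp (SD 0.3%) plus per-peak noise
(SD 0.01 min).  The warp is exactly the distortion that the retention-time
normalization step must undo.

**Units.** Contents in mg/g convert to extract concentrations via the 1.00 g
/ 50 mL preparation: C (µg/mL) = content · 1000 / 50.

**What the generator does not emulate:** gradient solvent effects, asymmetric
(tailing) peak shapes, co-eluting interferents, detector saturation, DAD
spectra and peak-purity indices.  Passing tests therefore demonstrate the
correctness of the *analysis chain* under the stated noise model, not the
behavior of any particular instrument.

## Numerical choices

* **Noise estimate**: median absolute deviation (scaled by 1.4826) of the
  linearly detrended trace in a peak-free window (default 0.5–2.0 min, before
  the first common peak).  The MAD is robust to stray spikes; linear
  detrending tolerates the slow baseline drift.
* **Peak detection**: prominence-filtered local maxima on a lightly smoothed
  trace (11-point moving average), apex refined on the raw trace, detection
  threshold `min_snr × noise` with `min_snr = 10` by default.
* **Peak bounds**: flanking valleys of the smoothed trace, capped at ±4
  estimated σ from the apex (σ from the half-prominence width).  A ±4σ window
  still contains 99.994% of a Gaussian peak.
* **Integration baseline**: chord through two robust anchors, each the median
  intensity of a 0.5 min window extending *outward* from a bound, positioned
  at the window centre.  Outward windows stay clear of the peak; anchoring the
  chord at window centres keeps the baseline unbiased under locally linear
  drift.  Raw valley intensities are not used directly — they are biased low
  by noise, which would violate the 2% area-recovery contract at SNR 50.
* **Common-peak matching**: nearest expected retention time within a relative
  tolerance (default 2%; no tolerance is published).  Closest candidate wins;
  exact ties go to the larger area and are logged.  A sample missing the
  internal-standard peak is flagged and excluded from RRT/RPA.
* **Retention normalization**: piecewise-linear warp through the matched
  (observed apex → expected time) anchors, extrapolated with the edge
  segments' slopes, intensities resampled by linear interpolation.
* **Calibration**: ordinary least squares, R² as the squared Pearson
  correlation; no weighting (the published fits are plain linear).  LOD/LOQ
  use signal-to-noise 3:1 and 10:1 through an auxiliary *height* calibration,
  since S/N is a height ratio; whether the published limits used height or
  area is not stated.
* **RSD** uses the sample (n−1) standard deviation.  This choice reproduces
  the published per-injection-volume RSDs from their own per-volume values;
  the population (n) denominator does not.
* **Clustering**: "between-groups linkage" is implemented as unweighted
  average linkage over all cross-pair leaf distances (the usual reading of
  that method name in statistical packages).  Ties in the minimal-pair search
  break lexicographically on (smaller cluster id, larger cluster id) for
  reproducibility.  Average linkage does not guarantee monotone merge
  heights; inversions are recorded on the tree, never hidden.
* **QAMS batch factor**: the F applied in quantification is the grand mean
  across all robustness conditions; per-run factors are available through the
  library API.  Injection volume scales analyte and reference areas jointly,
  so it appears only as a robustness axis, never in the content formula.
* **Agreement** reports the cosine (the published criterion) and the Pearson
  correlation (the published table footer) side by side.

## Reference-table quirks

Three internal inconsistencies of the published reference values are handled
explicitly rather than silently:

* The per-injection-volume RSDs reproduce from the printed per-volume RCFs
  only when the last printed digit is *truncated* (computed 0.834, 1.052,
  1.097, 1.156 vs printed 0.83, 1.05, 1.09, 1.15); tests assert agreement to
  one unit in the last printed digit.
* The printed RSDs of the instrument/column, flow-rate and temperature tables
  are not reproducible from their own printed values under either SD
  denominator; only the grand means are checked for those tables.  The
  flow-rate table's printed uridine mean (0.194) is treated as a misprint of
  1.194 and not checked.
* Two uridine rows of the 30-sample comparison (samples 5 and 9, ESM 1.189
  and 1.192) break the otherwise constant QAMS/ESM ratio; uridine is
  therefore excluded from the agreement checks, while uracil, adenine and
  guanosine all give cosines ≥ 0.999.

## Problem sizes and defaults

The default study is the full published design: 3 × 10 samples, 10 common
peaks, 6,001 grid points per trace; calibration uses six levels spanning each
analyte's linear range; robustness uses 7 injection volumes, 6 instrument ×
column combinations, 3 flow rates and 3 temperatures with n = 3 replicate
runs per condition.  A complete pipeline run (simulation included) takes on
the order of seconds, and all randomness flows from one seed through named
substreams, so a config + seed pair reproduces the output bundle byte for
byte.

## Known limitations

* No deconvolution of overlapping peaks — the simulated design keeps common
  peaks baseline-separated, as the real separation does.
* Quantification assumes the analyte peak is correctly matched; a mismatch
  within tolerance would be quantified, not rejected.
* The class-level "similarity value" is computed as the mean per-sample
  cosine against the class reference; the published definition of that scalar
  is not stated, so this is a documented interpretation.
* No uncertainty propagation beyond RSD summaries; no weighted or nonlinear
  calibration; no multi-marker QAMS variants.
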