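# Methods

## Scope

`deciquant` reimplements an automated, patch-based quantification of
NRF2/KEAP1 protein expression in bright-field immunohistochemistry (IHC)
scans of decidua basalis, stratified by local trophoblast density, together
with the statistical layer used for group comparisons and a gene-set
enrichment stage for NRF2-regulated transcriptional programs.  Because the
original clinical slides and the microarray accession are not distributable,
every stage is exercised on synthetic phantoms with exact ground truth; the
phantom generators are first-class, tested package code.

## Slide phantom model

A phantom describes one tissue block sampled by three "serial sections"
(CK7, NRF2, KEAP1) that share the spatial layout and differ only in stain
strength and a small rigid offset, as parallel 3 µm sections scanned on the
same stage would.

* **Stroma.** A smooth random blob (thresholded Gaussian field, synthesized
  at 1/8 resolution and upsampled) covers ~75 % of the canvas, with mild
  occupancy texture in [0.7, 1].  It models maternal decidual tissue.
* **Trophoblasts.** Interstitial clusters are disks (default radius 70 px)
  whose interior is fibrinoid (stroma-free); clustered cells (radius
  9–12 px) sit on a jittered triangular lattice with a guaranteed pairwise
  gap.  In the default `confluent` style the inter-cell space inside a
  cluster is filled by CK7-positive cytoplasm, giving genuinely dark,
  dense, high-trophoblast areas; the `discrete` style leaves cells as
  separate disks so that connected-component counting has an exact truth.
  Single cells (giant-cell-like, radius 13–17 px) lie in the stroma and
  produce the low-density band.
* **Excluded structures.** Two elliptical polygons (vessel/gland) render as
  dense counterstained tissue and are annotated as ground-truth exclusions.
* **Color model.** Lambert–Beer with the standard H-DAB reference
  absorbance vectors: per-pixel RGB = 255·10^−(c_H·v_H + c_DAB·v_DAB).
  Gray level is therefore strictly decreasing in stain strength (the
  inverse-intensity convention: darker = more protein), and the model is
  exactly invertible by color deconvolution.  Noise is additive Gaussian in
  absorbance (default SD 0.01 OD), which preserves monotonicity at zero
  noise.
* **Vignetting.** One radial-quadratic multiplicative shading field per
  section, gain 1 at a jittered optical center, minimum 1 − strength
  (default 0.2).  The field is shared by all tiles of a section because it
  originates in the optics; that is what makes a single flat-field
  estimate per scan meaningful.
* **Defaults as study conditions.** Canvas 1504×1504 px at 0.5 µm/px,
  4 clusters × 12 cells + 10 singles, DAB strengths CK7 (0.90, 0.02),
  NRF2 (0.65, 0.15), KEAP1 (0.60, 0.12) for (trophoblast, maternal), and
  section offsets within ±50 px.  The marker strengths were chosen so that
  the three density bands differ by ≥20 gray levels in ground truth, which
  is the premise of the end-to-end ordering check.  Pixel size is an
  explicit free parameter throughout; the patch grid is defined in pixels
  (default 50×50) and physical areas are derived from the declared µm/px.

Everything the phantom does not attempt: nuclear morphology,
multinucleated giant-cell texture, scanner color profiles, stain fading,
tissue folds.  Passing tests therefore show the pipeline's arithmetic and
geometry are right under the stated color model — not that segmentation
thresholds are optimal for any particular scanner or staining protocol.

## Pipeline

1. **Flat-field correction.** Per channel, the per-pixel median over
   background-classified pixels (luma > 150) of all tiles is fitted with a
   2-D quadratic surface, normalized to mean gain 1, and divided out with
   global mean brightness preserved.  If almost no background exists the
   identity field is returned with a warning.
2. **Stitching.** Tiles are placed at their declared grid positions
   (scanner stages report positions; no correlation-based placement), with
   linear feathering across overlaps.  At zero overlap the mosaic is the
   exact concatenation, which gives a pixel-exact cut→stitch round trip.
3. **Tissue and ROI.** Tissue is luma < 230 (no smoothing by default; a
   sigma is available for noisier data), with small holes filled and specks
   removed — larger unstained lakes such as fibrinoid remain background.
   Manually drawn exclusion polygons (WKT in a CSV) are rasterized and
   subtracted; tissue area in mm² counts tissue pixels only.
4. **Stain separation and CK7 mask.** Color deconvolution with the fixed
   H-DAB matrix; DAB optical density ≥ 0.15 with objects < 20 px removed
   defines CK7 positivity.  An OD threshold on the deconvolved DAB channel
   is robust to counterstain variation, unlike raw-color thresholds.
5. **Patch grid.** 50×50 px patches; trophoblast fraction = CK7⁺ pixels /
   included tissue pixels of the patch (tissue-denominator choice keeps
   edge patches undiluted; the alternative is one flag away).  Bands:
   0 → maternal, (0, 0.5] → low, (0.5, 1] → high — a fraction of exactly
   0.5 is "low" because the high band is strictly >50 %.
6. **Counting.** Connected components of the CK7 mask after a light
   opening; components below 100 px are debris, components above 1200 px
   are split by the median single-component area.  Density = count / mm².
   These size defaults bracket the phantom's cell areas (≈250–900 px);
   they are parameters, not constants, for real data.
7. **Registration.** Translation-only (serial sections on one stage),
   maximizing tissue-mask cross-correlation, coarse-to-fine (FFT at 4×
   decimation, direct refinement at 2× and 1×), search radius 100 px.
   Below a score floor of 0.2 the identity is returned with a warning.
8. **Intensity.** The marker scan is moved into the CK7 frame, converted
   to Rec. 601 luma (the convention of the original analysis environment),
   and each included patch's mean gray over included tissue pixels is
   computed.  Band means weight each patch equally; the overall mean
   averages all included patches.  Empty bands are NaN, never 0.  The
   gray scale is never inverted: lower gray ⇒ higher expression.

## Statistics

* **ROUT-style outliers:** median/MAD location-scale, t-like residuals
  (df n−1), Benjamini–Hochberg FDR at Q (default 0.01).  This follows the
  published robust-fit-plus-FDR idea on the constant model; it is not a
  bit-level clone of any proprietary implementation.  Zero-spread samples
  flag nothing; n ≥ 5 required.
* **Kruskal–Wallis + Dunn:** tie-corrected H; χ² p by default, exhaustive
  label-permutation p for total n ≤ 9 (`method="exact"`).  Dunn z uses the
  tie-corrected rank variance; pairwise p reported raw and Bonferroni
  adjusted (the classical Dunn adjustment; configurable) — the adjustment
  choice is a documented default because the source analyses name only
  "Dunn's test".
* **One-way ANOVA + Tukey HSD** for trophoblast amount/density.
* **Site-adjusted linear model** (`value ~ group + site`) for maternal-band
  and overall intensities: group contrasts against the normal-pregnancy
  reference, estimated marginal means averaging site levels with equal
  weight.  A constant site is dropped; rank deficiency raises an error
  naming the collinear columns.
* **Linear mixed model** for the trophoblast-containing bands (low, high):
  fixed effects group, band, group×band, site; subject random intercept;
  REML; Wald z for contrasts; group×band estimated means ± SEM.  When the
  random intercept is inestimable the model falls back to the
  fixed-effects-only fit with a warning.  α = 0.05 throughout.

## Gene-set enrichment

Genes are ranked by signal-to-noise ratio (difference of class means over
the sum of class SDs, denominator floored at 10⁻³; Welch t available).
The running sum at rank k is D(k) = Σ_{hits≤k} |m|^p / Σ_hits |m|^p − k/N,
which starts and ends at zero; ES is the signed maximum deviation and with
p = 0 reduces to the classical KS deviation of the set's ranks from
uniformity (the closed form for a single-gene set at rank 1 is 1 − 1/N).
Significance uses phenotype-label permutation (preserves inter-gene
correlation; 100 permutations by default), NES = ES / mean |same-signed
permutation ES|, and p = (r+1)/(m+1) over same-signed permutations — the
add-one convention both floors p at 1/(n+1) and keeps the null calibrated.
Five named NRF2 functional gene sets plus a deduplicated pooled row give
the tabular output; set membership is configuration (GMT), not code.
Per-set permutation streams are derived from the set name so results do
not depend on the order sets are supplied.

## Verification scale

The acceptance checks run 100 phantoms of 1504×1504 px (16 tiles of
376×376) with both markers; band-ordering accuracy is evaluated on
confluent-style phantoms (their three bands are all populated and
separated by ≥20 true gray levels), density recovery on discrete-style
phantoms whose cells never touch, and offset recovery (±50 px injected)
on all.  `scripts/acceptance.py` re-runs the same measurements at a
somewhat smaller replicate count (24 + 12 phantoms, 500 null simulations,
100 null enrichment datasets) and writes the observed rates as JSON.

## Known limitations

* The phantom's color model and the pipeline's deconvolution share the same
  H-DAB reference vectors, so stain-vector misspecification — a real
  failure mode on scanners with different chromogen batches — is not
  exercised.
* Registration is translation-only by construction; rotational or
  non-rigid section distortion is out of scope.
* Cluster splitting by median component area is a fallback, not a nuclear
  segmentation; confluent trophoblast sheets are not countable and density
  should only be interpreted for tissues with separable cells.
* The patch-fraction denominator (tissue pixels vs whole patch) and the
  intensity denominator are documented choices; the original description
  leaves both open.
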