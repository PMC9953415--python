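# Methods

## The measurement

An X-gal-stained culture is imaged twice per field of view: a brightfield
RGB image carrying the blue SA-β-gal reaction product, and a DAPI
fluorescence image of the nuclei. The two images are assumed co-registered
(same stage position); no alignment is attempted.

**Signal module.** A pixel is stain-positive iff each of its channels lies
in an inclusive `[min, max]` range (conjunction over R, G, B). The signal
of one image is the integrated density

    ID = Σ over positive pixels of (255 − (R+G+B)/3),

i.e. the sum of inverted-grayscale intensities, so darker (more stained)
pixels score higher. On unscaled 8-bit images this equals the raw
integrated density; `mean_gray = ID / area` is reported alongside. There
is no background subtraction, colour deconvolution, hole filling or
minimum-region filtering on the signal mask: the measurement is a plain
sum over the thresholded selection, which keeps the additivity and
monotonicity properties exact.

Grayscale conversion is the *unweighted* channel mean, computed in real
arithmetic (no integer truncation). ITU-R BT.601 luminance weights are
available (`luminance=True`) but off by default: the unweighted mean is
the common default of general-purpose image-analysis platforms and the
choice must simply be fixed and documented, since the two differ
systematically on blue-heavy stain. Sums use `math.fsum`, so the ID is
correctly rounded and independent of mask traversal order — "exact
equality" in the tests is well-defined.

**Threshold semantics.** Stained pixels on a light background are *darker*
in red and green while retaining blue, so the informative bounds are upper
bounds on R and G. Range semantics (rather than one-sided cuts) can
express either a raw-channel or an inverted-representation reading of
"above the colour threshold"; the ambiguity is noted, not resolved — the
calibration procedure makes the choice empirical.

**Nuclei module.** The DAPI image is binarized (Otsu on the ROI histogram
by default, or a fixed cutoff; foreground strictly above the threshold),
holes are filled, objects under `min_area_px` are removed, and 4-connected
components are labeled in raster-scan order. With `split_touching=True`,
each component is split by a distance-transform watershed seeded at local
maxima separated by at least `2·√(min_area/π)` — twice the radius of the
smallest admissible nucleus. Peaks are found *within each component
independently*: a global minimum-distance suppression could delete the
only marker of a small nucleus adjacent to a large one and silently drop
it from the count. Watershed fragments below the area floor are discarded.
A flat image under Otsu yields count 0 rather than an error. Border
nuclei are kept unless `exclude_border=True`.

**Per-cell normalization.** `id_per_cell = ID / (nuclei_count ·
cells_per_nucleus)`. A field with zero nuclei has no defined value and is
rejected with a reason — never silently zeroed, which would bias group
means downward. `cells_per_nucleus` (default 1.0) is the documented manual
correction for multinucleated cultures, where counting nuclei over-counts
cells.

## Calibration

The threshold is set on experimental data, not theory: control images
(low-passage, sub-confluent, background SA-β-gal only) and senescent or
positive-control images are measured under each candidate threshold, and a
candidate passes if the control group's mean ID is between 0 and 10% of
the senescent group's. The 10% band was chosen for a doxorubicin/H₂O₂
VSMC senescence model and may need revision for other systems, so it is a
parameter (`max_control_ratio`, default 0.10). The ratio is computed on
ID by default (`metric="area"` is available); a zero senescent mean flags
failure regardless of the control value.

The default grid sweeps a common R/G upper bound from 255 down to 0 in
steps of 5 (minima 0, blue max 255) — 52 candidates. Among passing
candidates the one with the **largest senescent mean ID** wins (maximal
signal retention), with ties broken to the lexicographically smallest
`(r_max, g_max)`. The constraint comes from the method; the retention
objective and tie-break are this package's design choices, made so
calibration is deterministic and reproducible. If nothing passes, a
`CalibrationError` reports the best achieved ratio. One threshold serves
the whole experiment: per-image adaptive thresholds are deliberately out
of scope, matching the requirement that all samples be stained and imaged
under identical conditions.

## Batch processing and statistics

Fields are processed in lexicographic field-id order, so results are
independent of directory-listing order. Per-field failures (unreadable
file, zero nuclei) reject that field with a recorded reason; the batch
continues. Supervision is headless: a magenta QC overlay
(`<field>_overlay.png`) and a 16-bit label map are written per field, and
in interactive mode the operator accepts/rejects each field at a terminal
prompt; decisions and timestamps land in `qc_log.txt`. Rejected fields
never enter statistics.

Group comparison is the two-tailed **equal-variance Student's t test**
(Welch behind a flag, never default), SD with the n−1 denominator, stars
at p ≤ 0.05 / 0.01 / 0.001; SEM is exposed on the results object for
figure captions, SD being primary. Zero pooled variance and groups of
fewer than two accepted fields raise errors (not infinities). The
experimental unit defaults to the field of view; records may carry a
`replicate` label, and `per_replicate=True` first averages fields within
each biological replicate and tests replicate means — the
publication-grade aggregation when fields within a dish are not
independent. The results CSV has the fixed 8-column schema
(`field_id, group, area_px, integrated_density, mean_gray, nuclei_count,
id_per_cell, qc_status`), comma-delimited, `.` decimal, UTF-8, numbers at
10 significant digits so a write→read round trip is lossless at that
precision.

## Synthetic data

The generator emulates the *structure* of the assay, not stain optics.
Cells are non-overlapping ellipses (rejection sampling, bounding-circle
separation with a 4 px margin) on a near-white background (250, 250,
248); a cell with stain intensity `s ∈ [0, 1]` has cytoplasm colour

    R = 250 − 190·s,  G = 250 − 120·s,  B = 250 − 20·s,

a linear blue-teal darkening ramp chosen so the true ID is exactly
computable. Per-cell intensities are drawn from a normal (mean per group,
SD default 0.05–0.02, clipped to [0, 1]). Nuclei are disks of intensity
200 on background 10 at the cell centres (on a small ring for
multinucleated mode), radius 5–8 px inside cells of radius 12–20 px.
Gaussian sensor noise (SD 2.0 grey levels) is added **after** ground truth
is computed on the quantized noise-free image, so oracle comparisons are
exact. Geometry is sampled before stain intensities, so two specs
differing only in stain share identical geometry at the same seed — the
basis of the monotonicity tests.

Default frame size is 320×320 px with 8 cells: a desk-scale stand-in for
a 2560×1920 field at 20× of a sub-confluent culture, preserving the
cell-to-frame area fraction and per-field count statistics while keeping
50-seed test loops cheap. Presets: `two_group` (control mean stain 0.05
vs senescent 0.8) and `timecourse` (control 0.05, early induction 0.5,
late 0.8, the late group with slightly enlarged nuclei mirroring the
senescence phenotype). Per-field seeds are `master_seed + global field
index`, so an experiment reproduces byte-identically.

What the generator does **not** emulate: illumination gradients, chromatic
aberration, staining artifacts (bubbles, crystals, debris), partial-volume
edges, textured cytoplasm, overlapping cells, nucleus-intensity variation.
Passing tests therefore demonstrate the *correctness of the computation*
(thresholding, integration, counting, normalization, statistics) and the
method's behaviour under controlled contrast and noise — not robustness to
real-world acquisition artifacts, which the supervised QC step exists to
catch.

## Numerical and design choices

- 16-bit inputs are converted by linear division by 257 (65535 → 255), a
  deterministic rescale with no data-dependent windowing.
- Coordinates are (row, col), 0-based, origin top-left; ROIs and bounding
  boxes are half-open (inclusive lower, exclusive upper edge).
- Labeling uses 4-connectivity; labels are renumbered 1..count by raster
  order of first appearance, making label maps deterministic.
- Pairing is by filename stem plus configurable suffixes (defaults `_BF`,
  `_DAPI`); unmatched files go to an `unpaired.txt` report. The group
  label defaults to the stem up to its last underscore unless a glob
  `group_map` overrides it.
- Empty selections measure (0, 0, 0); empty record lists, zero-variance
  groups, and zero-nuclei normalizations are errors, not sentinel values.

## Limitations

- Saturated stain compresses the upper end of the ID scale; staining time
  should be tuned to avoid saturation, especially in positive controls.
- The tool counts nuclei, not cells: multinucleated cultures need the
  `cells_per_nucleus` correction or manual counting.
- One calibration per experiment assumes simultaneous staining and a
  single imaging session; cross-batch comparisons are not supported.
- Dense cultures are handled (no per-cell perimeter is needed), but
  heavily overlapping monolayers violate the generator's assumptions and
  the watershed's marker geometry.
- No GUI; supervision is overlay files plus a terminal confirm.
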