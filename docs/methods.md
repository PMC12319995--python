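# Methods

`wmfunnet` maps functional networks (FNs) in the white matter (WM) and
gray matter (GM) of resting-state fMRI data by clustering voxels on their
functional-connectivity (FC) profiles. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic phantoms do and do not demonstrate.

## Motion quality control

Rigid-body realignment parameters (3 translations in mm, 3 rotations in
radians, one row per volume) are summarised per volume as framewise
displacement:

    FD[t] = |Δtx| + |Δty| + |Δtz| + r · (|Δpitch| + |Δroll| + |Δyaw|),

with backward differences, FD[0] = 0, and rotations converted to arc
length on a sphere of radius r = 50 mm. Participants are excluded when
any of three independent rules fires (all comparisons strictly `>`):
max FD > 5 mm, mean FD > 0.2 mm, or more than 20 % of volumes with
FD > 0.2 mm. All defaults are user-adjustable; `exclusion_grid` tabulates
rejected counts over a threshold grid in place of an interactive explorer.
Motion rows belonging to discarded initial volumes are dropped before FD
is computed against the analysed volumes, so QC and analysis stay aligned.
A DVARS-like index (variance across in-mask voxels of the difference of
consecutive volumes) and a correlation report among raw global mean,
motion, nuisance regressors and cleaned global mean complete the QC set.

## Denoising chain

Order: discard initial volumes (default 10) → nuisance regression →
band-pass → smoothing. The nuisance design always carries an intercept
and combines the Friston 24-parameter motion expansion (parameters,
squares, backward-difference derivatives with first row 0, squared
derivatives) with CSF signals. The CSF mask takes voxels with CSF
probability strictly above 0.95; its regressors are the mask-average
series (default) or the first 5 principal-component scores of the
demeaned CSF voxel-by-time matrix, components sign-fixed so the
largest-magnitude loading is positive. Each voxel series is replaced by
its OLS residual; zero-variance design columns are dropped with a
warning (on a motion-free phantom the entire Friston block is degenerate
by construction — the warning is expected there).

Temporal filtering is a second-order Butterworth band-pass (default
0.01–0.15 Hz; the upper edge is deliberately above the classical 0.1 Hz
because WM signal power extends higher), applied forward–backward
(`filtfilt`) for zero phase; with a zero lower edge the filter degrades
to a low-pass. Filtering needs more than 15 samples (the zero-phase edge
padding); shorter series raise an informative error.

Spatial smoothing (Gaussian, default FWHM 4 mm) is applied to GM and WM
*separately* so the two signals do not mix: a voxel belongs to the tissue
with the larger of its GM/WM probability provided that probability
exceeds 0.5; each compartment is smoothed by normalised masked
convolution (smooth(data·mask)/smooth(mask)), which preserves constants
inside a mask and provably leaks nothing across the boundary. Voxels in
neither compartment are zeroed and counted as "holes" in the report.

## Group masks

The WM group mask takes voxels where at least 100 % of participants
(default) have WM probability strictly above 0.6; the GM mask takes
voxels where at least 20 % of participants classify the voxel as GM (GM
the largest of the three tissue probabilities — the hard-segmentation
analogue) and that are not already WM. An optional subcortical label
image forces its voxels into the GM mask and out of the WM mask
(segmentation tends to mislabel iron-rich subcortical gray as WM); the
override is unconditional. Finally, voxels whose series carries no signal
(all-zero, zero-variance, or non-finite) in strictly more than 20 % of
participants are dropped. WM ∩ GM = ∅ is asserted on every run.

## FC features and K-means networks

For every mask voxel, the FC profile is its Pearson correlation with
every stride-th mask voxel (stride 1 when the full N×N matrix fits a
memory budget, else 2 for WM and 3 for GM; columns are raster indices 0,
stride, 2·stride, …). Per-participant profiles are Fisher-z transformed
(|r| clipped at 1 − 1e−7), averaged across participants, and transformed
back — the group-average FC is the clustering input. Zero-variance
series yield zero correlations with a warning.

Rows of the N×Ns matrix are data points, columns features. K-means uses
correlation distance: rows are centred and scaled to unit norm, so
1 − r = ‖x̂ − ĉ‖²/2, and centroids are re-standardised after every
update. Initialisation is k-means++ under the same distance; 10
restarts (default) keep the solution with minimal distortion (the mean
distance of points to their centroid — mean, not sum, so values are
comparable across mask sizes). Runs that empty a cluster are re-seeded
up to five times. Everything is reproducible from one master seed via a
deterministic seed tree.

### Choosing K

The feature set is split into ncv = 4 interleaved folds (feature j →
fold j mod ncv, so every fold spans the brain); each fold is clustered
independently at each K in the scan range (default 2–22). Fold agreement
is measured by the Dice coefficient between co-membership (adjacency)
matrices, computed in chunks of 100 voxels for memory parity with large
masks; the final partial chunk is included, and a chunk with no
co-membership in either labeling scores 1. The scan reports the mean
Dice over fold pairs and chunks plus the full-feature distortion per K;
stable K values appear as local Dice maxima with low distortion, and the
final K remains a user decision. Fold runs at a given K share their
seeded initial conditions, so identical fold inputs provably yield
identical clusterings and disagreement reflects the data, not the
initialisation.

## Corpus-callosum sub-parcellation

CC voxels (any nonzero label of a supplied CC atlas intersected with the
WM mask) are removed from the WM networks before the network-average
series are computed. Per participant, each CC voxel is partially
correlated with each network's series controlling for the other K−1
series (correlation of OLS residuals against an intercept plus the
controls); r is Fisher-z transformed, a one-sample t across participants
is formed per (voxel, network), and each voxel goes to the network with
maximal t — winner take all, no significance gate, ties to the smallest
network index. The t is used purely ordinally; t-maps are persisted
unthresholded. Degenerate residuals (series fully explained by the
controls, detected at a 1e−8 relative tolerance) contribute r = 0.

## FC statistics

Region-average series (unweighted means over member voxels; empty
regions yield flagged zero series) feed per-participant Pearson FC
matrices — square and symmetric with unit diagonal within a region set,
rectangular across sets. Edges (strict upper triangle for square kinds,
n(n−1)/2 tests; all cells for rectangular kinds) are Fisher-z transformed
by default and fitted by OLS against an intercept plus all covariate
columns; the named predictor's t and two-sided p are reported per edge.
Multiple comparisons are corrected per FC kind: Benjamini–Hochberg
step-up q-values (significant iff q ≤ α; implemented directly so it
matches the step-up definition exactly, and cross-checked against
statsmodels in the tests) or Bonferroni (α_corrected = α/n_total,
significant iff p ≤ α_corrected).

## Parcellation comparison and symmetry

Two parcellations are compared by the n1×n2 matrix of Dice coefficients
2|A∩B|/(|A|+|B|) between every region pair. Interhemispheric symmetry
mirrors voxels through the midsagittal plane (world x → −x through the
affine, rounded to the nearest voxel; reflections leaving the grid and
midline voxels within half a voxel of x = 0 are discarded): the global
score is the chunked adjacency Dice between the left and mirrored-right
co-membership matrices (diagonal excluded, as in the K scan) — label
names are irrelevant, only co-membership counts — while the per-network
variant Dices every left-restricted network against every mirrored
right-restricted network, exposing self-symmetric networks on the
diagonal and contralateral pairs off it.

## Synthetic phantoms

The phantom generator is first-class, tested code; its defaults define
the study conditions: a 24×24×24 grid of 3 mm voxels centred on the
midsagittal plane, TR 1 s, 200 volumes, 20 participants, 4 planted
networks at SNR 1. The geometry carves a GM shell, a WM core, a small
central CSF compartment and an interhemispheric CC slab; planted WM
networks are contiguous slabs (or, in mirrored-pairs mode, exactly
mirror-symmetric sets realised either as one self-symmetric label or as
a contralateral label pair). Latents are white Gaussian series
band-passed to the pipeline's default band and standardised; participant
latents share half their variance with group-level latents. A voxel
series is baseline + snr·latent + unit white noise, plus a 0.003 Hz
drift and a CSF-coupled signal that the denoising chain is expected to
remove. CC voxels are driven by the latent of a designated network.
Motion traces are still, drifting, or spiky (step jumps in tx, each an
isolated FD excursion). Group phantoms mix one network pair's latents in
the second group so that the pair's correlation equals tanh(Δz) —
effects propagate through the real pipeline rather than being painted
onto FC matrices. Same spec and seed reproduce the dataset byte-for-byte
(NIfTI gzip streams are written with a fixed mtime).

The phantoms contain no hemodynamics, no spatially correlated noise, no
physiological spectra and no scanner artifacts: passing tests demonstrate
the algorithms' correctness and statistical calibration, not robustness
to every property of real data.

## Problem sizes in the tests and the acceptance script

The validation experiments run on reduced phantoms chosen to keep the
full suite in the minutes range while leaving every statistical
conclusion intact: the stability-scan and recovery experiments use
14³-voxel grids, 120 volumes and 3 participants over 20 seeds
(~500-voxel WM masks); the CC-assignment experiment uses 20 participants
on the same grid; the group-difference experiments use 12³ grids, 150
volumes and 30+30 participants over 100 (power) and 160 (null
calibration) replicates. The K-scan conclusion is read from the
seed-averaged Dice curve, since single-seed curves saturate at 1.0 on
plateaus. Full-default-size phantoms behave identically but take roughly
two orders of magnitude longer per seed.

## Known limitations

- Whole-participant exclusion only; no volume scrubbing or censoring.
- Winner-take-all CC assignment cannot express mixed CC membership.
- The K scan reports candidates; it does not auto-select K.
- Symmetry is evaluated at the network level, not per voxel.
- Inputs must already be co-registered and spatially normalised;
  realignment, segmentation and normalisation are upstream of this
  package.
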