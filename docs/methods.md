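# Methods

## Problem and scope

`nucmorph` quantifies, per cell, the 3D shape of nuclei and the
nucleocytoplasmic (N/C) partitioning of fluorescent reporters in confocal
stacks of cell monolayers. The two core read-outs are:

* the **solidity index** `V / V_hull` of the segmented nucleus — an
  indirect proxy for nuclear-envelope wrinkling (a taut nucleus is convex,
  solidity ≈ 1; folds lower it), not a direct tension measurement;
* the **log2 N/C index** `log2((F̄_nuc − F̄_bg) / (F̄_cyt − F̄_bg))` of a
  reporter or immunostain — positive when the protein is nuclear-enriched.
  Applied to a mechanosensitive transport reporter this is the Sencyt
  index; applied to a YAP immunostain it is the log2 N/C YAP ratio.

Population statistics (local cell density in a square window, Spearman
rank correlation, binned mean maps, live/fixed nucleus matching) connect
the per-cell read-outs into monolayer-level analyses. Nucleus instance
segmentation itself is consumed from an external tool as an integer label
volume; a classical threshold/watershed fallback exists only so synthetic
scenes are processable end to end.

## Calibration model

Voxels are strongly anisotropic. Defaults mirror a typical fast-Airyscan
acquisition: xy pitch 0.1413 µm, nominal z step 0.4 µm, factor-4 xy median
binning for analysis (→ 0.5652 µm), and an axial scale factor of 0.860
that corrects the mechanical z step for the refractive-index mismatch
between immersion oil (n = 1.518) and the aqueous sample (n = 1.36),
giving an effective z spacing of 0.3440 µm. The factor is carried as a
single constant of the optical configuration rather than re-derived from
aberration theory; it reproduces both calibration pairs used in practice
(0.4 → 0.3440 µm and 0.159 → 0.137 µm) but should be re-measured for
other optics. Two slightly different published xy pitches exist for this
configuration (0.1413 / 0.1409 µm); the default is 0.1413 µm because it
reproduces the binned pitch 0.5652 µm exactly, and it is configurable.

All measurements are made in physical micrometres so grid anisotropy
never leaks into shape statistics. Morphological pixel distances
(erosion/dilation below) are defined in binned pixels of 0.5652 µm.

## Morphometry

* **Volume**: voxel count × voxel volume.
* **Surface area**: the binary mask is Gaussian-smoothed with a *physical*
  sigma of 0.3 µm (anisotropic in voxel units) and the 0.5 iso-surface is
  extracted by marching cubes with physical spacing; the mesh area is the
  reported surface area. Raw marching cubes on an unsmoothed mask
  overestimates area through staircase artefacts; too much smoothing
  shifts the 0.5 level inward in proportion to curvature. Sigma 0.3 µm was
  calibrated on analytically rasterized spheres at the default grid
  (area within 1%, sphericity 0.99).
* **Convex hull volume**: Qhull on the same iso-surface vertices, so hull
  and area share one sub-voxel surface estimate. Hulling voxel centres
  systematically understates the hull, hulling voxel corners overstates it
  by a half-voxel shell (≈12% at this grid — enough to push sphere
  solidity to 0.88); the iso-surface vertices remove both biases (sphere
  solidity 0.999). Solidity can exceed 1 by up to the voxelization
  tolerance (≈1–3%) on convex bodies.
* **Ellipsoid radii**: eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of the voxel-position
  covariance in physical coordinates, plus the uniform-box correction
  spacing²/12 per axis, mapped through Rᵢ = √(5λᵢ) — exact for a solid
  uniform ellipsoid, deterministic and rotation-equivariant. Radii of an
  (8, 5, 3) µm test ellipsoid are recovered within 0.5%, rotated or not.
* **Sphericity**: π^(1/3)·(6V)^(2/3) / A.
* **Oblateness / prolateness**: with f = (R₂ − R₃)/(R₁ − R₃),
  oblateness = 2f − 1 and prolateness = 1 − 2f, both in [−1, 1]; +1 marks
  a perfect disc (resp. rod) and both are defined 0 for a sphere. This
  symmetric triaxial form was chosen as the canonical pair; it is an open
  design point since several conventions circulate, and the formula is
  surfaced here and in the API docstrings. Note the pair is
  ill-conditioned near R₁ ≈ R₃, where rasterization noise can swing f.
* Instances with fewer than 4 non-coplanar voxels have no hull; they are
  returned flagged (`degenerate_hull`), never raised over.

Nuclei touching the first or last z-plane are excluded before shape
analysis (their masks are truncated); xy-border exclusion is optional and
off by default, since only axial truncation is unambiguous in a tiled
acquisition.

## Intensity measurement

Measurements are taken on the single z-plane of largest nuclear
cross-section (ties resolve to the lowest plane):

* nuclear region: in-plane mask eroded by 1 px;
* cytoplasmic ring: (mask ⊕ 3 px) minus (mask ⊕ 1 px), minus any pixel of
  a neighbouring nucleus on that plane. Morphology uses the 3×3 square
  element, so n-px dilation is Chebyshev distance n.
* background: mean of cell-free pixels — farther than a margin (default
  10 binned px) from the xy footprint of every nucleus and below the
  plane's Otsu threshold. "Cell-free" is not rigorously defined by any
  single convention; this operationalization (distance + intensity gate)
  is configurable, and a caller-supplied per-channel background estimate
  overrides the automatic region entirely.

Quality control discards records with a reason code per failed rule:

| rule | default | rationale |
|---|---|---|
| `snr`: (F̄_nuc − F̄_bg)/σ_bg < snr_min | 2 | conventional detection limit; the filter is standard but its numeric value is a free choice, hence prominent in config |
| `cv`: coefficient of variation of background-subtracted pixels > 0.8 in either region | 0.8 | rejects dim cells flanked by very bright ones (and vice versa) |
| `hoechst_nc`: raw nuclear/cytoplasmic DNA-stain ratio < 4 | 4 | flags bad nuclear masks; computed on raw means because the cytoplasmic DNA signal sits at background level and a subtracted ratio is numerically unstable |

Records whose erosion empties the nucleus, whose ring is fully occluded,
or whose background-subtracted means are non-positive are flagged and
counted, never silently dropped.

## Population statistics

* **Local density**: the number of nucleus centroids inside an
  axis-aligned square of side 113.04 µm (200 binned px) centred on each
  nucleus, focal nucleus included so the count equals window occupancy
  (an exclusive-count flag exists). Also reported per mm². Windows
  clipping the field edge are flagged; no edge correction is applied.
* **Live/fixed matching**: translation-only registration (phase
  cross-correlation of mask footprints, shift capped at a plausible stage
  drift of 20 px, zero-fill shifting) followed by one-to-one assignment by
  maximal voxel overlap; pairs below 50% overlap of the smaller mask stay
  unmatched. Fixation does not deform the field, so no elastic model.
* **Timelapse normalization**: each per-nucleus series is divided by the
  mean of its first 5 timepoints (configurable); zero baselines flag the
  series as NaN.
* **Spearman correlation**: Pearson correlation of mid-ranks (average
  ranks on ties). Two-tailed p: exact enumeration of all n! y-rank
  permutations for n ≤ 10, the t approximation with n − 2 df otherwise.
  Implemented in-package; the scipy implementation serves as an
  independent cross-check in the tests only.
* **Binned mean maps**: arithmetic mean of a value over a rectangular
  grid of covariate bins (default: decile edges of each covariate, since
  no canonical bin edges exist for these maps); empty bins are NaN and
  per-bin counts are reported.

## Synthetic scenes

The generator emulates the acquisition geometry, not its optics: nuclei
are triaxial ellipsoids (R₁ ∈ [4.5, 6.5], R₂ ∈ [3.5, 5.5],
R₃ ∈ [2.5, 3.5] µm — realistic epithelial nuclear semi-axes) whose radius
field is modulated by a band-limited angular perturbation
r(u) = r_ell(u)·(1 + α·P(u)), |P| ≤ 1, with per-nucleus random phases.
α = 0 gives a convex body; mean measured solidity decreases strictly over
α ∈ {0, 0.1, 0.2, 0.3}. Centres are dart-thrown with a 3D minimum
separation (16 µm default); orientations default to in-plane rotations
(monolayer nuclei lie flat, and a fully tumbled 6.5 µm nucleus would not
fit the 13.8 µm default z extent without touching the stack faces), with
full 3D rotations available for larger fields.

Channels: DNA (flat nuclear level over background), reporter (nuclear
level inside nuclei, cytoplasmic level in a 3 µm radial shell clipped
against neighbours and assigned uniquely to the nearest nucleus, flat
background B = 50 elsewhere — so the true index is exactly
log2(I_nuc/I_cyt)), and an optional uniform control with identical
concentration throughout each cell (true index 0). Noise: Gaussian with
sigma 2% of the nuclear reporter level (keeping recovery tolerances
analyzable) and optional Poisson resampling. The 3 µm shell thickness
guarantees the measurement ring (Chebyshev 1–3 px ≈ up to 2.4 µm beyond
the mask) stays inside the shell. An optional cell-free apron widens the
field border so background estimation succeeds even in densely packed
scenes.

Dependency hooks plant or break covariate structure: `density_to_alpha`
couples crowding to wrinkling; `ratio_from_alpha` couples the reporter
ratio to wrinkling (hence to measured solidity) while leaving it
independent of density. The wrinkle amplitude accepts a (lo, hi) range
sampled i.i.d. per nucleus, which is what lets the ratio track solidity
*without* tracking density. What passing recovery tests do **not** show:
robustness to optical blur (no PSF), photobleaching, chromatin texture,
segmentation errors of a learned segmenter, or non-flat background — all
deliberately out of the simulation.

## Problem sizes and numerical choices

The validation suite uses scenes of 4–25 nuclei on (40, 128–384, ·)
voxel grids, and one 500-nucleus scene on (40, 1040, 1040) for the
population-dissociation recovery; these sizes give stable statistics
(rank-correlation standard error ≈ 0.045 at n = 500) while the full
suite and the acceptance script each run in a few minutes on one CPU.
All randomness flows from a single integer seed per scene
(`numpy.random.default_rng`); identical seeds reproduce scenes
bit-identically, and pipeline outputs are deterministic given the
manifest's recorded config.

Known limitations: solidity (not curvature) is only an indirect
wrinkling read-out; the oblateness/prolateness pair is unstable for
near-spherical nuclei; the SNR threshold is a convention, not a measured
constant; hull volumes of very small instances (< ~100 voxels) carry
several-percent voxelization error; and the fallback segmenter is not a
substitute for a learned segmenter on real chromatin images.
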