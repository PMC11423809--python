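# nucmorph

Per-cell quantification of 3D nuclear shape and nucleocytoplasmic (N/C)
transport read-outs in confocal stacks of cell monolayers.

Mechanical forces on the nucleus change both its shape and the rate of
nucleocytoplasmic transport. Two per-cell numbers capture this in images:
the **solidity index** of the segmented nucleus,

    solidity = V / V_hull,

the ratio of nuclear volume to its convex-hull volume (≈1 for a taut,
convex nucleus; lower when the envelope wrinkles), and the **log2 N/C
index** of a fluorescent reporter or immunostain,

    index = log2( (F̄_nuc − F̄_bg) / (F̄_cyt − F̄_bg) ),

the background-subtracted ratio of mean nuclear to mean cytoplasmic
fluorescence measured on the plane of biggest nuclear area (positive =
nuclear enrichment). `nucmorph` computes these — plus volume, surface
area, ellipsoid radii R₁ ≥ R₂ ≥ R₃, sphericity, oblateness/prolateness,
local cell density, Spearman correlations and binned mean maps — from
calibrated multi-channel TIFF stacks and externally produced 3D nucleus
label masks, with the quality-control filters (signal-to-noise, regional
coefficient of variation, DNA-stain N/C sanity check) applied and
accounted per cell. A ground-truth synthetic scene generator makes every
stage testable by parameter recovery without any microscopy data.

Intended users: imaging groups quantifying nuclear mechanics or
transport-reporter localization in monolayers, and anyone needing a
tested reference implementation of these read-outs.

## Worked example

Simulate a small scene (9 ellipsoidal nuclei, reporter N/C ratio 2,
i.e. true index = 1) and measure it end to end:

```python
import dataclasses
from nucmorph import SceneSpec, ChannelModel, simulate_scene, measure_scene
from nucmorph.morphometry import measure_all

spec = SceneSpec(n_nuclei=9, seed=11,
                 channels=ChannelModel(gaussian_sigma_frac=0.0))
scene = simulate_scene(spec)

shapes = measure_all(scene.labels)          # one row per nucleus
cells = measure_scene(scene.stack, scene.labels)
table = shapes.merge(cells, on="nucleus_id").merge(scene.truth, on="nucleus_id")
print(table[["nucleus_id", "volume_um3_x", "solidity",
             "sencyt_index", "true_log2_nc", "qc_pass"]].head(3).round(3))
```

```
   nucleus_id  volume_um3_x  solidity  sencyt_index  true_log2_nc  qc_pass
0           1       226.156     1.000           1.0           1.0     True
1           2       240.222     1.003           1.0           1.0     True
2           3       320.223     0.999           1.0           1.0     True
```

Volumes are in µm³ on the calibrated anisotropic grid (0.5652 µm xy,
0.3440 µm corrected z); solidity ≈ 1 because unwrinkled nuclei are
convex; the measured index recovers the planted log2 ratio exactly in a
noise-free scene, and every cell passes QC.

The same chain is available from the shell:

```sh
nucmorph simulate --seed 11 --out scene/
nucmorph measure --config run.yaml --out results/   # stack_path/labels_path in run.yaml
nucmorph correlate --config run.yaml --out results/ # + density, correlations, heatmaps
nucmorph osmo                                       # osmotic-shock mixing arithmetic
```

Every run writes a `manifest.json` recording the config hash, seed and
per-stage record counts (input / kept / discarded with reasons), and
re-running a recorded config reproduces the tables bit-identically.

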