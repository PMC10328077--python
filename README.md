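# tirfquant

Single-molecule TIRF foci quantification and per-cell tissue
immunofluorescence analysis.

`tirfquant` is for researchers who count molecules with a fluorescence
microscope: it takes two-channel single-molecule TIRF movies of
surface-captured protein complexes and answers *how many labeled molecules
are in each spot* and *which spots in one colour channel sit on top of spots
in the other*, and it takes multi-channel tissue images with a nuclear stain
and answers *how correlated two markers are around each cell* and *how much
of each marker each cell carries*. Because raw single-molecule data are
rarely shareable, the package includes a first-class synthetic-data
generator that emulates the acquisition (integrated-Gaussian PSF, Poisson
shot noise, read noise, per-fluorophore stochastic photobleaching) with full
ground truth, so every stage of the analysis is verifiable by parameter
recovery.

## The analysis

**Single-molecule pipeline** (`simulate → detect → track → stoich → coloc`):

1. **Detection.** Per frame, candidate spots are local maxima of a
   band-pass-filtered image above a robust noise threshold. Each candidate
   is refined to sub-pixel accuracy by *iterative Gaussian masking*: the
   background-subtracted ROI is multiplied by a Gaussian mask centred on
   the current estimate and the intensity-weighted centroid of the product
   becomes the next estimate, iterated to convergence. The focus intensity
   *I* is the summed intensity in a small square ROI corrected for the
   local background *b* (the ROI's border-ring mean), and a focus is
   accepted only if its signal-to-noise ratio (mean background-corrected
   intensity per ROI pixel over the border-ring standard deviation) is
   strictly above 0.4.
2. **Tracking.** Accepted foci are linked frame-to-frame by optimal
   bipartite assignment within a link radius; tracks must last strictly
   longer than three frames.
3. **Stoichiometry.** The number of fluorophores in a focus is
   S = I₀ / I_single, where I₀ is the photobleach-corrected initial
   intensity — the intercept of an ordinary least-squares line through the
   first 4 intensity points of a track that starts within the first 10
   frames (equivalent to full exponential fitting for short extrapolations)
   — and I_single is the characteristic single-fluorophore intensity, the
   kernel-density mode of single-dye intensities obtained from
   photobleaching analysis (Chung–Kennedy filtering followed by
   change-point step detection).
4. **Colocalization.** Each green/red focus pair is scored by the
   normalized Gaussian overlap integral
   O = [2σ_Aσ_B/(σ_A²+σ_B²)]·exp(−d²/(2(σ_A²+σ_B²))) ∈ [0, 1];
   pairs with O strictly above 0.75 are colocalized, and the per-field
   proportion of colocalized green foci is reported, together with
   stoichiometry distributions stratified by colocalization status
   (two-sided Student's t-test).

**Tissue pipeline** (`tissue`): the nuclei (DAPI) channel is segmented with
Otsu's method, holes are filled and objects smaller than 50 pixels removed,
a 100×100-pixel ROI box is centred on each nucleus, and per-ROI Pearson
correlation between signal channels and summed background-corrected
intensities are computed per cell.

## Worked example

Simulate a two-channel movie of 24 immobilized complexes carrying 1–5
fluorophores each (5% per-frame bleaching, half the spots with a red
partner), then run the full pipeline:

```python
import numpy as np
from tirfquant import RunConfig, SimulationConfig, run_pipeline
from tirfquant.simulate import grid_spot_specs

specs = grid_spot_specs([1, 2, 3, 5] * 6, 120, 110, spacing=14, margin=12, seed=2)
sim = SimulationConfig(image_width=120, image_height=110, n_frames=60,
                       spot_specs=specs, bleach_prob=0.05,
                       colocalized_fraction=0.5, rng_seed=42)
result = run_pipeline(RunConfig(simulation=sim, seed=42), "out/demo")

print("green tracks:", len(result.tracks["green"]))
print("I_single (green): %.1f counts" % result.i_single["green"])
s = [e.stoichiometry for e in result.stoichiometries["green"]]
print("stoichiometries: n=%d, median=%.2f, range %.2f-%.2f"
      % (len(s), np.median(s), min(s), max(s)))
print("proportion colocalized: %.3f" % result.proportion_colocalized)
```

Output:

```
green tracks: 24
I_single (green): 2001.5 counts
stoichiometries: n=24, median=2.46, range 0.83-5.46
proportion colocalized: 0.375
```

All 24 simulated complexes are recovered as tracks. The characteristic
single-fluorophore intensity 2001.5 counts matches the generator's true
photon scale of 2000 counts/fluorophore/frame within 0.1%, so the
stoichiometries (0.83–5.46) track the simulated 1–5 fluorophores per spot.
The colocalized proportion 0.375 estimates the simulated fraction 0.5; with
only 24 green foci the exact binomial 95% interval around 0.5 spans
0.29–0.71, so this field is consistent with truth. The output directory
contains every stage's CSV table, the TIFF stacks, a log, and the exact
configuration used.

The same stages are available from the shell:

```bash
tirfquant simulate tirf --config cfg.yaml --out out/
tirfquant detect --stack out/stack_green.tif --config cfg.yaml --out foci.csv
tirfquant run --config cfg.yaml --out out/run --seed 42
tirfquant tissue --image tissue.tif --nuclei-channel 0 --out cells.csv
```

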