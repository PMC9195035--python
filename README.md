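# epidpsm

Pixel-sensitivity-map (PSM) determination for EPID dosimetry.

## The problem

The amorphous-silicon electronic portal imaging device (EPID) mounted on
a linac is an attractive dosimeter, but its vendor calibration — the
flood-field correction — divides every image by an open-field exposure.
That erases the detector's pixel-to-pixel gain differences **and** the
beam's own profile shape, which is precisely the information beam QA
needs.  The alternative is to calibrate with a *pixel-sensitivity-map*:
a raw (non-flood-field-corrected) portal image is modelled pixelwise as

```
raw(i, j) = k · PSM(i, j) · BR(x(i, j), y(i, j)) + noise
```

where `PSM` carries everything the imager introduces (gain structure,
dead pixels) and the Beam-Response `BR` carries everything the beam
introduces (profile dome, horns, penumbra), with `(x, y)` the beam-frame
off-axis position of a pixel.  Dividing raw images by the PSM preserves
the beam profile; the hard part is separating `PSM` from `BR` without a
uniform reference beam.

`epidpsm` implements four separation methods from the medical-physics
literature, plus a synthetic panel/beam simulator so that each method
can be validated against a known ground truth without a linac:

| method | idea | modules |
| --- | --- | --- |
| constant-beam offset grid ("CMN") | a small field is re-imaged at a grid of panel offsets; offset/centre ratios cancel the beam and sample the PSM; a not-a-knot tensor spline fit of the Beam-Response (linearly extrapolated) is divided out of a wide-field image | `epidpsm.cmn` |
| small-shift overlapping fields ("WashU") | large fields with whole-pixel panel shifts; pixels that saw the same beam location constrain sensitivity ratios, propagated from a central seed (log-domain least squares) | `epidpsm.washu`, `epidpsm.propagation` |
| three-stage ("Varian") | coarse PSM from 50-pixel-shifted fields, low-frequency fix from two source-to-imager distances via inverse-square/magnification, polynomial quadrant tuning | `epidpsm.varian` |
| radial ring average ("Monte-Carlo-style") | a noisy idealized response image is ring-averaged and spline-smoothed into a radially symmetric Beam-Response, divided out of a measured raw image | `epidpsm.radial` |

The simulator (`epidpsm.simulate`) emulates a 1190 × 1190 panel with a
40 × 40 cm² active area at isocenter (0.34 mm pixels), smooth gain
variation, per-pixel sensitivity spread, dead-pixel columns, a corner
shadow, a flattened beam with horns and small asymmetry, per-irradiation
output fluctuation, readout noise and frame lag, and alternating
beam/dark-field (ABDF) sequences.  Day-to-day work and the test suite
run on a 238 × 238 grid spanning the same 40 cm.

## Worked example

Recover a known panel with the small-shift method under realistic noise
(2% static pixel-gain spread, 0.1% readout noise, 0.05% output
fluctuation):

```python
from epidpsm import scenarios as sc
from epidpsm.metrics import recovery_report
from epidpsm.simulate import generate_ground_truth_psm

geom = sc.desk_geometry()                      # 238 x 238, 40 cm span
truth = generate_ground_truth_psm(sc.defects_realistic(geom, seed=11), geom)
out = sc.run_washu_study(truth, sc.default_beam(), geom, sc.study_noise(), seed=7)
rep = recovery_report(out["psm"], truth, geom)
print(f"median deviation: {rep['stats'].median:+.3f}%")
print(f"median |deviation|: {rep['median_abs']:.3f}%")
print(f"95th percentile |deviation|: {rep['stats'].p95_abs:.3f}%")
print(f"pixels outside the usable footprint: {rep['n_invalid']}")
```

prints

```
median deviation: +0.005%
median |deviation|: 0.211%
95th percentile |deviation|: 0.417%
pixels outside the usable footprint: 14011
```

i.e. the method reproduces the true per-pixel sensitivities to about
0.2% (median) wherever its 37 × 37 cm fields overlap; the 14 011 masked
pixels are the panel border outside that footprint plus the dead column,
which this method cannot constrain — one of the behavioural signatures
the simulator is designed to expose (see `docs/methods.md`).

## Command line

```sh
epidpsm simulate --seed 1 --out acq/          # synthetic acquisition campaign
epidpsm washu acq/ --out results/washu/       # (likewise: cmn, varian, radial)
epidpsm compare results/washu/psm.tiff acq/truth_psm.tiff --out cmp.json
epidpsm repeatability run1/psm.tiff run2/psm.tiff run3/psm.tiff --out rep.json
epidpsm run-all --seed 1 --out study/         # full four-method comparison
```

Images are float32 TIFF (or `.npy`) with JSON sidecars; DICOM RT Image
files are read directly.  Exit codes: 0 success, 2 validation error,
3 method failure.

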