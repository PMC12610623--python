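# rnptrack

Quantitative analysis for CRISPR–Cas9 delivery experiments in hard-to-transfect
cell lines. When comparing delivery routes (electroporation, lipid
nanoparticles, magnetofection) three questions keep recurring that pure imaging
cannot answer: *what physical state is the Cas9 protein in* (monomer or
aggregate), *where do cargo and carrier end up along the optical axis*, and
*how much reagent did each cell actually see*. This package implements the
corresponding analysis chains as a tested library with a CLI and a set of
narrative analysis scripts:

- **FCS** (`rnptrack.fcs`) — fluorescence correlation spectroscopy: multi-tau
  autocorrelation of photon-arrival streams, fitting of the two-component +
  triplet diffusion model, focal-volume calibration against reference dyes,
  and Stokes–Einstein hydrodynamic radii.
- **Axial offsets** (`rnptrack.zstack`) — per-ROI z-profiles and peak-slice
  differences between two confocal channels, quantifying the axial separation
  of carrier and cargo signals.
- **Dosimetry** (`rnptrack.dosimetry`) — per-cell dose arithmetic, BCA protein
  calibration, and bioconjugation mass balance.
- **Synthetic data** (`rnptrack.simulate`) — a Brownian-dynamics photon
  simulator (3D Gaussian detection volume, Poisson emission, optional triplet
  blinking) and a two-channel z-stack generator, both with analytically known
  ground truth, used to validate every stochastic step.

## The model

The autocorrelation of fluorescence fluctuations from molecules diffusing
through a 3D Gaussian confocal volume is fit with

```
G(t) = (1/N) [ R (1 + t/tD1)^-1 (1 + t/(ω² tD1))^-1/2
            + (1−R) (1 + t/tD2)^-1 (1 + t/(ω² tD2))^-1/2 ]
            · (1 + AT e^(−t/tT)) + b0
```

where `N` is the mean focal occupancy, `tD1`/`tD2` the diffusion correlation
times of the two species (fast component ≈ free label dye, slow component ≈
labeled protein) weighted by `R`, `ω` the axial/radial aspect ratio, `AT`/`tT`
the triplet amplitude and lifetime, and `b0` the baseline. A reference dye of
known diffusivity calibrates the beam waist, `Wxy = sqrt(4 D_ref tD_ref)`, so
a fitted diffusion time converts to a diffusion coefficient
`D = Wxy²/(4 tD)` and, through Stokes–Einstein, to a hydrodynamic radius
`RH = kB T / (6 π η D)`.

## Worked example

```python
from rnptrack.fcs import (FocalVolumeCalibration, SolventConditions,
                          beam_waist_from_reference, hydrodynamic_radius)

# calibrate the red channel against a dye with D = 3.6e-10 m^2/s whose
# fitted mean diffusion time was 271 us:
wxy = beam_waist_from_reference(3.6e-10, 271e-6)
print(f"Wxy = {wxy/1e-6:.2f} um")            # Wxy = 0.62 um

# a labeled Cas9 sample measured at D = 0.207e-10 m^2/s in cell medium,
# at 25 C in water (0.89 cP):
rh = hydrodynamic_radius(0.207e-10, SolventConditions())
print(f"RH = {rh/1e-9:.1f} nm")              # RH = 11.9 nm
```

An `RH` near 12 nm is what a Cas9 monomer should show; repeating the same
calculation for the HEPES lipofection buffer (`D = 0.111e-10`) gives ~22 nm,
i.e. roughly twice the monomer radius — the signature of aggregation in that
buffer. The full pipeline (simulate → correlate → fit → analyze) is exercised
by the scripts below and from the CLI:

```sh
rnptrack fcs simulate  --config sim.toml --out stream.bin
rnptrack fcs correlate --input stream.bin --bin-width 1e-6 --output curve.csv
rnptrack fcs analyze   --curve curve.csv --calibration cal.json --component 2 \
                       --output props.json
rnptrack zoffset run   --ch1 green.tif --ch2 red.tif --rois rois.csv \
                       --out report.csv
rnptrack dose per-cell --volume 75 --conc 25 --cells 20000   # 0.094 ng/cell
```

## Analysis scripts

Numbered drivers under `analysis/` write small tables to `results/`:

1. `01_calibrate_focal_volume.py` — beam waists (0.95 / 0.62 µm) and
   aspect-ratio-conditional focal volumes for the two optical configurations.
2. `02_cas9_diffusion.py` — diffusional properties of Cas9 in the two
   delivery buffers (11.9 nm vs 22 nm), each cross-checked through the full
   fit chain on a synthetic curve.
3. `03_simulate_and_fit_fcs.py` — ground-truth recovery of diffusion time and
   occupancy from a simulated photon stream (a few percent error at 1 s of
   acquisition).
4. `04_axial_offset.py` — exact recovery of 12 prescribed axial offsets
   (0–41 slices) from a noisy synthetic two-channel 121-slice stack.
5. `05_dosimetry.py` — per-cell dose tables, the BCA calibration line
   (slope 0.0092 per µg/mL) and the immobilization mass balances
   (42.90% / 38.68% bound).

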