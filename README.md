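# sdapkit

Quantitative analysis of dSTORM single-molecule localization data from the
distal end of the mother centriole — the region carrying distal appendages
(DAPs, e.g. SCLT1, FBF1, CEP83, CEP89) and subdistal appendages (sDAPs, e.g.
ODF2, CEP128, centriolin, ninein, CEP170).  It is written for microscopists
who have localization tables (frame, channel, x/y in nm, photons) from a
two-color dSTORM experiment and want the standard appendage-architecture
measurements, plus a synthetic-data generator so that every estimator can be
validated by parameter recovery.

## What it measures

**Axial view** (centriole seen end-on, the reference protein forms a ring):

- Puncta are density-based clusters of localizations.  The ring center **c**
  is a Kåsa algebraic circle fit refined by geometric Gauss–Newton, robust to
  background; the radius of punctum *j* is r_j = ‖p_j − c‖ and the **mean
  diameter** is 2·mean(r_j).
- **Angular occupancy** ("circular expansion"): localizations in an annulus
  around the ring are binned by polar angle (10°/bin); completeness is the
  fraction of occupied bins, and contiguous unoccupied runs are reported as
  gap arcs.
- **Nine-fold symmetry**: the mode-9 power ratio |Σ_j exp(i·9θ_j)|²/n² over
  punctum angles (1 for perfect nine-fold placement, expectation 1/n for
  uniform angles).

**Lateral view** (centriole seen from the side, the reference ring appears as
a rod): the centriole axis is the perpendicular to the SCLT1 rod through its
centroid, signed so that a distal marker (CP110) is positive.  Target
localizations are projected on the axis to give a **longitudinal profile**
with SCLT1 ≡ 0; layers are peaks of the kernel-smoothed profile, and the
distal spread of a cloud is summarized by its 0.95-quantile boundary.
Centrioles can be aligned on the reference and summed into composite images,
and α-tubulin fibers are detected as elongated localization clusters and
counted per radian / per longitudinal bin.

Pre-analysis corrections reproduce the standard chain: lateral drift is
measured from fiducial-bead tracks and subtracted per frame; chromatic
aberration between the 561 and 647 nm channels is removed with a full
second-order 2D polynomial fitted on calibration beads.

## Worked example

```python
from sdapkit import (AxialRingModel, LateralProfileModel,
                     build_model_from_paper, simulate_centriole)

# a packaged geometry preset of the wild-type appendage architecture
model = build_model_from_paper("wild_type", view="axial")
table, truth = simulate_centriole(model, seed=7)

print(AxialRingModel(table, channel="CEP128").fit().summary())
```

```
Axial ring fit
==============================================
channel                     CEP128
n localizations             787
n puncta                    9
center x, y [nm]            0.2, -1.5
mean diameter [nm]          245.8
radius sd [nm]              2.4
ring completeness           0.806
missing fraction            0.194
mode-9 power ratio          0.866
fit method                  kasa+gn
```

The CEP128 ring is recovered with nine blade puncta, a diameter of ~250 nm
(the preset encodes a 125 nm ring radius) and a strong nine-fold signature.
The same dataset in the lateral view:

```python
lat, _ = simulate_centriole(build_model_from_paper("wild_type", view="lateral"), seed=7)
res = LateralProfileModel(lat, "SCLT1", "ODF2", distal_marker_channel="CP110").fit()
print(res.summary())
```

```
Longitudinal layer profile
========================================================
reference channel           SCLT1
target channel              ODF2
n target localizations      1222
n detected layers           2
layer 0 position [nm]       -195.5   (FWHM 50 nm)
layer 1 position [nm]       -100.0   (FWHM 60 nm)
distal 95% boundary [nm]    -67.9
```

ODF2 resolves into its two layers ~100 nm and ~200 nm proximal to SCLT1.

A command-line interface chains the same steps
(`sdapkit simulate | correct | ring | lateral | fibers | report`); e.g.

```bash
sdapkit simulate --preset wild_type --seed 7 --out sim/
sdapkit ring --in sim/localizations.csv --channel CEP128 --out ring.json
```

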