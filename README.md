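# collaraccel

Behaviour categorisation from collar-mounted tri-axial accelerometers,
built around a captive-cheetah use case: how well can a random forest
recover an animal's ethogram from raw collar acceleration, and how much
does the data logger's specification (sampling rate, measurable range,
amplitude resolution) matter?

The package is organised as an analysis project. The library under
`src/collaraccel/` implements every step; the numbered scripts under
`analysis/` run the experiment end to end; `scripts/acceptance.py`
recomputes the headline numbers.

## The problem and the model

A collar accelerometer reports acceleration in three body axes — *heave*
(vertical), *surge* (longitudinal), *sway* (transverse) — in units of g.
Each sample ("logging event") decomposes into a gravity-driven postural
component and a movement-driven dynamic component:

- **static acceleration** per axis: a 2-s centred rolling mean — posture;
- **dynamic acceleration** per axis: |raw − static| — movement intensity;
- **VeDBA** = ‖(dyn_heave, dyn_surge, dyn_sway)‖ and
  **VeSBA** = ‖(stat_heave, stat_surge, stat_sway)‖;
- **pitch** = arcsin(stat_surge / VeSBA), **roll** = arcsin(stat_sway /
  VeSBA), in degrees;
- **Anim.stat**: the angle between the static vector and the calibrated
  resting orientation.

These 14 channels (3 raw + 3 static + 3 dynamic + VeDBA + VeSBA +
Anim.stat + pitch + roll) are the predictors of a per-sample random-forest
classifier, trained at three ethogram resolutions — 17 fine behaviours
(postures, stalks, the four gaits, pounce, a rag-bag "other"), a medium
level (sedentary postures and moving stalks merged, pounce folded into
"other"), and a coarse active / inactive / head-movement / "other" level.
Two logger profiles observe the same ground truth: a 30 Hz / ±2.3 g
device and a 50 Hz / ±8.6 g / 0.001 g device; their per-behaviour
accuracies are compared with 2×2 χ² tests (Fisher's exact test for sparse
tables).

Because the original collar recordings are not shipped, a gait-aware
simulator (`devicesim`) generates ground-truthed sessions: gravity
projected onto posture-specific collar orientations, footfall-locked
raised-cosine impulse trains for the gaits (4-beat walk, 2-beat diagonal
trot, 3-beat canter, 4-beat gallop with suspensions), band-limited wobble
for non-gait movement, Gaussian sensor noise, and a leading "rail" window
for mounting calibration. See `docs/methods.md` for model details and the
limits of what the synthetic data can show.

## Worked example

```sh
python analysis/01_simulate_session.py --seed 1 --size full
python analysis/02_build_datasets.py
python analysis/03_train_and_evaluate.py --seed 1 --size full
python analysis/04_compare_devices.py
python analysis/05_published_arithmetic.py
```

Output of the two dataset-building steps (seed 1, small session shown):

```
CEFAS: calibration residual 0.000 deg; 3576 labelled events kept, 300 unassignable removed
GCDC: calibration residual 0.000 deg; 5960 labelled events kept, 500 unassignable removed
CEFAS fine  : valid accuracy 0.990 (MSE 0.018, r2 0.999); other-disregarded 98.9%; CV 0.986 (sd 0.003); depth 20, 20 trees
CEFAS coarse: valid accuracy 0.997 (MSE 0.011, r2 0.990); other-disregarded 99.7%; CV 0.988 (sd 0.005); depth 10, 14 trees
      collapsing fine predictions to coarse: 0.990 -> 1.000
```

Reading this: the rail-window calibration recovered the planted collar
mounting offset essentially exactly; the fine 17-class model categorises
99% of validation logging events correctly (cross-validation agrees with
training, so no overfitting); disregarding the uninformative "other"
category changes the headline accuracy slightly; and collapsing the fine
model's predictions to the coarse vocabulary can only merge errors away
(0.990 → 1.000). The comparison step then prints per-behaviour accuracy
differences between the two loggers with their test statistics, and
`05_published_arithmetic.py` reproduces the published aggregate counts
(e.g. 48,925 sedentary events on the 30 Hz logger) and the mean
accuracy differences (−6.4 / −3.3 / −4.0 percentage points at fine /
medium / coarse resolution, higher-capacity logger ahead).

Synthetic accuracies are higher than field numbers: the simulator's
behaviours are cleaner than real cheetah data (see `docs/methods.md`).

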