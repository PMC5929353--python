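# braggscreen

A screening ("veto") tool for serial-crystallography diffraction frames.
A small convolutional network classifies each detector frame as **Hit**
(ten or more Bragg spots), **Maybe** (four to nine) or **Miss**, so that
frames without crystal diffraction can be discarded before storage and
downstream processing. The package bundles:

- **`io_formats`** — HDF5 frame stacks, CSV annotation tables, deterministic
  (optionally class-ratio-preserving) train/validation/test splitting.
- **`synth_data`** — a synthetic diffraction-frame simulator with known
  ground-truth spot counts, emulating two detector families
  (`cspad_like`: sub-pixel point spread, panel gaps, elevated border rows;
  `rayonix_like`: wide point spread, monolithic sensor with a central beam
  hole) plus water rings, jet spikes, partial shadowing, pulse-energy
  jitter, saturation and beam-off blanks.
- **`preprocess`** — dark/gain correction, photon-preserving binning,
  center/random cropping, augmentation, global normalization, local
  contrast normalization (LCN) and a linear-contrast comparator.
- **`spot_baseline`** — a threshold spotfinder (global threshold + local
  significance + minimum area) with a count-threshold Hit classifier, used
  as the comparison baseline.
- **`cnn_classifier`** — the network itself: four configurable stages of
  convolution (kernel 3, stride 2) / batch norm / ReLU / 2×2 max pooling,
  one fully connected layer and a SoftMax over the three classes. Forward
  **and** backward passes are implemented in pure NumPy (no deep-learning
  framework needed); training is mini-batch SGD on cross-entropy with
  class-balanced batches and an exponentially decaying learning rate.
  The default architecture maps a 720×720 frame to a 288-long feature
  vector.
- **`evaluation`** — confusion matrices, binary/three-class success rates,
  confidence histograms, input-gradient saliency maps (3σ masks), and
  drivers for cross-dataset, data-size and contrast-ablation experiments.
- **`cli`** — the `braggscreen` command.

## Command line

Each stage is a subcommand; `run` chains them end to end and writes every
artifact (frames, annotations, preprocessed images, model, history,
predictions, evaluation report and the resolved config) into one directory:

```sh
# end-to-end demo: simulate 600 frames, train, evaluate (~1 min)
braggscreen run --seed 0 --out demo/

# individual stages
braggscreen simulate --profile rayonix_like --n 200 --seed 7 \
    --out frames.h5 --annotations truth.csv
braggscreen preprocess --in frames.h5 --out lcn.npz --bin 2 --crop 48 --contrast lcn
braggscreen spotfind --in frames.h5 --out counts.csv
braggscreen train --frames lcn.npz --annotations truth.csv \
    --out model.npz --history history.csv
braggscreen predict --model model.npz --frames lcn.npz --out predictions.csv
braggscreen evaluate --truth truth.csv --pred predictions.csv --binary --out report.json

# experiment drivers
braggscreen xdataset --profiles cspad_like --profiles rayonix_like --n 300 --out matrix.csv
braggscreen ablation --profile rayonix_like --n 300 --out ablation.csv
```

All commands accept `--seed`; `run` and `train` also accept `--config`
with a YAML file that is deep-merged over the defaults (see
`braggscreen.cli.DEFAULT_CONFIG`). Every run writes `resolved_config.yaml`
beside its outputs, and reruns with an identical config reproduce outputs
byte for byte.

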