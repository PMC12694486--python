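# fedfer

Federated facial-emotion recognition with quantitative explanation-quality
evaluation.

`fedfer` is for researchers who want to study the interplay between
**privacy-preserving training** and **explainability** in facial emotion
recognition (FER) without shipping face data anywhere. It implements, end to
end and fully offline:

- a **configurable lightweight CNN family** for 48×48 grayscale faces over the
  four clinically relevant emotions {neutral, happy, sad, angry}: a stack of
  3–4 filter blocks (3×3 valid convolution + ReLU + 2×2 max-pool, widths such
  as (64, 128, 256)), a dense 256/128 head with dropout 0.2, and a 4-way
  softmax — with exact per-layer parameter, multiply–accumulate and size
  accounting;
- a **FedAvg simulator**: equal stratified client shards, 15 local epochs per
  round of Adam (batch 64, lr 0.001), and server-side sample-weighted
  averaging of client weight sets, `w = Σᵢ (nᵢ/Σn) wᵢ`, for ~20 rounds — plus
  the centralized baseline under the identical protocol;
- a **Grad-CAM++ explainer** from any filter block, combined with a
  parameter-free channel-attention map (softmax over per-channel GAP + GMP
  scores) into a final overlay normalized to [0, 1];
- a **seven-metric perturbation suite** for explanation faithfulness:
  insertion/deletion AUC (IAUC/DAUC), average drop (AD), increase in
  confidence (IC), average drop in accuracy (ADA), active pixel ratio, and
  accuracy after masking — per emotion and macro-aggregated — evaluated on the
  subset of samples every compared model classifies correctly;
- **multi-seed statistics** (sample std, Student-t 95% CIs) and a joint
  performance + explainability model-selection report;
- a **synthetic schematic-face generator** with ground-truth
  discriminative-region masks, so that training, federated simulation,
  explanation and metric evaluation all run and are validated with no
  downloads.

The neural-network core (forward, backward, Adam) is implemented directly in
NumPy with im2col convolutions; it is small, deterministic under a single
seed, and fast enough to train the family's smaller members on a laptop CPU in
seconds to minutes.

## Worked example

```python
import numpy as np
import fedfer as ff

# the flagship architecture and its complexity figures
arch = ff.ArchitectureConfig((64, 128, 256))
print("parameters:", ff.count_parameters(arch))
print("MFLOPs:", round(ff.count_flops(arch) / 1e6, 1))
print("size (MB):", ff.serialized_size(arch))

# federated training on the bundled synthetic task
data = ff.generate_dataset(ff.SyntheticSpec(n_per_class=200, seed=42))
train, test = ff.train_test_split_synthetic(data, 0.2, seed=42)
small = ff.ArchitectureConfig((16, 32, 64))
cfg = ff.FederatedConfig(n_clients=3, local_epochs=3, n_rounds=4, seed=42)
model, history = ff.run_federated(train, small, cfg, testset=test)
print("round accuracies:", [round(r.global_accuracy, 3) for r in history])

# explain one happy sample and score the explanation
i = int(np.flatnonzero(test.labels == 1)[0])
smap = ff.explain(model, test.images[i], target_class=1)
mask = ff.binarize(smap, 0.5)
print("active pixel ratio:", round(ff.active_pixel_ratio(mask), 3))
print("overlay mass in ground-truth region:",
      round(float(smap.values[test.masks[i]].sum() / smap.values.sum()), 3),
      "(uniform map would give", round(float(test.masks[i].mean()), 3), ")")
dauc = ff.deletion_curve(model, test.images[i, ..., 0], smap, 1, n_steps=50).auc
iauc = ff.insertion_curve(model, test.images[i, ..., 0], smap, 1, n_steps=50).auc
print("IAUC:", round(iauc, 3), " DAUC:", round(dauc, 3))
```

Output:

```
parameters: 1451908
MFLOPs: 107.4
size (MB): 5.54
round accuracies: [0.481, 0.775, 0.869, 0.931]
active pixel ratio: 0.045
overlay mass in ground-truth region: 0.071 (uniform map would give 0.046 )
IAUC: 0.825  DAUC: 0.387
```

Reading the numbers: the (64, 128, 256) model has 1.45 M trainable parameters,
costs ~107.4 MFLOPs per inference and stores in 5.54 MB of float32 weights.
Four FedAvg rounds over three clients lift held-out accuracy to 93%. The
Grad-CAM++ overlay for the happy sample is compact (4.5% of pixels above the
0.5 threshold), places 1.5× more mass on the ground-truth mouth/brow region
than a uniform map would, and its high insertion AUC (0.825) versus lower
deletion AUC (0.387) says the highlighted pixels genuinely drive the model's
confidence.

## Command line

```bash
fedfer synth-gen --n-per-class 100 --seed 42 --out data/
fedfer train-federated --data data/ --clients 3 --rounds 5 --out run/
fedfer explain --checkpoint run/model.npz --image data/happy/happy_00001.png \
       --target-class happy --out explained/
fedfer xai-eval --checkpoint run/model.npz --data data/ --out xai.csv
fedfer report --xai-csv xai.csv --out radar.png
fedfer client-sweep --data data/ --counts 3,6,9,15 --out sweep.csv
```

All commands accept `--config` (a YAML file mirroring
`fedfer.config.RunConfig`) and `--seed`; every source of randomness flows from
that single seed, and a fixed configuration reproduces byte-identical CSV
outputs.

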