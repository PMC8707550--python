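# augforge

Label-preserving image data augmentation for small specialist image
collections — virus micrographs, bark textures, time–frequency glitch maps,
paintings — where deep classifiers overfit and augmentation choice matters.
`augforge` implements eleven augmentation protocols (App1–App11) spanning
five families, plus an ensemble harness that trains one classifier per
protocol and fuses them by the sum rule:

| Family | Protocols | Outputs per image |
|---|---|---|
| Geometric (reflect / scale / rotate / translate / shear) | App1, App2, App3 | 3, 6, 4 |
| Subspace jittering (PCA, DCT) | App4, App5 | 3, 3 |
| Photometric (contrast, sharpen, color shift, HSV jitter, histogram specification, Reinhard transfer) | App6, App7, App8 | 3, 7, 2 |
| Elastic deformation (random displacement fields, raw and low-pass filtered) | App9 | 6 |
| Transform-domain coefficient perturbation (single-level db1 DWT; per-column constant-Q transform) | App10, App11 | 3, 3 |

The transform-domain protocols perturb an invertible representation of each
channel — the four Haar subbands cA, cH, cV, cD, or the stack of per-column
constant-Q coefficient blocks — with one of three operators (random zeroing
at p = 0.5; one additive constant σ_channel + U(−0.5, 0.5); element swaps at
p = 0.05 with five same-class peers) and reconstruct. A training set of N
images becomes N·(1 + k) images for a protocol emitting k outputs; the
ensemble prediction for sample x is argmax_c Σ_m s_m(x, c) over member
softmax scores s_m.

See `docs/methods.md` for the full model description, parameter defaults
and numerical choices.

## Worked example

```python
import augforge as af

# a seeded 3-class synthetic set: oriented gratings, one texture per class
train = af.make_fixtures(n_classes=3, per_class=8, size=(64, 64), channels=3, seed=21)
test  = af.make_fixtures(n_classes=3, per_class=6, size=(64, 64), channels=3, seed=22)

# augment one image with the wavelet protocol
img, label = train[0]
variants = af.augment_image("App10", img, label, train, af.RandomSource(5))
print(len(variants), variants[0].shape)

# train the five-member ensemble and the no-augmentation baseline
cfg = af.TrainConfig(epochs=100)
noda = af.evaluate(af.named_spec("noda"), train, test, cfg, af.RandomSource(5))
ens5 = af.evaluate(af.named_spec("ensda_5"), train, test, cfg, af.RandomSource(5))
print(f"NoDA accuracy:    {noda.fused_accuracy:.3f}")
print(f"EnsDA_5 accuracy: {ens5.fused_accuracy:.3f}")
print("members:", [round(a, 3) for _, a in ens5.member_accuracies])
```

prints

```
3 (64, 64, 3)
NoDA accuracy:    0.778
EnsDA_5 accuracy: 0.778
members: [0.778, 0.667, 0.667, 0.778, 0.778]
```

Three wavelet-perturbed variants of the input image, shape preserved. On
this deliberately tiny problem (24 training images, a one-hidden-layer
backbone) the five fused members — each trained on the originals plus one
protocol's augmented copies (App1–App5) — recover the accuracy of their best
member, 77.8% of the 18 test fixtures; individual members trained on the
harder augmented sets drop to 66.7%. The harness exists to make the
accounting and fusion machinery testable at desk scale — benefits from
augmentation show up at realistic data and backbone sizes, which is what the
pluggable `TrainConfig.backbone` callable is for.

The same workflow is available from the shell:

```
augforge fixtures --classes 3 --per-class 8 --size 64x64 --channels 3 --seed 21 --out train/
augforge augment  --method App10 --in train/ --out augmented/ --seed 5
augforge inspect  --in augmented/App10
augforge evaluate --spec ensda_5 --train train/ --test test/ --seed 5 --out report.csv
```

Grayscale sets are handled throughout, except that the color protocols
(App6–App8) refuse 1-channel input and are automatically excluded from
`ensda_all` for grayscale data.

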