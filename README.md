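# sitrans

Conditional image-to-image translation with **spatial-intensity
transforms** (SIT) for 2-D medical-style images.

Conditional GANs that edit an image along continuous patient attributes
(age, disease severity, ...) are attractive tools for visualizing and
forecasting disease: translate a brain slice "ten years older" and
inspect what changed. On small or noisy clinical datasets, however,
unconstrained generators inject bright/dark artifacts that look exactly
like the biomarkers one is searching for. `sitrans` constrains the
generator's output to

```
G(x, ỹ − y)  =  Φ_V(x + Δx)
```

where `Φ_V = exp(V)` is a **diffeomorphism** obtained by
scaling-and-squaring integration of a stationary velocity field `V`, and
`Δx` is a **sparse intensity difference map** penalized by its L1 norm
`‖Δx‖₁ = (1/|Ω|) Σ_ω |Δx(ω)|`. The deformation captures morphology
(e.g. ventricle expansion with age), the sparse intensity map captures
focal signal change (e.g. white-matter-hyperintensity growth with stroke
severity), and the two components can be visualized separately for a
disentangled view of what the model predicts. The head is parameter-free
beyond the final convolution: zeroing that layer makes the generator the
identity map, a robustness prior an unconstrained generator lacks.

The package provides:

* differentiable transform primitives (velocity integration, bilinear
  warping, composition, Jacobian diagnostics, L1/TV regularizers);
* a conditioned U-Net generator with six output parameterizations
  (`base`, `it`, `st_disp`, `st_diff`, `sit_disp`, `sit_diff`) for
  ablation;
* four training frameworks over any head: a regressor-guided
  autoencoder (`rgae`), a conditional adversarial autoencoder (`caae`),
  an identity-preserving GAN (`ipgan`) and a multi-attribute
  regressor+critic scheme (`stargan`), all with WGAN-GP critics,
  masked-attribute handling and bit-reproducible seeded training;
* evaluation metrics: RMSE/DSSIM on longitudinal pairs, Fréchet feature
  distance and PRD precision/recall (F₁/₈, F₈) with pluggable feature
  embedders, and AgeError from an independent evaluation regressor;
* a synthetic phantom cohort generator with known ground truth
  (attribute-controlled ventricle radius and lesion load, longitudinal
  subjects, missing labels), so everything is testable without any data
  download.

Training runs on a small self-contained numpy automatic-differentiation
engine (second-order capable, as WGAN-GP requires); no GPU framework is
needed. See `docs/methods.md` for the model, numerics and design
choices.

## Worked example

Train SIT-StarGAN on a small synthetic cohort and translate a held-out
phantom toward an older age-like attribute:

```python
import numpy as np
from sitrans import PhantomSpec, TranslationModel, generate_cohort
from sitrans.frameworks import TrainingConfig
from sitrans.networks import CriticConfig, GeneratorConfig
from sitrans.metrics import dssim, rmse
from sitrans.synthetic import measure_ventricle_radius

spec = PhantomSpec.scaled(32)
cohort = generate_cohort(n_subjects=60, timepoints_per_subject=2,
                         missing_rate=0.2, master_seed=7, spec=spec)
train, test = cohort.dataset().split_by_subject(test_fraction=0.1, seed=0)

config = TrainingConfig(
    framework="stargan", parameterization="sit_diff",
    max_iterations=300, batch_size=8, seed=1,
    generator=GeneratorConfig(resolutions=4, bottom_channels=16,
                              n_integration_steps=4, image_size=32),
    critic=CriticConfig(base_channels=8, image_size=32),
)
results = TranslationModel(train, "stargan", config=config).fit()
print(results.summary())

x = test.images[0]
y, mask = test.attribute_arrays()
dec = results.translate(x, y[0], y[0] + np.array([1.0, 0.0]))
print(f"input ventricle radius:  {measure_ventricle_radius(x, spec):.2f} px")
print(f"output ventricle radius: {measure_ventricle_radius(dec.output_image.data[0, 0], spec):.2f} px")
```

Output (numbers from this exact script):

```
Spatial-Intensity Transform Translation Results
=======================================================
framework:          stargan
parameterization:   sit_diff
iterations:         300
batch size:         8
image size:         32
attributes:         2
integration steps:  4
-------------------------------------------------------
loss components (mean of last 10 iterations):
  critic_wgan          -3.90862
  regressor_mse         0.34624
  critic_total         -0.44618
  gen_adv               1.30393
  gen_cc                0.15339
  gen_attr              0.52340
  gen_total             7.58142
=======================================================
input ventricle radius:  3.95 px
output ventricle radius: 4.62 px
```

Full diagnostics from the same run: `max |velocity| = 1.41 px`,
`mean |Δx| = 0.1072`, `RMSE(output, input) = 0.1380`,
`DSSIM(output, input) = 0.1543`.

The summary lists the running loss components of the final iterations
(`critic_wgan` is the Wasserstein critic objective including the
gradient penalty, `gen_attr` the relative-attribute loss, and so on).
The translation returns a `TransformDecomposition`: the output image
plus the velocity field `V` and intensity map `Δx` that produced it —
here the requested +1.0 change in the age-like attribute grows the
measured ventricle radius, while `Δx` stays small and sparse. With only
300 iterations at 32×32 this is a demonstration, not a converged model;
the test suite's parameter-recovery experiment trains 5× longer and
verifies monotone radius sweeps and AgeError on held-out subjects.

Equivalent shell workflow:

```sh
sitrans synth --n-subjects 100 --timepoints 2 --image-size 32 --out cohort/
sitrans train --data cohort/ --out run/ --iterations 300
sitrans translate --checkpoint run/final.pkl --input cohort/00000.png \
                  --target-attrs "a1=+1.0" --out out/
sitrans evaluate --checkpoint run/final.pkl --data cohort/ --out report
```

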