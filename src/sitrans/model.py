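"""Model/Results facade for conditional image-to-image translation.

Typical use::

    cohort = generate_cohort(300, master_seed=7)
    model = TranslationModel(cohort.dataset(), framework="stargan",
                             parameterization="sit_diff", max_iterations=2000)
    results = model.fit()
    print(results.summary())
    dec = results.translate(image, y, y_target)      # image + (V, dx)
    report = results.evaluate(test_dataset, ...)

``TranslationModel`` holds the data and configuration; ``fit`` runs the
adversarial training loop and returns a ``TranslationResults`` carrying
the trained weights, the per-iteration loss log and evaluation helpers.
"""

from __future__ import annotations

from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ImageAttributeDataset
from .frameworks import (
    CheckpointState,
    TrainingConfig,
    fit as _fit,
    log_frame,
    restore_generator,
    translate as _translate,
)
from .metrics import EvaluationReport, evaluate_translation
from .networks import TransformDecomposition


class TranslationModel:
    """A conditional translation model bound to a training dataset."""

    def __init__(
        self,
        dataset: ImageAttributeDataset,
        framework: str = "stargan",
        parameterization: str = "sit_diff",
        config: TrainingConfig | None = None,
        **overrides,
    ):
        if config is None:
            config = TrainingConfig(framework=framework, parameterization=parameterization)
        valid = {f.name for f in dataclass_fields(TrainingConfig)}
        for key, value in overrides.items():
            if key not in valid:
                raise TypeError(f"unknown training option {key!r}")
            setattr(config, key, value)
        config.framework = framework if config.framework is None else config.framework
        self.config = config
        self.dataset = dataset

    @classmethod
    def from_cohort(cls, cohort, **kw) -> "TranslationModel":
        return cls(cohort.dataset(), **kw)

    def fit(
        self,
        checkpoint_dir=None,
        resume_from: CheckpointState | None = None,
        progress: bool = False,
    ) -> "TranslationResults":
        state = _fit(
            self.config,
            self.dataset,
            checkpoint_dir=checkpoint_dir,
            resume_from=resume_from,
            progress=progress,
        )
        return TranslationResults(state, model=self)


class TranslationResults:
    """Fitted translation model: weights, training log, and evaluation."""

    def __init__(self, state: CheckpointState, model: TranslationModel | None = None):
        self.state = state
        self.model = model
        self._generator = None

    # -- access --------------------------------------------------------
    @property
    def log(self) -> pd.DataFrame:
        return log_frame(self.state)

    @property
    def generator(self):
        if self._generator is None:
            self._generator = restore_generator(self.state)
        return self._generator

    # -- inference -----------------------------------------------------
    def translate(self, x, y, y_target) -> TransformDecomposition:
        """Translate image(s); SIT heads also return V and dx."""
        return _translate(self.generator, x, y, y_target)

    def attribute_sweep(
        self, x, y, attribute_index: int, deltas
    ) -> list[TransformDecomposition]:
        """Translate one image across a range of changes in one attribute."""
        y = np.asarray(y, dtype=float)
        out = []
        for d in deltas:
            yt = y.copy()
            base = 0.0 if not np.isfinite(yt[attribute_index]) else yt[attribute_index]
            yt[attribute_index] = base + d
            out.append(self.translate(x, y, yt))
        return out

    # -- evaluation ----------------------------------------------------
    def evaluate(
        self,
        dataset: ImageAttributeDataset | None = None,
        embedder=None,
        eval_regressor=None,
        scaler=None,
        seed: int = 0,
    ) -> EvaluationReport:
        if dataset is None:
            if self.model is None:
                raise ValueError("no dataset available; pass one explicitly")
            dataset = self.model.dataset

        def translate_fn(imgs, y, y_mask, yt, yt_mask):
            yn = np.where(y_mask, y, np.nan)
            ytn = np.where(yt_mask, yt, np.nan)
            dec = _translate(self.generator, imgs, yn, ytn)
            return dec.output_image.data[:, 0]

        return evaluate_translation(
            translate_fn, dataset, embedder=embedder,
            eval_regressor=eval_regressor, scaler=scaler, seed=seed,
        )

    # -- reporting -----------------------------------------------------
    def summary(self, tail: int = 10) -> str:
        cfg = self.state.config
        df = self.log
        lines = [
            "Spatial-Intensity Transform Translation Results",
            "=" * 55,
            f"framework:          {cfg.framework}",
            f"parameterization:   {cfg.parameterization}",
            f"iterations:         {self.state.iteration}",
            f"batch size:         {cfg.batch_size}",
            f"image size:         {self.state.generator_config.image_size}",
            f"attributes:         {self.state.generator_config.m_attributes}",
            f"integration steps:  {self.state.generator_config.n_integration_steps}",
            "-" * 55,
            f"loss components (mean of last {min(tail, len(df))} iterations):",
        ]
        if len(df):
            tail_df = df.drop(columns=["iteration"]).tail(tail).mean()
            for name, value in tail_df.items():
                lines.append(f"  {name:<20s} {value: .5f}")
        lines.append("=" * 55)
        return "\n".join(lines)

    def __repr__(self):
        cfg = self.state.config
        return (
            f"<TranslationResults {cfg.framework}/{cfg.parameterization} "
            f"iter={self.state.iteration}>"
        )

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        self.state.save(path)

    @classmethod
    def load(cls, path) -> "TranslationResults":
        return cls(CheckpointState.load(Path(path)))
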