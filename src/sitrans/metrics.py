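"""Evaluation metrics: pairwise fidelity, distributional fidelity, and
attribute matching.

* RMSE and DSSIM compare a predicted image to a ground-truth image; the
  DSSIM of identical images is 0 and that of patchwise-uncorrelated
  images is 0.5.
* The Frechet feature distance and PRD precision/recall (F_1/8, F_8)
  compare the *distributions* of feature embeddings of generated and
  real image sets.  The embedder is pluggable: by default a small
  encoder trained on the synthetic cohort (or a seeded random
  projection), so reported values are embedder-relative and the report
  records the embedder's provenance.
* AgeError is the mean +/- sd difference between an independent
  evaluation regressor's estimate on translated images and the target
  value, de-normalized to the attribute's natural units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .data import AttributeScaler, ImageAttributeDataset
from .fields import ScalarField2D

SSIM_WINDOW = 7  # uniform window; C1=(0.01 L)^2, C2=(0.03 L)^2 with L = range


def _values(a) -> np.ndarray:
    return a.values if isinstance(a, ScalarField2D) else np.asarray(a, dtype=float)


def rmse(a, b) -> float:
    """Root mean squared pixel difference."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError("image shapes differ")
    return float(np.sqrt(((va - vb) ** 2).mean()))


def dssim(a, b, data_range: float = 1.0) -> float:
    """Structural dissimilarity (1 - SSIM) / 2 over sliding 7x7 patches."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError("image shapes differ")
    ssim = structural_similarity(
        va, vb, win_size=SSIM_WINDOW, gaussian_weights=False, data_range=data_range
    )
    return float((1.0 - ssim) / 2.0)


# ----------------------------------------------------------------------
# feature embedders
# ----------------------------------------------------------------------

@dataclass
class FeatureEmbedder:
    """Deterministic image -> d-vector map with provenance metadata."""

    fn: callable
    dim: int
    provenance: str

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Embed an (N, H, W) stack into (N, d) features."""
        out = self.fn(np.asarray(images, dtype=float))
        return np.asarray(out, dtype=float).reshape(len(images), self.dim)


def random_projection_embedder(image_size: int, dim: int = 32, seed: int = 0) -> FeatureEmbedder:
    """Seeded Gaussian random projection of raw pixels (fast fallback)."""
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(image_size * image_size, dim)) / np.sqrt(image_size * image_size)

    def fn(images):
        return images.reshape(len(images), -1) @ W

    return FeatureEmbedder(fn, dim, f"random_projection(seed={seed})")


def trained_encoder_embedder(
    dataset: ImageAttributeDataset, seed: int = 0, steps: int = 200, lr: float = 1e-3
) -> FeatureEmbedder:
    """Small convolutional encoder trained on the cohort with an
    attribute-regression objective; features are the penultimate layer."""
    from . import nn
    from .autodiff import Tensor
    from .networks import CriticConfig, Regressor
    from .objectives import regressor_mse

    cfg = CriticConfig(
        m_attributes=dataset.m, image_size=dataset.image_size,
        base_channels=8, n_down_blocks=2, hidden_dim=32,
    )
    R = Regressor(cfg, seed=seed)
    opt = nn.Adam(R.parameters(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    vals, mask = dataset.attribute_arrays()
    for _ in range(steps):
        idx = rng.integers(0, len(dataset), size=min(8, len(dataset)))
        x = Tensor(dataset.images[idx][:, None])
        loss = regressor_mse(R, x, vals[idx], mask[idx])
        nn.step_module(opt, R, loss)
    R.eval()

    def fn(images):
        from sitrans import autodiff as ad

        feats = []
        for i in range(0, len(images), 32):
            x = Tensor(images[i : i + 32][:, None])
            h = x
            for k in range(R.config.n_down_blocks):
                h = ad.relu(getattr(R, f"bn{k}")(getattr(R, f"conv{k}")(h)))
                h = nn.max_pool2x2(h)
            h = ad.relu(R.fc(h.reshape(h.shape[0], -1)))
            feats.append(h.data)
        return np.concatenate(feats, axis=0)

    return FeatureEmbedder(fn, cfg.hidden_dim, f"trained_encoder(seed={seed},steps={steps})")


# ----------------------------------------------------------------------
# distributional metrics
# ----------------------------------------------------------------------

def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, clipping
    negative eigenvalues at zero (numerical guard)."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_feature_distance(features_real, features_gen) -> float:
    """Frechet distance between Gaussian fits of two feature sets:
    ||mu1 - mu2||^2 + tr(S1 + S2 - 2 (S1 S2)^(1/2))."""
    fa = np.asarray(features_real, dtype=float)
    fb = np.asarray(features_gen, dtype=float)
    d = fa.shape[1]
    mu1, mu2 = fa.mean(axis=0), fb.mean(axis=0)
    s1 = np.cov(fa, rowvar=False)
    s2 = np.cov(fb, rowvar=False)
    if min(len(fa), len(fb)) < 2 * d:  # regularize small-sample covariances
        eps = 1e-6 * np.eye(d)
        s1, s2 = s1 + eps, s2 + eps
    s1h = _sqrtm_psd(s1)
    covmean = _sqrtm_psd(s1h @ s2 @ s1h)
    fid = float(((mu1 - mu2) ** 2).sum() + np.trace(s1) + np.trace(s2) - 2 * np.trace(covmean))
    return max(fid, 0.0)


def prd_curve(hist_real: np.ndarray, hist_gen: np.ndarray, angle_resolution: int = 1001):
    """PRD curve over cluster histograms: pairs (precision, recall) for
    slopes lambda = tan(theta), theta in (0, pi/2)."""
    p = np.asarray(hist_real, dtype=float)
    q = np.asarray(hist_gen, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    angles = np.linspace(1e-6, np.pi / 2 - 1e-6, angle_resolution)
    lam = np.tan(angles)
    precision = np.minimum(lam[:, None] * p[None, :], q[None, :]).sum(axis=1)
    recall = precision / lam
    return precision, recall


def _f_beta(precision, recall, beta):
    b2 = beta**2
    denom = b2 * precision + recall
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (1 + b2) * precision * recall / denom
    return float(np.nanmax(np.where(denom > 0, f, 0.0)))


def prd_scores(
    features_real,
    features_gen,
    n_clusters: int = 20,
    angle_resolution: int = 1001,
    seed: int = 0,
) -> tuple[float, float]:
    """Precision/recall for distributions: (F_1/8, F_8).

    Modes are estimated by k-means clustering the pooled feature sets;
    the two histograms over cluster assignments define the PRD curve.
    """
    from sklearn.cluster import KMeans

    fa = np.asarray(features_real, dtype=float)
    fb = np.asarray(features_gen, dtype=float)
    n_clusters = int(min(n_clusters, max(2, (len(fa) + len(fb)) // 4)))
    pooled = np.concatenate([fa, fb], axis=0)
    km = KMeans(n_clusters=n_clusters, n_init=5, random_state=seed).fit(pooled)
    la = km.labels_[: len(fa)]
    lb = km.labels_[len(fa):]
    hist_real = np.bincount(la, minlength=n_clusters) + 1e-12
    hist_gen = np.bincount(lb, minlength=n_clusters) + 1e-12
    precision, recall = prd_curve(hist_real, hist_gen, angle_resolution)
    return _f_beta(precision, recall, 1.0 / 8.0), _f_beta(precision, recall, 8.0)


# ----------------------------------------------------------------------
# attribute matching
# ----------------------------------------------------------------------

def age_error(
    eval_regressor,
    generated_images: np.ndarray,
    target_values_normalized: np.ndarray,
    scaler: AttributeScaler,
    attribute_index: int = 0,
) -> tuple[float, float]:
    """Mean and sd of (estimated - target) in the attribute's natural
    units.  ``eval_regressor`` maps an (N, H, W) stack to normalized
    attribute predictions and must be trained independently of any
    regressor used during translation training."""
    preds = np.asarray(eval_regressor(generated_images), dtype=float)
    if preds.ndim == 2:
        preds = preds[:, attribute_index]
    sd = scaler.sd[attribute_index]
    mean = scaler.mean[attribute_index]
    est_years = preds * sd + mean
    target_years = np.asarray(target_values_normalized, dtype=float) * sd + mean
    diff = est_years - target_years
    return float(diff.mean()), float(diff.std())


def longitudinal_pairing(
    dataset: ImageAttributeDataset,
    max_pairs: int = 5,
    min_gap_years: float = 1.0,
    seed: int = 0,
) -> list[tuple[int, int, np.ndarray]]:
    """Per subject, up to ``max_pairs`` ordered (earlier, later) scan
    pairs separated by at least ``min_gap_years``; returns index pairs
    with the masked attribute difference."""
    rng = np.random.default_rng(seed)
    vals, mask = dataset.attribute_arrays()
    pairs = []
    for s in np.unique(dataset.subjects):
        idx = np.where(dataset.subjects == s)[0]
        if idx.size < 2:
            continue
        order = idx[np.argsort(dataset.timepoints[idx])]
        candidates = [
            (int(i), int(j))
            for a, i in enumerate(order)
            for j in order[a + 1 :]
            if dataset.timepoints[j] - dataset.timepoints[i] >= min_gap_years
        ]
        if len(candidates) > max_pairs:
            sel = rng.choice(len(candidates), size=max_pairs, replace=False)
            candidates = [candidates[k] for k in sorted(sel)]
        for i, j in candidates:
            both = mask[i] & mask[j]
            dy = np.where(both, vals[j] - vals[i], 0.0)
            pairs.append((i, j, dy))
    return pairs


# ----------------------------------------------------------------------
# full evaluation
# ----------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Aggregate metrics plus the per-item values they derive from."""

    rmse_mean: float | None = None
    rmse_sd: float | None = None
    dssim_mean: float | None = None
    dssim_sd: float | None = None
    fid: float | None = None
    prd_precision: float | None = None  # F_1/8
    prd_recall: float | None = None  # F_8
    age_error_mean: float | None = None
    age_error_sd: float | None = None
    n_pairs: int = 0
    n_real: int = 0
    n_generated: int = 0
    embedder_provenance: str = ""
    seed: int = 0
    per_pair: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self):
        d = {k: v for k, v in self.__dict__.items() if k != "per_pair"}
        return d

    def save(self, path_prefix) -> None:
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        if self.per_pair is not None:
            self.per_pair.to_csv(f"{prefix}_pairs.csv", index=False)


def evaluate_translation(
    translate_fn,
    dataset: ImageAttributeDataset,
    embedder: FeatureEmbedder | None = None,
    eval_regressor=None,
    scaler: AttributeScaler | None = None,
    seed: int = 0,
    max_pairs: int = 5,
    min_gap_years: float = 1.0,
) -> EvaluationReport:
    """Run the full metric suite against a trained translator.

    ``translate_fn(images, y, y_mask, y_target, yt_mask) -> images``
    performs the batched translation.  Longitudinal RMSE/DSSIM use the
    dataset's subject/timepoint structure; FID/PRD compare the set of
    translated images against the real images; AgeError needs
    ``eval_regressor`` and ``scaler``.
    """
    vals, mask = dataset.attribute_arrays()
    report = EvaluationReport(seed=seed, n_real=len(dataset))

    pairs = longitudinal_pairing(dataset, max_pairs, min_gap_years, seed)
    rows = []
    generated = []
    targets = []
    if pairs:
        src = np.stack([dataset.images[i] for i, _j, _d in pairs])
        preds = translate_fn(
            src,
            np.stack([vals[i] for i, _j, _d in pairs]),
            np.stack([mask[i] for i, _j, _d in pairs]),
            np.stack([vals[j] for _i, j, _d in pairs]),
            np.stack([mask[j] for _i, j, _d in pairs]),
        )
        for k, (i, j, _dy) in enumerate(pairs):
            rows.append(
                {
                    "source": i,
                    "target": j,
                    "rmse": rmse(preds[k], dataset.images[j]),
                    "dssim": dssim(preds[k], dataset.images[j]),
                }
            )
        generated.append(preds)
        targets.append(np.stack([vals[j] for _i, j, _d in pairs]))
        per_pair = pd.DataFrame(rows)
        report.per_pair = per_pair
        report.n_pairs = len(pairs)
        report.rmse_mean = float(per_pair["rmse"].mean())
        report.rmse_sd = float(per_pair["rmse"].std(ddof=0))
        report.dssim_mean = float(per_pair["dssim"].mean())
        report.dssim_sd = float(per_pair["dssim"].std(ddof=0))
    else:
        # counterfactual setting: translate every scan to a permuted target
        rng = np.random.default_rng(seed)
        tidx = rng.permutation(len(dataset))
        preds = translate_fn(dataset.images, vals, mask, vals[tidx], mask[tidx])
        generated.append(preds)
        targets.append(vals[tidx])

    gen_images = np.concatenate(generated, axis=0)
    gen_targets = np.concatenate(targets, axis=0)
    report.n_generated = len(gen_images)

    if embedder is not None:
        f_real = embedder.embed(dataset.images)
        f_gen = embedder.embed(gen_images)
        report.fid = frechet_feature_distance(f_real, f_gen)
        report.prd_precision, report.prd_recall = prd_scores(f_real, f_gen, seed=seed)
        report.embedder_provenance = embedder.provenance

    if eval_regressor is not None and scaler is not None:
        report.age_error_mean, report.age_error_sd = age_error(
            eval_regressor, gen_images, gen_targets[:, 0], scaler
        )
    return report
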