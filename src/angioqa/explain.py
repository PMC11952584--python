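"""Per-case local surrogate explanations of the occlusion classifier.

For one aneurysm, the black-box probability of failure to occlude is probed
by Gaussian perturbation of the case's features (scaled by the training-set
standard deviation of each feature), the black box is scored on the perturbed
sample, and a locality-weighted ridge regression of the scores on the
standardized features is fitted around the case.  The regression coefficients
times the case's standardized feature values give signed contributions in
probability units: a positive contribution pushes the prediction toward
failure to occlude, a negative one toward successful occlusion.  Only the
top features by absolute contribution are reported (default six, to keep the
per-case display readable).

Sample weights follow the usual locality kernel ``exp(-d^2 / kernel_width^2)``
with ``d`` the Euclidean distance to the case in standardized space and
kernel width ``0.75 * sqrt(n_features)`` by default.  Perturbation is
continuous (no quartile discretization): all model features are continuous
post/pre ratios.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.linear_model import Ridge

from .tdc import InvalidInputError


@dataclasses.dataclass(frozen=True)
class FeatureStats:
    """Per-feature training-set location/scale used for perturbation and
    standardization."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, float)
        sds = np.asarray(self.sds, float)
        if means.shape != sds.shape or means.ndim != 1 or len(self.names) != means.size:
            raise InvalidInputError("names, means and sds must align")
        if np.any(sds <= 0):
            raise InvalidInputError("feature sds must be > 0")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @classmethod
    def from_table(cls, table, feature_cols) -> "FeatureStats":
        X = table[list(feature_cols)].to_numpy(float)
        sds = X.std(axis=0, ddof=0)
        return cls(tuple(feature_cols), X.mean(axis=0), np.where(sds > 0, sds, 1.0))


@dataclasses.dataclass(frozen=True)
class ExplainConfig:
    n_samples: int = 2000
    kernel_width: float | None = None  # default 0.75 * sqrt(n_features)
    top_k: int = 6
    perturbation_scale: float = 1.0  # in units of training-set sd
    ridge_alpha: float = 1.0
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class Explanation:
    """Signed feature contributions for one case, positive-class oriented."""

    base_rate: float
    predicted_probability: float
    contributions: tuple[tuple[str, float], ...]  # sorted by |weight| desc
    top_k: int = 6


def perturb(
    instance: np.ndarray,
    n_samples: int,
    feature_stats: FeatureStats,
    seed: int = 0,
    scale: float = 1.0,
) -> np.ndarray:
    """Gaussian perturbation sample around one case.

    Row 0 is the unperturbed instance; the remaining rows add zero-mean
    Gaussian noise with per-feature sd ``scale * training sd``.
    """
    instance = np.asarray(instance, float)
    if instance.shape != feature_stats.means.shape:
        raise InvalidInputError("instance does not match feature stats")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11E]))
    noise = rng.normal(0.0, 1.0, size=(n_samples, instance.size)) * (scale * feature_stats.sds)
    samples = instance[None, :] + noise
    samples[0] = instance
    return samples


def fit_local_surrogate(
    samples: np.ndarray,
    model_probs: np.ndarray,
    instance: np.ndarray,
    feature_stats: FeatureStats,
    kernel_width: float | None = None,
    k_features: int = 6,
    ridge_alpha: float = 1.0,
) -> Explanation:
    """Locality-weighted ridge fit of black-box scores around one case.

    Contribution of feature j = surrogate coefficient (per standardized unit)
    times the case's standardized value, i.e. the linear-model share of the
    displacement from the local mean prediction.  Constant scores yield an
    empty effective explanation (all contributions zero).
    """
    samples = np.asarray(samples, float)
    probs = np.asarray(model_probs, float).ravel()
    instance = np.asarray(instance, float)
    if samples.shape[0] != probs.size:
        raise InvalidInputError("one probability per sample row is required")
    n_feat = feature_stats.means.size
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(n_feat)

    Z = (samples - feature_stats.means) / feature_stats.sds
    z0 = (instance - feature_stats.means) / feature_stats.sds
    d2 = ((Z - z0) ** 2).sum(axis=1)
    weights = np.exp(-d2 / kernel_width**2)

    if np.ptp(probs) == 0:
        coefs = np.zeros(n_feat)
    else:
        reg = Ridge(alpha=ridge_alpha)
        reg.fit(Z, probs, sample_weight=weights)
        coefs = reg.coef_

    contrib = coefs * z0
    order = np.argsort(-np.abs(contrib))[:k_features]
    contributions = tuple((feature_stats.names[i], float(contrib[i])) for i in order)
    base_rate = float(np.average(probs, weights=weights))
    return Explanation(
        base_rate=base_rate,
        predicted_probability=float(probs[0]),
        contributions=contributions,
        top_k=k_features,
    )


def explain_case(
    model,
    instance: np.ndarray,
    training_stats: FeatureStats,
    cfg: ExplainConfig = ExplainConfig(),
) -> Explanation:
    """Perturb -> score -> fit surrogate for one case (deterministic per seed).

    ``model`` is anything with ``predict_proba(X) -> P(failure)`` per row.
    """
    samples = perturb(instance, cfg.n_samples, training_stats, cfg.seed, cfg.perturbation_scale)
    probs = np.asarray(model.predict_proba(samples), float).ravel()
    return fit_local_surrogate(
        samples,
        probs,
        instance,
        training_stats,
        kernel_width=cfg.kernel_width,
        k_features=cfg.top_k,
        ridge_alpha=cfg.ridge_alpha,
    )


def plot_explanation(explanation: Explanation, ax=None, title: str | None = None):
    """Horizontal-bar display of the top contributions (positive bars push
    toward failure to occlude)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    names = [n for n, _ in explanation.contributions][::-1]
    vals = [v for _, v in explanation.contributions][::-1]
    colors = ["tab:red" if v > 0 else "tab:green" for v in vals]
    ax.barh(names, vals, color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("contribution to P(failure to occlude)")
    if title:
        ax.set_title(title)
    return ax
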