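"""Per-feature attribution for the boosted-tree classifier.

Two complementary views:

* :func:`global_attribution` — exact per-sample Shapley-value
  attributions computed from the tree ensemble's structure (TreeSHAP,
  via xgboost's ``pred_contribs``), on the margin (log-odds) scale where
  the ensemble is additive.  Attributions satisfy local accuracy: for
  every sample they sum (with the base value) to the model's margin
  output.  Global importance is the mean absolute attribution per
  feature.

* :func:`local_explanation` — a local surrogate explanation in the
  LIME style: the model is probed with seeded perturbations around one
  instance, features are discretized into quartile bins of a background
  sample, and a weighted ridge regression on bin-membership indicators
  yields signed per-feature weights together with the feature-value
  range over which each weight applies.  Positive weight supports the
  ac4C call, negative opposes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from sklearn.linear_model import Ridge

from .encoders import FeatureMatrix
from .model import TrainedModel, _check_compat, predict_proba


@dataclass
class AttributionReport:
    """Global Shapley-value attribution summary.

    ``top_features`` holds the ``top_k`` highest-ranked features as
    dicts with the feature name, its global importance (mean |phi|) and
    the correlation between feature value and signed attribution (the
    red/high-blue/low relationship of a beeswarm summary).
    """

    feature_names: list[str]
    global_importance: np.ndarray
    per_sample_attributions: np.ndarray | None
    base_value: float
    top_k: int
    top_features: list[dict] = field(default_factory=list)

    def top_feature_names(self) -> list[str]:
        return [f["feature"] for f in self.top_features]


def shap_values(model: TrainedModel, X: FeatureMatrix) -> tuple[np.ndarray, float]:
    """Per-sample Shapley attributions (n x p) and the base value,
    on the margin scale."""
    _check_compat(model, X)
    if not isinstance(model.booster, xgb.XGBClassifier):
        raise ValueError(
            "Shapley attribution requires the boosted-tree model, "
            f"got {type(model.booster).__name__}"
        )
    dmat = xgb.DMatrix(X.values)
    contribs = model.booster.get_booster().predict(dmat, pred_contribs=True)
    return contribs[:, :-1], float(contribs[0, -1]) if len(contribs) else 0.0


def global_attribution(
    model: TrainedModel, X: FeatureMatrix, top_k: int = 20
) -> AttributionReport:
    """Rank features by mean absolute Shapley attribution over ``X``."""
    phi, base = shap_values(model, X)
    importance = np.abs(phi).mean(axis=0)
    order = np.argsort(importance)[::-1]
    top_k = min(top_k, len(model.feature_names))
    top = []
    for j in order[:top_k]:
        values = X.values[:, j]
        # sign relationship between feature value and attribution
        if values.std() > 0 and phi[:, j].std() > 0:
            corr = float(np.corrcoef(values, phi[:, j])[0, 1])
        else:
            corr = 0.0
        top.append(
            {
                "feature": model.feature_names[j],
                "mean_abs_attribution": float(importance[j]),
                "value_attribution_corr": corr,
            }
        )
    return AttributionReport(
        feature_names=list(model.feature_names),
        global_importance=importance,
        per_sample_attributions=phi,
        base_value=base,
        top_k=top_k,
        top_features=top,
    )


@dataclass
class LocalExplanation:
    """Signed surrogate weights for one instance.

    ``feature_weights`` is a list of (feature name, signed weight,
    active-range description) tuples, largest |weight| first.
    """

    sequence_id: str
    feature_weights: list[tuple[str, float, str]]
    predicted_probability: float
    intercept: float
    seed: int


def _quartile_bins(column: np.ndarray) -> np.ndarray:
    """Interior quartile edges of a background column (deduplicated)."""
    edges = np.unique(np.quantile(column, [0.25, 0.5, 0.75]))
    return edges


def _bin_of(value: float, edges: np.ndarray) -> int:
    return int(np.searchsorted(edges, value, side="left"))


def _range_description(name: str, b: int, edges: np.ndarray) -> str:
    if len(edges) == 0:
        return f"{name} = const"
    if b == 0:
        return f"{name} <= {edges[0]:.4g}"
    if b == len(edges):
        return f"{name} > {edges[-1]:.4g}"
    return f"{edges[b - 1]:.4g} < {name} <= {edges[b]:.4g}"


def local_explanation(
    model: TrainedModel,
    x: np.ndarray,
    num_features: int = 10,
    seed: int = 42,
    background: FeatureMatrix | None = None,
    n_samples: int = 5000,
    sequence_id: str = "",
) -> LocalExplanation:
    """Explain one prediction with a weighted local surrogate.

    ``background`` provides the reference distribution for quartile
    discretization and for drawing replacement values; typically the
    training (or any representative) feature matrix.
    """
    if background is None:
        raise ValueError(
            "local_explanation requires a background FeatureMatrix for "
            "discretization"
        )
    x = np.asarray(x, dtype=float).ravel()
    p = len(model.feature_names)
    if x.shape[0] != p:
        raise ValueError(f"row has {x.shape[0]} features, model expects {p}")
    if background.n_features != p:
        raise ValueError("background width does not match the model")

    rng = np.random.default_rng(seed)
    bg = background.values
    edges = [_quartile_bins(bg[:, j]) for j in range(p)]
    n_bins = np.array([len(e) + 1 for e in edges])
    x_bins = np.array([_bin_of(x[j], edges[j]) for j in range(p)])

    # bin membership per background row, for empirical replacement draws
    bg_bins = np.stack(
        [np.searchsorted(edges[j], bg[:, j], side="left") for j in range(p)], axis=1
    )

    # perturbations: per feature, pick a bin uniformly; z = same bin as x
    sampled_bins = (rng.random((n_samples, p)) * n_bins).astype(int)
    sampled_bins[0] = x_bins  # first row is the instance itself
    z = (sampled_bins == x_bins).astype(float)

    values = np.empty((n_samples, p))
    for j in range(p):
        same = sampled_bins[:, j] == x_bins[j]
        values[same, j] = x[j]
        for b in range(n_bins[j]):
            rows = np.flatnonzero(~same & (sampled_bins[:, j] == b))
            if rows.size == 0:
                continue
            pool = bg[bg_bins[:, j] == b, j]
            if pool.size == 0:
                values[rows, j] = x[j]
                z[rows, j] = 1.0
            else:
                values[rows, j] = pool[rng.integers(0, pool.size, rows.size)]

    probe = FeatureMatrix(
        scheme=model.scheme, feature_names=model.feature_names, values=values
    )
    target = predict_proba(model, probe)

    kernel_width = 0.75 * np.sqrt(p)
    d_sq = (1.0 - z).sum(axis=1)
    weights = np.exp(-d_sq / kernel_width**2)

    surrogate = Ridge(alpha=1.0)
    surrogate.fit(z, target, sample_weight=weights)
    order = np.argsort(np.abs(surrogate.coef_))[::-1][:num_features]

    refit = Ridge(alpha=1.0)
    refit.fit(z[:, order], target, sample_weight=weights)
    feature_weights = [
        (
            model.feature_names[j],
            float(w),
            _range_description(model.feature_names[j], x_bins[j], edges[j]),
        )
        for j, w in zip(order, refit.coef_)
    ]
    return LocalExplanation(
        sequence_id=sequence_id,
        feature_weights=feature_weights,
        predicted_probability=float(target[0]),
        intercept=float(refit.intercept_),
        seed=seed,
    )


def plot_global_attribution(report: AttributionReport, path) -> None:
    """Optional bar chart of the top-ranked features (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = report.top_feature_names()[::-1]
    vals = [f["mean_abs_attribution"] for f in report.top_features][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(names) + 1))
    ax.barh(names, vals)
    ax.set_xlabel("mean |Shapley attribution| (log-odds)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
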