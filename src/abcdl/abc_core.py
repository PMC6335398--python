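"""ABC rejection on learned summaries, model posteriors and parameter
posteriors.

The rejection step standardizes every summary coordinate by its median
absolute deviation across all simulations, ranks simulations by Euclidean
distance to the observed summary and retains the closest ``n_accept``
(default 1,000 of 100,000).  Model choice refines the retained-label
frequencies with a multinomial-logistic regression of label on summary,
evaluated at the observed summary; parameter estimation applies the
Beaumont local-linear adjustment with an Epanechnikov kernel on distance,
run on a transformed scale per parameter class (log for times, sizes and
rates; logit for admixture fractions) and back-transformed.

``ABCModelChoice`` and ``ABCParameterEstimator`` expose the two inference
modes as scikit-learn-style estimators; the module-level operations are
thin wrappers kept for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from . import dlsum
from .coalsim import JointSFS
from .dlsum import NoiseSpec, TrainingSet

__all__ = [
    "AbcConfig",
    "AcceptedSet",
    "ModelPosterior",
    "ParameterPosterior",
    "ABCModelChoice",
    "ABCParameterEstimator",
    "mad_standardize",
    "rejection_sample",
    "mnlogistic_model_posterior",
    "loclinear_adjust",
    "posterior_summary",
    "cross_validation_confusion",
    "bayes_factor",
    "default_transform",
]


@dataclass(frozen=True)
class AbcConfig:
    n_sims: int = 100_000
    n_accept: int = 1_000
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if not 0 < self.n_accept <= self.n_sims:
            raise ValueError("need 0 < n_accept <= n_sims")
        if self.distance != "euclidean":
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass
class AcceptedSet:
    """Retained simulations, sorted by nondecreasing distance."""

    indices: np.ndarray
    distances: np.ndarray
    ss: np.ndarray                       # standardized summaries of retained sims
    observed_ss: np.ndarray              # standardized observed summary
    labels: np.ndarray | None = None
    params: np.ndarray | None = None
    param_names: list[str] | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be sorted nondecreasing")


@dataclass
class ModelPosterior:
    probabilities: dict[str, float]
    method: str                          # mnlogistic | rejection-frequency

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9 or min(self.probabilities.values()) < -1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    def map_label(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


@dataclass
class ParameterPosterior:
    param_names: list[str]
    samples: np.ndarray                  # n_accept x p, adjusted scale
    weights: np.ndarray
    adjusted: bool


def bayes_factor(posterior: ModelPosterior, a: str, b: str) -> float:
    """Posterior-probability ratio P(a)/P(b) (how many times more likely)."""
    return posterior.probabilities[a] / posterior.probabilities[b]


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

def mad_standardize(sims: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate (median, MAD) across simulations; MAD floor avoids
    division by zero on constant coordinates."""
    center = np.median(sims, axis=0)
    mad = np.median(np.abs(sims - center), axis=0)
    mad[mad < 1e-12] = 1.0
    return center, mad


def rejection_sample(observed_ss: np.ndarray, sims: np.ndarray, cfg: AbcConfig,
                     labels: np.ndarray | None = None,
                     params: np.ndarray | None = None,
                     param_names: Sequence[str] | None = None) -> AcceptedSet:
    """Retain the ``n_accept`` simulations closest to the observed summary.

    Distances are Euclidean after MAD standardization of each coordinate
    (computed from the simulations themselves).  Ties at the acceptance
    boundary break by simulation index, so the retained set is deterministic.
    """
    sims = np.atleast_2d(np.asarray(sims, dtype=float))
    observed_ss = np.asarray(observed_ss, dtype=float).reshape(-1)
    if cfg.n_accept > len(sims):
        raise ValueError("n_accept exceeds the number of simulations")
    center, scale = mad_standardize(sims)
    zs = (sims - center) / scale
    zo = (observed_ss - center) / scale
    dist = np.sqrt(((zs - zo) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:cfg.n_accept]
    return AcceptedSet(
        indices=order, distances=dist[order], ss=zs[order], observed_ss=zo,
        labels=None if labels is None else np.asarray(labels)[order],
        params=None if params is None else np.asarray(params, dtype=float)[order],
        param_names=list(param_names) if param_names is not None else None)


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

def _frequency_posterior(labels: np.ndarray, classes: np.ndarray) -> dict[str, float]:
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    probs = counts / counts.sum()
    return {str(c): float(p) for c, p in zip(classes, probs)}


def mnlogistic_model_posterior(accepted: AcceptedSet,
                               observed_ss: np.ndarray | None = None) -> ModelPosterior:
    """Multinomial-logistic posterior model probabilities at the observed
    summary, with a rejection-frequency fallback on degenerate fits."""
    if accepted.labels is None:
        raise ValueError("accepted set carries no model labels")
    labels = accepted.labels
    classes = np.unique(labels)
    if len(classes) == 1:
        return ModelPosterior({str(classes[0]): 1.0}, "rejection-frequency")
    zo = accepted.observed_ss if observed_ss is None else np.asarray(observed_ss)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # effectively unregularized, like the classical multinomial fit
            lr = LogisticRegression(C=1e6, max_iter=2000)
            lr.fit(accepted.ss, labels)
            probs = lr.predict_proba(zo.reshape(1, -1))[0]
        if not np.all(np.isfinite(probs)):
            raise ValueError("non-finite probabilities")
        out = {str(c): 0.0 for c in classes}
        out.update({str(c): float(p) for c, p in zip(lr.classes_, probs)})
        total = sum(out.values())
        return ModelPosterior({k: v / total for k, v in out.items()}, "mnlogistic")
    except Exception as exc:   # degrade, never fail model choice
        warnings.warn(f"mnlogistic fit failed ({exc}); falling back to "
                      "rejection frequencies")
        return ModelPosterior(_frequency_posterior(labels, classes),
                              "rejection-frequency")


# ---------------------------------------------------------------------------
# parameter adjustment
# ---------------------------------------------------------------------------

_LOGIT_EPS = 1e-9


def default_transform(name: str) -> str:
    """Scale on which a parameter is adjusted, by naming convention:
    fractions (``f_*``) on logit scale, times/sizes/rates on log scale."""
    if name.startswith("f_"):
        return "logit"
    if name.startswith(("t_", "n_", "m_")):
        return "log"
    return "none"


def _fwd(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "log":
        return np.log(np.maximum(x, 1e-300))
    if kind == "logit":
        x = np.clip(x, _LOGIT_EPS, 1 - _LOGIT_EPS)
        return np.log(x / (1 - x))
    return x


def _inv(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "log":
        return np.exp(x)
    if kind == "logit":
        return 1.0 / (1.0 + np.exp(-x))
    return x


def epanechnikov_weights(distances: np.ndarray) -> np.ndarray:
    dmax = distances.max()
    if dmax == 0:
        return np.ones_like(distances)
    w = 1.0 - (distances / dmax) ** 2
    # the boundary simulation gets weight 0; keep it infinitesimally positive
    return np.maximum(w, 1e-12)


def loclinear_adjust(accepted: AcceptedSet,
                     observed_ss: np.ndarray | None = None,
                     transforms: Mapping[str, str] | None = None) -> ParameterPosterior:
    """Beaumont local-linear regression adjustment of retained parameters.

    Each parameter (on its transformed scale) is regressed on the summary
    coordinates with Epanechnikov kernel weights on distance; retained draws
    are shifted by the fitted linear trend to the observed summary:
    ``theta* = theta - B (ss - ss_obs)``.  A rank-deficient design degrades
    to the unadjusted rejection posterior with a warning.
    """
    if accepted.params is None:
        raise ValueError("accepted set carries no parameter draws")
    zo = accepted.observed_ss if observed_ss is None else np.asarray(observed_ss)
    names = accepted.param_names or [f"param_{i}"
                                     for i in range(accepted.params.shape[1])]
    kinds = [
        (transforms or {}).get(n, default_transform(n)) for n in names]
    theta = np.column_stack([_fwd(accepted.params[:, j], k)
                             for j, k in enumerate(kinds)])
    w = epanechnikov_weights(accepted.distances)
    X = np.column_stack([np.ones(len(accepted.ss)), accepted.ss - zo])
    sw = np.sqrt(w)
    coef, _res, rank, _sv = np.linalg.lstsq(X * sw[:, None], theta * sw[:, None],
                                            rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient local-linear design; returning the "
                      "unadjusted rejection posterior")
        return ParameterPosterior(names, accepted.params.copy(), w, adjusted=False)
    adj = theta - (accepted.ss - zo) @ coef[1:, :]
    samples = np.column_stack([_inv(adj[:, j], k) for j, k in enumerate(kinds)])
    return ParameterPosterior(names, samples, w, adjusted=True)


def weighted_quantile(values: np.ndarray, q: Sequence[float],
                      weights: np.ndarray) -> np.ndarray:
    """Quantiles of a weighted sample (linear interpolation on the weighted
    empirical CDF)."""
    values = np.asarray(values)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights sum to zero")
    keep = weights > 0
    order = np.argsort(values[keep])
    v, w = values[keep][order], weights[keep][order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(q, cdf, v)


def posterior_summary(post: ParameterPosterior) -> pd.DataFrame:
    """Weighted mean and central 95% credible interval per parameter."""
    if post.samples.size == 0:
        raise ValueError("empty posterior sample")
    if post.weights.sum() <= 0:
        raise ValueError("all-zero weights")
    rows = []
    wnorm = post.weights / post.weights.sum()
    for j, name in enumerate(post.param_names):
        v = post.samples[:, j]
        lo, hi = weighted_quantile(v, [0.025, 0.975], post.weights)
        rows.append({"parameter": name, "mean": float(np.sum(wnorm * v)),
                     "q2.5": float(lo), "q97.5": float(hi)})
    return pd.DataFrame(rows, columns=["parameter", "mean", "q2.5", "q97.5"])


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

class ABCModelChoice(BaseEstimator):
    """Rejection + multinomial-logistic ABC model choice.

    ``fit(ss, labels)`` stores the simulated summary table;
    ``predict_proba(observed_ss)`` returns the model posterior at one or
    more observed summaries.
    """

    def __init__(self, n_accept: int = 1_000):
        self.n_accept = n_accept

    def fit(self, ss, labels):
        self.ss_ = np.atleast_2d(np.asarray(ss, dtype=float))
        self.labels_ = np.asarray(labels)
        self.classes_ = np.unique(self.labels_)
        return self

    def posterior(self, observed_ss) -> ModelPosterior:
        cfg = AbcConfig(n_sims=len(self.ss_), n_accept=self.n_accept)
        accepted = rejection_sample(observed_ss, self.ss_, cfg, labels=self.labels_)
        return mnlogistic_model_posterior(accepted)

    def predict_proba(self, observed_ss) -> np.ndarray:
        obs = np.atleast_2d(np.asarray(observed_ss, dtype=float))
        out = np.empty((len(obs), len(self.classes_)))
        for i, row in enumerate(obs):
            post = self.posterior(row)
            out[i] = [post.probabilities.get(str(c), 0.0) for c in self.classes_]
        return out

    def predict(self, observed_ss) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(observed_ss), axis=1)]


class ABCParameterEstimator(BaseEstimator):
    """Rejection + local-linear-adjustment ABC parameter estimation."""

    def __init__(self, n_accept: int = 1_000,
                 transforms: Mapping[str, str] | None = None):
        self.n_accept = n_accept
        self.transforms = transforms

    def fit(self, ss, params, param_names=None):
        self.ss_ = np.atleast_2d(np.asarray(ss, dtype=float))
        self.params_ = np.atleast_2d(np.asarray(params, dtype=float))
        self.param_names_ = list(param_names) if param_names is not None else \
            [f"param_{i}" for i in range(self.params_.shape[1])]
        return self

    def posterior(self, observed_ss) -> ParameterPosterior:
        cfg = AbcConfig(n_sims=len(self.ss_), n_accept=self.n_accept)
        accepted = rejection_sample(observed_ss, self.ss_, cfg,
                                    params=self.params_,
                                    param_names=self.param_names_)
        return loclinear_adjust(accepted, transforms=self.transforms)

    def predict(self, observed_ss) -> np.ndarray:
        """Posterior-mean point estimate per parameter."""
        obs = np.atleast_2d(np.asarray(observed_ss, dtype=float))
        out = np.empty((len(obs), self.params_.shape[1]))
        for i, row in enumerate(obs):
            post = self.posterior(row)
            wn = post.weights / post.weights.sum()
            out[i] = (post.samples * wn[:, None]).sum(axis=0)
        return out


# ---------------------------------------------------------------------------
# cross-validation confusion matrix
# ---------------------------------------------------------------------------

def cross_validation_confusion(
        model_labels: Sequence[str],
        simulate_fn: Callable[[str, np.random.Generator], JointSFS],
        n_train: int,
        n_pseudo: int,
        rng: np.random.Generator,
        cfg: AbcConfig | None = None,
        noise: NoiseSpec | None = None,
        hyper: Mapping | None = None,
        summarizer_factory: Callable[[TrainingSet], Callable] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Full-pipeline confusion matrix on pseudo-observed simulations.

    For every model, ``n_train + n_pseudo`` spectra are simulated; networks
    and the ABC reference table use only the training records, and each
    pseudo-observed record is pushed through summary + rejection +
    multinomial-logistic model choice with a hard (max-posterior)
    assignment.  Returns the row-stochastic confusion matrix
    P(assigned | true) and the mean posterior probability of the true model
    per row.
    """
    if n_pseudo <= 0:
        raise ValueError("n_pseudo must be positive")
    model_labels = list(model_labels)
    train_records, pseudo_records = [], []
    for label in model_labels:
        for i in range(n_train + n_pseudo):
            sfs = simulate_fn(label, rng)
            (train_records if i < n_train else pseudo_records).append((label, sfs))
    train = TrainingSet.from_records(train_records)
    if summarizer_factory is None:
        net = dlsum.train_classifier_net(train, noise=noise, hyper=hyper)
        summarizer = lambda X: net.forward(X)
    else:
        summarizer = summarizer_factory(train)
    ss_train = summarizer(train.X)
    cfg = cfg or AbcConfig(n_sims=len(ss_train),
                           n_accept=max(1, len(ss_train) // 100))
    choice = ABCModelChoice(n_accept=cfg.n_accept).fit(ss_train, train.labels)
    counts = pd.DataFrame(0.0, index=model_labels, columns=model_labels)
    true_post = pd.Series(0.0, index=model_labels)
    for label, sfs in pseudo_records:
        ss_obs = summarizer(sfs.to_vector()[None, :])[0]
        post = choice.posterior(ss_obs)
        counts.loc[label, post.map_label()] += 1
        true_post[label] += post.probabilities.get(label, 0.0)
    confusion = counts.div(counts.sum(axis=1), axis=0)
    return confusion, true_post / n_pseudo
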