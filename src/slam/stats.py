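"""Score calibration and screen evaluation.

The background of maximal alignment scores across a screen is modelled as a
Gumbel extreme-value distribution, F(x) = exp(−exp(−(x−μ)/β)). On the
double-log transform log(−log F̂) the background is a straight line in x, so
the significance threshold is the knee where the empirical curve departs
from its linear regime; the published operating points are fixed at 25
(significant), 30 (stringent comparisons) and 35 (surface screens).

Screen evaluation counts hits (alignment score strictly above threshold),
classifies each as true positive iff its FE-score < −1.5, and reports the
ROC/AUC of the score ranking against those labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import FitError

#: published operating points for the alignment score
SIGNIFICANT_THRESHOLD = 25.0
STRINGENT_THRESHOLD = 30.0
SURFACE_THRESHOLD = 35.0

_FIXED_POLICIES = {
    "significant": SIGNIFICANT_THRESHOLD,
    "stringent": STRINGENT_THRESHOLD,
    "surface": SURFACE_THRESHOLD,
}


@dataclass
class GumbelFit:
    mu: float
    beta: float
    n: int
    method: str = "moments"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise FitError(f"beta must be > 0, got {self.beta}")


def gumbel_cdf(x, fit: GumbelFit):
    """F(x) = exp(−exp(−(x−μ)/β))."""
    return sps.gumbel_r.cdf(x, loc=fit.mu, scale=fit.beta)


def gumbel_quantile(p, fit: GumbelFit):
    return sps.gumbel_r.ppf(p, loc=fit.mu, scale=fit.beta)


def fit_gumbel(scores, method: str = "moments") -> GumbelFit:
    """Fit μ, β; moment estimates β̂ = s·√6/π, μ̂ = x̄ − γ·β̂ by default."""
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 30:
        raise FitError(f"need ≥ 30 finite scores, got {len(x)}")
    if x.std() == 0.0:
        raise FitError("zero-variance scores")
    if method == "moments":
        beta = x.std(ddof=1) * np.sqrt(6.0) / np.pi
        mu = x.mean() - np.euler_gamma * beta
    elif method == "mle":
        mu, beta = sps.gumbel_r.fit(x)
    else:
        raise FitError(f"unknown method {method!r}")
    return GumbelFit(mu=float(mu), beta=float(beta), n=len(x), method=method)


def double_log_curve(scores, max_points: int = 500):
    """(x, log(−log F̂(x))) over the sorted sample.

    Uses the Weibull plotting position F̂ = rank/(n+1), which keeps the
    empirical CDF strictly inside (0, 1); under a true Gumbel law the curve
    is linear with slope −1/β.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    n = len(x)
    if n < 3:
        raise FitError("need at least 3 scores")
    F = np.arange(1, n + 1) / (n + 1.0)
    if n > max_points:
        idx = np.unique(np.linspace(0, n - 1, max_points).round().astype(int))
        x, F = x[idx], F[idx]
    return x, np.log(-np.log(F))


def significance_threshold(
    scores,
    policy: str = "knee",
    fixed: float | None = None,
    fit_quantile: float = 0.90,
    z_threshold: float = 4.0,
    min_tail_count: int = 5,
    return_diagnostics: bool = False,
):
    """Score threshold separating background from significant alignments.

    ``knee`` fits the Gumbel background on scores up to the
    ``fit_quantile`` quantile and scans the tail for the smallest score
    whose observed exceedance count is more than ``z_threshold`` Poisson
    standard deviations above the Gumbel-predicted count (requiring at
    least ``min_tail_count`` observations above it); None when no such
    departure exists (pure background). The fixed policies return the
    published operating points; a numeric ``fixed`` value is passed
    through.
    """
    if policy in _FIXED_POLICIES:
        return _FIXED_POLICIES[policy]
    if policy == "fixed":
        if fixed is None:
            raise FitError("fixed policy requires a value")
        return float(fixed)
    if policy != "knee":
        raise FitError(f"unknown policy {policy!r}")

    x = np.sort(np.asarray(scores, dtype=float))
    x = x[np.isfinite(x)]
    n = len(x)
    cutoff = np.quantile(x, fit_quantile)
    # moments of the full sample: a rare signal component barely moves them,
    # while fitting a truncated bulk would bias the predicted tail
    fit = fit_gumbel(x)
    # scan the tail: observed exceedance counts vs the Gumbel prediction.
    # The empirical curve departs from the linear (Gumbel) regime where the
    # observed count of scores above x significantly exceeds the expected
    # count n·(1−F(x)) — Poisson z-test with a minimum absolute excess.
    knee = None
    first_z = None
    tail_idx = np.where(x > cutoff)[0]
    for i in tail_idx:
        observed = n - i - 1  # scores strictly above x[i]
        expected = n * float(sps.gumbel_r.sf(x[i], loc=fit.mu, scale=fit.beta))
        if observed < min_tail_count:
            break
        z = (observed - expected) / np.sqrt(max(expected, 1e-12))
        if z > z_threshold:
            knee = float(x[i])
            first_z = float(z)
            break
    if return_diagnostics:
        return knee, {
            "mu": fit.mu,
            "beta": fit.beta,
            "fit_cutoff": float(cutoff),
            "n": n,
            "z_at_knee": first_z,
        }
    return knee


def evaluate_screen(
    scores,
    fe_scores,
    score_threshold: float,
    fe_threshold: float = -1.5,
):
    """Summary of a screen: hit counts, TP rate and ROC/AUC.

    A result is a hit when its alignment score is strictly above
    *score_threshold*; a hit is a true positive when its FE-score is
    strictly below *fe_threshold*. The ROC ranks all results by alignment
    score against the TP labels; AUC is trapezoidal and None when only one
    class is present.
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    fe = np.asarray(fe_scores, dtype=float)
    if scores.shape != fe.shape:
        raise FitError("scores and fe_scores must have equal length")
    labels = fe < fe_threshold
    hits = scores > score_threshold
    n_hits = int(hits.sum())
    n_tp = int((hits & labels).sum())
    tp_rate = 100.0 * n_tp / n_hits if n_hits else float("nan")
    if labels.all() or not labels.any():
        fpr, tpr, auc_value = None, None, None
    else:
        fpr, tpr, _ = roc_curve(labels, scores)
        auc_value = float(sk_auc(fpr, tpr))
    return {
        "n": len(scores),
        "n_hits": n_hits,
        "n_tp": n_tp,
        "tp_rate": tp_rate,
        "roc": (fpr, tpr),
        "auc": auc_value,
    }


def plot_roc(fpr, tpr, auc_value=None, path=None):
    """ROC plot (optional output of the evaluate command)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, lw=2)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    label = f"AUC = {auc_value:.3f}" if auc_value is not None else ""
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
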