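"""Logistic propensity model and pre-match specification checks.

The propensity score e(x) = P(fast_track | x) is estimated by maximum
likelihood (iteratively reweighted least squares).  Before matching, the
model specification is checked stratum-wise: within each decile of the
pooled score distribution, treated and control patients should be
indistinguishable both in their scores and in every covariate; the checks
use two-sided Mann-Whitney U tests with Bonferroni adjustment within each
family of 10 decile tests.  A failed check is advisory: the pipeline
warns, and halts only in strict mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, InputError, SeparationError
from .outcomes import mann_whitney_rbc

N_STRATA = 10


@dataclass
class PropensityFit:
    """MLE coefficients and per-patient scores of the assignment model."""

    coefficients: np.ndarray      # log-odds units, aligned with labels
    labels: list[str]
    scores: np.ndarray            # e(x) in (0, 1)
    converged: bool
    n_iterations: int
    log_likelihood: float

    def coefficient(self, label: str) -> float:
        return float(self.coefficients[self.labels.index(label)])


@dataclass
class DecileDiagnostics:
    """Stratum-wise model-specification check results.

    ``score_test_p`` and each row of ``covariate_test_p`` are
    Bonferroni-adjusted within their own 10-test family and capped at 1.
    Strata where one group is empty are untestable: their p is set to 1
    and the stratum index is recorded in ``untestable``.
    """

    decile_edges: np.ndarray                 # len 11: min + 10 right-closed uppers
    score_test_p: np.ndarray                 # len 10, adjusted
    covariate_test_p: dict[str, np.ndarray]  # covariate label -> len-10 adjusted
    untestable: list[tuple[str, int]]
    alpha: float
    passed: bool
    adjustment: str = "bonferroni"

    def to_dict(self) -> dict:
        return {
            "decile_edges": [float(v) for v in self.decile_edges],
            "score_test_p": [float(v) for v in self.score_test_p],
            "covariate_test_p": {k: [float(v) for v in vals]
                                 for k, vals in self.covariate_test_p.items()},
            "untestable": [[name, int(i)] for name, i in self.untestable],
            "alpha": self.alpha,
            "passed": bool(self.passed),
            "adjustment": self.adjustment,
        }


def fit_propensity(design: np.ndarray, treatment: np.ndarray,
                   labels: list[str] | None = None,
                   max_iter: int = 100, tol: float = 1e-8) -> PropensityFit:
    """Fit the logistic assignment model by IRLS.

    Convergence: max absolute coefficient update < ``tol`` (default 1e-8)
    or ``max_iter`` iterations.  Raises :class:`DesignError` on a
    rank-deficient design and :class:`SeparationError` when coefficients
    diverge (||beta||_inf > 1e4), the IRLS signature of perfect
    separation.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(treatment, dtype=float)
    n, p = X.shape
    if labels is None:
        labels = [f"x{j}" for j in range(p)]
    if y.min() == y.max():
        raise InputError("both treatment groups must be non-empty")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, X.T @ (w * z))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guard above
            raise DesignError(f"weighted least squares failed: {exc}") from exc
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if np.max(np.abs(beta)) > 1e4:
            raise SeparationError(
                "coefficients diverged (perfect separation?)")
        if step < tol:
            converged = True
            break

    mu = expit(X @ beta)
    # keep scores strictly inside (0, 1)
    scores = np.clip(mu, 1e-12, 1.0 - 1e-12)
    ll = float(np.sum(y * np.log(scores) + (1.0 - y) * np.log1p(-scores)))
    return PropensityFit(beta, list(labels), scores, converged, it, ll)


def assign_deciles(scores: np.ndarray) -> np.ndarray:
    """Stratum index (0..9) per patient from the pooled score distribution.

    Patients are ranked by score (ties broken by input order, a stable
    sort) and rank k of n goes to stratum floor(10*k/n), so stratum sizes
    differ by at most one.
    """
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    strata = np.empty(n, dtype=int)
    strata[order] = (np.arange(n) * N_STRATA) // n
    return strata


def _bonferroni(pvals: list[float]) -> np.ndarray:
    return multipletests(pvals, method="bonferroni")[1]


def decile_checks(fit: PropensityFit, design: np.ndarray,
                  treatment: np.ndarray, alpha: float = 0.05,
                  labels: list[str] | None = None) -> DecileDiagnostics:
    """Stratum-wise Mann-Whitney specification checks of the fitted model.

    Within each decile of the pooled score distribution, compares treated
    vs control (a) propensity scores and (b) every non-intercept design
    column; p-values are Bonferroni-adjusted within each 10-test family.
    ``passed`` is True iff every adjusted p >= ``alpha``.
    """
    labels = labels or fit.labels
    y = np.asarray(treatment, dtype=bool)
    scores = fit.scores
    strata = assign_deciles(scores)

    edges = np.empty(N_STRATA + 1)
    edges[0] = scores.min()
    for k in range(N_STRATA):
        in_k = strata == k
        edges[k + 1] = scores[in_k].max() if in_k.any() else edges[k]

    untestable: list[tuple[str, int]] = []

    def stratum_p(values: np.ndarray, k: int, name: str) -> float:
        in_k = strata == k
        vt, vc = values[in_k & y], values[in_k & ~y]
        if len(vt) == 0 or len(vc) == 0:
            untestable.append((name, k))
            return 1.0
        return mann_whitney_rbc(vt, vc)[1]

    score_raw = [stratum_p(scores, k, "propensity_score") for k in range(N_STRATA)]
    score_adj = _bonferroni(score_raw)

    cov_adj: dict[str, np.ndarray] = {}
    X = np.asarray(design, dtype=float)
    for j, name in enumerate(labels):
        if name == "intercept":
            continue
        raw = [stratum_p(X[:, j], k, name) for k in range(N_STRATA)]
        cov_adj[name] = _bonferroni(raw)

    all_p = np.concatenate([score_adj, *cov_adj.values()]) if cov_adj else score_adj
    passed = bool(np.all(all_p >= alpha))
    if not passed:
        warnings.warn("decile specification checks failed "
                      f"(min adjusted p = {all_p.min():.4g} < alpha = {alpha})",
                      stacklevel=2)
    return DecileDiagnostics(edges, score_adj, cov_adj, untestable, alpha, passed)
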