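"""Two-step weighted logistic GLM and per-junction posterior statistics.

Reads anchored to linear junctions with concordant mates (class 1,
presumed true alignments) and decoy reads (class 2, presumed artifacts)
train a logistic regression of class membership on three R1 alignment
features: boundary offset, alignment score, and mapping quality.  The
fit is performed twice.  In step 1 each class receives equal total
weight.  In step 2, reads whose features conflict with their
mate-geometry label are downweighted -- linear reads in proportion to
p-hat, decoy reads in proportion to 1 - p-hat -- keeping class totals
equal, and the model is refit.

The per-read predicted probabilities p-hat_i of reads at a junction are
then combined into a posterior probability that the junction is truly
expressed::

    P = prod(p) / (prod(p) + prod(1 - p))

computed in log space over all non-decoy reads.  Significance is
assessed against a permutation null for linear junctions (empirical
moments of l_i = log((1-p_i)/p_i) across all decoy and linear reads)
and against a fixed two-point null for circular junctions, with
Benjamini-Hochberg FDR control.  A naive Poisson mismatch test covers
single-end data and de novo candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from circjunct.classify import ReadFeatureRecord

EPS = 1e-6
FEATURE_NAMES = ("intercept", "offset", "alignment_score", "mapq")


class SeparationWarning(UserWarning):
    """Raised when the logistic fit falls back to a ridge penalty."""


@dataclass
class GLMFit:
    """Final two-step fit: coefficients, covariance, and training predictions."""

    beta: np.ndarray
    cov: np.ndarray
    p_hat: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    weights: np.ndarray
    labels: np.ndarray  # 1 = linear, 2 = decoy
    coefficient_pvalues: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    penalized: bool = False
    step1_beta: np.ndarray | None = None  # pre-reweighting fit (unbiased
    step1_cov: np.ndarray | None = None   # under correct category labels)

    def design(self, features: Sequence[ReadFeatureRecord]) -> np.ndarray:
        return _design(features)

    def predict(self, features: Sequence[ReadFeatureRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predicted probability and 95% Wald interval for new reads.

        The interval is computed on the linear predictor from the
        coefficient covariance and mapped through the logistic link.
        """
        X = _design(features)
        eta = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        z = stats.norm.ppf(0.975)
        return expit(eta), expit(eta - z * se), expit(eta + z * se)


def _design(features: Sequence[ReadFeatureRecord]) -> np.ndarray:
    X = np.empty((len(features), 4))
    X[:, 0] = 1.0
    X[:, 1] = [f.offset for f in features]
    X[:, 2] = [f.alignment_score for f in features]
    X[:, 3] = [f.mapq for f in features]
    return X


def _ridge_logistic(X: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float = 1.0,
                    max_iter: int = 200, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Weighted ridge-penalized logistic fit by IRLS (separation fallback).

    Predictors are standardized internally and a unit ridge prior
    applied on that scale (intercept nearly unpenalized), keeping
    coefficients and Wald covariance finite under separation; the
    returned beta/cov are on the raw feature scale.
    """
    m = X[:, 1:].mean(axis=0)
    s = X[:, 1:].std(axis=0)
    s[s == 0] = 1.0
    Z = np.column_stack([X[:, 0], (X[:, 1:] - m) / s])
    pen = np.diag([1e-4] + [alpha] * (X.shape[1] - 1))
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(Z @ beta)
        sw = np.clip(mu * (1 - mu), 1e-10, None) * w
        grad = Z.T @ (w * (y - mu)) - pen @ beta
        hess = (Z.T * sw) @ Z + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(Z @ beta)
    sw = np.clip(mu * (1 - mu), 1e-10, None) * w
    cov_std = np.linalg.inv((Z.T * sw) @ Z + pen)
    # map back to the raw feature scale
    T = np.eye(X.shape[1])
    T[0, 1:] = -m / s
    T[1:, 1:] = np.diag(1.0 / s)
    return T @ beta, T @ cov_std @ T.T


def _fit_weighted(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """One weighted logistic fit; returns (beta, cov, pvalues, penalized)."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            raise PerfectSeparationError("divergent coefficients")
        # quasi-separation: Wald uncertainty on the linear predictor blows
        # up even though the point fit converged
        eta_se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, cov, X), 0.0))
        if np.median(eta_se) > 4.0:
            raise PerfectSeparationError("degenerate Wald covariance")
        return beta, cov, np.asarray(res.pvalues), False
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        warnings.warn(
            "perfect or quasi-separation detected; using ridge-penalized fit",
            SeparationWarning, stacklevel=3,
        )
        beta, cov = _ridge_logistic(X, y, w)
        se = np.sqrt(np.diag(cov))
        pv = 2 * stats.norm.sf(np.abs(beta) / np.where(se > 0, se, np.inf))
        return beta, cov, pv, True


def fit_two_step_glm(features: Sequence[ReadFeatureRecord], min_per_class: int = 10) -> GLMFit:
    """Fit the two-step weighted logistic model on linear vs decoy reads.

    Step 1 gives every read weight 1/|class| so the two classes have
    equal total influence.  Step 2 reweights within class -- linear
    reads proportional to p-hat from step 1, decoy reads proportional to
    1 - p-hat -- renormalized so class totals stay equal, and refits.
    """
    train = [f for f in features if f.category in ("linear", "decoy")]
    y = np.array([1.0 if f.category == "linear" else 0.0 for f in train])
    n1, n2 = int(y.sum()), int((1 - y).sum())
    if n1 < min_per_class or n2 < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} reads per class; got {n1} linear, {n2} decoy"
        )
    X = _design(train)

    # step 1: equal class influence; weights rescaled to total n so the
    # fit's information content (hence Wald inference) stays at sample size
    n = len(train)
    w1 = np.where(y == 1, 1.0 / n1, 1.0 / n2)
    w1 *= n / w1.sum()
    beta, cov, _, pen1 = _fit_weighted(X, y, w1)
    step1_beta, step1_cov = beta.copy(), cov.copy()
    p1 = expit(X @ beta)

    # step 2: downweight reads conflicting with the model's assignment
    w2 = np.empty_like(w1)
    lin, dec = y == 1, y == 0
    w2[lin] = p1[lin] / p1[lin].sum()
    w2[dec] = (1 - p1[dec]) / (1 - p1[dec]).sum()
    w2 *= n / w2.sum()
    beta, cov, pvals, pen2 = _fit_weighted(X, y, w2)

    eta = X @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, cov, X), 0.0))
    zq = stats.norm.ppf(0.975)
    return GLMFit(
        beta=beta,
        cov=cov,
        p_hat=expit(eta),
        ci_lo=expit(eta - zq * se),
        ci_hi=expit(eta + zq * se),
        weights=w2,
        labels=np.where(y == 1, 1, 2),
        coefficient_pvalues=pvals,
        penalized=pen1 or pen2,
        step1_beta=step1_beta,
        step1_cov=step1_cov,
    )


def predict_conservative(
    fit: GLMFit, features: Sequence[ReadFeatureRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Conservative per-read probability for scoring.

    For reads the model assigns to class 1 (p-hat >= 0.5) the 95% CI
    lower bound is used; for class 2 the upper bound -- each shrunk
    toward 0.5 -- then clamped away from {0, 1}.
    """
    p_hat, lo, hi = fit.predict(features)
    p_used = np.where(p_hat >= 0.5, lo, hi)
    return p_hat, np.clip(p_used, EPS, 1 - EPS)


# ---------------------------------------------------------------------------
# junction-level statistics

def log_odds_against(p: np.ndarray) -> np.ndarray:
    """l_i = log((1 - p_i) / p_i), the per-read evidence against expression."""
    p = np.clip(np.asarray(p, dtype=float), EPS, 1 - EPS)
    return np.log1p(-p) - np.log(p)


def junction_posterior(p_list: Sequence[float]) -> float:
    """Aggregate posterior P = prod(p)/(prod(p) + prod(1-p)), in log space."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("junction_posterior requires at least one read")
    if np.any((p <= 0) | (p >= 1)):
        p = np.clip(p, EPS, 1 - EPS)
    l_n = float(np.sum(log_odds_against(p)))
    return float(expit(-l_n))


def null_moments(p_list: Sequence[float]) -> tuple[float, float]:
    """Empirical mean and variance of l_i over all decoy and linear reads."""
    l = log_odds_against(np.asarray(p_list, dtype=float))
    if l.size < 2:
        raise ValueError("need at least two reads to estimate null moments")
    return float(np.mean(l)), float(np.var(l, ddof=1))


def linear_junction_pvalue(p_list: Sequence[float], mu: float, var1: float) -> float:
    """Permutation-null p-value for a linear junction's posterior.

    z_n = (l_n - n*mu)/sqrt(n*var1); the one-sided p = Phi(z_n) is small
    when the posterior is higher than expected by chance.
    """
    if var1 <= 0:
        raise ValueError("null variance must be positive")
    l = log_odds_against(np.asarray(p_list, dtype=float))
    n = l.size
    if n == 0:
        raise ValueError("empty read list")
    z = (float(l.sum()) - n * mu) / np.sqrt(n * var1)
    return float(stats.norm.cdf(z))


def circular_junction_pvalue(n_reads: int) -> tuple[float, float]:
    """Fixed-null p-value for a circular junction with ``n_reads`` reads.

    The artifact null puts a read at predicted probability 0.1 with 95%
    chance and 0.9 with 5% chance; with mu = log(9) and
    var(l_n) = n*log(9)^2, and l_n evaluated conservatively at the
    minimum reportable posterior 0.9, the z-score reduces to -2*sqrt(n).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    z = -2.0 * np.sqrt(n_reads)
    return float(stats.norm.cdf(z)), float(z)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def naive_mismatch_pvalue(total_mismatches: int, total_bases: int, rate: float = 0.01) -> float:
    """Upper-tail Poisson test of the aggregate mismatch count.

    Under the null that all mismatches are sequencing error at ``rate``
    per base, p = P(X >= observed) with X ~ Poisson(rate * bases); a low
    p flags excess mismatches, i.e. a likely false-positive junction.
    """
    if total_bases <= 0 or total_mismatches < 0:
        raise ValueError("total_bases must be positive and mismatches non-negative")
    lam = rate * total_bases
    return float(stats.poisson.sf(total_mismatches - 1, lam))


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class JunctionCall:
    junction_id: str
    cls: str
    n_reads: int
    posterior: float
    p_value: float
    fdr: float
    verdict: str = "fail"
    decoy_count: int = 0
    extras: dict = field(default_factory=dict)


def score_junctions(
    features: Sequence[ReadFeatureRecord],
    mode: str = "glm",
    fit: GLMFit | None = None,
    read_len: int = 100,
    error_rate: float = 0.01,
    min_per_class: int = 10,
) -> list[JunctionCall]:
    """Score every junction with aligned reads and return unfiltered calls.

    ``glm`` mode fits (or reuses) the two-step model, scores each read
    conservatively, and aggregates posteriors; linear junctions get
    permutation-null p-values and circular junctions the fixed-null
    p-value with BH FDR.  ``naive`` mode applies the Poisson mismatch
    test per junction (the single-end default), reporting its p-value as
    the confidence measure.
    """
    decoys: dict[str, int] = {}
    groups: dict[str, list[ReadFeatureRecord]] = {}
    cls_of: dict[str, str] = {}
    for f in features:
        cls_of.setdefault(f.junction_id, f.junction_cls or ("linear" if f.category == "linear" else "scrambled"))
        if f.category == "decoy":
            decoys[f.junction_id] = decoys.get(f.junction_id, 0) + 1
        else:
            groups.setdefault(f.junction_id, []).append(f)

    calls: list[JunctionCall] = []
    if mode == "naive":
        for jid, reads in sorted(groups.items()):
            total_mm = sum(f.mismatches for f in reads)
            p = naive_mismatch_pvalue(total_mm, len(reads) * read_len, error_rate)
            calls.append(
                JunctionCall(
                    junction_id=jid, cls=cls_of[jid], n_reads=len(reads),
                    posterior=float("nan"), p_value=p, fdr=float("nan"),
                    decoy_count=decoys.get(jid, 0),
                    extras={"total_mismatches": total_mm},
                )
            )
        return calls
    if mode != "glm":
        raise ValueError(f"unknown scoring mode: {mode!r}")

    if fit is None:
        fit = fit_two_step_glm(features, min_per_class=min_per_class)

    all_scored = [f for f in features if f.category != "decoy"]
    train = [f for f in features if f.category in ("linear", "decoy")]
    _, p_used_train = predict_conservative(fit, train)
    mu, var1 = null_moments(p_used_train)

    p_used_by_read: dict[tuple[str, str], float] = {}
    if all_scored:
        _, p_used = predict_conservative(fit, all_scored)
        for f, p in zip(all_scored, p_used):
            p_used_by_read[(f.read_id, f.junction_id)] = float(p)

    for jid, reads in sorted(groups.items()):
        ps = [p_used_by_read[(f.read_id, f.junction_id)] for f in reads]
        post = junction_posterior(ps)
        if cls_of[jid] == "linear":
            pv = linear_junction_pvalue(ps, mu, var1)
        else:
            pv, _ = circular_junction_pvalue(len(reads))
        calls.append(
            JunctionCall(
                junction_id=jid, cls=cls_of[jid], n_reads=len(reads),
                posterior=post, p_value=pv, fdr=float("nan"),
                decoy_count=decoys.get(jid, 0),
            )
        )

    # BH within class over the tested junctions
    for cls in sorted({c.cls for c in calls}):
        idx = [i for i, c in enumerate(calls) if c.cls == cls]
        fdrs = bh_fdr([calls[i].p_value for i in idx])
        for i, q in zip(idx, fdrs):
            calls[i].fdr = float(q)
    return calls


def report_calls(
    calls: Sequence[JunctionCall],
    posterior_threshold: float = 0.9,
    n_min: int = 2,
    naive_threshold: float = 0.9,
) -> list[JunctionCall]:
    """Apply verdicts and return passing calls sorted by posterior, count.

    GLM calls pass at posterior >= threshold with at least ``n_min``
    reads; naive calls (posterior undefined) pass at p-value >= 0.9,
    where a high p indicates mismatch rates consistent with sequencing
    error alone.
    """
    out: list[JunctionCall] = []
    for c in calls:
        if np.isnan(c.posterior):
            ok = c.p_value >= naive_threshold and c.n_reads >= n_min
        else:
            ok = c.posterior >= posterior_threshold and c.n_reads >= n_min
        c.verdict = "pass" if ok else "fail"
        if ok:
            out.append(c)
    out.sort(key=lambda c: (-(c.posterior if not np.isnan(c.posterior) else c.p_value), -c.n_reads, c.junction_id))
    return out


def calls_to_dataframe(calls: Iterable[JunctionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.junction_id, c.cls, c.n_reads, c.decoy_count, c.posterior, c.p_value, c.fdr, c.verdict)
            for c in calls
        ],
        columns=["junction_id", "class", "n_reads", "decoy_count", "posterior", "p_value", "fdr", "verdict"],
    )
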