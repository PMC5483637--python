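"""Single-predictor MS/HC classification with resampling-based inference.

For each predictor the screen fits a two-parameter binary logistic
regression (intercept + slope) and reports

* within-sample accuracy with a stratified BCa bootstrap 95 % interval
  (significant when the lower limit exceeds binary chance, 0.50),
* leave-one-out cross-validated (LOOCV) accuracy with a label-permutation
  p-value using the +1/(K+1) small-sample correction,
* Benjamini-Hochberg adjusted p-values across predictors,
* a Welch unequal-variance t-test and Cohen's d for the plain group
  comparison.

Outliers are screened once per group before modelling: +/-3 MAD from the
group median for classification, +/-2 SD from the group mean for the
group comparisons.

The logistic fits are a hand-rolled, vectorised Newton solver: the
permutation and bootstrap engines need on the order of a million refits,
and complete separation (common for n = 23 with strong predictors) must
degrade deterministically to a midpoint-threshold rule rather than to an
unbounded MLE.  Accuracy depends only on the decision boundary, so the
fallback leaves every reported statistic well defined.  The solver is
cross-checked against statsmodels and a grid-search likelihood oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClassificationConfig",
    "LogisticFit",
    "BcaInterval",
    "PredictorResult",
    "GroupComparison",
    "ScreenResult",
    "filter_outliers_sd",
    "filter_outliers_mad",
    "fit_logistic",
    "predict_proba",
    "within_accuracy",
    "bca_bootstrap_accuracy",
    "loocv_accuracy",
    "permutation_pvalue",
    "benjamini_hochberg",
    "welch_t",
    "cohens_d",
    "run_full_screen",
]

# fit kinds used by the batched engine
_NEWTON, _SEP_UP, _SEP_DN, _ONLY0, _ONLY1 = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class ClassificationConfig:
    """Knobs of the resampling screen (defaults are the study settings)."""

    n_boot: int = 10_000
    n_perm: int = 5_000
    alpha: float = 0.05
    chance: float = 0.50
    mad_k: float = 3.0
    sd_k: float = 2.0
    seed: int = 0
    # permutation accuracies "better than" observed: >= (conservative) or >
    perm_greater_equal: bool = True
    # +1/(K+1) correction; False gives the raw percentage
    perm_plus_one: bool = True

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LogisticFit:
    """Fitted 1-predictor logistic model (or its separation fallback)."""

    intercept: float
    slope: float
    separated: bool
    threshold: float = np.nan  # midpoint decision boundary when separated
    direction: int = 0  # +1: positive class above threshold, -1: below


@dataclass
class BcaInterval:
    observed: float
    lcl: float
    ucl: float
    significant: bool


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    d: float


@dataclass
class PredictorResult:
    name: str
    n_used: int
    within_accuracy: float
    bca_lcl: float
    bca_ucl: float
    significant_within: bool
    loocv_accuracy: float
    perm_p: float
    bh_p: float = np.nan
    separated: bool = False


@dataclass
class ScreenResult:
    results: list  # PredictorResult, ranked
    comparisons: dict  # name -> GroupComparison
    skipped: dict  # name -> reason
    config: ClassificationConfig = field(default_factory=ClassificationConfig)

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(r) for r in self.results]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outlier screens (single pass, statistics from the unfiltered group)


def filter_outliers_sd(values, k: float = 2.0) -> np.ndarray:
    """Drop values >= k group SDs from the group mean (single pass)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy()
    return x[np.abs(x - x.mean()) < k * sd]


def filter_outliers_mad(values, k: float = 3.0, scale: float = 1.4826) -> np.ndarray:
    """Drop values >= k scaled-MADs from the group median (single pass).

    MAD is the median absolute deviation from the median; ``scale`` is
    the Gaussian consistency constant.  When MAD = 0 any value different
    from the median is dropped.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x[x == med]
    return x[np.abs(x - med) < k * scale * mad]


def _mad_keep_mask(x: np.ndarray, k: float, scale: float = 1.4826) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x == med
    return np.abs(x - med) < k * scale * mad


# ---------------------------------------------------------------------------
# batched logistic engine


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30.0, 30.0)))


def _fit_batch(x: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Fit K independent 1-predictor logistic models.

    x, y : (K, n).  Returns (kind, b0, b1, thr, direction sign built into
    kind).  Rows with complete separation or a single class bypass Newton.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k_rows, n = x.shape
    n1 = y.sum(axis=1)
    n0 = n - n1

    max0 = np.where(y == 0, x, -np.inf).max(axis=1)
    min0 = np.where(y == 0, x, np.inf).min(axis=1)
    max1 = np.where(y == 1, x, -np.inf).max(axis=1)
    min1 = np.where(y == 1, x, np.inf).min(axis=1)

    kind = np.full(k_rows, _NEWTON, dtype=np.int8)
    kind[n1 == 0] = _ONLY0
    kind[n0 == 0] = _ONLY1
    both = (n0 > 0) & (n1 > 0)
    sep_up = both & (max0 < min1)
    sep_dn = both & (max1 < min0)
    kind[sep_up] = _SEP_UP
    kind[sep_dn] = _SEP_DN

    thr = np.full(k_rows, np.nan)
    thr[sep_up] = 0.5 * (max0[sep_up] + min1[sep_up])
    thr[sep_dn] = 0.5 * (max1[sep_dn] + min0[sep_dn])

    b0 = np.zeros(k_rows)
    b1 = np.zeros(k_rows)
    todo = kind == _NEWTON
    if todo.any():
        xs = x[todo]
        ys = y[todo]
        m = xs.shape[0]
        p1 = ys.mean(axis=1)
        c0 = np.log(p1 / (1.0 - p1))
        c1 = np.zeros(m)
        active = np.ones(m, dtype=bool)
        for _ in range(max_iter):
            eta = c0[:, None] + c1[:, None] * xs
            mu = _sigmoid(eta)
            w = mu * (1.0 - mu) + 1e-12
            r = ys - mu
            g0 = r.sum(axis=1)
            g1 = (r * xs).sum(axis=1)
            h00 = w.sum(axis=1)
            h01 = (w * xs).sum(axis=1)
            h11 = (w * xs * xs).sum(axis=1)
            det = h00 * h11 - h01 * h01
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            d0 = (h11 * g0 - h01 * g1) / det
            d1 = (h00 * g1 - h01 * g0) / det
            # damp huge steps (quasi-separation) to keep the iteration stable
            step = np.maximum(np.abs(d0), np.abs(d1))
            damp = np.minimum(1.0, 10.0 / np.maximum(step, 1e-30))
            c0 += damp * d0 * active
            c1 += damp * d1 * active
            active &= step > tol
            if not active.any():
                break
        b0[todo] = c0
        b1[todo] = c1
    return kind, b0, b1, thr


def _predict_batch(kind, b0, b1, thr, x_eval) -> np.ndarray:
    """P(class 1) for each row's model at x_eval (same leading shape)."""
    x_eval = np.asarray(x_eval, dtype=float)
    expand = (slice(None),) + (None,) * (x_eval.ndim - 1)
    p = _sigmoid(b0[expand] + b1[expand] * x_eval)
    thr_e = thr[expand] * np.ones_like(x_eval)
    p = np.where((kind == _SEP_UP)[expand], (x_eval > thr_e) + 0.5 * (x_eval == thr_e), p)
    p = np.where((kind == _SEP_DN)[expand], (x_eval < thr_e) + 0.5 * (x_eval == thr_e), p)
    p = np.where((kind == _ONLY0)[expand], 0.0, p)
    p = np.where((kind == _ONLY1)[expand], 1.0, p)
    return p


def fit_logistic(x, y) -> LogisticFit:
    """Maximum-likelihood logistic fit of binary labels on one predictor.

    Complete separation is detected up front and replaced by the
    deterministic midpoint-threshold rule (flagged via ``separated``;
    coefficient fields are NaN in that case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D arrays")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    kind, b0, b1, thr = _fit_batch(x[None, :], y[None, :])
    if kind[0] == _NEWTON:
        return LogisticFit(float(b0[0]), float(b1[0]), separated=False)
    direction = +1 if kind[0] == _SEP_UP else -1
    return LogisticFit(np.nan, np.nan, separated=True, threshold=float(thr[0]), direction=direction)


def predict_proba(fit: LogisticFit, x) -> np.ndarray:
    """P(positive class) under a fitted model (ties at the boundary -> 0.5)."""
    x = np.asarray(x, dtype=float)
    if not fit.separated:
        return _sigmoid(fit.intercept + fit.slope * x)
    above = x > fit.threshold if fit.direction > 0 else x < fit.threshold
    p = above.astype(float)
    p[x == fit.threshold] = 0.5
    return p


def within_accuracy(fit: LogisticFit, x, y, threshold: float = 0.5) -> float:
    """Training-sample accuracy; P >= threshold predicts the positive class."""
    y = np.asarray(y, dtype=float)
    pred = predict_proba(fit, x) >= threshold
    return float(np.mean(pred == (y == 1)))


# ---------------------------------------------------------------------------
# resampling inference


def _accuracy_rows(kind, b0, b1, thr, x, y) -> np.ndarray:
    p = _predict_batch(kind, b0, b1, thr, x)
    return np.mean((p >= 0.5) == (y == 1), axis=-1)


def loocv_accuracy(x, y) -> float:
    """Leave-one-out cross-validated accuracy of the logistic classifier.

    Each fold refits on the remaining N-1 points; a fold whose training
    set holds a single class predicts that class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 observations")
    return float(_loocv_batch(x, y[None, :])[0])


def _loocv_batch(x: np.ndarray, ys: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """LOOCV accuracy for many labelings of one predictor.

    x : (n,), ys : (P, n).  Returns (P,) accuracies.  All P*n folds are
    fitted in one batched Newton call (chunked to bound memory).
    """
    n = x.size
    p_rows = ys.shape[0]
    keep = ~np.eye(n, dtype=bool)
    x_folds = np.broadcast_to(x, (n, n))[keep].reshape(n, n - 1)  # (n, n-1)

    acc = np.empty(p_rows)
    rows_per_chunk = max(chunk // n, 1)
    for lo in range(0, p_rows, rows_per_chunk):
        hi = min(lo + rows_per_chunk, p_rows)
        block = ys[lo:hi]  # (B, n)
        b = block.shape[0]
        y_folds = (
            np.broadcast_to(block[:, None, :], (b, n, n))[:, keep]
            .reshape(b * n, n - 1)
        )
        x_rep = np.broadcast_to(x_folds, (b, n, n - 1)).reshape(b * n, n - 1)
        kind, b0, b1, thr = _fit_batch(x_rep, y_folds)
        p_held = _predict_batch(kind, b0, b1, thr, np.tile(x, b))
        correct = (p_held >= 0.5) == (block.reshape(b * n) == 1)
        acc[lo:hi] = correct.reshape(b, n).mean(axis=1)
    return acc


def permutation_pvalue(
    x,
    y,
    config: ClassificationConfig = ClassificationConfig(),
    rng: np.random.Generator | None = None,
    observed: float | None = None,
) -> float:
    """Permutation p-value of the LOOCV accuracy.

    Labels are permuted uniformly ``n_perm`` times, LOOCV accuracy is
    recomputed for each, and p = (#{acc_perm >= acc_obs} + 1)/(n_perm + 1)
    (the small-sample correction; flags in the config switch to strict >
    or to the raw percentage).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if observed is None:
        observed = loocv_accuracy(x, y)
    perms = np.stack([rng.permutation(y) for _ in range(config.n_perm)])
    acc = _loocv_batch(x, perms)
    if config.perm_greater_equal:
        better = int(np.sum(acc >= observed - 1e-12))
    else:
        better = int(np.sum(acc > observed + 1e-12))
    if config.perm_plus_one:
        return (better + 1) / (config.n_perm + 1)
    return better / config.n_perm


def _empirical_quantile(sorted_stats: np.ndarray, q: float) -> float:
    """Left-continuous inverse CDF: an order statistic of the bootstrap."""
    b = sorted_stats.size
    idx = int(np.ceil(q * b)) - 1
    return float(sorted_stats[np.clip(idx, 0, b - 1)])


def bca_bootstrap_accuracy(
    x,
    y,
    config: ClassificationConfig = ClassificationConfig(),
    rng: np.random.Generator | None = None,
) -> BcaInterval:
    """Stratified BCa bootstrap CI of within-sample accuracy.

    Resamples preserve each group's n exactly (sampling with replacement
    within group).  The bias correction z0 comes from the bootstrap CDF
    at the observed statistic with ties counted half (accuracy is heavily
    discrete); the acceleration comes from a leave-one-out jackknife.
    ``significant`` is True when the lower limit exceeds chance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if idx0.size < 2 or idx1.size < 2:
        raise ValueError("need at least 2 observations per group")

    fit = fit_logistic(x, y)
    observed = within_accuracy(fit, x, y)

    b_res = config.n_boot
    pick0 = idx0[rng.integers(0, idx0.size, size=(b_res, idx0.size))]
    pick1 = idx1[rng.integers(0, idx1.size, size=(b_res, idx1.size))]
    pick = np.concatenate([pick0, pick1], axis=1)
    xb = x[pick]
    yb = y[pick]
    kind, b0, b1, thr = _fit_batch(xb, yb)
    stats_boot = _accuracy_rows(kind, b0, b1, thr, xb, yb)

    if np.ptp(stats_boot) == 0:
        c = float(stats_boot[0])
        return BcaInterval(observed, c, c, c > config.chance)

    # bias correction, ties at the observed value counted half
    below = np.sum(stats_boot < observed - 1e-12)
    ties = np.sum(np.abs(stats_boot - observed) <= 1e-12)
    prop = (below + 0.5 * ties) / b_res
    prop = np.clip(prop, 0.5 / b_res, 1.0 - 0.5 / b_res)
    z0 = sps.norm.ppf(prop)

    # acceleration from the leave-one-out jackknife of the statistic
    n = x.size
    keep = ~np.eye(n, dtype=bool)
    xj = np.broadcast_to(x, (n, n))[keep].reshape(n, n - 1)
    yj = np.broadcast_to(y, (n, n))[keep].reshape(n, n - 1)
    kj, j0, j1, tj = _fit_batch(xj, yj)
    theta_j = _accuracy_rows(kj, j0, j1, tj, xj, yj)
    dev = theta_j.mean() - theta_j
    denom = np.sum(dev**2) ** 1.5
    accel = float(np.sum(dev**3) / (6.0 * denom)) if denom > 0 else 0.0

    sorted_stats = np.sort(stats_boot)
    limits = []
    for zq in (sps.norm.ppf(config.alpha / 2), sps.norm.ppf(1 - config.alpha / 2)):
        denom_a = 1.0 - accel * (z0 + zq)
        if denom_a <= 0:
            adj = 1.0 if (z0 + zq) > 0 else 0.0
        else:
            adj = sps.norm.cdf(z0 + (z0 + zq) / denom_a)
        limits.append(_empirical_quantile(sorted_stats, float(adj)))
    lcl, ucl = min(limits), max(limits)
    return BcaInterval(observed, lcl, ucl, lcl > config.chance)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# group comparisons


def welch_t(x_a, x_b) -> GroupComparison:
    """Welch unequal-variance t-test with Satterthwaite fractional df."""
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups are constant: test undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    try:
        d = cohens_d(a, b)
    except ValueError:
        d = np.nan
    return GroupComparison(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), d=d)


def cohens_d(x_a, x_b) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# full screen


def run_full_screen(
    table: pd.DataFrame,
    config: ClassificationConfig = ClassificationConfig(),
    positive_label: str | None = None,
) -> ScreenResult:
    """Screen every predictor column of a participant table.

    ``table`` must hold a two-level ``group`` column; every other numeric
    column is a predictor.  Per predictor: drop missing cells, MAD-filter
    per group, fit the classifier, and compute within-sample accuracy
    with its stratified BCa interval, LOOCV accuracy, and the permutation
    p-value; Benjamini-Hochberg then adjusts the permutation p-values
    across predictors.  Group comparisons (Welch t, Cohen's d) are run on
    SD-filtered values.  Results are ranked by within-sample accuracy
    (name as tie-break) and are bit-reproducible given ``config.seed``.
    """
    if "group" not in table.columns:
        raise ValueError("table must contain a 'group' column")
    levels = sorted(pd.unique(table["group"].dropna()))
    if len(levels) != 2:
        raise ValueError(f"'group' must have exactly two levels, got {levels}")
    if positive_label is None:
        positive_label = "MS" if "MS" in levels else levels[0]
    if positive_label not in levels:
        raise ValueError(f"positive label {positive_label!r} not in {levels}")

    y_all = (table["group"] == positive_label).to_numpy(dtype=float)
    predictors = [c for c in table.columns if c != "group"]
    seeds = np.random.SeedSequence(config.seed).spawn(len(predictors))

    results: list[PredictorResult] = []
    comparisons: dict[str, GroupComparison] = {}
    skipped: dict[str, str] = {}

    for name, seed_seq in zip(predictors, seeds):
        col = pd.to_numeric(table[name], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(col)
        x, y = col[ok], y_all[ok]

        # group comparison on SD-filtered values
        a, b = x[y == 1], x[y == 0]
        if a.size >= 3 and b.size >= 3:
            try:
                comparisons[name] = welch_t(
                    filter_outliers_sd(a, config.sd_k),
                    filter_outliers_sd(b, config.sd_k),
                )
            except ValueError:
                pass

        # classification on MAD-filtered values
        keep = np.zeros(x.size, dtype=bool)
        for g in (0.0, 1.0):
            gi = y == g
            if gi.sum() >= 3:
                keep[gi] = _mad_keep_mask(x[gi], config.mad_k)
            else:
                keep[gi] = True
        xk, yk = x[keep], y[keep]
        if np.sum(yk == 1) < 2 or np.sum(yk == 0) < 2:
            skipped[name] = "fewer than 2 observations per class after filtering"
            continue

        rng = np.random.default_rng(seed_seq)
        fit = fit_logistic(xk, yk)
        acc = within_accuracy(fit, xk, yk)
        interval = bca_bootstrap_accuracy(xk, yk, config, rng)
        loocv = loocv_accuracy(xk, yk)
        perm_p = permutation_pvalue(xk, yk, config, rng, observed=loocv)
        results.append(
            PredictorResult(
                name=name,
                n_used=int(xk.size),
                within_accuracy=acc,
                bca_lcl=interval.lcl,
                bca_ucl=interval.ucl,
                significant_within=interval.significant,
                loocv_accuracy=loocv,
                perm_p=perm_p,
                separated=fit.separated,
            )
        )

    if results:
        adj = benjamini_hochberg([r.perm_p for r in results])
        for r, q in zip(results, adj):
            r.bh_p = float(q)
    results.sort(key=lambda r: (-r.within_accuracy, r.name))
    return ScreenResult(results=results, comparisons=comparisons, skipped=skipped, config=config)
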