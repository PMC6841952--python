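"""Psychometric analysis: logistic fits, PSE, step bias, bootstrap, reliability.

The psychometric function is a range-limited logistic

    p(x) = gamma + (ceiling - gamma) / (1 + exp(-(x - alpha) / beta))

with the floor ``gamma`` and ``ceiling`` fixed by the task (0.5-1 for 2AFC
detection, 0-1 for continuity judgments) and (alpha, beta) fitted.  The
default fit is least squares on the mean proportions across participants;
a Bernoulli maximum-likelihood option is available.  The point of subjective
equality is the x at the midpoint of the range (= alpha for this symmetric
parameterisation), and the threshold at a criterion fraction f of the dynamic
range is alpha + beta * log(f / (1 - f)).

Step bias is the difference between the PSEs of the two step directions; its
confidence interval and p-value come from a bootstrap over participants, with
the p-value read from a Gaussian fitted to the bootstrap distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, pearsonr


TRIAL_COLUMNS = ("participant", "condition", "x", "n", "k")


def make_trial_table(rows) -> pd.DataFrame:
    """Build and validate a trial table (participant, condition, x, n, k)."""
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    if ((df["k"] < 0) | (df["k"] > df["n"])).any():
        raise ValueError("trial counts must satisfy 0 <= k <= n")
    if not np.all(np.isfinite(df["x"])):
        raise ValueError("stimulus values must be finite")
    return df


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted range-limited logistic; beta > 0, gamma < ceiling."""

    alpha: float
    beta: float
    floor: float = 0.0
    ceiling: float = 1.0
    method: str = "lsq"
    residual_ss: float = np.nan
    increasing: bool = True

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.floor < self.ceiling <= 1.0:
            raise ValueError("need 0 <= floor < ceiling <= 1")

    def predict(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.alpha) / self.beta
        if not self.increasing:
            z = -z
        return self.floor + (self.ceiling - self.floor) / (1.0 + np.exp(-z))


def _aggregate(data, x_col="x") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean proportion per x level.  Accepts a trial table or (x, p) arrays."""
    if isinstance(data, pd.DataFrame):
        props = data.assign(p=data["k"] / data["n"]).groupby(x_col)["p"].mean()
        x = props.index.to_numpy(dtype=float)
        p = props.to_numpy(dtype=float)
        n = data.groupby(x_col)["n"].sum().to_numpy(dtype=float)
        return x, p, n
    x, p = data
    return np.asarray(x, dtype=float), np.asarray(p, dtype=float), None


def fit_logistic(data, floor: float = 0.0, ceiling: float = 1.0,
                 method: str = "lsq") -> PsychometricFit:
    """Fit the range-limited logistic to proportion data.

    ``data`` is either a trial table (fit to the across-participant mean
    proportions) or a tuple ``(x, p)`` of levels and proportions.
    ``method='lsq'`` (default) minimises squared error on the mean
    proportions; ``method='ml'`` maximises the Bernoulli likelihood (needs a
    trial table for the counts).
    """
    x, p, n = _aggregate(data)
    if len(x) < 3:
        raise ValueError("need at least 3 distinct x levels to fit")
    if np.ptp(p) < 1e-12:
        raise ValueError("all proportions identical; slope is unidentifiable")
    span = (ceiling - floor)
    # initial alpha: x where p crosses the midpoint; initial beta from the x range
    mid = floor + span / 2.0
    order = np.argsort(x)
    xs, ps = x[order], p[order]
    sign = 1.0 if ps[-1] >= ps[0] else -1.0
    crossings = np.nonzero(np.diff(np.sign(sign * (ps - mid))) > 0)[0]
    if len(crossings):
        i = crossings[0]
        frac = (mid - sign * ps[i]) / max(sign * (ps[i + 1] - ps[i]), 1e-12)
        alpha0 = xs[i] + np.clip(frac, 0, 1) * (xs[i + 1] - xs[i])
    else:
        alpha0 = float(np.median(x))
    beta0 = max(np.ptp(x) / 5.0, 1e-6)

    if method == "lsq":
        def resid(theta):
            a, logb = theta
            z = sign * (x - a) / np.exp(logb)
            return floor + span / (1.0 + np.exp(-z)) - p

        sol = least_squares(resid, [alpha0, np.log(beta0)], method="lm")
        alpha, beta = sol.x[0], float(np.exp(sol.x[1]))
        rss = float(np.sum(sol.fun**2))
    elif method == "ml":
        if n is None or not isinstance(data, pd.DataFrame):
            raise ValueError("maximum-likelihood fitting needs a trial table")
        agg = data.groupby("x")[["n", "k"]].sum()
        xs_ml = agg.index.to_numpy(dtype=float)
        nn = agg["n"].to_numpy(dtype=float)
        kk = agg["k"].to_numpy(dtype=float)

        def nll(theta):
            a, logb = theta
            z = sign * (xs_ml - a) / np.exp(logb)
            q = floor + span / (1.0 + np.exp(-z))
            q = np.clip(q, 1e-9, 1 - 1e-9)
            return -np.sum(kk * np.log(q) + (nn - kk) * np.log(1 - q))

        from scipy.optimize import minimize

        sol = minimize(nll, [alpha0, np.log(beta0)], method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000})
        alpha, beta = sol.x[0], float(np.exp(sol.x[1]))
        rss = float(sol.fun)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    return PsychometricFit(alpha=float(alpha), beta=beta, floor=floor,
                           ceiling=ceiling, method=method, residual_ss=rss,
                           increasing=bool(sign > 0))


def point_of_subjective_equality(fit: PsychometricFit) -> float:
    """x at which p(x) reaches the midpoint of (floor, ceiling) — alpha here."""
    return float(fit.alpha)


def step_bias(fit_up: PsychometricFit, fit_down: PsychometricFit) -> float:
    """PSE(up) - PSE(down)."""
    return point_of_subjective_equality(fit_up) - point_of_subjective_equality(fit_down)


def threshold_at_criterion(fit: PsychometricFit, criterion_fraction: float) -> float:
    """x at which p(x) = floor + criterion_fraction * (ceiling - floor).

    For fraction 2/3 this is the 0.833 point on a 0.5-1 range (2AFC masking)
    and the 0.667 point on a 0-1 range (continuity); analytically
    alpha + beta * log(f / (1-f)).
    """
    f = criterion_fraction
    if not 0.0 < f < 1.0:
        raise ValueError(f"criterion fraction must lie strictly in (0, 1), got {f}")
    offset = fit.beta * np.log(f / (1.0 - f))
    return float(fit.alpha + offset if fit.increasing else fit.alpha - offset)


# --------------------------------------------------------------------------
# batched least-squares logistic fitting (for the bootstrap)


def _fit_logistic_batch(P: np.ndarray, x: np.ndarray, floor: float,
                        ceiling: float, n_iter: int = 80) -> np.ndarray:
    """Levenberg-Marquardt least-squares logistic fits, vectorised over rows.

    ``P`` is (B, L) mean proportions at the L levels ``x``.  Returns (B, 2)
    arrays of (alpha, beta).  Matches the scalar ``fit_logistic`` solution to
    high accuracy on well-behaved curves; used for bootstrap replicates where
    calling scipy per replicate would dominate the runtime.
    """
    B, L = P.shape
    span = ceiling - floor
    mid = floor + span / 2.0
    # initial alpha from the first midpoint crossing of the (assumed
    # increasing) mean curve; initial beta from the x range
    idx = np.clip(np.argmax(P >= mid, axis=1), 1, L - 1)
    x_hi = x[idx]
    x_lo = x[idx - 1]
    p_hi = P[np.arange(B), idx]
    p_lo = P[np.arange(B), idx - 1]
    frac = np.clip((mid - p_lo) / np.maximum(p_hi - p_lo, 1e-9), 0.0, 1.0)
    alpha = x_lo + frac * (x_hi - x_lo)
    logb = np.full(B, np.log(max(np.ptp(x) / 5.0, 1e-6)))

    lam = np.full(B, 1e-3)
    xb = x[None, :]

    def residuals(a, lb):
        z = (xb - a[:, None]) / np.exp(lb)[:, None]
        sig = 1.0 / (1.0 + np.exp(-z))
        return floor + span * sig - P, sig, z

    r, sig, z = residuals(alpha, logb)
    cost = np.sum(r**2, axis=1)
    for _ in range(n_iter):
        dsig = span * sig * (1.0 - sig)
        beta = np.exp(logb)
        J_a = -dsig / beta[:, None]
        J_b = -dsig * z  # derivative w.r.t. log beta
        g_a = np.sum(J_a * r, axis=1)
        g_b = np.sum(J_b * r, axis=1)
        H_aa = np.sum(J_a * J_a, axis=1) * (1.0 + lam)
        H_bb = np.sum(J_b * J_b, axis=1) * (1.0 + lam)
        H_ab = np.sum(J_a * J_b, axis=1)
        det = H_aa * H_bb - H_ab**2
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        da = -(H_bb * g_a - H_ab * g_b) / det
        db = -(H_aa * g_b - H_ab * g_a) / det
        db = np.clip(db, -2.0, 2.0)
        new_alpha = alpha + da
        new_logb = np.clip(logb + db, np.log(1e-6), np.log(1e6))
        r_new, sig_new, z_new = residuals(new_alpha, new_logb)
        cost_new = np.sum(r_new**2, axis=1)
        improved = cost_new < cost
        alpha = np.where(improved, new_alpha, alpha)
        logb = np.where(improved, new_logb, logb)
        lam = np.where(improved, lam * 0.5, lam * 4.0)
        lam = np.clip(lam, 1e-9, 1e9)
        r = np.where(improved[:, None], r_new, r)
        sig = np.where(improved[:, None], sig_new, sig)
        z = np.where(improved[:, None], z_new, z)
        cost = np.where(improved, cost_new, cost)
    return np.column_stack([alpha, np.exp(logb)])


@dataclass(frozen=True)
class BootstrapBiasResult:
    bias: float
    ci_low: float
    ci_high: float
    p_value: float
    boot_mean: float
    boot_sd: float
    n_boot: int
    replicates: np.ndarray


def _proportion_cube(trials: pd.DataFrame):
    """(participants, levels, conditions) proportion array from a trial table."""
    participants = np.sort(trials["participant"].unique())
    levels = np.sort(trials["x"].unique())
    conditions = np.sort(trials["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(
            f"expected exactly two step-direction conditions, got {list(conditions)}"
        )
    pivot_k = trials.pivot_table(index="participant", columns=["condition", "x"],
                                 values="k", aggfunc="sum")
    pivot_n = trials.pivot_table(index="participant", columns=["condition", "x"],
                                 values="n", aggfunc="sum")
    cube = np.empty((len(participants), len(levels), 2))
    for ci, cond in enumerate(conditions):
        kk = pivot_k[cond].reindex(index=participants, columns=levels).to_numpy()
        nn = pivot_n[cond].reindex(index=participants, columns=levels).to_numpy()
        if np.isnan(kk).any() or np.isnan(nn).any():
            raise ValueError("every participant needs trials at every (condition, x)")
        cube[:, :, ci] = kk / nn
    return cube, levels, conditions


def bootstrap_bias(trials: pd.DataFrame, n_boot: int = 10_000, seed: int = 0,
                   floor: float = 0.0, ceiling: float = 1.0) -> BootstrapBiasResult:
    """Step bias with participant-bootstrap CI and Gaussian-fit p-value.

    Conditions are taken in sorted order as (down, up); the bias is
    PSE(second) - PSE(first).  Each bootstrap replicate resamples participants
    with replacement, recomputes the mean curves, refits both conditions, and
    recomputes the bias.  The 95% CI is the percentile interval of the
    replicate distribution; the p-value is the two-tailed tail probability of
    zero under a Gaussian fitted to the replicates.
    """
    cube, levels, conditions = _proportion_cube(trials)
    n_part = cube.shape[0]
    if n_part < 2:
        raise ValueError("bootstrap over participants needs at least 2 participants")

    mean_curves = cube.mean(axis=0)  # (L, 2)
    fits = _fit_logistic_batch(mean_curves.T, levels, floor, ceiling)
    bias = float(fits[1, 0] - fits[0, 0])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_part, size=(n_boot, n_part))
    boot_curves = cube[idx].mean(axis=1)  # (n_boot, L, 2)
    stacked = np.concatenate([boot_curves[:, :, 0], boot_curves[:, :, 1]], axis=0)
    params = _fit_logistic_batch(stacked, levels, floor, ceiling)
    pse_down = params[:n_boot, 0]
    pse_up = params[n_boot:, 0]
    replicates = pse_up - pse_down
    ci_low, ci_high = np.percentile(replicates, [2.5, 97.5])
    mu, sd = float(replicates.mean()), float(replicates.std())
    if sd == 0:
        p_value = 0.0 if mu != 0 else 1.0
    else:
        p_value = float(2.0 * norm.cdf(-abs(mu) / sd))
    return BootstrapBiasResult(bias=bias, ci_low=float(ci_low), ci_high=float(ci_high),
                               p_value=p_value, boot_mean=mu, boot_sd=sd,
                               n_boot=n_boot, replicates=replicates)


@dataclass(frozen=True)
class DisattenuatedCorrelation:
    value: float
    clipped: bool

    def __float__(self):
        return self.value


def disattenuated_correlation(r_xy: float, r_xx: float, r_yy: float
                              ) -> DisattenuatedCorrelation:
    """Correlation corrected for attenuation: r_xy / sqrt(r_xx * r_yy).

    Reliabilities must be positive; results outside [-1, 1] are clipped and
    flagged.
    """
    if not (0.0 < r_xx <= 1.0 and 0.0 < r_yy <= 1.0):
        raise ValueError("reliabilities must lie in (0, 1]")
    if abs(r_xy) > 1.0:
        raise ValueError("|r_xy| cannot exceed 1")
    raw = r_xy / np.sqrt(r_xx * r_yy)
    clipped = abs(raw) > 1.0
    return DisattenuatedCorrelation(value=float(np.clip(raw, -1.0, 1.0)),
                                    clipped=bool(clipped))


def split_half_reliability(responses: np.ndarray, n_splits: int = 10_000,
                           seed: int = 0) -> float:
    """Mean split-half Pearson correlation over random participant splits.

    ``responses`` is a (participants x items) matrix.  For each split the
    participants are randomly divided into halves (sizes differing by one for
    odd counts) and the Pearson correlation between the halves' per-item means
    is computed; the average over splits is returned.
    """
    responses = np.asarray(responses, dtype=float)
    n_part, n_items = responses.shape
    if n_part < 4:
        raise ValueError("need at least 4 participants")
    if n_items < 3:
        raise ValueError("need at least 3 items")
    rng = np.random.default_rng(seed)
    half = n_part // 2
    rs = np.empty(n_splits)
    for i in range(n_splits):
        perm = rng.permutation(n_part)
        m1 = responses[perm[:half]].mean(axis=0)
        m2 = responses[perm[half:]].mean(axis=0)
        rs[i] = pearsonr(m1, m2)[0]
    return float(np.mean(rs))
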