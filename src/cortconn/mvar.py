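"""Sliding-window multivariate autoregressive modeling of ROI signals.

The MVAR estimator is the Vieira-Morf lattice: an order-recursive algorithm
computing forward/backward reflection coefficient matrices with
geometric-mean (Cholesky) normalization.  Sums of forward/backward error
covariances are accumulated across the trial ensemble rather than over a
concatenation of trials, so no spurious cross-trial transitions enter the
estimate.  The lattice yields coefficient matrices and residual covariances
for every order up to the maximum in a single pass, which makes the
six-criterion order scan cheap.

Model validation covers residual whiteness (autocorrelation bounds plus the
Box-Pierce, Ljung-Box and Li-McLeod multivariate portmanteau statistics),
percent consistency (how much of the data's correlation structure a model
simulation reproduces) and stability (log spectral radius of the companion
matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.signal
import scipy.stats

__all__ = [
    "WindowedMVAR",
    "ValidationReport",
    "detrend_normalize",
    "sliding_windows",
    "vieira_morf_fit",
    "vieira_morf_all_orders",
    "order_criteria",
    "select_order",
    "simulate_var",
    "whiteness_tests",
    "percent_consistency",
    "stability_index",
    "fit_windowed_mvar",
    "validate_windowed_mvar",
]


@dataclass
class WindowedMVAR:
    """Per-window VAR(p) coefficient sets for one epoch ensemble."""

    window_starts_s: np.ndarray            # (W,)
    A: list[np.ndarray]                    # per window: (p, M, M)
    Sigma: list[np.ndarray]                # per window: (M, M)
    order: int
    fs: float
    window_len_s: float
    step_s: float

    @property
    def n_windows(self) -> int:
        return len(self.A)

    @property
    def n_nodes(self) -> int:
        return self.A[0].shape[1]


@dataclass
class ValidationReport:
    """Per-window model diagnostics."""

    whiteness: list[dict]          # per window: acf_pass_fraction + test p-values
    consistency_pct: np.ndarray    # (W,)
    stability: np.ndarray          # (W,) log spectral radius

    def summary(self) -> dict:
        lb = np.array([w["ljung_box_p"] for w in self.whiteness])
        return {
            "consistency_mean": float(np.mean(self.consistency_pct)),
            "consistency_sd": float(np.std(self.consistency_pct, ddof=1)) if len(self.consistency_pct) > 1 else 0.0,
            "stability_pass_rate": float(np.mean(self.stability < 0)),
            "whiteness_pass_rate_ljung_box": float(np.mean(lb > 0.05)),
            "acf_pass_fraction_mean": float(np.mean([w["acf_pass_fraction"] for w in self.whiteness])),
        }


# ---------------------------------------------------------------------------
# preprocessing of ROI ensembles
# ---------------------------------------------------------------------------


def detrend_normalize(data: np.ndarray, channel_names: list[str] | None = None) -> np.ndarray:
    """Detrend and normalize an (M, T, N) ensemble across time and trials.

    Steps: per-trial linear detrend and temporal z-scoring of each channel,
    then ensemble normalization (per-timepoint mean removal and variance
    scaling across trials).  The ensemble step removes the phase-locked
    evoked component so the AR model sees the induced dynamics.
    """
    data = np.asarray(data, dtype=float)
    M, T, N = data.shape
    if N < 2:
        raise ValueError("ensemble normalization needs at least 2 trials")
    out = scipy.signal.detrend(data, axis=1, type="linear")
    sd = out.std(axis=1, keepdims=True)
    tiny = 1e-10 * max(float(np.abs(data).max()), 1e-300)
    bad = np.flatnonzero(np.any(sd[:, 0, :] <= tiny, axis=1))
    if bad.size:
        name = channel_names[bad[0]] if channel_names else str(bad[0])
        raise ValueError(f"zero-variance channel after detrend: {name}")
    out = out / sd
    mu = out.mean(axis=2, keepdims=True)
    sd_e = out.std(axis=2, keepdims=True)
    sd_e[sd_e == 0] = 1.0
    return (out - mu) / sd_e


def sliding_windows(T_samples: int, fs: float, window_len_s: float, step_s: float) -> list[tuple[int, int]]:
    """Half-open sample index pairs of a sliding window over the epoch.

    ``count = floor((T - w) / s) + 1`` with ``w = round(window_len * fs)``
    and ``s = round(step * fs)``.
    """
    w = int(round(window_len_s * fs))
    s = int(round(step_s * fs))
    if s < 1:
        raise ValueError("window step shorter than one sample at this rate")
    if w > T_samples:
        raise ValueError(f"window of {w} samples exceeds epoch of {T_samples} samples")
    n = (T_samples - w) // s + 1
    return [(i * s, i * s + w) for i in range(n)]


# ---------------------------------------------------------------------------
# Vieira-Morf lattice
# ---------------------------------------------------------------------------


def vieira_morf_all_orders(data: np.ndarray, p_max: int):
    """One lattice pass returning (A, Sigma) for every order 1..p_max.

    ``data`` is (M, w, N).  Reflection coefficients use the geometric-mean
    normalization: rho_m = Lf^-1 Rfb Lb^-T with Cholesky factors of the
    forward/backward error covariances, accumulated over the ensemble.
    """
    data = np.asarray(data, dtype=float)
    M, w, N = data.shape
    if p_max < 1:
        raise ValueError("order must be >= 1")
    if w <= p_max:
        raise ValueError("window too short for requested order")
    ef = data.copy()  # forward errors, valid on [m, w)
    eb = data.copy()  # backward errors, valid on [m, w) (index t holds e_b(t))
    A: list[np.ndarray] = []   # A[i] = (i+1, M, M) not stored; keep current
    B: list[np.ndarray] = []
    A_cur = np.zeros((0, M, M))
    B_cur = np.zeros((0, M, M))
    results = []
    for m in range(1, p_max + 1):
        vf = ef[:, m:, :].reshape(M, -1)
        vb = eb[:, m - 1 : w - 1, :].reshape(M, -1)
        Rff = vf @ vf.T
        Rbb = vb @ vb.T
        Rfb = vf @ vb.T
        try:
            Lf = np.linalg.cholesky(Rff)
            Lb = np.linalg.cholesky(Rbb)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular error covariance at lattice stage {m}; "
                "window may be too short or channels collinear"
            ) from exc
        rho = sla.solve_triangular(Lf, Rfb, lower=True)
        rho = sla.solve_triangular(Lb, rho.T, lower=True).T  # Lf^-1 Rfb Lb^-T
        Kf = Lf @ rho @ np.linalg.inv(Lb)
        Kb = Lb @ rho.T @ np.linalg.inv(Lf)
        # Levinson-Whittle coefficient update
        A_new = np.empty((m, M, M))
        B_new = np.empty((m, M, M))
        A_new[m - 1] = Kf
        B_new[m - 1] = Kb
        for i in range(m - 1):
            A_new[i] = A_cur[i] - Kf @ B_cur[m - 2 - i]
            B_new[i] = B_cur[i] - Kb @ A_cur[m - 2 - i]
        A_cur, B_cur = A_new, B_new
        # error update on the shrunken valid range
        f_part = ef[:, m:, :]
        b_part = eb[:, m - 1 : w - 1, :]
        ef_new = f_part - np.einsum("ij,jtn->itn", Kf, b_part)
        eb_new = b_part - np.einsum("ij,jtn->itn", Kb, f_part)
        ef[:, m:, :] = ef_new
        eb[:, m:, :] = eb_new
        n_valid = (w - m) * N
        res = ef[:, m:, :].reshape(M, -1)
        Sigma = res @ res.T / n_valid
        results.append((A_cur.copy(), 0.5 * (Sigma + Sigma.T)))
    return results


def vieira_morf_fit(data: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit VAR(order) to an (M, w, N) ensemble window by the Vieira-Morf
    lattice.  Returns (A, Sigma) with A of shape (order, M, M).

    Warns when the data-to-parameter ratio ``N*w*M / (order*M^2)`` drops
    below 10:1, the regime where the unregularized lattice becomes
    unreliable.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    M, w, N = data.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    ratio = (N * w * M) / (order * M * M)
    if ratio < 10:
        warnings.warn(
            f"data-to-parameter ratio {ratio:.1f} < 10:1 "
            f"({N * w * M} points for {order * M * M} coefficients)",
            stacklevel=2,
        )
    return vieira_morf_all_orders(data, order)[-1]


def residuals(A: np.ndarray, data: np.ndarray) -> np.ndarray:
    """One-step-ahead prediction errors (M, w-p, N) of a VAR(p) model."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    p = A.shape[0]
    M, w, N = data.shape
    pred = np.zeros((M, w - p, N))
    for k in range(1, p + 1):
        pred += np.einsum("ij,jtn->itn", A[k - 1], data[:, p - k : w - k, :])
    return data[:, p:, :] - pred


# ---------------------------------------------------------------------------
# order selection
# ---------------------------------------------------------------------------

CRITERIA = ("aic", "aicc", "sbc", "hq", "fpe", "rissanen")


def order_criteria(data: np.ndarray, p_max: int = 30, p_min: int = 1) -> dict[str, np.ndarray]:
    """Information-criterion curves over candidate orders for one ensemble.

    Every criterion is the log-determinant of the order-p residual
    covariance plus its standard multivariate penalty with k = p*M^2
    parameters and n the number of ensemble sample points:

    * ``aic``       L + 2k/n
    * ``aicc``      L + 2k/(n - k - 1)       (small-sample corrected)
    * ``sbc``       L + k ln(n)/n            (Schwarz-Bayes)
    * ``hq``        L + 2k ln(ln n)/n        (Hannan-Quinn)
    * ``fpe``       L + M ln((n + Mp + 1)/(n - Mp - 1))  (log final
      prediction error)
    * ``rissanen``  L + k (ln n + ln ln n)/n (minimum description length;
      a heavier-than-Schwarz code-length penalty)
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    M, w, N = data.shape
    n = w * N
    fits = vieira_morf_all_orders(data, p_max)
    orders = np.arange(p_min, p_max + 1)
    out = {name: np.empty(len(orders)) for name in CRITERIA}
    out["orders"] = orders
    for oi, p in enumerate(orders):
        _, Sigma = fits[p - 1]
        sign, logdet = np.linalg.slogdet(Sigma)
        L = logdet if sign > 0 else np.inf
        k = p * M * M
        out["aic"][oi] = L + 2.0 * k / n
        out["aicc"][oi] = L + (2.0 * k / (n - k - 1) if n - k - 1 > 0 else np.inf)
        out["sbc"][oi] = L + k * np.log(n) / n
        out["hq"][oi] = L + 2.0 * k * np.log(np.log(n)) / n
        denom = n - M * p - 1
        out["fpe"][oi] = L + (M * np.log((n + M * p + 1) / denom) if denom > 0 else np.inf)
        out["rissanen"][oi] = L + k * (np.log(n) + np.log(np.log(n))) / n
    return out


def select_order(curves: dict[str, np.ndarray]) -> int:
    """Floor of the mean of the six criteria's argmin orders."""
    orders = curves["orders"]
    mins = [orders[int(np.argmin(curves[name]))] for name in CRITERIA]
    return int(np.floor(np.mean(mins)))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def stability_index(A: np.ndarray) -> float:
    """Natural log of the spectral radius of the VAR companion matrix.

    Negative values indicate a stable (stationary) process; zero is the
    marginal boundary.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, M, _ = A.shape
    comp = np.zeros((M * p, M * p))
    comp[:M] = A.transpose(1, 0, 2).reshape(M, M * p)
    if p > 1:
        comp[M:, : M * (p - 1)] = np.eye(M * (p - 1))
    radius = np.max(np.abs(np.linalg.eigvals(comp)))
    with np.errstate(divide="ignore"):
        return float(np.log(radius))


def simulate_var(
    A: np.ndarray,
    Sigma: np.ndarray,
    T: int,
    N: int,
    rng: np.random.Generator,
    burn: int | None = None,
) -> np.ndarray:
    """Simulate (M, T, N) trials from a stationary VAR(p) model."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, M, _ = A.shape
    if burn is None:
        burn = 10 * p
    L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(M))
    out = np.empty((M, T, N))
    for nidx in range(N):
        innov = rng.standard_normal((burn + T, M)) @ L.T
        x = np.zeros((burn + T, M))
        for t in range(burn + T):
            acc = innov[t].copy()
            for k in range(1, p + 1):
                if t - k >= 0:
                    acc += A[k - 1] @ x[t - k]
            x[t] = acc
        out[:, :, nidx] = x[burn:].T
    return out


def _lagged_cov(res: np.ndarray, h: int) -> np.ndarray:
    """Ensemble-pooled lagged covariance matrices C_0..C_h of residuals."""
    M, n, N = res.shape
    flat_n = n * N
    C = np.empty((h + 1, M, M))
    for k in range(h + 1):
        a = res[:, k:, :].reshape(M, -1)
        b = res[:, : n - k, :].reshape(M, -1)
        C[k] = a @ b.T / flat_n
    return C


def whiteness_tests(A: np.ndarray, data: np.ndarray, lags: int | None = None, order: int | None = None) -> dict:
    """Residual-whiteness diagnostics for one fitted window.

    Returns the fraction of residual auto/cross-correlations inside the
    +-1.96/sqrt(n) band over lags 1..h, and the Box-Pierce, Ljung-Box and
    Li-McLeod multivariate portmanteau p-values against a chi-square with
    M^2 (h - p) degrees of freedom.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    res = residuals(A, data)
    M, n, N = res.shape
    p = A.shape[0] if A.ndim == 3 else 1
    if order is not None:
        p = order
    if lags is None:
        lags = min(20, n // 4)
    if lags < p + 1:
        lags = p + 1
    if lags >= n:
        raise ValueError(f"lag count {lags} must be below residual length {n}")
    n_eff = n * N
    C = _lagged_cov(res, lags)
    C0_inv = np.linalg.inv(C[0] + 1e-12 * np.trace(C[0]) / M * np.eye(M))
    q_bp = 0.0
    q_lb = 0.0
    for k in range(1, lags + 1):
        t = np.trace(C[k].T @ C0_inv @ C[k] @ C0_inv)
        q_bp += t
        q_lb += t / (n_eff - k)
    q_bp *= n_eff
    q_lb *= n_eff * (n_eff + 2)
    q_lm = q_bp + M * M * lags * (lags + 1) / (2.0 * n_eff)
    df = M * M * (lags - p)
    df = max(df, 1)
    # ACF band check over all pairs and lags
    d0 = np.sqrt(np.diag(C[0]))
    acf = C[1:] / np.outer(d0, d0)[None]
    bound = 1.96 / np.sqrt(n_eff)
    acf_pass = float(np.mean(np.abs(acf) <= bound))
    chi2 = scipy.stats.chi2(df)
    return {
        "acf_pass_fraction": acf_pass,
        "acf_pass": acf_pass >= 0.95,
        "box_pierce_stat": float(q_bp),
        "box_pierce_p": float(chi2.sf(q_bp)),
        "ljung_box_stat": float(q_lb),
        "ljung_box_p": float(chi2.sf(q_lb)),
        "li_mcleod_stat": float(q_lm),
        "li_mcleod_p": float(chi2.sf(q_lm)),
        "lags": int(lags),
        "df": int(df),
    }


def percent_consistency(A: np.ndarray, Sigma: np.ndarray, data: np.ndarray, seed: int | np.random.Generator = 0, lags: int = 10) -> float:
    """Percentage of the data's correlation structure captured by the model.

    ``PC = 100 * (1 - ||r_sim - r_real|| / ||r_real||)`` where r stacks all
    auto- and cross-correlations up to ``lags`` of the real ensemble and of
    a model-simulated ensemble with matched trial count and length.
    """
    if stability_index(A) >= 0:
        raise ValueError("model is unstable; percent consistency undefined")
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    M, w, N = data.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = simulate_var(A, Sigma, w, N, rng)
    h = min(lags, w - 2)

    def corr_vector(x: np.ndarray) -> np.ndarray:
        C = _lagged_cov(x - x.mean(axis=(1, 2), keepdims=True), h)
        d0 = np.sqrt(np.diag(C[0]))
        return (C / np.outer(d0, d0)[None]).ravel()

    r_real = corr_vector(data)
    r_sim = corr_vector(sim)
    return float(100.0 * (1.0 - np.linalg.norm(r_sim - r_real) / np.linalg.norm(r_real)))


# ---------------------------------------------------------------------------
# windowed driver
# ---------------------------------------------------------------------------


def fit_windowed_mvar(
    data: np.ndarray,
    fs: float,
    window_len_s: float = 0.55,
    step_s: float = 0.01,
    order: int = 7,
    t0: float = 0.0,
) -> WindowedMVAR:
    """Fit a VAR(order) in every sliding window of an (M, T, N) ensemble."""
    data = np.asarray(data, dtype=float)
    M, T, N = data.shape
    wins = sliding_windows(T, fs, window_len_s, step_s)
    A_list, S_list, starts = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ratio warning raised once below
        for lo, hi in wins:
            A, S = vieira_morf_fit(data[:, lo:hi, :], order)
            A_list.append(A)
            S_list.append(S)
            starts.append(t0 + lo / fs)
    w = int(round(window_len_s * fs))
    ratio = (N * w * M) / (order * M * M)
    if ratio < 10:
        warnings.warn(f"data-to-parameter ratio {ratio:.1f} < 10:1 in sliding windows", stacklevel=2)
    return WindowedMVAR(
        window_starts_s=np.asarray(starts),
        A=A_list,
        Sigma=S_list,
        order=order,
        fs=fs,
        window_len_s=window_len_s,
        step_s=step_s,
    )


def validate_windowed_mvar(model: WindowedMVAR, data: np.ndarray, seed: int = 0, consistency_lags: int = 10) -> ValidationReport:
    """Whiteness, consistency and stability diagnostics for every window."""
    data = np.asarray(data, dtype=float)
    wins = sliding_windows(data.shape[1], model.fs, model.window_len_s, model.step_s)
    white, cons, stab = [], [], []
    rng = np.random.default_rng(seed)
    for (lo, hi), A, S in zip(wins, model.A, model.Sigma):
        wdata = data[:, lo:hi, :]
        white.append(whiteness_tests(A, wdata))
        stab.append(stability_index(A))
        if stab[-1] < 0:
            cons.append(percent_consistency(A, S, wdata, rng, lags=consistency_lags))
        else:
            cons.append(np.nan)
    return ValidationReport(
        whiteness=white,
        consistency_pct=np.asarray(cons),
        stability=np.asarray(stab),
    )
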