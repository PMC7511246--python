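"""Statistical estimation for fNIRS task responses.

Three solvers for the channel-wise linear model ``y = X_task b + X_short g + e``:

* ``ols_fit`` — ordinary least squares with classical t inference.  Serially
  correlated physiological noise violates its white-noise assumption and
  inflates type-I error badly.
* ``ar_irls_fit`` — iterative autoregressive robust least squares: alternate
  (a) Tukey-bisquare robust regression, (b) an AR(p) fit to the residuals
  with p chosen by AIC, (c) whitening of both sides of the model by the AR
  filter, until the coefficients converge.  Inference is run on the whitened,
  robust-weighted model, which restores near-nominal false-positive rates.
* ``me_ar_irls_fit`` — a mixed-effects variant in which the short-separation
  coefficients (Gamma) of all channels are treated as draws from a common
  zero-mean normal prior N(0, sigma^2).  sigma is pooled across the probe via
  the robust scale 1.4826 * MAD and updated in an EM-style outer loop; the
  prior acts as a ridge penalty on the Gamma block only.

Short-separation regressors are built from the scalp-only SS channels and
(optionally) decorrelated by PCA so the nuisance block is orthonormal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from statsmodels.tsa.stattools import levinson_durbin

from .probe_signal import CHROMOPHORES, HemoScan, ProbeGeometry, nearest_ss

__all__ = [
    "StimulusDesign",
    "DesignMatrix",
    "GLMChannelResult",
    "MEState",
    "canonical_hrf",
    "build_task_design",
    "build_ss_design",
    "ols_fit",
    "ar_irls_fit",
    "me_ar_irls_fit",
    "hotelling_joint",
]

BISQUARE_TUNING = 4.685  # 95% efficiency at the normal
MAD_TO_SD = 1.4826  # median-consistency factor


@dataclass(frozen=True)
class StimulusDesign:
    """Event timing for one condition: onsets and durations in seconds."""

    onsets: np.ndarray
    durations: np.ndarray
    condition: str = "task"

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))
        object.__setattr__(self, "durations", np.asarray(self.durations, dtype=float))
        if self.onsets.ndim != 1 or self.onsets.shape != self.durations.shape:
            raise ValueError("onsets and durations must be 1D arrays of equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")


@dataclass
class DesignMatrix:
    """Task regressors plus optional short-separation nuisance block."""

    xtask: np.ndarray
    task_labels: list
    fs: float
    xshort: np.ndarray | None = None
    short_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.xtask = np.atleast_2d(np.asarray(self.xtask, dtype=float))
        if self.xtask.shape[0] < self.xtask.shape[1]:
            raise ValueError("xtask must be time x k")
        if np.any(np.all(self.xtask == 0, axis=0)):
            raise ValueError("design contains an all-zero task column")
        if len(set(self.task_labels)) != len(self.task_labels):
            raise ValueError("task column labels must be unique")
        if self.xshort is not None:
            self.xshort = np.atleast_2d(np.asarray(self.xshort, dtype=float))
            if self.xshort.shape[0] != self.xtask.shape[0]:
                raise ValueError("xtask and xshort must share the time axis")

    @property
    def n_time(self) -> int:
        return self.xtask.shape[0]

    def full(self, include_const: bool = True):
        """Stacked [xtask | xshort | const] matrix with column labels."""
        blocks = [self.xtask]
        labels = list(self.task_labels)
        if self.xshort is not None:
            blocks.append(self.xshort)
            labels += list(self.short_labels)
        if include_const:
            blocks.append(np.ones((self.n_time, 1)))
            labels.append("const")
        return np.hstack(blocks), labels


@dataclass
class GLMChannelResult:
    """Per-channel fit: coefficients, covariance, AR model, robust weights,
    and t/p inference for the task coefficients."""

    channel: int
    chromophore: str
    labels: list
    beta: np.ndarray
    cov: np.ndarray
    task_slice: slice
    short_slice: slice
    ar_coefficients: np.ndarray
    robust_weights: np.ndarray
    dof: float
    sigma2: float
    t: np.ndarray
    p: np.ndarray
    converged: bool = True

    @property
    def beta_task(self) -> np.ndarray:
        return self.beta[self.task_slice]

    @property
    def beta_short(self) -> np.ndarray:
        return self.beta[self.short_slice]


@dataclass
class MEState:
    """Pooled random-effect scale for the mixed-effects solver."""

    sigma: float
    iterations: int
    converged: bool


def canonical_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities: a positive lobe peaking ~5-6 s after
    the impulse and an undershoot around 16 s scaled by ``ratio``.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion) - ratio * stats.gamma.pdf(
        t, undershoot_delay / dispersion, scale=dispersion
    )
    return h


def build_task_design(
    stims,
    n_time: int,
    fs: float,
    hrf_kernel_duration: float = 40.0,
    **hrf_kwargs,
):
    """Boxcar-convolved canonical-HRF task regressors, one column per
    condition, each normalised to unit peak.

    Returns ``(X, labels)``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if isinstance(stims, StimulusDesign):
        stims = [stims]
    t_kernel = np.arange(0, hrf_kernel_duration, 1.0 / fs)
    hrf = canonical_hrf(t_kernel, **hrf_kwargs)
    cols, labels = [], []
    scan_end = n_time / fs
    for stim in stims:
        if stim.onsets.size == 0:
            raise ValueError(f"empty condition {stim.condition!r}: no events")
        if np.any(stim.onsets + stim.durations > scan_end):
            raise ValueError(
                f"condition {stim.condition!r} has events beyond scan end ({scan_end:.1f} s)"
            )
        box = np.zeros(n_time)
        for onset, dur in zip(stim.onsets, stim.durations):
            i0 = int(np.round(onset * fs))
            i1 = min(n_time, int(np.round((onset + dur) * fs)))
            box[i0:i1] = 1.0
        col = np.convolve(box, hrf)[:n_time]
        peak = np.abs(col).max()
        if peak == 0:
            raise ValueError(f"empty condition {stim.condition!r}: zero regressor")
        cols.append(col / peak)
        labels.append(stim.condition)
    return np.column_stack(cols), labels


def build_ss_design(
    scan: HemoScan,
    geometry: ProbeGeometry,
    ld_channel: int | None = None,
    mode: str = "both",
    n_nearest: int | None = None,
    decorrelate: bool = True,
):
    """Short-separation nuisance block: selected SS time courses (z-scored),
    optionally replaced by their orthonormal nonzero principal components to
    remove collinearity among SS channels.

    ``mode`` selects which chromophores contribute columns: 'HbO2', 'Hb' or
    'both'.  ``n_nearest`` restricts to the n SS channels nearest to
    ``ld_channel`` (midpoint distance); ``None`` uses all SS channels.

    Returns ``(xshort, labels)``.
    """
    if mode not in ("HbO2", "Hb", "both"):
        raise ValueError("mode must be 'HbO2', 'Hb' or 'both'")
    if n_nearest is None or n_nearest == "all":
        ss_idx = geometry.ss_indices()
    else:
        if ld_channel is None:
            raise ValueError("n_nearest selection requires an LD channel")
        ss_idx = nearest_ss(geometry, ld_channel, int(n_nearest))
    chroms = CHROMOPHORES if mode == "both" else (mode,)
    cols, labels = [], []
    for chrom in chroms:
        block = scan.chrom(chrom)[:, ss_idx]
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        z = (block - block.mean(axis=0)) / sd
        cols.append(z)
        labels += [f"SS{int(i)}:{chrom}" for i in ss_idx]
    x = np.hstack(cols)
    if decorrelate:
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        keep = s > s[0] * 1e-10 if s.size else np.zeros(0, bool)
        x = u[:, keep]  # orthonormal columns spanning the raw SS block
        labels = [f"SS_pc{i}" for i in range(int(keep.sum()))]
    return x, labels


# ---------------------------------------------------------------------------
# solver internals


def _check_rank(x, labels):
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {x.shape[1]} columns); "
            f"collinear columns among {labels}"
        )


def _robust_inference(st, k, penalty=None):
    """t/p inference for a whitened robust fit: Huber-sandwich covariance
    with dof = sum(robust weights) - rank (documented interpretation of the
    effective sample size after downweighting)."""
    dof = st["n_eff"] - k
    if dof <= 0:
        raise ValueError("not enough effective samples for the requested design")
    gram = st["xtx"]
    if penalty is not None:
        gram = gram + penalty.T @ penalty
    cov = st["cov_scale"] * np.linalg.inv(gram)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    beta = st["beta"] if penalty is None else st["beta_pen"]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    sigma2 = st["rss"] / dof
    return cov, sigma2, dof, t, p


def _classical_inference(beta, xtx_inv, rss, n_eff, rank):
    dof = n_eff - rank
    if dof <= 0:
        raise ValueError("not enough time points for the requested design")
    sigma2 = rss / dof
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return cov, sigma2, dof, t, p


def _irls_bisquare(x, y, tune=BISQUARE_TUNING, max_iter=50, tol=1e-6):
    """Tukey-bisquare IRLS.  Returns (beta, weights, robust scale)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    w = np.ones(len(y))
    s = 0.0
    for _ in range(max_iter):
        r = y - x @ beta
        s = MAD_TO_SD * np.median(np.abs(r - np.median(r)))
        if s <= 0:
            w = np.ones(len(y))
            break
        u = r / (tune * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        w = np.clip(w, 1e-8, 1.0)  # weights stay in (0, 1]
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) <= tol * max(np.max(np.abs(beta)), 1e-300):
            beta = beta_new
            break
        beta = beta_new
    return beta, w, s


def _sandwich_scale(r, s, n_minus_k, tune=BISQUARE_TUNING):
    """Huber sandwich variance scale for the bisquare M-estimate.

    ``cov(beta) = scale * (X'X)^-1`` with
    ``scale = [sum psi(r)^2 / (n-k)] / [mean psi'(r)]^2``; with all weights
    at 1 this reduces to the classical residual variance.  The naive
    weighted-residual variance underestimates cov and inflates t even on
    clean normal noise.
    """
    if s <= 0:
        return float(r @ r) / max(n_minus_k, 1.0)
    u = r / (tune * s)
    inside = np.abs(u) < 1
    psi = np.where(inside, r * (1 - u**2) ** 2, 0.0)
    dpsi = np.where(inside, (1 - u**2) * (1 - 5 * u**2), 0.0)
    den = float(np.mean(dpsi)) ** 2
    if den <= 0:
        return float(r @ r) / max(n_minus_k, 1.0)
    return float(psi @ psi) / max(n_minus_k, 1.0) / den


def _burg_all_orders(x, pmax):
    """Burg recursion up to order pmax in one pass.

    Returns (coefs, sigma2) where ``coefs[k]`` are the AR(k+1) coefficients
    (prediction form: x_t ~ sum a_i x_{t-i}) and ``sigma2[k]`` the order-k+1
    prediction error variance.  Burg's lattice estimate keeps poles close to
    the unit circle far better than Yule-Walker, which matters for the very
    slow physiological drifts encountered here.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    f = x[1:].copy()  # forward prediction error
    b = x[:-1].copy()  # backward prediction error
    a = np.zeros(0)
    e = float(x @ x) / n
    coefs = []
    sigma2 = np.empty(pmax)
    for m in range(pmax):
        den = float(f @ f + b @ b)
        k = -2.0 * float(f @ b) / den if den > 0 else 0.0
        a = np.concatenate([a + k * a[::-1], [k]])
        f, b = f + k * b, b + k * f
        f = f[1:]
        b = b[:-1]
        e = e * (1.0 - k * k)
        coefs.append(-a.copy())  # prediction-form sign
        sigma2[m] = max(e, 1e-300)
    return coefs, sigma2


def _design_absorption(x) -> np.ndarray:
    """Spectral footprint of a design matrix: sum_j |F(q_j)(f)|^2 / n over
    an orthonormal basis Q of the columns, on the padded rfft grid.  This is
    the fraction of noise power the regression absorbs at each frequency."""
    q, _ = np.linalg.qr(np.atleast_2d(x))
    n = q.shape[0]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    absorbed = np.zeros(nfft // 2 + 1)
    for j in range(q.shape[1]):
        absorbed += np.abs(np.fft.rfft(q[:, j], nfft)) ** 2 / n
    return absorbed


def _fit_ar_aic(resid, max_order, absorption=None):
    """AR(p) fit to regression residuals with p chosen by AIC over
    1..max_order (order 0 / no whitening wins if AIC prefers it).

    When ``absorption`` (the design's spectral footprint from
    ``_design_absorption``) is given, the residual periodogram is first
    corrected for the power absorbed by the regression: residuals are
    (I - QQ')eps, so their spectrum is biased low by the factor
    1 - sum_j |F(q_j)(f)|^2 / n exactly where the design has spectral mass.
    Without the correction the noise model understates power at the task
    frequencies and the GLM becomes anti-conservative whenever slow
    physiological drift aligns with the regressor by chance.  The corrected
    autocovariance feeds a Levinson recursion; without a design the Burg
    lattice is used directly.
    """
    n = len(resid)
    pmax = int(min(max_order, n // 5))
    if pmax < 1:
        return np.zeros(0)
    var0 = float(resid @ resid) / n
    if var0 <= 0:
        return np.zeros(0)
    orders = np.arange(1, pmax + 1)
    if absorption is None:
        coefs, sigma2 = _burg_all_orders(resid, pmax)
        aic = n * np.log(sigma2) + 2 * (orders + 1)
        aic0 = n * np.log(var0) + 2
        if aic0 <= aic.min():
            return np.zeros(0)
        return coefs[int(np.argmin(aic))]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    pxx = np.abs(np.fft.rfft(resid, nfft)) ** 2 / n
    pxx = pxx / np.clip(1.0 - absorption, 0.1, 1.0)
    acov = np.fft.irfft(pxx, nfft)[: pmax + 1]
    if acov[0] <= 0:
        return np.zeros(0)
    _, _, _, sigma, phi = levinson_durbin(acov, nlags=pmax, isacov=True)
    sigma = np.asarray(sigma)
    aic = n * np.log(np.clip(sigma[1:], 1e-300, None)) + 2 * (orders + 1)
    aic0 = n * np.log(acov[0]) + 2
    if aic0 <= aic.min():
        return np.zeros(0)
    k = int(orders[np.argmin(aic)])
    return phi[1 : k + 1, k].copy()


def _whiten(arr, ar):
    """Apply the AR whitening filter [1, -a1..-ap] along axis 0, dropping the
    first p warm-up samples."""
    p = len(ar)
    if p == 0:
        return arr
    b = np.concatenate([[1.0], -np.asarray(ar)])
    out = sps.lfilter(b, [1.0], arr, axis=0)
    return out[p:]


def default_max_ar_order(fs: float) -> int:
    """AIC search cap: about 4 seconds of lags (= 32 at 7.8125 Hz)."""
    return int(np.ceil(4.0 * fs))


def _iter_channels(scan, chromophores):
    for chrom in chromophores:
        data = scan.chrom(chrom)
        for ch in range(scan.n_channels):
            yield chrom, ch, data[:, ch]


def ols_fit(scan: HemoScan, design: DesignMatrix, chromophores=CHROMOPHORES):
    """Ordinary least squares per channel with classical t inference.

    Returns ``{chromophore: [GLMChannelResult, ...]}``.
    """
    x, labels = design.full()
    _check_rank(x, labels)
    if design.n_time <= x.shape[1]:
        raise ValueError("more design columns than time points")
    k_task = design.xtask.shape[1]
    k_short = 0 if design.xshort is None else design.xshort.shape[1]
    task_slice = slice(0, k_task)
    short_slice = slice(k_task, k_task + k_short)
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    results: dict = {c: [] for c in chromophores}
    for chrom, ch, y in _iter_channels(scan, chromophores):
        beta = pinv @ y
        r = y - x @ beta
        cov, sigma2, dof, t, p = _classical_inference(
            beta, xtx_inv, float(r @ r), len(y), x.shape[1]
        )
        results[chrom].append(
            GLMChannelResult(
                channel=ch,
                chromophore=chrom,
                labels=labels,
                beta=beta,
                cov=cov,
                task_slice=task_slice,
                short_slice=short_slice,
                ar_coefficients=np.zeros(0),
                robust_weights=np.ones(len(y)),
                dof=dof,
                sigma2=sigma2,
                t=t[task_slice],
                p=p[task_slice],
            )
        )
    return results


def _ar_irls_single(y, x, max_ar_order, max_iter=10, tol=1e-4, absorption=None):
    """One channel of AR-IRLS.  Returns a dict with the converged state,
    including the weighted whitened system used for inference (reused by the
    mixed-effects solver)."""
    beta = None
    ar = np.zeros(0)
    w = np.ones(len(y))
    converged = False
    if absorption is None:
        absorption = _design_absorption(x)
    for _ in range(max_iter):
        yw = _whiten(y, ar)
        xw = _whiten(x, ar)
        beta_new, w, _ = _irls_bisquare(xw, yw)
        resid = y - x @ beta_new
        ar = _fit_ar_aic(resid, max_ar_order, absorption=absorption)
        if beta is not None and np.max(np.abs(beta_new - beta)) <= tol * max(
            np.max(np.abs(beta)), 1e-300
        ):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    # final whitened robust system for inference
    yw = _whiten(y, ar)
    xw = _whiten(x, ar)
    beta, w, s = _irls_bisquare(xw, yw)
    sw = np.sqrt(w)
    aw = xw * sw[:, None]
    bw = yw * sw
    rw = bw - aw @ beta
    n_eff = float(w.sum())
    k = x.shape[1]
    r_unw = yw - xw @ beta
    return {
        "beta": beta,
        "ar": ar,
        "w": w,
        "aw": aw,
        "bw": bw,
        "xtx": xw.T @ xw,
        "cov_scale": _sandwich_scale(r_unw, s, len(yw) - k),
        "rss": float(rw @ rw),
        "n_eff": n_eff,
        "converged": converged,
    }


def ar_irls_fit(
    scan: HemoScan,
    design: DesignMatrix,
    max_ar_order: int | None = None,
    max_iter: int = 10,
    tol: float = 1e-4,
    chromophores=CHROMOPHORES,
):
    """AR-IRLS prewhitened robust GLM per channel.

    Alternates bisquare robust regression, AIC-selected AR fitting of the
    residuals, and whitening of both y and X by the AR filter, until the
    coefficients stabilise.  Inference uses the whitened robust-weighted
    model with effective dof = sum(weights) - rank(X).

    Returns ``{chromophore: [GLMChannelResult, ...]}``.
    """
    x, labels = design.full()
    _check_rank(x, labels)
    if max_ar_order is None:
        max_ar_order = default_max_ar_order(design.fs)
    if design.n_time <= max_ar_order + x.shape[1]:
        raise ValueError("scan too short for the AR order and design size")
    k_task = design.xtask.shape[1]
    k_short = 0 if design.xshort is None else design.xshort.shape[1]
    task_slice = slice(0, k_task)
    short_slice = slice(k_task, k_task + k_short)
    absorption = _design_absorption(x)  # shared across channels
    results: dict = {c: [] for c in chromophores}
    for chrom, ch, y in _iter_channels(scan, chromophores):
        st = _ar_irls_single(
            y, x, max_ar_order, max_iter=max_iter, tol=tol, absorption=absorption
        )
        if not st["converged"]:
            warnings.warn(f"AR-IRLS did not converge for channel {ch} ({chrom})")
        cov, sigma2, dof, t, p = _robust_inference(st, x.shape[1])
        results[chrom].append(
            GLMChannelResult(
                channel=ch,
                chromophore=chrom,
                labels=labels,
                beta=st["beta"],
                cov=cov,
                task_slice=task_slice,
                short_slice=short_slice,
                ar_coefficients=st["ar"],
                robust_weights=st["w"],
                dof=dof,
                sigma2=sigma2,
                t=t[task_slice],
                p=p[task_slice],
                converged=st["converged"],
            )
        )
    return results


def me_ar_irls_fit(
    scan: HemoScan,
    xtask: np.ndarray,
    zshort: np.ndarray,
    fs: float,
    task_labels=None,
    short_labels=None,
    max_ar_order: int | None = None,
    max_outer: int = 20,
    sigma_tol: float = 1e-3,
    sigma_floor: float = 1e-6,
    chromophores=CHROMOPHORES,
):
    """Mixed-effects AR-IRLS: short-separation coefficients Gamma are shrunk
    toward zero by a common prior N(0, sigma^2) whose scale is pooled across
    all channels of the probe.

    EM-style outer loop: (i) with the current sigma, each channel solves a
    ridge-penalised whitened robust regression — penalty rows
    (sigma_eps / sigma) I on the Gamma block only, where sigma_eps is that
    channel's residual scale, i.e. the exact ridge implied by the prior
    Gamma ~ N(0, sigma^2) against noise N(0, sigma_eps^2); sigma = infinity
    on the first pass means no penalty, which reproduces plain AR-IRLS with
    the SS columns appended.  (ii) sigma <- 1.4826 * median(|Gamma|) pooled
    over channels, the robust scale about zero, keeping the prior zero-mean;
    (iii) repeat until sigma stabilises.  The AR whitening filter and robust
    weights from the initial unpenalised pass are held fixed across the
    sigma iterations.

    ``zshort`` may be a single time x m matrix shared by every channel, or a
    list of per-channel matrices with a common column count m (e.g. each LD
    channel regressing on its own nearest-n SS channels); the prior scale is
    pooled over all channels either way.

    Returns ``({chromophore: [GLMChannelResult, ...]}, {chromophore: MEState})``.
    """
    xtask = np.atleast_2d(np.asarray(xtask, dtype=float))
    if isinstance(zshort, (list, tuple)):
        z_per_channel = [np.atleast_2d(np.asarray(z, dtype=float)) for z in zshort]
        if len(z_per_channel) != scan.n_channels:
            raise ValueError("need one zshort block per channel")
        if len({z.shape[1] for z in z_per_channel}) != 1:
            raise ValueError("per-channel zshort blocks must share the column count")
    else:
        z_per_channel = [np.atleast_2d(np.asarray(zshort, dtype=float))] * scan.n_channels
    if z_per_channel[0].shape[1] < 2:
        raise ValueError("the mixed-effects model needs at least 2 SS regressors")
    if scan.n_channels < 2:
        raise ValueError("the mixed-effects model needs at least 2 channels")
    task_labels = task_labels or [f"task{i}" for i in range(xtask.shape[1])]
    short_labels = short_labels or [f"SS{i}" for i in range(z_per_channel[0].shape[1])]
    designs = [
        DesignMatrix(
            xtask=xtask, task_labels=list(task_labels), fs=fs,
            xshort=z, short_labels=list(short_labels),
        )
        for z in z_per_channel
    ]
    xs_labels = [d.full() for d in designs]
    labels = xs_labels[0][1]
    for x_ch, lab_ch in xs_labels:
        _check_rank(x_ch, lab_ch)
    if max_ar_order is None:
        max_ar_order = default_max_ar_order(fs)
    k_task = xtask.shape[1]
    m = z_per_channel[0].shape[1]
    task_slice = slice(0, k_task)
    short_slice = slice(k_task, k_task + m)
    k_total = xs_labels[0][0].shape[1]
    penalty_mask = np.zeros(k_total)
    penalty_mask[short_slice] = 1.0

    absorption_cache: dict = {}

    def _absorption_for(ch):
        key = id(z_per_channel[ch])
        if key not in absorption_cache:
            absorption_cache[key] = _design_absorption(xs_labels[ch][0])
        return absorption_cache[key]

    results: dict = {}
    states: dict = {}
    for chrom in chromophores:
        data = scan.chrom(chrom)
        systems = []
        for ch in range(scan.n_channels):
            st = _ar_irls_single(
                data[:, ch], xs_labels[ch][0], max_ar_order,
                absorption=_absorption_for(ch),
            )
            systems.append(st)
        # channel noise scale from the unpenalised pass fixes the ridge units
        sigma_eps = [
            np.sqrt(st["rss"] / max(st["n_eff"] - k_total, 1.0)) for st in systems
        ]
        sigma = np.inf
        betas = [st["beta"] for st in systems]
        converged = False
        iterations = 0
        for it in range(max_outer):
            iterations = it + 1
            gammas = np.concatenate([b[short_slice] for b in betas])
            new_sigma = float(MAD_TO_SD * np.median(np.abs(gammas)))
            if new_sigma < sigma_floor:
                warnings.warn("pooled sigma collapsed; clamped to floor")
                new_sigma = sigma_floor
            if np.isfinite(sigma) and abs(new_sigma - sigma) <= sigma_tol * new_sigma:
                sigma = new_sigma
                converged = True
                break
            sigma = new_sigma
            betas = []
            for st, se in zip(systems, sigma_eps):
                pen = np.diag(penalty_mask * (se / sigma))
                a = np.vstack([st["aw"], pen])
                b = np.concatenate([st["bw"], np.zeros(k_total)])
                beta, *_ = np.linalg.lstsq(a, b, rcond=None)
                betas.append(beta)
        states[chrom] = MEState(sigma=sigma, iterations=iterations, converged=converged)

        res_list = []
        for ch, (st, beta) in enumerate(zip(systems, betas)):
            pen = (
                np.diag(penalty_mask * (sigma_eps[ch] / sigma))
                if np.isfinite(sigma)
                else None
            )
            st_pen = dict(st, beta_pen=beta)
            cov, sigma2, dof, t, p = _robust_inference(
                st_pen, k_total, penalty=pen
            )
            res_list.append(
                GLMChannelResult(
                    channel=ch,
                    chromophore=chrom,
                    labels=labels,
                    beta=beta,
                    cov=cov,
                    task_slice=task_slice,
                    short_slice=short_slice,
                    ar_coefficients=st["ar"],
                    robust_weights=st["w"],
                    dof=dof,
                    sigma2=sigma2,
                    t=t[task_slice],
                    p=p[task_slice],
                    converged=st["converged"],
                )
            )
        results[chrom] = res_list
    return results, states


def hotelling_joint(res_hbo: GLMChannelResult, res_hbr: GLMChannelResult,
                    coef: int = 0, cross_cov: float = 0.0):
    """Hotelling T^2 joint test of the (HbO2, Hb) task coefficient pair.

    The 2x2 covariance is assembled from the per-chromophore coefficient
    variances (the two fits are independent regressions, so the cross term
    defaults to zero).  The p-value uses the F transform of T^2 with the
    smaller of the two dof.

    Returns ``(T2, p)``.
    """
    if res_hbo.channel != res_hbr.channel:
        raise ValueError("results must come from the same channel")
    b = np.array([res_hbo.beta_task[coef], res_hbr.beta_task[coef]])
    i_hbo = res_hbo.task_slice.start + coef
    i_hbr = res_hbr.task_slice.start + coef
    c = np.array(
        [
            [res_hbo.cov[i_hbo, i_hbo], cross_cov],
            [cross_cov, res_hbr.cov[i_hbr, i_hbr]],
        ]
    )
    det = np.linalg.det(c)
    if not np.isfinite(det) or det <= 0:
        raise ValueError("singular 2x2 covariance in joint test")
    t2 = float(b @ np.linalg.solve(c, b))
    nu = float(min(res_hbo.dof, res_hbr.dof))
    f_stat = (nu - 1.0) / (2.0 * nu) * t2
    p = float(stats.f.sf(f_stat, 2, nu - 1.0))
    return t2, p
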