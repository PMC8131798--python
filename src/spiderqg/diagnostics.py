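"""MCMC convergence diagnostics: Heidelberger-Welch, autocorrelation, ESS.

The Heidelberger-Welch procedure tests stationarity by a Cramer-von Mises
statistic on the Brownian-bridge functional of the chain's cumulative sums
(normalized by the spectral density at frequency zero), discarding leading
10% increments up to 50% until the test passes, and then checks whether the
half-width of the 95% interval for the mean on the retained segment is
small relative to the mean itself.  The spectral density at zero is
estimated from a low-order autoregressive approximation with the order
chosen by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz
from scipy.special import gamma as gamma_fn, kv
from scipy.stats import norm

__all__ = [
    "HeidelbergerWelchResult",
    "DiagnosticReport",
    "heidelberger_welch",
    "autocorrelation",
    "effective_sample_size",
    "spectral_density_zero",
    "cramer_von_mises_pvalue",
    "diagnose_draws",
]


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation at lags 0..max_lag with the biased normalization.

    c_k = (1/n) sum (x_t - xbar)(x_{t+k} - xbar); rho_k = c_k / c_0, so
    rho_0 = 1 exactly.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the chain length")
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / n
    if c0 == 0.0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    # FFT-based autocovariance
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[: max_lag + 1].real / n
    return acov / c0


def _yule_walker(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """AR coefficients and innovation variance via Yule-Walker equations."""
    n = x.size
    xc = x - x.mean()
    c = np.array(
        [np.dot(xc[: n - k], xc[k:]) / n for k in range(order + 1)]
    )
    if order == 0:
        return np.zeros(0), float(c[0])
    phi = solve_toeplitz(c[:-1], c[1:])
    sigma2 = float(c[0] - np.dot(phi, c[1:]))
    return phi, max(sigma2, 0.0)


def spectral_density_zero(chain: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit.

    S(0) = sigma^2 / (1 - sum phi)^2; a constant chain has S(0) = 0.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if np.ptp(x) == 0.0:
        return 0.0
    if max_order is None:
        max_order = int(min(n - 1, np.floor(10.0 * np.log10(n))))
    best_aic = np.inf
    best = (np.zeros(0), float(np.var(x)))
    for p in range(max_order + 1):
        phi, sigma2 = _yule_walker(x, p)
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2.0 * p
        if aic < best_aic:
            best_aic = aic
            best = (phi, sigma2)
    phi, sigma2 = best
    denom = (1.0 - phi.sum()) ** 2
    if denom <= 0:
        denom = np.finfo(float).tiny
    return float(sigma2 / denom)


def cramer_von_mises_pvalue(stat: float, eps: float = 1e-5) -> float:
    """Asymptotic upper tail of the Cramer-von Mises distribution.

    Series representation with Bessel-K terms, accurate far beyond the
    levels used for testing.
    """
    if stat <= 0:
        return 1.0
    total = 0.0
    log_eps = np.log(eps)
    for k in range(4):
        z = (
            gamma_fn(k + 0.5)
            * np.sqrt(4.0 * k + 1.0)
            / (gamma_fn(k + 1.0) * np.pi**1.5 * np.sqrt(stat))
        )
        u = (4.0 * k + 1.0) ** 2 / (16.0 * stat)
        if u <= -log_eps:
            total += z * np.exp(-u) * kv(0.25, u)
    return float(min(max(1.0 - total, 0.0), 1.0))


@dataclass(frozen=True)
class HeidelbergerWelchResult:
    """Stationarity and halfwidth test outcome for one chain."""

    stationarity_passed: bool
    start_fraction: float           # fraction of the chain discarded
    start_iteration: int
    cvm_statistic: float
    cvm_pvalue: float
    halfwidth_passed: bool
    mean: float
    halfwidth: float
    relative_halfwidth: float
    n_kept: int
    flag: str = ""

    def as_dict(self) -> dict:
        return {
            "stationarity_passed": self.stationarity_passed,
            "start_fraction": self.start_fraction,
            "start_iteration": self.start_iteration,
            "cvm_statistic": self.cvm_statistic,
            "cvm_pvalue": self.cvm_pvalue,
            "halfwidth_passed": self.halfwidth_passed,
            "mean": self.mean,
            "halfwidth": self.halfwidth,
            "relative_halfwidth": self.relative_halfwidth,
            "n_kept": self.n_kept,
            "flag": self.flag,
        }


def _cvm_statistic(x: np.ndarray, s0: float) -> float:
    """Cramer-von Mises statistic of the standardized cumulative-sum bridge."""
    n = x.size
    b = np.cumsum(x) - x.mean() * np.arange(1, n + 1)
    return float(np.sum(b * b) / (n * n * s0))


def heidelberger_welch(
    chain: np.ndarray, alpha: float = 0.05, eps: float = 0.1
) -> HeidelbergerWelchResult:
    """Heidelberger-Welch stationarity and halfwidth tests.

    Stationarity: starting from the full chain, drop leading 10%
    increments (up to 50%) until the Cramer-von Mises statistic of the
    Brownian bridge of cumulative sums -- normalized by the spectral
    density at zero estimated from the last half of the chain -- is
    non-significant at ``alpha``.  Halfwidth: on the retained segment,
    passed iff z_{1-alpha/2} * sqrt(S(0)/n_kept) / |mean| <= eps.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for Heidelberger-Welch (need >= 100)")

    if np.ptp(x) == 0.0:
        # constant chain: trivially stationary, halfwidth exactly zero
        return HeidelbergerWelchResult(
            stationarity_passed=True, start_fraction=0.0, start_iteration=0,
            cvm_statistic=0.0, cvm_pvalue=1.0, halfwidth_passed=True,
            mean=float(x[0]), halfwidth=0.0, relative_halfwidth=0.0,
            n_kept=n, flag="constant chain: zero spectral density",
        )

    s0 = spectral_density_zero(x[n // 2:])
    passed = False
    frac = 0.0
    stat = np.nan
    pval = np.nan
    start = 0
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(np.floor(frac * n))
        seg = x[start:]
        stat = _cvm_statistic(seg, s0) if s0 > 0 else 0.0
        pval = cramer_von_mises_pvalue(stat)
        if pval > alpha:
            passed = True
            break

    kept = x[start:] if passed else x
    n_kept = kept.size
    s0_kept = spectral_density_zero(kept)
    mean = float(kept.mean())
    hw = float(norm.ppf(1.0 - alpha / 2) * np.sqrt(s0_kept / n_kept))
    rel = hw / abs(mean) if mean != 0 else np.inf
    hw_passed = bool(passed and rel <= eps)
    return HeidelbergerWelchResult(
        stationarity_passed=passed,
        start_fraction=frac if passed else 1.0,
        start_iteration=start if passed else n,
        cvm_statistic=stat,
        cvm_pvalue=pval,
        halfwidth_passed=hw_passed,
        mean=mean,
        halfwidth=hw,
        relative_halfwidth=float(rel),
        n_kept=n_kept,
        flag="" if passed else "stationarity failed at all start points",
    )


def effective_sample_size(chain: np.ndarray) -> tuple[float, str]:
    """Effective sample size by Geyer's initial monotone sequence estimator.

    ESS = n / (1 + 2 * sum rho_k) with the sum truncated where successive
    autocorrelation pairs stop being positive, and the pair sums forced
    non-increasing.  Returns (ess, flag); a constant chain reports 0 with a
    flag.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for an ESS estimate (need >= 100)")
    if np.ptp(x) == 0.0:
        return 0.0, "constant chain"
    rho = autocorrelation(x, max_lag=n // 2 - 1)
    m_max = (rho.size - 1) // 2
    tau = 0.0
    prev = np.inf
    used = 0
    for m in range(m_max):
        g = rho[2 * m] + rho[2 * m + 1]
        if g <= 0:
            break
        g = min(g, prev)
        prev = g
        tau += g
        used = m + 1
    tau = max(2.0 * tau - 1.0, 1.0)  # = 1 + 2 sum rho over the kept window
    del used
    return float(n / tau), ""


@dataclass
class DiagnosticReport:
    """Per-parameter convergence diagnostics for one fitted model."""

    entries: dict[str, HeidelbergerWelchResult] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    autocorr_lag1: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def all_stationary(self) -> bool:
        return all(e.stationarity_passed for e in self.entries.values())

    def failing_halfwidth(self) -> list[str]:
        return [k for k, e in self.entries.items() if not e.halfwidth_passed]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.entries.items():
            d = {"parameter": name, **e.as_dict()}
            d["ess"] = self.ess.get(name, np.nan)
            d["autocorr_lag1"] = self.autocorr_lag1.get(name, np.nan)
            rows.append(d)
        return pd.DataFrame(rows)


def diagnose_draws(
    draws: pd.DataFrame, alpha: float = 0.05, eps: float = 0.1
) -> DiagnosticReport:
    """Run the full diagnostic battery on every column of a draw matrix."""
    report = DiagnosticReport()
    for name in draws.columns:
        x = draws[name].to_numpy(dtype=float)
        hw = heidelberger_welch(x, alpha=alpha, eps=eps)
        report.entries[name] = hw
        ess, flag = effective_sample_size(x)
        report.ess[name] = ess
        if flag:
            report.flags[name] = flag
        report.autocorr_lag1[name] = (
            float(autocorrelation(x, 1)[1]) if np.ptp(x) > 0 else 0.0
        )
    return report
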