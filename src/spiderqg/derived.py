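"""Derived quantitative-genetic statistics over posterior draws.

All ratios are computed draw-by-draw (never as ratios of posterior means):
narrow-sense heritability h2 = V_A / (V_A + V_CE/M + V_PE + V_R [+ V_C]),
the cross-sex genetic correlation r_mf = COV_Amf / sqrt(V_Af * V_Am), and
the mean-standardized evolvability coefficients CV_A = sqrt(V_A)/mean,
I_A = V_A/mean^2, CV_CE/M, CV_PE and CV_R, with female-minus-male posterior
contrasts and two-tailed pMCMC sign probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np

from .model import PosteriorDraws

__all__ = [
    "SummaryRow",
    "heritability",
    "cross_sex_correlation",
    "evolvability_coefficients",
    "sex_contrast",
    "pmcmc",
    "summarize",
]

SEX_SUFFIX = {"female": "f", "male": "m", "f": "f", "m": "m"}


@dataclass(frozen=True)
class SummaryRow:
    """Posterior mean, 95% credible interval and (for contrasts) pMCMC."""

    name: str
    mean: float
    lower: float
    upper: float
    pmcmc: float | None = None
    n_draws: int = 0
    n_undefined: int = 0
    withheld: bool = False
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "quantity": self.name,
            "mean": self.mean,
            "lower": self.lower,
            "upper": self.upper,
            "pMCMC": self.pmcmc,
            "n_draws": self.n_draws,
            "n_undefined": self.n_undefined,
            "withheld": self.withheld,
            "note": self.note,
        }


def _col(draws: PosteriorDraws | np.ndarray, name: str) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        return draws[name]
    return np.asarray(draws)


def heritability(
    draws: PosteriorDraws, sex: str, dyadic: bool = False
) -> np.ndarray:
    """Per-draw narrow-sense heritability for one sex.

    The denominator is the sex's own components V_A + V_CE/M + V_PE + V_R,
    plus the pooled contest variance V_C for dyadic traits.  Draws with an
    all-zero denominator come back as NaN.
    """
    s = SEX_SUFFIX[sex]
    va = draws[f"V_A_{s}"]
    denom = va + draws[f"V_CEM_{s}"] + draws[f"V_PE_{s}"] + draws[f"V_R_{s}"]
    if dyadic:
        denom = denom + draws["V_C"]
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(denom > 0, va / np.where(denom > 0, denom, 1.0), np.nan)
    return h2


def cross_sex_correlation(
    draws: PosteriorDraws, floor: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Per-draw r_mf = COV_Amf / sqrt(V_Af * V_Am) and the defined fraction.

    Draws whose variance product falls below ``floor`` (trait-scale
    units^4) are flagged undefined (NaN): when the additive variance of one
    or both sexes tends to zero the correlation does not exist.
    """
    va_f, va_m = draws["V_A_f"], draws["V_A_m"]
    cov = draws["COV_A_mf"]
    prod = va_f * va_m
    defined = prod >= floor
    r = np.full(prod.shape, np.nan)
    r[defined] = cov[defined] / np.sqrt(prod[defined])
    frac = float(defined.mean()) if prod.size else 0.0
    return r, frac


def evolvability_coefficients(
    draws: PosteriorDraws,
    phenotypic_mean_f: float,
    phenotypic_mean_m: float,
) -> dict[str, np.ndarray]:
    """Per-draw mean-standardized coefficients by sex.

    Means must be raw-scale phenotypic means pooled across the parental and
    offspring generations (sex-specific by default).  Returns a dict keyed
    ``CV_A_f``, ``I_A_f``, ``CV_CEM_f``, ``CV_PE_f``, ``CV_R_f`` and the
    male analogues.
    """
    means = {"f": phenotypic_mean_f, "m": phenotypic_mean_m}
    for s, m in means.items():
        if not np.isfinite(m) or m <= 0:
            raise ValueError(f"phenotypic mean for sex {s!r} must be positive")
    out: dict[str, np.ndarray] = {}
    for s, m in means.items():
        va = draws[f"V_A_{s}"]
        out[f"CV_A_{s}"] = np.sqrt(va) / m
        out[f"I_A_{s}"] = va / m**2
        out[f"CV_CEM_{s}"] = np.sqrt(draws[f"V_CEM_{s}"]) / m
        out[f"CV_PE_{s}"] = np.sqrt(draws[f"V_PE_{s}"]) / m
        out[f"CV_R_{s}"] = np.sqrt(draws[f"V_R_{s}"]) / m
    return out


def pmcmc(vec: np.ndarray) -> float:
    """Two-tailed posterior sign probability.

    2 * min(P(draw >= 0), P(draw <= 0)), capped at 1 and floored at
    1/n_draws; a vector that is identically zero is maximally two-sided
    (pMCMC = 1).
    """
    v = np.asarray(vec, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        return float("nan")
    p = 2.0 * min(float(np.mean(v >= 0)), float(np.mean(v <= 0)))
    return float(min(1.0, max(p, 1.0 / n)))


def sex_contrast(
    female_draws: np.ndarray, male_draws: np.ndarray, name: str = "contrast",
    interval: str = "hpd",
) -> tuple[np.ndarray, SummaryRow]:
    """Per-draw female-minus-male contrast with posterior summary.

    Draw vectors must be aligned (same chain, same retained iterations);
    by linearity the summary mean equals mean(female) - mean(male) exactly.
    """
    f = np.asarray(female_draws, dtype=float)
    m = np.asarray(male_draws, dtype=float)
    if f.shape != m.shape:
        raise ValueError("female and male draw vectors differ in length")
    diff = f - m
    row = summarize(diff, name=name, interval=interval, is_contrast=True)
    return diff, row


def _hpd_interval(v: np.ndarray, level: float) -> tuple[float, float]:
    lo, hi = az.hdi(np.asarray(v, dtype=float), hdi_prob=level)
    return float(lo), float(hi)


def summarize(
    vec: np.ndarray,
    name: str = "",
    interval: str = "hpd",
    level: float = 0.95,
    is_contrast: bool = False,
    max_undefined_fraction: float = 0.5,
) -> SummaryRow:
    """Posterior mean and 95% interval (HPD by default) for a draw vector.

    NaN draws count as undefined; when more than ``max_undefined_fraction``
    of the draws are undefined the point estimate is withheld and only the
    diagnostic counts are reported.
    """
    v = np.asarray(vec, dtype=float)
    n = v.size
    finite = v[np.isfinite(v)]
    n_undef = n - finite.size
    if finite.size < max(1, n * (1.0 - max_undefined_fraction)):
        return SummaryRow(
            name=name, mean=float("nan"), lower=float("nan"),
            upper=float("nan"), pmcmc=None, n_draws=n, n_undefined=n_undef,
            withheld=True,
            note=f"withheld: {n_undef}/{n} draws undefined",
        )
    if finite.size < 100:
        raise ValueError("need at least 100 defined draws for a summary")
    if np.ptp(finite) == 0.0:
        lo = hi = float(finite[0])
    elif interval == "hpd":
        lo, hi = _hpd_interval(finite, level)
    elif interval == "quantile":
        alpha = 1.0 - level
        lo, hi = np.quantile(finite, [alpha / 2, 1 - alpha / 2])
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError(f"unknown interval type {interval!r}")
    return SummaryRow(
        name=name,
        mean=float(finite.mean()),
        lower=lo,
        upper=hi,
        pmcmc=pmcmc(finite) if is_contrast else None,
        n_draws=n,
        n_undefined=n_undef,
    )
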