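"""Posterior summaries and heritability / genetic-correlation algebra.

All derived quantities (phenotypic variance, heritabilities, correlations) are
computed *per posterior sample* and only then summarized — never as ratios of
posterior means — so their uncertainty propagates correctly.

An estimate is called significant when 0 lies outside its HPD95, the narrowest
interval containing 95% of the samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticSummary",
    "hpd_interval",
    "posterior_summary",
    "phenotypic_variance_dominance",
    "heritability_dominance",
    "heritability_linear",
    "genetic_correlations",
    "summary_table",
]

#: variances below this are treated as zero in correlation denominators,
#: because near-zero denominators produce spurious +/-1 spikes
VAR_FLOOR = 1e-10


@dataclass
class GeneticSummary:
    """Posterior mean, its Monte-Carlo SE, HPD95 bounds and significance."""

    quantity: str
    posterior_mean: float
    posterior_se: float
    hpd95_low: float
    hpd95_high: float
    significant: bool
    n_samples: int
    n_undefined: int = 0
    multimodal_flag: bool = False

    def as_row(self) -> dict:
        return {
            "quantity": self.quantity,
            "mean": self.posterior_mean,
            "se": self.posterior_se,
            "hpd95_low": self.hpd95_low,
            "hpd95_high": self.hpd95_high,
            "significant": self.significant,
        }


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the samples (unimodal HPD)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no samples")
    # floor(prob*n)+1 points always cover at least prob of the sample
    m = int(np.floor(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def _ess(samples: np.ndarray) -> float:
    try:
        import arviz

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(arviz.ess(np.asarray(samples)[None, :]))
        if np.isfinite(ess) and ess > 0:
            return min(ess, len(samples))
    except Exception:
        pass
    return float(len(samples))


def posterior_summary(samples, quantity: str = "", min_samples: int = 100) -> GeneticSummary:
    """Summarize one scalar chain: mean, autocorrelation-adjusted SE, HPD95.

    NaN samples (e.g. correlations with a zero-variance denominator) are
    excluded and counted in ``n_undefined``.
    """
    x = np.asarray(samples, dtype=float)
    n_undef = int(np.isnan(x).sum())
    x = x[~np.isnan(x)]
    if len(x) < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples to summarize, got {len(x)}"
        )
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    se = sd / np.sqrt(_ess(x)) if sd > 0 else 0.0
    low, high = hpd_interval(x)
    significant = not (low <= 0.0 <= high)
    tol = 1e-9 * max(1.0, abs(mean))
    multimodal = not (low - tol <= mean <= high + tol)
    if multimodal:
        warnings.warn(f"posterior mean of {quantity or 'chain'} outside its HPD95; "
                      "chain may be multimodal")
    return GeneticSummary(quantity, mean, se, low, high, significant, len(x), n_undef,
                          multimodal)


# ----------------------------------------------------------------- dominance
_DOM_OPTIONAL = (
    "sigma2_PeD", "sigma2_PeC", "sigma_PeD_PeC",
    "sigma2_herdD", "sigma2_herdC", "sigma_herdD_herdC",
)


def phenotypic_variance_dominance(vc: pd.DataFrame | dict) -> np.ndarray | float:
    """Phenotypic variance of the dominance liability.

    sigma2_P = sigma2_aD + sigma2_aC + 2 sigma_aDC
             + sigma2_PeD + sigma2_PeC + 2 sigma_PeDC
             + sigma2_herdD + sigma2_herdC + 2 sigma_herdDC + sigma2_e.

    Missing Pe/herd columns count as zero (e.g. fits without herd); sigma2_e
    defaults to 1, the threshold-model convention.
    """
    get = (lambda k, d=0.0: vc[k] if k in vc else d) if isinstance(vc, dict) else (
        lambda k, d=0.0: vc[k] if k in vc.columns else d
    )
    total = (
        get("sigma2_aD") + get("sigma2_aC") + 2.0 * get("sigma_aD_aC")
        + get("sigma2_PeD") + get("sigma2_PeC") + 2.0 * get("sigma_PeD_PeC")
        + get("sigma2_herdD") + get("sigma2_herdC") + 2.0 * get("sigma_herdD_herdC")
        + get("sigma2_e", 1.0)
    )
    return np.asarray(total) if not np.isscalar(total) else float(total)


def heritability_dominance(vc: pd.DataFrame) -> pd.DataFrame:
    """Per-sample direct, indirect and total heritability of dominance.

    h2_direct = sigma2_aD / sigma2_P; h2_indirect = sigma2_aC / sigma2_P;
    h2_total = (sigma2_aD + sigma2_aC + 2 sigma_aDC) / sigma2_P, the genetic
    variance actually available to selection when both components transmit.
    """
    s2p = np.asarray(phenotypic_variance_dominance(vc), dtype=float)
    if np.any(s2p <= 0):
        raise ValueError("non-positive phenotypic variance")
    num_tot = vc["sigma2_aD"] + vc["sigma2_aC"] + 2.0 * vc["sigma_aD_aC"]
    return pd.DataFrame(
        {
            "h2_direct": vc["sigma2_aD"] / s2p,
            "h2_indirect": vc["sigma2_aC"] / s2p,
            "h2_total": num_tot / s2p,
        }
    )


def heritability_linear(vc: pd.DataFrame | dict) -> np.ndarray | float:
    """h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e [+ sigma2_herd + sigma2_HTD])."""
    get = (lambda k: vc.get(k, 0.0)) if isinstance(vc, dict) else (
        lambda k: vc[k] if k in vc.columns else 0.0
    )
    s2a = np.asarray(get("sigma2_a"), dtype=float)
    s2p = s2a + get("sigma2_pe") + get("sigma2_e") + get("sigma2_herd") + get("sigma2_htd")
    if np.any(np.asarray(s2p) <= 0):
        raise ValueError("non-positive phenotypic variance")
    out = s2a / s2p
    return float(out) if out.ndim == 0 else out


def _safe_corr(cov, v1, v2):
    cov = np.asarray(cov, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    denom = v1 * v2
    out = np.full(np.broadcast(cov, denom).shape, np.nan)
    ok = denom > VAR_FLOOR
    out[ok] = np.asarray(cov * 1.0)[ok] / np.sqrt(denom[ok])
    return out


def genetic_correlations(vc: pd.DataFrame) -> pd.DataFrame:
    """Per-sample genetic correlations of the bivariate model.

    r_a(1, D2) = sigma_a1,aD2 / sqrt(sigma2_a1 sigma2_aD2), and analogously for
    (1, C2) and (D2, C2). Samples whose denominator variance is below 1e-10
    are reported as NaN (undefined), never coerced to 0 or +/-1.
    """
    return pd.DataFrame(
        {
            "r_a1_aD2": _safe_corr(vc["sigma_a1_aD2"], vc["sigma2_a1"], vc["sigma2_aD2"]),
            "r_a1_aC2": _safe_corr(vc["sigma_a1_aC2"], vc["sigma2_a1"], vc["sigma2_aC2"]),
            "r_aD2_aC2": _safe_corr(vc["sigma_aD2_aC2"], vc["sigma2_aD2"], vc["sigma2_aC2"]),
        }
    )


def summary_table(samples: pd.DataFrame, quantities: list[str] | None = None) -> pd.DataFrame:
    """GeneticSummary rows for each column of a per-sample DataFrame."""
    cols = quantities if quantities is not None else list(samples.columns)
    rows = [posterior_summary(samples[c].to_numpy(), c).as_row() for c in cols]
    return pd.DataFrame(rows).set_index("quantity")
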