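"""Results container for Gibbs chains: EBVs, summaries, diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import summaries as _sm
from .pedigree import Pedigree

__all__ = ["GibbsResults"]


@dataclass
class GibbsResults:
    """Thinned posterior chain of a threshold(-linear) animal-model fit.

    Attributes
    ----------
    variance_samples : DataFrame
        One row per retained sample; covariance components named
        ``sigma2_<comp>`` / ``sigma_<comp1>_<comp2>`` (for constrained fits the
        derived direct/indirect columns are included alongside ``sigma2_a``).
    solutions : dict
        Thinned effect samples per stored group, shape (samples, k, levels);
        ``genetic`` and ``fixed`` are stored by default.
    posterior_mean : dict
        Posterior-mean effects for *every* group (k, levels).
    """

    variance_samples: pd.DataFrame
    solutions: dict
    posterior_mean: dict
    groups_meta: dict
    config: object
    constrained: bool
    kind: str
    pedigree: Pedigree
    residual_contest: float
    liabilities: np.ndarray | None = None
    outcomes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.variance_samples)

    # ----------------------------------------------------------------- EBVs
    def _genetic_axis(self) -> tuple[list, list]:
        comps, labels = self.groups_meta["genetic"]
        return comps, labels

    def ebv(self) -> pd.DataFrame:
        """Posterior-mean EBVs per pedigree animal, with posterior SDs.

        Constrained fits report the single genetic solution as the direct
        component and its negation as the indirect one (a_C = -a_D by
        construction). Animals without own records still receive an EBV
        through the relationship matrix (shrunk toward relatives).
        """
        comps, labels = self._genetic_axis()
        mean = self.posterior_mean["genetic"]
        if "genetic" in self.solutions:
            sd = np.std(self.solutions["genetic"], axis=0, ddof=1)
        else:
            sd = np.full_like(mean, np.nan)
        out = pd.DataFrame({"animal": labels})
        if self.constrained:
            out["ebv_direct"] = mean[0]
            out["ebv_indirect"] = -mean[0]
            out["sd_direct"] = sd[0]
            out["sd_indirect"] = sd[0]
        else:
            names = {"a_D": "direct", "a_C": "indirect", "a_1": "trait1",
                     "a_D2": "direct", "a_C2": "indirect", "a": "direct"}
            for c, comp in enumerate(comps):
                tag = names.get(comp, comp)
                out[f"ebv_{tag}"] = mean[c]
                out[f"sd_{tag}"] = sd[c]
        return out

    def ebv_samples(self, component: str = "direct") -> np.ndarray:
        """Thinned posterior samples of one genetic component, (samples, animals)."""
        if "genetic" not in self.solutions:
            raise ValueError("solutions were not stored (store_solutions=False)")
        sols = self.solutions["genetic"]
        if self.constrained:
            return sols[:, 0, :] if component == "direct" else -sols[:, 0, :]
        comps, _ = self._genetic_axis()
        lookup = {"direct": ["a_D", "a_D2"], "indirect": ["a_C", "a_C2"],
                  "trait1": ["a_1"]}
        for c, comp in enumerate(comps):
            if comp in lookup.get(component, [component]):
                return sols[:, c, :]
        raise ValueError(f"unknown genetic component {component!r}")

    # ------------------------------------------------------------- summaries
    def heritability_samples(self) -> pd.DataFrame:
        """Per-sample heritabilities (dominance algebra, liability scale)."""
        if self.kind == "dominance":
            return _sm.heritability_dominance(self.variance_samples)
        vs = self.variance_samples.rename(
            columns={
                "sigma2_aD2": "sigma2_aD", "sigma2_aC2": "sigma2_aC",
                "sigma_aD2_aC2": "sigma_aD_aC",
                "sigma2_PeD2": "sigma2_PeD", "sigma2_PeC2": "sigma2_PeC",
                "sigma_PeD2_PeC2": "sigma_PeD_PeC",
                "sigma2_herdD2": "sigma2_herdD", "sigma2_herdC2": "sigma2_herdC",
                "sigma_herdD2_herdC2": "sigma_herdD_herdC",
                "sigma2_e2": "sigma2_e",
            }
        )
        return _sm.heritability_dominance(vs)

    def correlation_samples(self) -> pd.DataFrame:
        """Per-sample genetic correlations (bivariate fits only)."""
        if self.kind != "bivariate":
            raise ValueError("correlations are defined for bivariate fits")
        return _sm.genetic_correlations(self.variance_samples)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, MC standard error, HPD95 and significance flag for
        every variance component and every derived quantity."""
        frames = [self.variance_samples]
        frames.append(self.heritability_samples())
        if self.kind == "bivariate":
            frames.append(self.correlation_samples())
        elif not self.constrained:
            vs = self.variance_samples
            frames.append(
                pd.DataFrame(
                    {"r_aD_aC": _sm._safe_corr(vs["sigma_aD_aC"], vs["sigma2_aD"],
                                               vs["sigma2_aC"])}
                )
            )
        allq = pd.concat(frames, axis=1)
        allq = allq.loc[:, ~allq.columns.duplicated()]
        return _sm.summary_table(allq)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"{type(self).__name__} kind={self.kind} "
            f"{'constrained' if self.constrained else 'unconstrained'} "
            f"samples={self.n_samples}\n"
        )
        with pd.option_context("display.float_format", "{:.4f}".format):
            return head + self.summary().to_string()

    # ----------------------------------------------------------- diagnostics
    def effective_sample_sizes(self) -> pd.Series:
        """ESS per variance component (arviz); warns below 200."""
        import arviz

        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in self.variance_samples.columns:
                x = self.variance_samples[c].to_numpy()
                if np.ptp(x) == 0:
                    continue
                out[c] = float(arviz.ess(x[None, :]))
        ess = pd.Series(out)
        low = ess[ess < 200]
        if len(low):
            warnings.warn(
                "low effective sample size (<200) for: " + ", ".join(low.index)
            )
        return ess

    def to_tidy(self) -> pd.DataFrame:
        """Chain in tidy (sample, parameter, value) form for export."""
        vs = self.variance_samples.reset_index(names="sample")
        return vs.melt(id_vars="sample", var_name="parameter", value_name="value")
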