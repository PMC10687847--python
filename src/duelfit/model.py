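"""Threshold and threshold-linear animal models fitted by Gibbs sampling.

:class:`DominanceThresholdModel` fits the single-trait liability model of
dyadic contest outcomes

    l = X beta + W_D Pe_D + W_C Pe_C + Z_D a_D + Z_C a_C
        + H_D herd_D + H_C herd_C + e,      e ~ N(0, 1),

with (a_D, a_C) ~ N(0, G (x) A) and correlated 2x2 Pe and herd blocks, in two
parameterizations: *unconstrained* (all 2x2 blocks free) and *constrained*
(multimembership: one genetic and one Pe vector entering through the signed
incidence Z_D - Z_C, which forces a_C = -a_D, equal variances and a
direct-indirect correlation of exactly -1).

:class:`BivariateThresholdLinearModel` couples the dominance liability (trait
2) with one continuous trait (trait 1, direct effects only), estimating 3x3
genetic / Pe / herd blocks with the residual cross-covariance fixed at zero
and the liability residual fixed at 1.

Sampling scheme: liabilities are drawn from their truncated-normal full
conditionals (data augmentation); location effects from normal full
conditionals of the mixed-model equations (blocked per animal across
correlated components); covariance blocks from their inverse-Wishart full
conditionals. The default prior on each covariance block is flat (the
conditional is then the likelihood's own inverse-Wishart kernel: scale S,
df = n_levels - k - 1); a proper inverse-Wishart prior with identity scale
and nu = k + 1 is available via ``prior="invwishart"`` but note it is far
from flat for components of magnitude well below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from ._gibbs import sweep_block, sweep_scalar
from .contests import filter_both_roles, prepare_contest_records
from .design import DesignMatrices, bivariate_design, dominance_design
from .pedigree import Pedigree
from .results import GibbsResults

__all__ = ["GibbsConfig", "DominanceThresholdModel", "BivariateThresholdLinearModel"]

#: logistic residual variance, for reporting on a logit-comparable scale
LOGIT_RESIDUAL = math.pi**2 / 3.0


@dataclass
class GibbsConfig:
    """Gibbs run configuration.

    The default desk-scale chain (60,000 iterations, 10,000 burn-in, thin 10)
    is a 10x reduction of the full production configuration (600,000 /
    100,000 / 100), which remains available by passing those values.
    """

    iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    start_variance: float = 0.1
    prior: str = "flat"
    prior_scale: float = 1.0
    variance_cap: float = 1e4
    store_solutions: bool = True
    store_liabilities: bool = False
    #: covariance blocks held fixed (never sampled), e.g. {"genetic": 0.2 * I};
    #: mainly for oracle comparisons on tiny data
    fixed_covariances: dict | None = None

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior not in ("flat", "invwishart"):
            raise ValueError("prior must be 'flat' or 'invwishart'")

    @property
    def n_samples(self) -> int:
        """Retained samples: (iterations - burn_in) / thin (rounded up)."""
        return -(-(self.iterations - self.burn_in) // self.thin)


def _group_colnames(name: str, components: list[str]) -> list[str]:
    shorts = [c.replace("_", "") for c in components]
    cols = [f"sigma2_{s}" for s in shorts]
    k = len(shorts)
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(f"sigma_{shorts[i]}_{shorts[j]}")
    return cols


def _flatten_cov(cov: np.ndarray) -> np.ndarray:
    k = cov.shape[0]
    out = [cov[i, i] for i in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            out.append(cov[i, j])
    return np.array(out)


def _run_gibbs(design: DesignMatrices, config: GibbsConfig, *,
               residual_contest: float = 1.0) -> dict:
    rng = np.random.default_rng(config.seed)
    ainv = design.pedigree.a_inverse()
    a_diag = ainv.diagonal()
    a_indptr = ainv.indptr.astype(np.int64)
    a_indices = ainv.indices.astype(np.int64)
    a_data = ainv.data

    groups = design.groups
    crows = design.contest_rows
    trows = design.trait_rows
    y = design.outcomes
    has_trait = len(trows) > 0
    n1 = len(trows)

    u = {name: np.zeros((g.k, g.n_levels)) for name, g in groups.items()}
    fixed_covs = config.fixed_covariances or {}
    covs = {
        name: np.atleast_2d(np.asarray(fixed_covs[name], dtype=float)).copy()
        if name in fixed_covs else config.start_variance * np.eye(g.k)
        for name, g in groups.items()
        if g.prior != "none"
    }
    if config.prior == "flat":
        for name, g in groups.items():
            if g.prior != "none" and name not in fixed_covs and g.n_levels < 2 * g.k + 1:
                raise ValueError(
                    f"group {name!r} has too few levels ({g.n_levels}) for a flat "
                    "prior; use prior='invwishart' or fix its covariance"
                )
    sigma2_e1 = float(np.var(design.trait_values) * 0.5 + 1e-3) if has_trait else np.nan

    obs = np.zeros(design.n_records)
    sd_c = math.sqrt(residual_contest)
    obs[crows] = np.where(y == 1, 0.674, -0.674) * sd_c
    if has_trait:
        obs[trows] = design.trait_values
    e = obs.copy()
    liab = obs[crows].copy()
    tau = np.full(design.n_records, 1.0 / residual_contest)
    if has_trait:
        tau[trows] = 1.0 / sigma2_e1

    n_keep = config.n_samples
    var_store = {
        name: np.empty((n_keep, g.k, g.k))
        for name, g in groups.items() if g.prior != "none"
    }
    e1_store = np.empty(n_keep) if has_trait else None
    sol_store: dict[str, np.ndarray] = {}
    if config.store_solutions:
        g = groups["genetic"]
        sol_store["genetic"] = np.empty((n_keep, g.k, g.n_levels))
        gf = groups["fixed"]
        sol_store["fixed"] = np.empty((n_keep, gf.k, gf.n_levels))
    liab_store = np.empty((n_keep, len(crows))) if config.store_liabilities else None
    mean_acc = {name: np.zeros_like(arr) for name, arr in u.items()}

    zero_prec = {name: np.zeros((g.k, g.k)) for name, g in groups.items()}
    kept = 0
    for it in range(config.iterations):
        # --- liabilities: truncated-normal data augmentation
        mu = liab - e[crows]
        pneg = ndtr(-mu / sd_c)
        u01 = rng.random(len(crows))
        p = np.where(y == 1, pneg + u01 * (1.0 - pneg), u01 * pneg)
        np.clip(p, 1e-300, 1.0 - 1e-16, out=p)
        liab_new = mu + sd_c * np.clip(ndtri(p), -38.0, 38.0)
        e[crows] += liab_new - liab
        liab = liab_new

        # --- location effects
        for name, g in groups.items():
            if g.prior == "none":
                prec = zero_prec[name]
            else:
                prec = np.linalg.inv(covs[name])
            z = rng.standard_normal(g.k * g.n_levels)
            if g.block:
                sweep_block(
                    e, tau, u[name], g.colptr, g.rows, g.vals, prec,
                    g.prior == "rel", a_indptr, a_indices, a_data, a_diag, z,
                )
            else:
                sweep_scalar(e, tau, u[name], g.colptr, g.rows, g.vals, prec, z)

        # --- covariance blocks (inverse-Wishart full conditionals)
        for name, g in groups.items():
            if g.prior == "none" or name in fixed_covs:
                continue
            U = u[name]
            if g.prior == "rel":
                S = U @ (ainv @ U.T)
            else:
                S = U @ U.T
            S = 0.5 * (S + S.T)
            if config.prior == "flat":
                # flat prior on the covariance block: the conditional is the
                # inverse-Wishart kernel of the likelihood itself
                df = g.n_levels - g.k - 1
                S += 1e-8 * np.eye(g.k)
            else:
                S += config.prior_scale * np.eye(g.k)
                df = g.n_levels + g.k + 1
            draw = invwishart.rvs(df=df, scale=S, random_state=rng)
            covs[name] = np.atleast_2d(draw)

        # --- trait residual variance
        if has_trait:
            ssr = float(e[trows] @ e[trows])
            if config.prior == "flat":
                sigma2_e1 = ssr / rng.chisquare(n1 - 2)
            else:
                sigma2_e1 = (ssr + config.prior_scale) / rng.chisquare(n1 + 2)
            tau[trows] = 1.0 / sigma2_e1

        worst = max(float(np.max(np.diag(c))) for c in covs.values())
        if has_trait:
            worst = max(worst, sigma2_e1)
        if not np.isfinite(worst) or worst > config.variance_cap:
            raise RuntimeError(
                f"sampler diverged at iteration {it}: a variance exceeded "
                f"{config.variance_cap} (max diag {worst:.3g})"
            )

        # --- storage
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            for name in var_store:
                var_store[name][kept] = covs[name]
            if has_trait:
                e1_store[kept] = sigma2_e1
            for name in sol_store:
                sol_store[name][kept] = u[name]
            if liab_store is not None:
                liab_store[kept] = liab
            for name in mean_acc:
                mean_acc[name] += u[name]
            kept += 1

    for name in mean_acc:
        mean_acc[name] /= max(kept, 1)

    cols = {}
    for name, g in groups.items():
        if g.prior == "none":
            continue
        flat = np.array([_flatten_cov(var_store[name][s]) for s in range(kept)])
        for j, col in enumerate(_group_colnames(name, g.components)):
            cols[col] = flat[:, j]
    if has_trait:
        cols["sigma2_e1"] = e1_store[:kept]
        cols["sigma2_e2"] = np.full(kept, residual_contest)
    else:
        cols["sigma2_e"] = np.full(kept, residual_contest)
    variance_samples = pd.DataFrame(cols)

    return {
        "variance_samples": variance_samples,
        "solutions": sol_store,
        "posterior_mean": mean_acc,
        "liabilities": liab_store,
    }


class _BaseModel:
    """Shared fit plumbing for the two model classes."""

    kind = "base"

    def __init__(self):
        self.design: DesignMatrices | None = None
        self.residual_contest = 1.0
        self.constrained = False

    def fit(self, iterations: int = 60_000, burn_in: int = 10_000, thin: int = 10,
            seed: int = 0, **kwargs) -> GibbsResults:
        """Run the Gibbs sampler; extra kwargs go to :class:`GibbsConfig`."""
        config = GibbsConfig(iterations=iterations, burn_in=burn_in, thin=thin,
                             seed=seed, **kwargs)
        raw = _run_gibbs(self.design, config, residual_contest=self.residual_contest)
        vs = raw["variance_samples"]
        if self.constrained:
            # derived view of the constrained parameterization: equal direct and
            # indirect variances, covariance forced to the negative variance
            vs = vs.assign(
                sigma2_aD=vs["sigma2_a"], sigma2_aC=vs["sigma2_a"],
                sigma_aD_aC=-vs["sigma2_a"],
                sigma2_PeD=vs["sigma2_Pe"], sigma2_PeC=vs["sigma2_Pe"],
                sigma_PeD_PeC=-vs["sigma2_Pe"],
            )
        meta = {
            name: (g.components, g.level_labels) for name, g in self.design.groups.items()
        }
        return GibbsResults(
            variance_samples=vs,
            solutions=raw["solutions"],
            posterior_mean=raw["posterior_mean"],
            groups_meta=meta,
            config=config,
            constrained=self.constrained,
            kind=self.kind,
            pedigree=self.design.pedigree,
            residual_contest=self.residual_contest,
            liabilities=raw["liabilities"],
            outcomes=self.design.outcomes,
        )


class DominanceThresholdModel(_BaseModel):
    """Single-trait threshold animal model for dyadic contest outcomes.

    Parameters
    ----------
    contests : DataFrame
        Prepared one-row-per-duel records (``focal``, ``opponent``,
        ``outcome``, fixed-effect levels, ``herd_focal``, ``herd_opponent``)
        already satisfying the both-roles rule; see :meth:`from_raw_duels` for
        the full preparation pipeline.
    pedigree : Pedigree
        Must cover every contestant.
    constrained : bool
        Multimembership parameterization forcing r(a_D, a_C) = -1.
    include_herd : bool
        Estimate the correlated 2x2 herd block (the production analysis did;
        the constrained reference protocol did not).
    link : str
        "probit" fixes the liability residual at 1; "logit" at pi^2/3 (a
        residual-scale convention — augmentation is always Gaussian).
    """

    kind = "dominance"

    def __init__(self, contests: pd.DataFrame, pedigree: Pedigree, *,
                 constrained: bool = False, include_herd: bool = True,
                 link: str = "probit"):
        super().__init__()
        contests, self.filter_report = filter_both_roles(contests)
        self.contests = contests
        self.constrained = constrained
        self.residual_contest = 1.0 if link == "probit" else LOGIT_RESIDUAL
        self.design = dominance_design(
            contests, pedigree, constrained=constrained, include_herd=include_herd
        )

    @classmethod
    def from_raw_duels(cls, raw: pd.DataFrame, pedigree: Pedigree, *, seed: int = 0,
                       **kwargs) -> "DominanceThresholdModel":
        """Build from winner/loser rows: deduplicate, randomize focal roles,
        then apply the both-roles filter."""
        return cls(prepare_contest_records(raw, seed=seed), pedigree, **kwargs)

    @classmethod
    def from_csv(cls, contests_path, pedigree_path, **kwargs) -> "DominanceThresholdModel":
        return cls(pd.read_csv(contests_path), Pedigree.from_csv(pedigree_path), **kwargs)


class BivariateThresholdLinearModel(_BaseModel):
    """Bivariate threshold-linear animal model: dominance plus one linear trait.

    Only the unconstrained parameterization is offered; a near -1 posterior
    for r(a_D2, a_C2) serves as the internal diagnostic of the dyadic
    symmetry. The residual covariance between traits is structurally zero.
    """

    kind = "bivariate"

    def __init__(self, contests: pd.DataFrame, traits: pd.DataFrame,
                 pedigree: Pedigree, *, trait_model: str = "pe_herd_htd",
                 trait_fixed: list[str] | None = None, link: str = "probit"):
        super().__init__()
        contests, self.filter_report = filter_both_roles(contests)
        self.contests = contests
        self.trait_model = trait_model
        self.residual_contest = 1.0 if link == "probit" else LOGIT_RESIDUAL
        self.design = bivariate_design(
            contests, traits, pedigree, trait_model=trait_model, trait_fixed=trait_fixed
        )

    @classmethod
    def from_csv(cls, contests_path, traits_path, pedigree_path, **kwargs):
        return cls(
            pd.read_csv(contests_path), pd.read_csv(traits_path),
            Pedigree.from_csv(pedigree_path), **kwargs
        )
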