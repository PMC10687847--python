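"""Synthetic pedigreed populations with dyadic contests and a continuous trait.

The generator emulates the data structure the dominance models assume: a
multi-generation pedigree under random (or truncation-selected) mating;
trivariate breeding values (direct dominance a_D, indirect dominance a_C, one
linear trait a_1) with covariance G (x) A; per-animal permanent-environment and
per-herd effect triples sharing the same component structure; probit-liability
contest outcomes with randomized focal roles; and repeated continuous-trait
records with herd / contemporary-group effects.

By the symmetry argument for dyadic traits (assigning the focal role is
arbitrary), the default genetic and permanent-environment blocks follow the
mirror constraint sigma2_D = sigma2_C = -sigma_DC, which makes the direct-
indirect correlation exactly -1 and the total genetic variance of a duel zero.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "TrueParameters",
    "SimulatedDataset",
    "constrained_block",
    "scs_transform",
    "simulate_pedigree",
    "simulate_selected_population",
    "simulate_breeding_values",
    "simulate_contests",
    "simulate_linear_trait",
    "simulate_study",
]

N_AGE_DIFF_CLASSES = 13  # centre class = equal age
N_WEIGHT_DIFF_CLASSES = 7  # centre class = equal weight
WEIGHT_CATEGORY_MEANS = (500.0, 550.0, 650.0)  # kg


def constrained_block(v_direct: float, v_trait: float = 0.0, r_trait_direct: float = 0.0) -> np.ndarray:
    """3x3 covariance over (direct, indirect, trait) under the mirror constraint.

    The dyadic components get equal variances ``v_direct`` and covariance
    ``-v_direct`` (correlation exactly -1); the linear trait gets variance
    ``v_trait`` and correlation ``r_trait_direct`` with the direct component
    (hence ``-r_trait_direct`` with the indirect one, forced by the constraint).
    """
    c = r_trait_direct * math.sqrt(v_direct * v_trait)
    return np.array(
        [
            [v_direct, -v_direct, c],
            [-v_direct, v_direct, -c],
            [c, -c, v_trait],
        ]
    )


@dataclass
class TrueParameters:
    """Generative parameters: covariance structure plus population sizes.

    Component order everywhere is ``(a_D, a_C, a_1)``: direct dominance,
    indirect dominance, linear trait. The dominance liability residual is
    fixed at 1 (probit convention) and is not a free parameter; ``residual``
    below is the linear trait's residual variance.
    """

    # (co)variance structure, liability / standardized trait scale
    G: np.ndarray = field(default_factory=lambda: constrained_block(0.15, 0.224))
    pe_cov: np.ndarray = field(default_factory=lambda: constrained_block(0.10, 0.15))
    herd_cov: np.ndarray = field(default_factory=lambda: constrained_block(0.03, 0.10))
    residual_linear: float = 0.426
    htd_var: float = 0.10
    mu_linear: float = 0.0
    link: str = "probit"  # residual of the liability: "probit" N(0,1), "logit" logistic

    # fixed-effect tables (level -> effect); zeros unless supplied
    fixed_effects: dict = field(default_factory=dict)

    # population structure: a 14-generation herdbook-like pedigree of roughly
    # constant census, ~3,800 animals in total with the defaults
    n_founders: int = 270
    n_generations: int = 14
    offspring_per_pair: float = 2.0
    base_year: int = 2000
    n_herds: int = 60

    # contests: ~45% of the pedigree competes (the youngest animals), each
    # contestant averaging ~20 duel appearances at the default duel count
    n_duels: int = 20_000
    n_contestants: int | None = 1800  # None: every pedigree animal may fight
    n_years: int = 5
    n_days: int = 21

    # linear trait
    n_trait_animals: int = 2500
    records_per_animal: int = 2

    def __post_init__(self):
        for name in ("G", "pe_cov", "herd_cov"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            if m.shape != (3, 3) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{name} is not positive semi-definite")
        if self.link not in ("probit", "logit"):
            raise ValueError("link must be 'probit' or 'logit'")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=1)


@dataclass
class SimulatedDataset:
    """One synthetic study: pedigree, true effects, contests, trait records."""

    pedigree: Pedigree
    true_bv: pd.DataFrame  # index animal id, columns a_D, a_C, a_1
    contests: pd.DataFrame
    trait_records: pd.DataFrame
    params: TrueParameters
    seed: int
    true_pe: pd.DataFrame | None = None
    true_herd: pd.DataFrame | None = None

    def write(self, directory) -> None:
        """Write pedigree/contests/traits CSVs and a JSON parameter sidecar."""
        from pathlib import Path

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_csv(out / "pedigree.csv")
        self.contests.to_csv(out / "contests.csv", index=False)
        self.trait_records.to_csv(out / "traits.csv", index=False)
        sidecar = json.loads(self.params.to_json())
        sidecar["seed"] = int(self.seed)
        (out / "parameters.json").write_text(json.dumps(sidecar, indent=1))


def scs_transform(scc) -> np.ndarray | float:
    """Somatic cell score: SCS = 3 + log2(SCC / 100,000 cells/mL).

    Doubling the count adds one point; 100,000 cells/mL maps to 3.
    """
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("somatic cell count must be positive")
    out = 3.0 + np.log2(scc / 100_000.0)
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------------ pedigree
def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_pair: float = 3.6,
    base_year: int = 2000,
    seed: int | np.random.Generator = 0,
) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders get birth year ``base_year``; each later generation increments the
    year. Half the animals in every generation are used as sires, half as dams,
    paired at random; each pair leaves a Poisson(offspring_per_pair) litter
    (at least one pair is guaranteed fertile so every generation is non-empty).
    """
    ped, _ = _grow_pedigree(
        n_founders, n_generations, offspring_per_pair, base_year,
        np.random.default_rng(seed), G=None, select_on=None,
    )
    return ped


def simulate_selected_population(
    n_founders: int,
    n_generations: int,
    G: np.ndarray,
    offspring_per_pair: float = 3.6,
    base_year: int = 2000,
    seed: int | np.random.Generator = 0,
    select_on: int | None = 0,
    selected_fraction: float = 0.5,
) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree plus breeding values grown jointly, with optional truncation
    selection of parents on one true breeding-value component.

    ``select_on`` is the component column (0 = a_D) or None for random mating.
    Returns (pedigree, true_bv DataFrame).
    """
    return _grow_pedigree(
        n_founders, n_generations, offspring_per_pair, base_year,
        np.random.default_rng(seed), G=np.asarray(G, dtype=float),
        select_on=select_on, selected_fraction=selected_fraction,
    )


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _grow_pedigree(n_founders, n_generations, offspring_per_pair, base_year, rng,
                   G=None, select_on=None, selected_fraction=0.5):
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")

    rows = []
    t = G.shape[0] if G is not None else 0
    sq = _psd_sqrt(G) if G is not None else None
    bv = {}

    founders = [f"F{k:05d}" for k in range(n_founders)]
    for a in founders:
        rows.append((a, "0", "0", base_year))
        if G is not None:
            bv[a] = sq @ rng.standard_normal(t)

    current = list(founders)
    f_coeff = {a: 0.0 for a in founders}

    # parent inbreeding tracked approximately as zero for founders and via
    # tabular bookkeeping is avoided: Mendelian variance uses parental F
    # computed exactly below through a growing kinship dictionary would be
    # O(n^2); instead F of parents is taken from the realized pedigree at the
    # end only for *validation*. Within-generation mating of unrelated-ish
    # animals keeps F small; the exact G (x) A covariance route is
    # simulate_breeding_values, which uses exact inbreeding.
    for g in range(1, n_generations + 1):
        if len(current) < 2:
            raise ValueError("population died out; raise offspring_per_pair")
        perm = rng.permutation(len(current))
        if select_on is not None and G is not None:
            score = np.array([bv[current[k]][select_on] for k in range(len(current))])
            keep = max(2, int(round(selected_fraction * len(current))))
            chosen = np.argsort(score)[::-1][:keep]
            pool = [current[k] for k in chosen]
            perm = rng.permutation(len(pool))
            current = pool
        half = len(current) // 2
        sires = [current[perm[k]] for k in range(half)]
        dams = [current[perm[k]] for k in range(half, 2 * half)]
        nxt = []
        litters = rng.poisson(offspring_per_pair, size=half)
        if litters.sum() == 0:
            litters[rng.integers(half)] = 1
        for p, (s, d) in enumerate(zip(sires, dams)):
            for c in range(litters[p]):
                a = f"G{g}_{p:04d}_{c}"
                rows.append((a, s, d, base_year + g))
                if G is not None:
                    ms_var = 0.5 - 0.25 * (f_coeff.get(s, 0.0) + f_coeff.get(d, 0.0))
                    bv[a] = 0.5 * (bv[s] + bv[d]) + math.sqrt(ms_var) * (
                        sq @ rng.standard_normal(t)
                    )
                    f_coeff[a] = 0.0
                nxt.append(a)
        current = nxt

    ped = Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year"]))
    if G is None:
        return ped, None
    bv_df = pd.DataFrame(
        [bv[a] for a in ped.ids], index=ped.ids, columns=["a_D", "a_C", "a_1"][:t]
    )
    return ped, bv_df


# ------------------------------------------------------------- breeding values
def simulate_breeding_values(
    ped: Pedigree, G: np.ndarray, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Gene-drop t-variate breeding values through a pedigree.

    Founders are MVN(0, G); a non-founder is the parent average plus a
    Mendelian-sampling deviation with covariance d_i * G, where d_i is
    0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_s with one,
    and 1 with none. The stacked vector then has covariance G (x) A exactly.
    """
    rng = np.random.default_rng(seed)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if not np.allclose(G, G.T) or np.linalg.eigvalsh(G).min() < -1e-8:
        raise ValueError("G must be symmetric positive semi-definite")
    t = G.shape[0]
    sq = _psd_sqrt(G)
    f = ped.inbreeding()
    n = len(ped)
    z = rng.standard_normal((n, t))
    bv = np.zeros((n, t))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        mean = np.zeros(t)
        if s >= 0:
            mean += 0.5 * bv[s]
        if d >= 0:
            mean += 0.5 * bv[d]
        ms = 0.5 - 0.25 * (fs + fd)
        bv[i] = mean + math.sqrt(ms) * (sq @ z[i])
    cols = ["a_D", "a_C", "a_1"][:t] if t <= 3 else [f"a{j}" for j in range(t)]
    return pd.DataFrame(bv, index=ped.ids, columns=cols)


# ------------------------------------------------------------------- contests
def simulate_contests(
    ped: Pedigree,
    true_bv: pd.DataFrame,
    params: TrueParameters,
    seed: int | np.random.Generator = 0,
    pe: pd.DataFrame | None = None,
    herd_effects: np.ndarray | None = None,
    herd_of: pd.Series | None = None,
    contestants: list | None = None,
) -> pd.DataFrame:
    """Dyadic duels with probit-liability outcomes and randomized focal roles.

    Pairs are drawn within weight category. The liability of "focal wins" is
    the sum of the fixed effects, a_D(focal) + a_C(opponent), the matching
    permanent-environment and herd effects, and a residual (standard normal
    for the probit link, standard logistic for the logit option). Records of
    animals that never appear in one of the two roles are dropped at the end
    (the fixed point of the both-roles filter), so the output satisfies the
    both-roles rule by construction.
    """
    rng = np.random.default_rng(seed)
    if contestants is not None:
        ids = list(contestants)
    elif params.n_contestants is not None and params.n_contestants < len(ped.ids):
        # prefer the youngest animals, mimicking an active competing cohort
        order = np.argsort(ped.birth_year, kind="stable")[::-1]
        ids = sorted(ped.ids[i] for i in order[: params.n_contestants])
    else:
        ids = list(ped.ids)
    if len(ids) < 2:
        raise ValueError("need at least two contestants")
    m = len(ids)
    idx = {a: k for k, a in enumerate(ids)}

    a_d = true_bv["a_D"].reindex(ids).to_numpy()
    a_c = true_bv["a_C"].reindex(ids).to_numpy()
    if pe is None:
        pe_sq = _psd_sqrt(params.pe_cov[:2, :2])
        pe_mat = rng.standard_normal((m, 2)) @ pe_sq.T
        pe_d, pe_c = pe_mat[:, 0], pe_mat[:, 1]
    else:
        pe_d = pe["pe_D"].reindex(ids).to_numpy()
        pe_c = pe["pe_C"].reindex(ids).to_numpy()

    if herd_of is None:
        herd_assign = rng.integers(params.n_herds, size=m)
    else:
        herd_assign = herd_of.reindex(ids).to_numpy(int)
    if herd_effects is None:
        h_sq = _psd_sqrt(params.herd_cov[:2, :2])
        herd_effects = rng.standard_normal((params.n_herds, 2)) @ h_sq.T

    by = ped.birth_year[ped.index_of(ids)]
    weight_cat = rng.integers(3, size=m)
    weight = np.array([WEIGHT_CATEGORY_MEANS[c] for c in weight_cat]) + rng.normal(
        0, 15, size=m
    )

    fe = {
        name: np.asarray(params.fixed_effects.get(name, np.zeros(size)), dtype=float)
        for name, size in (
            ("year", params.n_years),
            ("day", params.n_days),
            ("weight_cat", 3),
            ("age_diff_class", N_AGE_DIFF_CLASSES),
            ("weight_diff_class", N_WEIGHT_DIFF_CLASSES),
        )
    }

    # within-category pairing
    cats = [np.flatnonzero(weight_cat == c) for c in range(3)]
    if all(len(c) < 2 for c in cats):
        raise ValueError("fewer than 2 animals in every weight category")
    weights_avail = np.array([len(c) * (len(c) - 1) if len(c) >= 2 else 0 for c in cats], float)
    p_cat = weights_avail / weights_avail.sum()

    rows = []
    half_age = N_AGE_DIFF_CLASSES // 2
    half_wt = N_WEIGHT_DIFF_CLASSES // 2
    cat_choice = rng.choice(3, size=params.n_duels, p=p_cat)
    for k in range(params.n_duels):
        pool = cats[cat_choice[k]]
        f, o = pool[rng.choice(len(pool), size=2, replace=False)]
        year = int(rng.integers(params.n_years))
        day = int(rng.integers(params.n_days))
        age_cls = int(np.clip(round(by[f] - by[o]), -half_age, half_age)) + half_age
        wt_cls = int(np.clip(round((weight[f] - weight[o]) / 15.0), -half_wt, half_wt)) + half_wt
        liab = (
            fe["year"][year]
            + fe["day"][day]
            + fe["weight_cat"][cat_choice[k]]
            + fe["age_diff_class"][age_cls]
            + fe["weight_diff_class"][wt_cls]
            + a_d[f] + a_c[o]
            + pe_d[f] + pe_c[o]
            + herd_effects[herd_assign[f], 0] + herd_effects[herd_assign[o], 1]
        )
        if params.link == "probit":
            liab += rng.standard_normal()
        else:
            liab += rng.logistic()
        rows.append(
            (
                ids[f], ids[o], int(liab > 0), year, day, int(cat_choice[k]),
                age_cls, wt_cls, int(herd_assign[f]), int(herd_assign[o]),
            )
        )

    contests = pd.DataFrame(
        rows,
        columns=[
            "focal", "opponent", "outcome", "year", "day", "weight_cat",
            "age_diff_class", "weight_diff_class", "herd_focal", "herd_opponent",
        ],
    )
    from .contests import filter_both_roles

    contests, _ = filter_both_roles(contests)
    return contests.reset_index(drop=True)


# --------------------------------------------------------------- linear trait
def simulate_linear_trait(
    ped: Pedigree,
    true_bv: pd.DataFrame,
    params: TrueParameters,
    seed: int | np.random.Generator = 0,
    pe1: pd.Series | None = None,
    herd_effects: np.ndarray | None = None,
    herd_of: pd.Series | None = None,
    animals: list | None = None,
) -> pd.DataFrame:
    """Repeated records of the continuous trait.

    value = mu + fixed + a_1 + pe_1 + herd + HTD + e; repeated records of an
    animal share a_1 and pe_1. The contemporary group (HTD) is a herd x
    test-day cell with an iid effect of variance ``htd_var``.
    """
    rng = np.random.default_rng(seed)
    if animals is None:
        k = min(params.n_trait_animals, len(ped.ids))
        animals = [ped.ids[i] for i in rng.choice(len(ped.ids), size=k, replace=False)]
    m = len(animals)
    a1 = true_bv["a_1"].reindex(animals).to_numpy()
    if pe1 is None:
        pe1_arr = rng.normal(0, math.sqrt(max(params.pe_cov[2, 2], 0.0)), size=m)
    else:
        pe1_arr = pe1.reindex(animals).to_numpy()
    if herd_of is None:
        herd_assign = rng.integers(params.n_herds, size=m)
    else:
        herd_assign = herd_of.reindex(animals).to_numpy(int)
    if herd_effects is None:
        herd1 = rng.normal(0, math.sqrt(max(params.herd_cov[2, 2], 0.0)), size=params.n_herds)
    else:
        herd1 = herd_effects[:, 2]

    n_days = 10  # test days per herd
    htd = rng.normal(0, math.sqrt(params.htd_var), size=(params.n_herds, n_days))
    fixed_tab = np.asarray(params.fixed_effects.get("parity", np.zeros(3)), dtype=float)

    rows = []
    for k, a in enumerate(animals):
        for _ in range(params.records_per_animal):
            day = int(rng.integers(n_days))
            lvl = int(rng.integers(len(fixed_tab)))
            val = (
                params.mu_linear
                + fixed_tab[lvl]
                + a1[k] + pe1_arr[k]
                + herd1[herd_assign[k]]
                + htd[herd_assign[k], day]
                + rng.normal(0, math.sqrt(params.residual_linear))
            )
            rows.append((a, val, int(herd_assign[k]), f"{herd_assign[k]}:{day}", lvl))
    return pd.DataFrame(rows, columns=["animal", "value", "herd", "htd", "parity"])


# -------------------------------------------------------------------- studies
def simulate_study(
    params: TrueParameters | None = None,
    seed: int = 0,
    selection_on: int | None = None,
    selected_fraction: float = 0.5,
) -> SimulatedDataset:
    """Full synthetic study with consistent shared effects.

    Permanent-environment triples (pe_D, pe_C, pe_1) are drawn once per animal
    from ``pe_cov`` and herd triples once per herd from ``herd_cov``, then
    reused by both the contest and the trait generator, so the cross-trait
    covariance structure of the bivariate model holds in the generated data.
    """
    if params is None:
        params = TrueParameters()
    rng = np.random.default_rng(seed)
    s_ped, s_bv, s_pe, s_herd, s_con, s_tr = rng.integers(2**31 - 1, size=6)

    if selection_on is None:
        ped = simulate_pedigree(
            params.n_founders, params.n_generations, params.offspring_per_pair,
            params.base_year, int(s_ped),
        )
        bv = simulate_breeding_values(ped, params.G, int(s_bv))
    else:
        ped, bv = simulate_selected_population(
            params.n_founders, params.n_generations, params.G,
            params.offspring_per_pair, params.base_year, int(s_ped),
            select_on=selection_on, selected_fraction=selected_fraction,
        )

    rng_pe = np.random.default_rng(int(s_pe))
    pe = pd.DataFrame(
        rng_pe.standard_normal((len(ped), 3)) @ _psd_sqrt(params.pe_cov).T,
        index=ped.ids, columns=["pe_D", "pe_C", "pe_1"],
    )
    rng_h = np.random.default_rng(int(s_herd))
    herd_effects = rng_h.standard_normal((params.n_herds, 3)) @ _psd_sqrt(params.herd_cov).T
    herd_of = pd.Series(rng_h.integers(params.n_herds, size=len(ped)), index=ped.ids)

    contests = simulate_contests(
        ped, bv, params, int(s_con), pe=pe, herd_effects=herd_effects, herd_of=herd_of
    )
    traits = simulate_linear_trait(
        ped, bv, params, int(s_tr), pe1=pe["pe_1"], herd_effects=herd_effects,
        herd_of=herd_of,
    )
    return SimulatedDataset(
        pedigree=ped, true_bv=bv, contests=contests, trait_records=traits,
        params=params, seed=seed, true_pe=pe,
        true_herd=pd.DataFrame(herd_effects, columns=["herd_D", "herd_C", "herd_1"]),
    )
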