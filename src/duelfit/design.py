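"""Sparse incidence structures for the threshold and threshold-linear models.

Effects are organized into *groups*: a group holds k correlated components
(e.g. direct and indirect genetic effects, k = 2) over a common set of levels
(pedigree animals, contest animals, herds, ...). Each component's incidence is
stored column-wise (records per level, with a +/-1 value), the layout the Gibbs
sweep kernels consume.

Fixed effects are one group with no prior: year keeps all its levels (the
liability-scale intercept is absorbed into year); every other factor drops its
first (reference) level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contests import CONTEST_FIXED_FACTORS
from .pedigree import Pedigree, PedigreeError

__all__ = ["GroupDesign", "DesignMatrices", "dominance_design", "bivariate_design"]


@dataclass
class GroupDesign:
    """Column-compressed incidence of one effect group.

    ``colptr[c, i] : colptr[c, i+1]`` indexes into ``rows``/``vals`` and lists
    the records touched by component ``c`` at level ``i``.
    """

    name: str
    k: int
    n_levels: int
    colptr: np.ndarray  # (k, n_levels + 1), absolute offsets
    rows: np.ndarray
    vals: np.ndarray
    prior: str  # "rel" (A^-1 structured), "iid", or "none" (fixed effects)
    block: bool  # True when components never share a record (joint update valid)
    components: list = field(default_factory=list)  # component names
    level_labels: list = field(default_factory=list)

    def to_dense(self, n_records: int) -> np.ndarray:
        """Dense (n_records, k * n_levels) incidence, test support only."""
        out = np.zeros((n_records, self.k * self.n_levels))
        for c in range(self.k):
            for i in range(self.n_levels):
                for p in range(self.colptr[c, i], self.colptr[c, i + 1]):
                    out[self.rows[p], c * self.n_levels + i] += self.vals[p]
        return out


def _make_group(name, components, n_levels, prior, block, comp_names, labels=None):
    """components: list of (level_idx, row_idx, vals) triplets per component."""
    k = len(components)
    if len(comp_names) != k:
        raise ValueError(f"group {name!r}: {k} components but {len(comp_names)} names")
    colptr = np.zeros((k, n_levels + 1), dtype=np.int64)
    rows_all, vals_all = [], []
    offset = 0
    for c, (li, ri, vi) in enumerate(components):
        li = np.asarray(li, dtype=np.int64)
        ri = np.asarray(ri, dtype=np.int64)
        vi = np.asarray(vi, dtype=np.float64)
        order = np.argsort(li, kind="stable")
        counts = np.bincount(li, minlength=n_levels)
        colptr[c, 0] = offset
        colptr[c, 1:] = offset + np.cumsum(counts)
        rows_all.append(ri[order])
        vals_all.append(vi[order])
        offset += len(ri)
    rows = np.concatenate(rows_all) if rows_all else np.empty(0, dtype=np.int64)
    vals = np.concatenate(vals_all) if vals_all else np.empty(0)
    return GroupDesign(
        name, k, n_levels, colptr, rows, vals, prior, block,
        components=comp_names, level_labels=list(labels) if labels is not None else [],
    )


def _categorical_block(df: pd.DataFrame, full: list[str], drop_first: list[str],
                       row_offset: int = 0, prefix: str = ""):
    """Dummy coding: (level_idx, row_idx, names). ``full`` factors keep all
    levels; ``drop_first`` factors lose their first sorted level."""
    cols, rows, names = [], [], []
    ridx = np.arange(len(df)) + row_offset
    for fac in full + drop_first:
        cat = pd.Categorical(df[fac])
        codes = cat.codes.astype(np.int64)
        if (codes < 0).any():
            raise ValueError(f"missing values in fixed factor {fac!r}")
        base = len(names)
        if fac in drop_first:
            usable = list(cat.categories[1:])
            mask = codes > 0
            cols.append(base + codes[mask] - 1)
            rows.append(ridx[mask])
        else:
            usable = list(cat.categories)
            cols.append(base + codes)
            rows.append(ridx)
        names.extend(f"{prefix}{fac}:{lvl}" for lvl in usable)
    col_idx = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    row_idx = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    return col_idx, row_idx, names


@dataclass
class DesignMatrices:
    """Everything a Gibbs run needs, plus labels for reporting."""

    groups: dict
    n_records: int
    contest_rows: np.ndarray  # record indices with a latent liability
    outcomes: np.ndarray  # 0/1 per contest row
    trait_rows: np.ndarray  # record indices with an observed Gaussian response
    trait_values: np.ndarray
    pedigree: Pedigree
    fixed_names: list


def _check_contestants(contests: pd.DataFrame, ped: Pedigree) -> None:
    seen = set(contests["focal"].astype(str)) | set(contests["opponent"].astype(str))
    absent = sorted(a for a in seen if a not in ped)
    if absent:
        raise PedigreeError(
            f"{len(absent)} contestant(s) absent from pedigree, e.g. {absent[:5]}"
        )


def dominance_design(
    contests: pd.DataFrame,
    ped: Pedigree,
    constrained: bool = False,
    include_herd: bool = True,
) -> DesignMatrices:
    """Design for the single-trait threshold model of contest outcomes.

    Unconstrained: separate direct/indirect genetic (over pedigree order) and
    permanent-environment (over contest animals) components. Constrained: the
    multimembership form — one genetic and one Pe vector entering through the
    signed incidence (Z_D - Z_C), (W_D - W_C), which forces a_C = -a_D.
    """
    _check_contestants(contests, ped)
    n = len(contests)
    ridx = np.arange(n)
    focal_ped = ped.index_of(contests["focal"].astype(str))
    opp_ped = ped.index_of(contests["opponent"].astype(str))

    animals = sorted(set(contests["focal"].astype(str)) | set(contests["opponent"].astype(str)))
    amap = {a: k for k, a in enumerate(animals)}
    focal_pe = contests["focal"].astype(str).map(amap).to_numpy()
    opp_pe = contests["opponent"].astype(str).map(amap).to_numpy()

    ones = np.ones(n)
    groups: dict[str, GroupDesign] = {}
    if constrained:
        groups["genetic"] = _make_group(
            "genetic",
            [(np.concatenate([focal_ped, opp_ped]), np.concatenate([ridx, ridx]),
              np.concatenate([ones, -ones]))],
            len(ped), "rel", True, ["a"], ped.ids,
        )
        groups["pe"] = _make_group(
            "pe",
            [(np.concatenate([focal_pe, opp_pe]), np.concatenate([ridx, ridx]),
              np.concatenate([ones, -ones]))],
            len(animals), "iid", True, ["Pe"], animals,
        )
    else:
        groups["genetic"] = _make_group(
            "genetic",
            [(focal_ped, ridx, ones), (opp_ped, ridx, ones)],
            len(ped), "rel", True, ["a_D", "a_C"], ped.ids,
        )
        groups["pe"] = _make_group(
            "pe",
            [(focal_pe, ridx, ones), (opp_pe, ridx, ones)],
            len(animals), "iid", True, ["Pe_D", "Pe_C"], animals,
        )

    if include_herd:
        herds = sorted(set(contests["herd_focal"]) | set(contests["herd_opponent"]))
        hmap = {h: k for k, h in enumerate(herds)}
        hf = contests["herd_focal"].map(hmap).to_numpy()
        ho = contests["herd_opponent"].map(hmap).to_numpy()
        # same-herd duels make the two components share records: scalar updates
        groups["herd"] = _make_group(
            "herd", [(hf, ridx, ones), (ho, ridx, ones)],
            len(herds), "iid", False, ["herd_D", "herd_C"], herds,
        )

    factors = [f for f in CONTEST_FIXED_FACTORS if f in contests.columns]
    full = [f for f in factors if f == "year"]
    dropf = [f for f in factors if f != "year"]
    cidx, rrows, names = _categorical_block(contests, full, dropf)
    groups["fixed"] = _make_group(
        "fixed", [(cidx, rrows, np.ones(len(cidx)))],
        len(names), "none", False, ["beta"], names,
    )

    return DesignMatrices(
        groups=groups,
        n_records=n,
        contest_rows=ridx,
        outcomes=contests["outcome"].to_numpy(np.int64),
        trait_rows=np.empty(0, dtype=np.int64),
        trait_values=np.empty(0),
        pedigree=ped,
        fixed_names=names,
    )


TRAIT_MODELS = ("pe_herd", "pe_herd_htd", "hyc")


def bivariate_design(
    contests: pd.DataFrame,
    traits: pd.DataFrame,
    ped: Pedigree,
    trait_model: str = "pe_herd_htd",
    trait_fixed: list[str] | None = None,
) -> DesignMatrices:
    """Stacked design coupling the dominance threshold model (trait 2) with one
    continuous trait (trait 1, direct genetic effects only).

    ``trait_model`` picks the trait-1 random-effect shape: ``pe_herd``
    (fertility-like), ``pe_herd_htd`` (milk/SCS-like, adds a herd-test-day
    contemporary group), or ``hyc`` (morphology-like: a single herd-year-
    classifier contemporary group, no Pe/herd).

    Component order in correlated groups is (trait1, direct, indirect).
    """
    if trait_model not in TRAIT_MODELS:
        raise ValueError(f"trait_model must be one of {TRAIT_MODELS}")
    _check_contestants(contests, ped)
    missing = sorted(set(traits["animal"].astype(str)) - set(ped.ids))
    if missing:
        raise PedigreeError(f"trait animals absent from pedigree, e.g. {missing[:5]}")

    n2 = len(contests)
    n1 = len(traits)
    contest_rows = np.arange(n2)
    trait_rows = np.arange(n2, n2 + n1)

    focal_ped = ped.index_of(contests["focal"].astype(str))
    opp_ped = ped.index_of(contests["opponent"].astype(str))
    trait_ped = ped.index_of(traits["animal"].astype(str))
    ones2, ones1 = np.ones(n2), np.ones(n1)

    groups: dict[str, GroupDesign] = {}
    groups["genetic"] = _make_group(
        "genetic",
        [
            (trait_ped, trait_rows, ones1),
            (focal_ped, contest_rows, ones2),
            (opp_ped, contest_rows, ones2),
        ],
        len(ped), "rel", True, ["a_1", "a_D2", "a_C2"], ped.ids,
    )

    has_pe1 = trait_model in ("pe_herd", "pe_herd_htd")
    contest_animals = set(contests["focal"].astype(str)) | set(contests["opponent"].astype(str))
    if has_pe1:
        union = sorted(contest_animals | set(traits["animal"].astype(str)))
    else:
        union = sorted(contest_animals)
    amap = {a: k for k, a in enumerate(union)}
    focal_pe = contests["focal"].astype(str).map(amap).to_numpy()
    opp_pe = contests["opponent"].astype(str).map(amap).to_numpy()
    pe_comps = []
    pe_names = []
    if has_pe1:
        pe_comps.append((traits["animal"].astype(str).map(amap).to_numpy(), trait_rows, ones1))
        pe_names.append("Pe_1")
    pe_comps += [(focal_pe, contest_rows, ones2), (opp_pe, contest_rows, ones2)]
    pe_names += ["Pe_D2", "Pe_C2"]
    groups["pe"] = _make_group("pe", pe_comps, len(union), "iid", True, pe_names, union)

    has_herd1 = trait_model in ("pe_herd", "pe_herd_htd")
    herd_set = set(contests["herd_focal"]) | set(contests["herd_opponent"])
    if has_herd1:
        herd_set |= set(traits["herd"])
    herds = sorted(herd_set)
    hmap = {h: k for k, h in enumerate(herds)}
    herd_comps = []
    herd_names = []
    if has_herd1:
        herd_comps.append((traits["herd"].map(hmap).to_numpy(), trait_rows, ones1))
        herd_names.append("herd_1")
    herd_comps += [
        (contests["herd_focal"].map(hmap).to_numpy(), contest_rows, ones2),
        (contests["herd_opponent"].map(hmap).to_numpy(), contest_rows, ones2),
    ]
    herd_names += ["herd_D2", "herd_C2"]
    groups["herd"] = _make_group("herd", herd_comps, len(herds), "iid", False,
                                 herd_names, herds)

    cg_col = {"pe_herd_htd": "htd", "hyc": "hyc"}.get(trait_model)
    if cg_col is not None:
        if cg_col not in traits.columns:
            raise ValueError(f"trait records lack the {cg_col!r} contemporary-group column")
        cg = pd.Categorical(traits[cg_col])
        groups["cgroup"] = _make_group(
            "cgroup", [(cg.codes.astype(np.int64), trait_rows, ones1)],
            len(cg.categories), "iid", False, [cg_col], list(cg.categories),
        )

    # fixed effects: dominance block + trait-1 block (intercept + factors)
    factors = [f for f in CONTEST_FIXED_FACTORS if f in contests.columns]
    full = [f for f in factors if f == "year"]
    dropf = [f for f in factors if f != "year"]
    c2, r2, names2 = _categorical_block(contests, full, dropf)

    tf = list(trait_fixed) if trait_fixed is not None else (
        ["parity"] if "parity" in traits.columns else []
    )
    c1, r1, names1 = _categorical_block(traits, [], tf, row_offset=n2, prefix="trait1:")
    icept_col = len(names2) + len(names1)
    cidx = np.concatenate([c2, len(names2) + c1, np.full(n1, icept_col, dtype=np.int64)])
    rrows = np.concatenate([r2, r1, trait_rows])
    names = names2 + names1 + ["trait1:intercept"]
    groups["fixed"] = _make_group(
        "fixed", [(cidx, rrows, np.ones(len(cidx)))],
        len(names), "none", False, ["beta"], names,
    )

    return DesignMatrices(
        groups=groups,
        n_records=n2 + n1,
        contest_rows=contest_rows,
        outcomes=contests["outcome"].to_numpy(np.int64),
        trait_rows=trait_rows,
        trait_values=traits["value"].to_numpy(float),
        pedigree=ped,
        fixed_names=names,
    )
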