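"""Preparation and filtering of dyadic contest records.

A physical duel has two animals and one winner. For modelling, each duel enters
the data exactly once: one animal is drawn at random as *focal* (seeded), the
other as *opponent*, and the 0/1 outcome is expressed relative to the focal.
Records are then filtered to the fixed point at which every remaining animal
appears at least once as focal and at least once as opponent — the condition
for both its direct and indirect genetic effects to touch the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["prepare_contest_records", "filter_both_roles", "FilterReport"]

CONTEST_FIXED_FACTORS = ["year", "day", "weight_cat", "age_diff_class", "weight_diff_class"]


@dataclass
class FilterReport:
    """Counts from the both-roles fixed-point filter."""

    n_records_in: int
    n_records_out: int
    n_animals_in: int
    n_animals_out: int
    n_passes: int

    @property
    def records_removed(self) -> int:
        return self.n_records_in - self.n_records_out

    @property
    def animals_removed(self) -> int:
        return self.n_animals_in - self.n_animals_out


def prepare_contest_records(raw: pd.DataFrame, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """One-row-per-duel records with a seeded random focal-role assignment.

    Parameters
    ----------
    raw : DataFrame
        Columns ``winner`` and ``loser`` plus any context columns (year, day,
        ...), one row per recorded duel. Duplicated duels (same unordered pair
        and identical context) are kept once; duels of an animal against
        itself are dropped with a warning.

    Returns
    -------
    DataFrame with columns ``focal``, ``opponent``, ``outcome`` and the
    context columns carried through.
    """
    rng = np.random.default_rng(seed)
    if not {"winner", "loser"} <= set(raw.columns):
        raise ValueError("raw duels need 'winner' and 'loser' columns")
    df = raw.copy()
    self_mask = df["winner"].astype(str) == df["loser"].astype(str)
    if self_mask.any():
        warnings.warn(f"dropped {int(self_mask.sum())} duel(s) with identical ids")
        df = df[~self_mask]

    context = [c for c in df.columns if c not in ("winner", "loser")]
    lo = np.minimum(df["winner"].astype(str), df["loser"].astype(str))
    hi = np.maximum(df["winner"].astype(str), df["loser"].astype(str))
    key = pd.DataFrame({"_lo": lo, "_hi": hi})
    for c in context:
        key[c] = df[c].values
    dup = key.duplicated()
    df = df[~dup.values]

    focal_is_winner = rng.random(len(df)) < 0.5
    out = pd.DataFrame(
        {
            "focal": np.where(focal_is_winner, df["winner"].astype(str), df["loser"].astype(str)),
            "opponent": np.where(focal_is_winner, df["loser"].astype(str), df["winner"].astype(str)),
            "outcome": focal_is_winner.astype(int),
        }
    )
    for c in context:
        out[c] = df[c].values
    return out.reset_index(drop=True)


def filter_both_roles(contests: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Iterate to the fixed point of the both-roles rule.

    Removes every record involving an animal that does not appear at least
    once as focal *and* at least once as opponent, re-checking until stable.

    Raises
    ------
    ValueError
        If no records survive (advice: re-randomize focal roles).
    """
    df = contests
    n_in = len(df)
    animals_in = len(set(df["focal"]) | set(df["opponent"]))
    passes = 0
    while True:
        passes += 1
        focal_set = set(df["focal"])
        opp_set = set(df["opponent"])
        ok = focal_set & opp_set
        keep = df["focal"].isin(ok) & df["opponent"].isin(ok)
        if keep.all():
            break
        df = df[keep]
        if len(df) == 0:
            raise ValueError(
                "both-roles filtering removed every record; "
                "re-randomize focal roles and retry"
            )
    animals_out = len(set(df["focal"]) | set(df["opponent"]))
    report = FilterReport(n_in, len(df), animals_in, animals_out, passes)
    return df.reset_index(drop=True), report
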