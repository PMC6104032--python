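"""Haplotype-class characterization and the rare-favorable screen.

Profiles give, per block class, its frequency and per trait-environment
mean; the screen keeps classes that are rare (default <= 15% of assigned
lines), sit in a block whose association scan is significant for the
target trait in enough environments, show no penalty environment, and —
mandatorily — whose block is NOT associated with the phenology confounder
(days to heading), mirroring the logic that excludes blocks whose apparent
stress advantage is an escape through earliness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import HaplotypeBlock, TraitTable

__all__ = ["ClassProfile", "class_profiles", "RareFavorable",
           "RareHaplotypeScreen", "screen_rare_favorable",
           "consistency_matrix"]


@dataclass
class ClassProfile:
    """Frequency and per trait-environment means of one haplotype class."""

    block: str
    class_string: str
    frequency: float  # fraction of assigned lines
    n_lines: int
    low_support: bool
    cells: pd.DataFrame  # columns: trait, environment, mean, n, diff_vs_best_other


def class_profiles(blocks: list[HaplotypeBlock], traits: TraitTable,
                   min_n: int = 3) -> list[ClassProfile]:
    """Per-class arithmetic trait means across environments.

    ``diff_vs_best_other`` is the class mean minus the best mean among the
    block's other *supported* classes (n >= ``min_n``) for that
    trait-environment (positive = this class leads); singleton classes are
    too noisy to serve as a baseline.  Classes carried by fewer than
    ``min_n`` lines are still reported but flagged ``low_support``.
    """
    df = traits.records
    profiles: list[ClassProfile] = []
    for blk in blocks:
        if not blk.assignments:
            raise ValueError(f"block {blk.name} has no class assignments")
        assign = pd.Series(blk.assignments, name="class_string")
        merged = df.merge(assign.rename_axis("line_id").reset_index(),
                          on="line_id")
        cell = (merged.groupby(["class_string", "trait", "environment"])
                ["value"].agg(["mean", "count"]).reset_index()
                .rename(columns={"count": "n"}))
        counts = assign.value_counts()
        total = int(counts.sum())
        supported = {c for c, n in counts.items() if n >= min_n}
        for cls, n_cls in counts.items():
            mine = cell[cell["class_string"] == cls].copy()
            others = cell[(cell["class_string"] != cls)
                          & cell["class_string"].isin(supported)]
            best_other = (others.groupby(["trait", "environment"])["mean"]
                          .max().rename("best_other"))
            mine = mine.merge(best_other.reset_index(),
                              on=["trait", "environment"], how="left")
            mine["diff_vs_best_other"] = mine["mean"] - mine["best_other"]
            profiles.append(ClassProfile(
                block=blk.name, class_string=str(cls),
                frequency=float(n_cls) / total, n_lines=int(n_cls),
                low_support=bool(n_cls < min_n),
                cells=mine[["trait", "environment", "mean", "n",
                            "diff_vs_best_other"]].reset_index(drop=True)))
    return profiles


@dataclass
class RareFavorable:
    """One screened candidate: a rare class with a favorable, unconfounded
    stress effect and no penalty environment."""

    block: str
    class_string: str
    frequency: float
    favorable_environments: list[str] = field(default_factory=list)
    penalty_environments: list[str] = field(default_factory=list)
    n_significant_instances: int = 0
    min_p: float = 1.0
    confounded: bool = False
    exotic_specific: bool | None = None
    mean_advantage: float = 0.0


class RareHaplotypeScreen(BaseEstimator):
    """Screen class profiles against association-scan results.

    Parameters
    ----------
    rare_max : float
        Maximum class frequency to count as rare (default 0.15, covering
        the low-frequency classes of interest).
    min_instances : int
        Minimum number of environments in which the block must be
        significant for the target trait.
    min_support : int
        Minimum number of carrier lines for a class to be screenable.
    penalty_tol_sd : float
        A class is penalized in an environment if its mean trails the best
        other class by more than this many trait standard deviations.
    confounder_trait : str
        Scan that must be non-significant for the block (mandatory).

    Attributes
    ----------
    candidates_ : list[RareFavorable]
        Ranked candidates (most significant instances, then advantage).
    """

    def __init__(self, rare_max: float = 0.15, min_instances: int = 1,
                 penalty_tol_sd: float = 0.25, min_support: int = 3,
                 confounder_trait: str = "days_to_heading",
                 require_confounder_scan: bool = True):
        self.rare_max = rare_max
        self.min_instances = min_instances
        self.penalty_tol_sd = penalty_tol_sd
        self.min_support = min_support
        self.confounder_trait = confounder_trait
        self.require_confounder_scan = require_confounder_scan

    def fit(self, profiles: list[ClassProfile], scan_results: pd.DataFrame,
            target_trait: str, traits: TraitTable,
            exotic_specific: dict[str, bool] | None = None
            ) -> "RareHaplotypeScreen":
        res = scan_results
        if self.require_confounder_scan:
            conf = res[res["trait"] == self.confounder_trait]
            if conf.empty:
                raise ValueError(
                    f"confounder trait {self.confounder_trait!r} was not "
                    "scanned; the phenology check is mandatory")
        sig = res[(res["trait"] == target_trait) & res["significant"]]
        sig_envs = sig.groupby("feature")["environment"].apply(set).to_dict()
        best_p = sig.groupby("feature")["p_value"].min().to_dict()
        conf_blocks = set(
            res[(res["trait"] == self.confounder_trait)
                & res["significant"]]["feature"])
        env_sd = (traits.records[traits.records["trait"] == target_trait]
                  .groupby("environment")["value"].std().to_dict())
        candidates: list[RareFavorable] = []
        for prof in profiles:
            if prof.frequency > self.rare_max:
                continue
            if prof.n_lines < self.min_support:
                # a class carried by one or two lines cannot support a
                # favorability judgement
                continue
            envs = sig_envs.get(prof.block, set())
            if len(envs) < self.min_instances:
                continue
            confounded = prof.block in conf_blocks
            cells = prof.cells[prof.cells["trait"] == target_trait]
            favorable, penalty = [], []
            advantage = []
            for _, row in cells.iterrows():
                diff = row["diff_vs_best_other"]
                if np.isnan(diff) or row["environment"] not in envs:
                    # an environment where the block's scan is not
                    # significant carries neither evidence of advantage
                    # nor of penalty
                    continue
                tol = self.penalty_tol_sd * env_sd.get(row["environment"], 0.0)
                if diff > 0:
                    favorable.append(row["environment"])
                    advantage.append(diff)
                elif diff < -tol:
                    penalty.append(row["environment"])
            if confounded or penalty or not favorable:
                continue
            candidates.append(RareFavorable(
                block=prof.block, class_string=prof.class_string,
                frequency=prof.frequency,
                favorable_environments=sorted(favorable),
                penalty_environments=sorted(penalty),
                n_significant_instances=len(envs),
                min_p=float(best_p.get(prof.block, 1.0)),
                confounded=confounded,
                exotic_specific=(None if exotic_specific is None
                                 else exotic_specific.get(prof.block)),
                mean_advantage=float(np.mean(advantage)) if advantage else 0.0,
            ))
        # rank by consistency across environments, then strength of the
        # association evidence; the (noisier) class-mean advantage breaks
        # remaining ties
        candidates.sort(key=lambda c: (-c.n_significant_instances, c.min_p,
                                       -c.mean_advantage, c.block,
                                       c.class_string))
        self.candidates_ = candidates
        return self


def screen_rare_favorable(profiles, scan_results, target_trait, traits,
                          exotic_specific=None, **params) -> list[RareFavorable]:
    """Functional wrapper over :class:`RareHaplotypeScreen`."""
    screen = RareHaplotypeScreen(**params)
    return screen.fit(profiles, scan_results, target_trait, traits,
                      exotic_specific).candidates_


def consistency_matrix(scan_results: pd.DataFrame,
                       alpha: float | None = None) -> pd.DataFrame:
    """Feature x (trait, environment) significance-mark table.

    Cells are 1 where the feature is significant for that trait-environment
    instance (by the scan's two-condition call, or by ``p <= alpha`` when
    given); a ``row_sum`` column counts significant instances per feature.
    """
    df = scan_results.copy()
    if alpha is not None:
        df["mark"] = (df["p_value"] <= alpha).astype(int)
    else:
        df["mark"] = df["significant"].astype(int)
    if df.empty:
        return pd.DataFrame(columns=["row_sum"])
    table = df.pivot_table(index="feature",
                           columns=["trait", "environment"],
                           values="mark", aggfunc="max", fill_value=0)
    table.columns = [f"{t}|{e}" for t, e in table.columns]
    table["row_sum"] = table.sum(axis=1)
    return table
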