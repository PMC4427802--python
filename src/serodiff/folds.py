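"""Stratified fold plans for cross-validated marker selection.

A fold plan splits the cohort k times into a large training set and a small
held-out validation set, stratified by group.  In ``partition`` mode
(default, the conventional reading of "k-fold cross-validation") the k
validation sets are pairwise disjoint and cover the cohort; in ``resample``
mode each fold's split is drawn independently.  For the reference 36-sample
cohort (19 CCA / 17 BBTD, k=6) every training set holds 30 samples with
13-15 BBTD and 15-17 CCA and every validation set 6 samples with 2-4 of each
group; for other cohorts the per-fold group bounds scale proportionally
(floor(n_g/k) - 1 to ceil(n_g/k) + 1, never below 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from serodiff.cohort import validate_design

__all__ = ["FoldPlan", "build_folds", "validation_count_bounds"]

_MAX_TRIES = 1000


def validation_count_bounds(n_group: int, k: int) -> tuple[int, int]:
    """Allowed per-fold validation count for a group of size ``n_group``."""
    lo = max(1, math.floor(n_group / k) - 1)
    hi = math.ceil(n_group / k) + 1
    return lo, hi


@dataclass(frozen=True)
class FoldPlan:
    """k train/validation splits over the cohort's sample ids."""

    k: int
    mode: str
    seed: int
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, validation)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if len(self.folds) != self.k:
            raise ValueError(f"expected {self.k} folds, got {len(self.folds)}")

    @property
    def samples(self) -> tuple[str, ...]:
        train, val = self.folds[0]
        return tuple(sorted(train + val))

    def validate(self, design: pd.DataFrame) -> None:
        """Check the plan's invariants against a cohort design."""
        validate_design(design)
        all_ids = set(design["sample_id"])
        group = dict(zip(design["sample_id"], design["group"]))
        n_cca = sum(1 for g in group.values() if g == "CCA")
        n_bbtd = len(group) - n_cca
        bounds = {
            "CCA": validation_count_bounds(n_cca, self.k),
            "BBTD": validation_count_bounds(n_bbtd, self.k),
        }
        for i, (train, val) in enumerate(self.folds):
            tset, vset = set(train), set(val)
            if tset & vset:
                raise ValueError(f"fold {i}: training and validation overlap")
            if tset | vset != all_ids:
                raise ValueError(f"fold {i}: split does not cover the cohort")
            for g in ("CCA", "BBTD"):
                c = sum(1 for s in val if group[s] == g)
                lo, hi = bounds[g]
                if not lo <= c <= hi:
                    raise ValueError(
                        f"fold {i}: validation holds {c} {g} samples, "
                        f"outside [{lo}, {hi}]"
                    )
        if self.mode == "partition":
            concat = sorted(s for _, val in self.folds for s in val)
            if concat != sorted(all_ids):
                raise ValueError(
                    "partition mode: validation sets must partition the cohort"
                )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "mode": self.mode,
            "seed": self.seed,
            "folds": [
                {"train": list(train), "validation": list(val)}
                for train, val in self.folds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldPlan":
        folds = tuple(
            (tuple(f["train"]), tuple(f["validation"])) for f in d["folds"]
        )
        return cls(k=d["k"], mode=d["mode"], seed=d["seed"], folds=folds)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _chunk_sizes(n: int, k: int, front_loaded: bool) -> list[int]:
    base, rem = divmod(n, k)
    if front_loaded:
        return [base + 1] * rem + [base] * (k - rem)
    return [base] * (k - rem) + [base + 1] * rem


def build_folds(
    design: pd.DataFrame, k: int = 6, mode: str = "partition", seed: int = 0
) -> FoldPlan:
    """Build a stratified fold plan over the cohort.

    Group members are shuffled, allocated round-robin into k validation
    chunks (remainders placed at opposite ends of the fold list for the two
    groups so fold sizes stay even), and the plan is re-drawn until every
    per-fold group-count bound holds.  Raises with the violated bound when
    the cohort cannot satisfy the constraints (e.g. fewer samples in a group
    than folds in partition mode).
    """
    validate_design(design)
    if mode not in ("partition", "resample"):
        raise ValueError(f"mode must be 'partition' or 'resample', got {mode!r}")
    ids = {
        g: design.loc[design["group"] == g, "sample_id"].tolist()
        for g in ("CCA", "BBTD")
    }
    n_cca, n_bbtd = len(ids["CCA"]), len(ids["BBTD"])
    if n_cca == 0 or n_bbtd == 0:
        raise ValueError("design must contain both CCA and BBTD samples")
    if mode == "partition" and (n_cca < k or n_bbtd < k):
        raise ValueError(
            f"partition mode needs >= {k} samples per group (each validation "
            f"set must hold at least one of each); got CCA={n_cca}, BBTD={n_bbtd}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    all_ids = ids["CCA"] + ids["BBTD"]

    plan: FoldPlan | None = None
    for _ in range(_MAX_TRIES):
        folds = []
        if mode == "partition":
            chunks: dict[str, list[list[str]]] = {}
            for front, g in ((True, "CCA"), (False, "BBTD")):
                perm = list(rng.permutation(ids[g]))
                sizes = _chunk_sizes(len(perm), k, front_loaded=front)
                out, pos = [], 0
                for s in sizes:
                    out.append(perm[pos : pos + s])
                    pos += s
                chunks[g] = out
            for i in range(k):
                val = sorted(chunks["CCA"][i] + chunks["BBTD"][i])
                train = sorted(set(all_ids) - set(val))
                folds.append((tuple(train), tuple(val)))
        else:
            v = round(len(all_ids) / k)
            lo_c, hi_c = validation_count_bounds(n_cca, k)
            lo_b, hi_b = validation_count_bounds(n_bbtd, k)
            feasible = [
                c for c in range(lo_c, hi_c + 1) if lo_b <= v - c <= hi_b
            ]
            if not feasible:
                raise ValueError(
                    f"no feasible validation composition: need CCA in "
                    f"[{lo_c}, {hi_c}] and BBTD in [{lo_b}, {hi_b}] summing to {v}"
                )
            for _ in range(k):
                c = int(rng.choice(feasible))
                val = sorted(
                    list(rng.choice(ids["CCA"], size=c, replace=False))
                    + list(rng.choice(ids["BBTD"], size=v - c, replace=False))
                )
                train = sorted(set(all_ids) - set(val))
                folds.append((tuple(train), tuple(val)))
        candidate = FoldPlan(k=k, mode=mode, seed=seed, folds=tuple(folds))
        try:
            candidate.validate(design)
        except ValueError:
            continue
        plan = candidate
        break
    if plan is None:
        raise ValueError(
            f"could not build a fold plan satisfying the count bounds for "
            f"CCA={n_cca}, BBTD={n_bbtd}, k={k} (mode={mode})"
        )
    return plan
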