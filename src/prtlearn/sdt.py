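"""Model-free signal-detection analysis of PRT trial tables.

Six behavioural variables summarise a session without any learning model:

- Response bias ``RB = 0.5 * log10[(rich_correct * lean_incorrect) /
  (rich_incorrect * lean_correct)]`` — the tendency to report the rich
  stimulus regardless of what was shown (log b).
- Discriminability ``DR = 0.5 * log10[(rich_correct * lean_correct) /
  (rich_incorrect * lean_incorrect)]`` — perceptual separation of the two
  stimuli (log d).
- Cumulative reward ``CR`` (points), accuracies for rich (``AR``) and lean
  (``AL``) trials, and overall fraction correct ``FC``.

Whenever any cell of the 2x2 response table is zero, 0.5 is added to every
cell before the log-ratios are formed, keeping both measures finite.  Mean
reaction times are reported per stimulus x accuracy cell.  Trials whose RT
falls outside a validity window (default 150-2500 ms) are excluded from
scoring; trials without an RT are always scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResponseCounts",
    "tabulate_counts",
    "response_bias",
    "discriminability",
    "accuracy_and_reward",
    "rt_summary",
    "summarize_sessions",
    "DEFAULT_RT_WINDOW",
]

DEFAULT_RT_WINDOW: tuple[float, float] = (150.0, 2500.0)

RT_CELL_COLUMNS = [
    "rt_rich_correct",
    "rt_rich_error",
    "rt_lean_correct",
    "rt_lean_error",
]


@dataclass(frozen=True)
class ResponseCounts:
    rich_correct: int
    rich_incorrect: int
    lean_correct: int
    lean_incorrect: int

    def __post_init__(self):
        for name in ("rich_correct", "rich_incorrect", "lean_correct", "lean_incorrect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return (
            self.rich_correct
            + self.rich_incorrect
            + self.lean_correct
            + self.lean_incorrect
        )

    def cells(self) -> np.ndarray:
        return np.array(
            [
                self.rich_correct,
                self.rich_incorrect,
                self.lean_correct,
                self.lean_incorrect,
            ],
            dtype=float,
        )


def _scored_mask(trials: pd.DataFrame, rt_window) -> np.ndarray:
    if rt_window is None or "rt" not in trials.columns:
        return np.ones(len(trials), dtype=bool)
    rt = pd.to_numeric(trials["rt"], errors="coerce")
    lo, hi = rt_window
    return (rt.isna() | ((rt >= lo) & (rt <= hi))).to_numpy()


def tabulate_counts(
    trials: pd.DataFrame,
    rt_window: tuple[float, float] | None = DEFAULT_RT_WINDOW,
) -> tuple[ResponseCounts, int]:
    """Response table for one session; returns (counts, n_excluded)."""
    if len(trials) == 0:
        raise ValueError("cannot tabulate an empty trial table")
    for col in ("stimulus", "correct"):
        if col not in trials.columns or trials[col].isna().any():
            raise ValueError(f"every trial needs a {col!r} value")
    scored = _scored_mask(trials, rt_window)
    sub = trials.loc[scored]
    rich = sub["stimulus"] == "rich"
    correct = sub["correct"].astype(bool)
    counts = ResponseCounts(
        rich_correct=int((rich & correct).sum()),
        rich_incorrect=int((rich & ~correct).sum()),
        lean_correct=int((~rich & correct).sum()),
        lean_incorrect=int((~rich & ~correct).sum()),
    )
    return counts, int((~scored).sum())


def _corrected_cells(counts: ResponseCounts) -> np.ndarray:
    cells = counts.cells()
    if (cells == 0).any():
        cells = cells + 0.5
    return cells


def response_bias(counts: ResponseCounts) -> float:
    """Log-b response bias, positive when responding favours the rich action."""
    rc, ri, lc, li = _corrected_cells(counts)
    return 0.5 * math.log10((rc * li) / (ri * lc))


def discriminability(counts: ResponseCounts) -> float:
    """Log-d discriminability, zero at chance performance."""
    rc, ri, lc, li = _corrected_cells(counts)
    return 0.5 * math.log10((rc * lc) / (ri * li))


def accuracy_and_reward(
    trials: pd.DataFrame,
    rt_window: tuple[float, float] | None = DEFAULT_RT_WINDOW,
) -> dict[str, float]:
    """AR, AL, FC and cumulative reward CR (points) for one session.

    A stimulus type with no scored trials yields NaN accuracy rather than a
    silent zero.  CR sums the points column over all trials (reward
    delivery is not affected by RT-based scoring exclusions).
    """
    if len(trials) == 0:
        raise ValueError("cannot summarise an empty trial table")
    counts, _ = tabulate_counts(trials, rt_window)
    n_rich = counts.rich_correct + counts.rich_incorrect
    n_lean = counts.lean_correct + counts.lean_incorrect
    ar = counts.rich_correct / n_rich if n_rich else math.nan
    al = counts.lean_correct / n_lean if n_lean else math.nan
    fc = (
        (counts.rich_correct + counts.lean_correct) / counts.total
        if counts.total
        else math.nan
    )
    cr = float(pd.to_numeric(trials["points"]).sum()) if "points" in trials else math.nan
    return {"AR": ar, "AL": al, "FC": fc, "CR": cr}


def rt_summary(
    trials: pd.DataFrame,
    rt_window: tuple[float, float] | None = DEFAULT_RT_WINDOW,
) -> dict[str, float]:
    """Mean RT per stimulus (rich/lean) x accuracy (correct/error) cell.

    Cells with no scored trials are NaN.
    """
    out = dict.fromkeys(RT_CELL_COLUMNS, math.nan)
    if "rt" not in trials.columns:
        return out
    scored = _scored_mask(trials, rt_window)
    sub = trials.loc[scored].copy()
    sub["rt"] = pd.to_numeric(sub["rt"], errors="coerce")
    sub = sub.dropna(subset=["rt"])
    for stim in ("rich", "lean"):
        for acc, label in ((True, "correct"), (False, "error")):
            cell = sub[(sub["stimulus"] == stim) & (sub["correct"].astype(bool) == acc)]
            if len(cell):
                out[f"rt_{stim}_{label}"] = float(cell["rt"].mean())
    return out


def summarize_sessions(
    trials: pd.DataFrame,
    rt_window: tuple[float, float] | None = DEFAULT_RT_WINDOW,
    per_block: bool = False,
) -> pd.DataFrame:
    """Per subject-session (optionally per block) table of the six variables.

    Output columns: subject_id, session [, block], RB, DR, CR, AR, AL, FC,
    the four RT cell means, and n_excluded (trials dropped by the RT
    window).
    """
    keys = ["subject_id", "session"] + (["block"] if per_block else [])
    rows = []
    for key, grp in trials.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        counts, n_excluded = tabulate_counts(grp, rt_window)
        acc = accuracy_and_reward(grp, rt_window)
        row = dict(zip(keys, key))
        row.update(
            RB=response_bias(counts),
            DR=discriminability(counts),
            CR=acc["CR"],
            AR=acc["AR"],
            AL=acc["AL"],
            FC=acc["FC"],
        )
        row.update(rt_summary(grp, rt_window))
        row["n_excluded"] = n_excluded
        rows.append(row)
    return pd.DataFrame(rows)
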