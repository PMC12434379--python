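"""Subjective quality: MOS aggregation, session scheduling, rater reliability.

A listening panel rates each reconstructed trial on the usual 5-point
opinion scale (1 = bad, 5 = excellent), each trial several times in
randomised order.  The mean opinion score (MOS) of a trial is the plain
arithmetic mean over every (rater x repetition) score.  Panel consistency
is summarised by Cronbach's alpha with raters as items; repetitions are
averaged within rater first, so alpha measures between-rater agreement
rather than within-rater test-retest noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

RATING_COLUMNS = ["trial_id", "rater_id", "repetition", "score"]


class RatingError(ValueError):
    """Malformed or degenerate rating data."""


@dataclass(frozen=True)
class RatingTable:
    """Long-format integer ratings: one row per (trial, rater, repetition)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in RATING_COLUMNS if c not in df.columns]
        if missing:
            raise RatingError(f"rating table missing columns: {missing}")
        scores = df["score"]
        if not np.array_equal(scores, scores.astype(int)):
            raise RatingError("scores must be integers")
        if not scores.isin([1, 2, 3, 4, 5]).all():
            raise RatingError("scores must lie in {1,...,5}")
        if df.duplicated(["trial_id", "rater_id", "repetition"]).any():
            raise RatingError("(trial, rater, repetition) keys must be unique")

    @property
    def trial_ids(self) -> list[str]:
        return sorted(self.frame["trial_id"].unique())

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.frame["rater_id"].unique())

    @classmethod
    def from_records(cls, records) -> "RatingTable":
        return cls(pd.DataFrame(records, columns=RATING_COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "RatingTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.frame[RATING_COLUMNS].to_csv(path, index=False)


def mos(table: RatingTable, trial_id: str) -> float:
    """Mean opinion score of one trial: MOS = (1/N) sum_i R_i over all scores."""
    scores = table.frame.loc[table.frame["trial_id"] == trial_id, "score"]
    if scores.empty:
        raise RatingError(f"no ratings for trial {trial_id!r}")
    return float(scores.mean())


def mos_all(table: RatingTable) -> pd.Series:
    """MOS for every trial, indexed by trial_id."""
    return table.frame.groupby("trial_id")["score"].mean().astype(float)


def schedule_session(trial_ids, repetitions: int = 3, seed: int = 0) -> list:
    """Seeded random presentation order with each trial appearing ``repetitions`` times."""
    trial_ids = list(trial_ids)
    if not trial_ids:
        raise RatingError("cannot schedule an empty trial list")
    if repetitions < 1:
        raise RatingError("repetitions must be >= 1")
    order = trial_ids * repetitions
    rng = np.random.default_rng(seed)
    return [order[i] for i in rng.permutation(len(order))]


def cronbach_alpha(table: RatingTable) -> float:
    """Cronbach's alpha of the rater panel, raters as items.

    Repetitions are averaged within each (trial, rater) cell first; then

        alpha = k/(k-1) * (1 - sum_j var(item_j) / var(sum_j item_j))

    with k raters and variances taken across trials (unbiased, n-1
    denominator).  1 means perfectly consistent raters; values near 0
    mean the panel is indistinguishable from noise.
    """
    cell_means = (table.frame
                  .groupby(["trial_id", "rater_id"])["score"].mean()
                  .unstack())
    if cell_means.isna().any().any():
        raise RatingError("unbalanced panel: every rater must rate every trial")
    k = cell_means.shape[1]
    n = cell_means.shape[0]
    if k < 2 or n < 2:
        raise RatingError("alpha needs at least 2 raters and 2 trials")
    items = cell_means.to_numpy()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise RatingError("zero total variance; reliability undefined")
    item_vars = items.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))
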