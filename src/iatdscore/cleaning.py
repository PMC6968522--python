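"""Trial-level filters and participant-level exclusion flags.

The pipeline applies the steps in a fixed, documented order:

1. remove trials slower than 10,000 ms;
2. count trials under 300 ms and under 400 ms, and flag fast participants
   (more than 10% of trials under 300 ms), on the remaining trials;
3. flag inaccurate participants (error percentage exceeding the threshold,
   default 25%, in at least one mapping condition), on the same trials;
4. delete trials under 400 ms — only for algorithms with the lower-tail
   treatment (D2, D5, D6);
5. hand the retained trials to the scoring module (error inflation, D-score).

All latency and percentage comparisons are strict inequalities: a trial of
exactly 10,000 ms is retained, a trial of exactly 400 ms survives the
lower-tail deletion, a participant at exactly 25% errors or exactly 10%
fast trials is not flagged.

Exclusion flags never drop rows from the results: flagged participants are
scored and written to the output file, and are only hidden from the
displayed summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import TrialTable


@dataclass(frozen=True)
class CleaningConfig:
    """Cleaning options and thresholds.

    ``error_threshold`` is a percentage (default 25); the remaining
    thresholds reproduce the conventional values of the scoring family and
    are exposed for transparency rather than for tuning.
    """

    accuracy_cleaning: bool = False
    error_threshold: float = 25.0
    speed_cleaning: bool = False
    fast_participant_threshold: float = 10.0  # percent of trials
    fast_trial_ms: float = 300.0
    slow_trial_ms: float = 10_000.0
    lower_tail_ms: float = 400.0

    def __post_init__(self) -> None:
        if not 0.0 < self.error_threshold < 100.0:
            raise ValidationError(
                f"error_threshold must be strictly between 0 and 100 percent, "
                f"got {self.error_threshold}"
            )


@dataclass(frozen=True, eq=False)
class CleaningReport:
    """Per-participant counts and exclusion flags, plus table-level totals.

    ``removed_400`` is ``None`` for algorithms without the lower-tail
    treatment ("not expected for this D"); ``num_400`` is always reported.
    All Series are indexed by participant in order of first appearance.
    """

    config: CleaningConfig
    n_trial: pd.Series
    slow10000: pd.Series
    num_300: pd.Series
    num_400: pd.Series
    removed_400: Optional[pd.Series]
    excluded_accuracy: pd.Series
    excluded_speed: pd.Series

    @property
    def excluded(self) -> pd.Series:
        return self.excluded_accuracy | self.excluded_speed

    @property
    def total_slow_removed(self) -> int:
        return int(self.slow10000.sum())

    @property
    def total_lower_tail_removed(self) -> Optional[int]:
        if self.removed_400 is None:
            return None
        return int(self.removed_400.sum())

    @property
    def n_excluded_accuracy(self) -> int:
        return int(self.excluded_accuracy.sum())

    @property
    def n_excluded_speed(self) -> int:
        return int(self.excluded_speed.sum())


def _per_participant_count(
    mask: pd.Series, data: pd.DataFrame, participants: np.ndarray
) -> pd.Series:
    counts = data.loc[mask].groupby("participant", sort=False).size()
    return counts.reindex(participants, fill_value=0).astype(int)


def remove_slow_trials(
    trials: TrialTable, threshold_ms: float = 10_000.0
) -> tuple[TrialTable, pd.Series]:
    """Drop trials with latency strictly above ``threshold_ms``.

    Returns the filtered table and the per-participant count of removed
    trials (0 for untouched participants).  Idempotent.
    """
    df = trials.data
    mask = df["latency"] > threshold_ms
    counts = _per_participant_count(mask, df, trials.participants)
    return trials.with_data(df.loc[~mask]), counts


def remove_lower_tail(
    trials: TrialTable, algorithm, threshold_ms: float = 400.0
) -> tuple[TrialTable, Optional[pd.Series]]:
    """Delete trials faster than 400 ms when the algorithm calls for it.

    For D2/D5/D6 returns the filtered table and per-participant counts; for
    the other algorithms the table passes through and the count is ``None``
    (not applicable).
    """
    if not algorithm.lower_tail_deletion:
        return trials, None
    df = trials.data
    mask = df["latency"] < threshold_ms
    counts = _per_participant_count(mask, df, trials.participants)
    return trials.with_data(df.loc[~mask]), counts


def count_fast_trials(trials: TrialTable, threshold_ms: float) -> pd.Series:
    """Per-participant count of trials strictly faster than ``threshold_ms``."""
    df = trials.data
    return _per_participant_count(df["latency"] < threshold_ms, df, trials.participants)


def flag_inaccurate_participants(
    trials: TrialTable, config: CleaningConfig
) -> pd.Series:
    """Flag participants whose error percentage exceeds the threshold.

    The percentage is computed separately in each mapping condition (all
    Mapping A trials pooled; all Mapping B trials pooled); exceeding the
    threshold in either condition flags the participant.  With
    ``accuracy_cleaning`` off, nobody is flagged.
    """
    participants = trials.participants
    if not config.accuracy_cleaning:
        return pd.Series(False, index=pd.Index(participants, name="participant"))
    df = trials.data
    err_pct = (
        df.assign(error=lambda d: 1 - d["correct"])
        .groupby(["participant", "condition"], sort=False)["error"]
        .mean()
        * 100.0
    )
    flagged = (err_pct > config.error_threshold).groupby("participant", sort=False).any()
    return flagged.reindex(participants, fill_value=False)


def flag_fast_participants(trials: TrialTable, config: CleaningConfig) -> pd.Series:
    """Flag participants with more than 10% of trials faster than 300 ms."""
    participants = trials.participants
    if not config.speed_cleaning:
        return pd.Series(False, index=pd.Index(participants, name="participant"))
    fast = count_fast_trials(trials, config.fast_trial_ms)
    total = (
        trials.data.groupby("participant", sort=False)
        .size()
        .reindex(participants, fill_value=0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * fast / total
    return (pct > config.fast_participant_threshold).fillna(False)


def apply_cleaning(
    trials: TrialTable, algorithm, config: CleaningConfig | None = None
) -> tuple[TrialTable, CleaningReport]:
    """Run the full documented cleaning order; see the module docstring.

    Returns the table of retained trials (ready for error inflation and
    scoring) and a :class:`CleaningReport` with every count the app reports.
    """
    if config is None:
        config = CleaningConfig()
    participants = trials.participants
    n_trial = (
        trials.data.groupby("participant", sort=False)
        .size()
        .reindex(participants, fill_value=0)
        .astype(int)
    )
    after_slow, slow_counts = remove_slow_trials(trials, config.slow_trial_ms)
    num_300 = count_fast_trials(after_slow, config.fast_trial_ms)
    num_400 = count_fast_trials(after_slow, config.lower_tail_ms)
    excluded_speed = flag_fast_participants(after_slow, config)
    excluded_accuracy = flag_inaccurate_participants(after_slow, config)
    cleaned, removed_400 = remove_lower_tail(after_slow, algorithm, config.lower_tail_ms)
    report = CleaningReport(
        config=config,
        n_trial=n_trial,
        slow10000=slow_counts,
        num_300=num_300,
        num_400=num_400,
        removed_400=removed_400,
        excluded_accuracy=excluded_accuracy,
        excluded_speed=excluded_speed,
    )
    return cleaned, report
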