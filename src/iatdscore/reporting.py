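"""Sample-level summaries: six-number summaries, reliability, descriptives.

Everything here is computed on the same cleaned trial set the D-score
consumed: trials discarded by the slow-trial or lower-tail filters do not
contribute, and participants flagged for exclusion are left out of the
displayed statistics by default (they stay in the results file regardless).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import UndefinedScoreError
from .io import TrialTable
from .scoring import get_algorithm, inflated_latencies

SUMMARY_ROWS = ("min", "first_quartile", "median", "mean", "third_quartile", "max")
SCORE_COLUMNS = ("d_practice", "d_test", "dscore")

#: The eight descriptive groupings, in display order.
DESCRIPTIVE_GROUPS = (
    "MappingA",
    "MappingB",
    "practice",
    "test",
    "practiceMappingA",
    "practiceMappingB",
    "testMappingA",
    "testMappingB",
)

_GROUP_MASKS = {
    "MappingA": ("condition", "MappingA"),
    "MappingB": ("condition", "MappingB"),
    "practice": ("pair", "practice"),
    "test": ("pair", "test"),
    "practiceMappingA": ("block_role", "practice_A"),
    "practiceMappingB": ("block_role", "practice_B"),
    "testMappingA": ("block_role", "test_A"),
    "testMappingB": ("block_role", "test_B"),
}


def _displayed(results: pd.DataFrame, include_excluded: bool) -> pd.DataFrame:
    if include_excluded or "excluded" not in results.columns:
        return results
    return results.loc[~results["excluded"].astype(bool)]


def summarize_scores(
    results: pd.DataFrame, include_excluded: bool = False
) -> pd.DataFrame:
    """Six-number summary of D-practice, D-test and the D-score.

    Rows: minimum, first quartile, median, mean, third quartile, maximum
    (quartiles by linear interpolation between order statistics).  Computed
    over participants with a defined value, excluding flagged participants
    unless ``include_excluded``.
    """
    sub = _displayed(results, include_excluded)
    if sub["dscore"].dropna().empty:
        raise UndefinedScoreError("no defined D-scores to summarize")
    table = {}
    for col in SCORE_COLUMNS:
        v = sub[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            table[col] = [np.nan] * 6
            continue
        table[col] = [
            v.min(),
            np.percentile(v, 25),
            np.median(v),
            v.mean(),
            np.percentile(v, 75),
            v.max(),
        ]
    return pd.DataFrame(table, index=pd.Index(SUMMARY_ROWS, name="statistic"))


def practice_test_reliability(
    results: pd.DataFrame, include_excluded: bool = False
) -> float:
    """IAT reliability: Pearson correlation of D-practice with D-test.

    Computed across participants with both components defined.  Requires at
    least three such participants and non-zero variance in both vectors.
    """
    sub = _displayed(results, include_excluded)
    pairs = sub[["d_practice", "d_test"]].dropna()
    if len(pairs) < 3:
        raise UndefinedScoreError(
            f"practice-test reliability needs >= 3 participants with both "
            f"components defined, got {len(pairs)}"
        )
    x = pairs["d_practice"].to_numpy(dtype=float)
    y = pairs["d_test"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedScoreError(
            "practice-test reliability undefined: zero variance in a component"
        )
    return float(np.corrcoef(x, y)[0, 1])


def compute_descriptives(
    trials: TrialTable,
    algorithm=None,
    exclude: Optional[Iterable] = None,
) -> pd.DataFrame:
    """Mean latency and proportion correct for the eight groupings.

    ``trials`` must be the cleaned table used for scoring.  When an
    algorithm is given, latencies are taken post-inflation so the
    descriptives describe exactly what the score consumed; otherwise raw
    latencies are used.  ``exclude`` drops the listed participants (the
    cleaned-out ones).  Empty groupings yield NaN entries.

    The pooled rows are trial-weighted: the MappingA row pools exactly the
    practiceMappingA and testMappingA trials, and similarly for the others.
    """
    df = trials.data
    if exclude is not None:
        excluded = {str(p) for p in exclude}
        df = df.loc[~df["participant"].isin(excluded)]
    if algorithm is not None:
        lat = inflated_latencies(trials.with_data(df), get_algorithm(algorithm))
        df = df.reset_index(drop=True).assign(latency=lat.to_numpy())
    df = df.assign(
        pair=df["block_role"].map(
            {"practice_A": "practice", "practice_B": "practice",
             "test_A": "test", "test_B": "test"}
        )
    )
    rows = []
    for name in DESCRIPTIVE_GROUPS:
        col, value = _GROUP_MASKS[name]
        sub = df.loc[df[col] == value]
        if sub.empty:
            rows.append((name, 0, np.nan, np.nan))
        else:
            lat_values = sub["latency"].to_numpy(dtype=float)
            rows.append(
                (name, len(sub), float(np.mean(lat_values)), float(sub["correct"].mean()))
            )
    out = pd.DataFrame(rows, columns=["grouping", "n_trials", "mean_latency", "prop_correct"])
    return out.set_index("grouping")


def format_report(
    results: pd.DataFrame,
    report,
    algorithm,
    descriptives: Optional[pd.DataFrame] = None,
    include_excluded: bool = False,
) -> str:
    """Render the textual results report mirroring the app's result boxes.

    Includes the six-number summary, the slow-trial and lower-tail removal
    counts ("None" when nothing was removed; "Not expected for this D" when
    the algorithm has no lower-tail treatment), the practice-test
    reliability, the exclusion counts for whichever cleaning options were
    on, and optionally the descriptive statistics table.
    """
    alg = get_algorithm(algorithm)
    direction = results.attrs.get("direction", "B-A")
    dir_text = "MappingB - MappingA" if direction == "B-A" else "MappingA - MappingB"
    n_all = len(results)
    shown = _displayed(results, include_excluded)
    lines = [
        f"D-score results — algorithm {alg.id}, direction {dir_text}",
        f"Participants: {len(shown)} displayed of {n_all} scored",
        "",
        "Summary of D-practice, D-test, D-score:",
    ]
    try:
        lines.append(summarize_scores(results, include_excluded).to_string(float_format=lambda v: f"{v:.4f}"))
    except UndefinedScoreError as exc:
        lines.append(f"  (unavailable: {exc})")
    slow = report.total_slow_removed
    lines.append("")
    lines.append(f"Trials > 10,000 ms: {slow if slow else 'None'}")
    lower = report.total_lower_tail_removed
    if lower is None:
        lines.append("Trials < 400 ms: Not expected for this D")
    else:
        lines.append(f"Trials < 400 ms: {lower if lower else 'None'}")
    try:
        r = practice_test_reliability(results, include_excluded)
        lines.append(f"Practice-test reliability: r = {r:.4f}")
    except UndefinedScoreError as exc:
        lines.append(f"Practice-test reliability: unavailable ({exc})")
    if report.config.accuracy_cleaning:
        lines.append(
            f"Accuracy deletion (> {report.config.error_threshold:g}% errors in a "
            f"condition): {report.n_excluded_accuracy or 'None'}"
        )
    if report.config.speed_cleaning:
        lines.append(
            f"Participants < 300 ms (> {report.config.fast_participant_threshold:g}% "
            f"fast trials): {report.n_excluded_speed or 'None'}"
        )
    if descriptives is not None:
        lines.append("")
        lines.append("Descriptive statistics (cleaned trials):")
        lines.append(descriptives.to_string(float_format=lambda v: f"{v:.4f}"))
    return "\n".join(lines)
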