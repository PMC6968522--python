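"""The D-score core: error inflation, block statistics, standardization.

The D-score summarizes the IAT effect per participant as a standardized
mean difference between the two mapping conditions, computed separately for
the associative practice blocks and the associative test blocks and then
averaged:

    D_practice = (M_practiceB - M_practiceA) / SD_pooled(practice trials)
    D_test     = (M_testB     - M_testA)     / SD_pooled(test trials)
    D-score    = (D_practice + D_test) / 2

Six algorithm variants (D1-D6) differ only in the treatment of error and
fast responses:

=====  =======================================  ========================
  id   error inflation                          lower-tail treatment
=====  =======================================  ========================
  D1   built-in correction                      none
  D2   built-in correction                      delete trials < 400 ms
  D3   mean of correct responses + 2 SD         none
  D4   mean of correct responses + 600 ms       none
  D5   mean of correct responses + 2 SD         delete trials < 400 ms
  D6   mean of correct responses + 600 ms       delete trials < 400 ms
=====  =======================================  ========================

With the built-in correction the recorded latency of an error trial already
includes the time needed to correct the response, so D1/D2 use latencies as
given.  The ex-post strategies (D3-D6) replace each error latency with the
block's correct-trial mean plus a penalty; the 2-SD penalty uses the sample
standard deviation (n-1 denominator) of the block's correct trials.

Numerical conventions, fixed and documented here because they determine the
exact value: the pooled SD of each component is the sample SD of the
concatenated, post-inflation latencies of both blocks (inflated error
trials included); the default direction is MappingB - MappingA, and the
reversed direction is an exact sign flip.  Undefined components (no correct
trials for an ex-post penalty, fewer than two pooled trials, zero pooled
variance, an emptied block) propagate as missing values with a
machine-readable reason code, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from .cleaning import CleaningConfig, apply_cleaning
from .errors import ValidationError
from .io import BLOCK_ROLES, TrialTable

DIRECTIONS = ("B-A", "A-B")

#: Effect-size band edges shared with the plots' reference lines.
EFFECT_BANDS = (0.15, 0.35, 0.65)


@dataclass(frozen=True)
class AlgorithmSpec:
    """One D-score algorithm: error-inflation strategy x lower-tail rule."""

    id: str
    error_inflation: str  # "builtin" | "mean_plus_2sd" | "mean_plus_600"
    lower_tail_deletion: bool

    @property
    def number(self) -> int:
        return int(self.id[1:])


ALGORITHMS: dict[str, AlgorithmSpec] = {
    "D1": AlgorithmSpec("D1", "builtin", False),
    "D2": AlgorithmSpec("D2", "builtin", True),
    "D3": AlgorithmSpec("D3", "mean_plus_2sd", False),
    "D4": AlgorithmSpec("D4", "mean_plus_600", False),
    "D5": AlgorithmSpec("D5", "mean_plus_2sd", True),
    "D6": AlgorithmSpec("D6", "mean_plus_600", True),
}


def get_algorithm(algorithm: Union[str, int, AlgorithmSpec]) -> AlgorithmSpec:
    """Resolve ``"D3"``, ``3`` or an :class:`AlgorithmSpec` to the spec."""
    if isinstance(algorithm, AlgorithmSpec):
        return algorithm
    key = f"D{algorithm}" if isinstance(algorithm, int) else str(algorithm).strip().upper()
    try:
        return ALGORITHMS[key]
    except KeyError:
        raise ValidationError(
            f"unknown algorithm {algorithm!r}; choose one of {sorted(ALGORITHMS)}"
        ) from None


def _check_direction(direction: str) -> str:
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    return direction


class EffectSize(NamedTuple):
    label: str  # negligible | slight | moderate | strong | undefined
    sign: int   # -1, 0, +1 (0 also for undefined)


def classify_effect_size(dscore: float) -> EffectSize:
    """Band a D-score by the conventional +-0.15 / +-0.35 / +-0.65 cutoffs."""
    if dscore is None or not np.isfinite(dscore):
        return EffectSize("undefined", 0)
    a = abs(dscore)
    if a < EFFECT_BANDS[0]:
        label = "negligible"
    elif a < EFFECT_BANDS[1]:
        label = "slight"
    elif a < EFFECT_BANDS[2]:
        label = "moderate"
    else:
        label = "strong"
    sign = 0 if dscore == 0 else (1 if dscore > 0 else -1)
    return EffectSize(label, sign)


def inflate_errors(
    latencies: Sequence[float],
    correct: Sequence[int],
    strategy: str,
) -> np.ndarray:
    """Apply one block's error-inflation strategy and return the latencies.

    ``builtin`` returns the latencies unchanged (the correction time is
    already inside them); ``mean_plus_600`` replaces each error latency with
    the correct-trial mean + 600 ms; ``mean_plus_2sd`` with the correct-trial
    mean + 2 x the correct-trial sample SD.  When the block has no correct
    trials (or only one, for the 2-SD penalty) the replacement is NaN, which
    downstream turns into an undefined component for that participant.
    """
    lat = np.asarray(latencies, dtype=float)
    cor = np.asarray(correct, dtype=int)
    if lat.shape != cor.shape:
        raise ValidationError("latencies and correct must have equal length")
    if strategy == "builtin":
        return lat.copy()
    ok = lat[cor == 1]
    if strategy == "mean_plus_600":
        repl = ok.mean() + 600.0 if ok.size >= 1 else np.nan
    elif strategy == "mean_plus_2sd":
        repl = ok.mean() + 2.0 * ok.std(ddof=1) if ok.size >= 2 else np.nan
    else:
        raise ValidationError(f"unknown error-inflation strategy {strategy!r}")
    return np.where(cor == 1, lat, repl)


def pooled_sd(latencies_x: Sequence[float], latencies_y: Sequence[float]) -> float:
    """Sample SD of the pooled (concatenated) trials of two blocks.

    Returns NaN when fewer than two trials are pooled, when the pooled
    variance is zero, or when any latency is missing (an undefined error
    replacement upstream).
    """
    z = np.concatenate([np.asarray(latencies_x, float), np.asarray(latencies_y, float)])
    if z.size < 2:
        return float("nan")
    s = z.std(ddof=1)
    return float("nan") if s == 0 else float(s)


def d_component(
    block_A: Sequence[float],
    block_B: Sequence[float],
    direction: str = "B-A",
) -> float:
    """Standardized mean difference of two blocks' post-inflation latencies."""
    _check_direction(direction)
    a = np.asarray(block_A, float)
    b = np.asarray(block_B, float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    sd = pooled_sd(a, b)
    d = (b.mean() - a.mean()) / sd
    return float(-d if direction == "A-B" else d)


# --------------------------------------------------------------------------
# vectorized dataset path

def _strict_mean(s: pd.Series) -> float:
    a = s.to_numpy(dtype=float)
    return float(np.mean(a)) if a.size else float("nan")


def _strict_pooled_sd(s: pd.Series) -> float:
    a = s.to_numpy(dtype=float)
    if a.size < 2:
        return float("nan")
    sd = float(np.std(a, ddof=1))
    return float("nan") if sd == 0 else sd


def inflated_latencies(trials: TrialTable, algorithm) -> pd.Series:
    """Post-inflation latency for every trial row, aligned to ``trials.data``.

    Built-in strategies return the column unchanged; ex-post strategies
    replace error latencies block-wise by the correct-trial mean plus the
    penalty, yielding NaN where the penalty is undefined.
    """
    alg = get_algorithm(algorithm)
    df = trials.data
    lat = df["latency"].astype(float)
    if alg.error_inflation == "builtin":
        return lat.copy()
    correct_only = df.loc[df["correct"] == 1]
    stats = correct_only.groupby(["participant", "block_role"], sort=False)["latency"].agg(
        ["mean", "std", "count"]
    )
    if alg.error_inflation == "mean_plus_600":
        repl = stats["mean"] + 600.0
    else:  # mean_plus_2sd; std is NaN for a single correct trial (ddof=1)
        repl = stats["mean"] + 2.0 * stats["std"]
    idx = pd.MultiIndex.from_frame(df[["participant", "block_role"]])
    repl_aligned = repl.reindex(idx).to_numpy(dtype=float)
    out = np.where(df["correct"].to_numpy() == 1, lat.to_numpy(), repl_aligned)
    return pd.Series(out, index=df.index, name="latency")


_PAIR_OF_ROLE = {
    "practice_A": "practice",
    "test_A": "test",
    "practice_B": "practice",
    "test_B": "test",
}


def _undefined_reasons(df: pd.DataFrame, alg: AlgorithmSpec, participants) -> pd.Series:
    """Machine-readable reason codes for undefined components, per participant."""
    grid = pd.MultiIndex.from_product(
        [participants, BLOCK_ROLES], names=["participant", "block_role"]
    )
    n_total = (
        df.groupby(["participant", "block_role"], sort=False)
        .size()
        .reindex(grid, fill_value=0)
        .unstack("block_role")
    )
    n_correct = (
        df.loc[df["correct"] == 1]
        .groupby(["participant", "block_role"], sort=False)
        .size()
        .reindex(grid, fill_value=0)
        .unstack("block_role")
    )
    pair_sizes = (
        df.assign(pair=df["block_role"].map(_PAIR_OF_ROLE))
        .groupby(["participant", "pair"], sort=False)
        .size()
        .unstack("pair")
        .reindex(index=participants, columns=["practice", "test"], fill_value=0)
    )
    lat_col = "lat_inf" if "lat_inf" in df.columns else "latency"

    def _is_zero_variance(s: pd.Series) -> bool:
        a = s.to_numpy(dtype=float)
        return bool(a.size >= 2 and not np.isnan(a).any() and np.std(a, ddof=1) == 0)

    zero_var = (
        df.assign(pair=df["block_role"].map(_PAIR_OF_ROLE))
        .groupby(["participant", "pair"], sort=False)[lat_col]
        .agg(_is_zero_variance)
        .unstack("pair")
        .reindex(index=participants, columns=["practice", "test"], fill_value=False)
    )
    ex_post = alg.error_inflation != "builtin"
    min_correct = 2 if alg.error_inflation == "mean_plus_2sd" else 1
    reasons = []
    for p in participants:
        codes = []
        for role in BLOCK_ROLES:
            nt = int(n_total.at[p, role])
            nc = int(n_correct.at[p, role])
            has_errors = nt > nc
            if nt == 0:
                codes.append(f"empty_block:{role}")
            elif ex_post and has_errors and nc == 0:
                codes.append(f"no_correct_trials:{role}")
            elif ex_post and has_errors and nc < min_correct:
                codes.append(f"insufficient_correct_trials:{role}")
        for pair in ("practice", "test"):
            if 0 < int(pair_sizes.at[p, pair]) < 2:
                codes.append(f"too_few_trials:{pair}")
            elif bool(zero_var.at[p, pair]):
                codes.append(f"zero_variance:{pair}")
        reasons.append(";".join(codes))
    return pd.Series(reasons, index=pd.Index(participants, name="participant"))


def _component_frame(trials: TrialTable, alg: AlgorithmSpec, direction: str) -> pd.DataFrame:
    """Scores, proportions and diagnostics for already-cleaned trials."""
    participants = trials.participants
    df = trials.data.copy()
    df["lat_inf"] = inflated_latencies(trials, alg)
    df["pair"] = df["block_role"].map(_PAIR_OF_ROLE)

    block_mean = (
        df.groupby(["participant", "block_role"], sort=False)["lat_inf"]
        .agg(_strict_mean)
        .unstack("block_role")
        .reindex(index=participants, columns=list(BLOCK_ROLES))
    )
    pair_sd = (
        df.groupby(["participant", "pair"], sort=False)["lat_inf"]
        .agg(_strict_pooled_sd)
        .unstack("pair")
        .reindex(index=participants, columns=["practice", "test"])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d_practice = (block_mean["practice_B"] - block_mean["practice_A"]) / pair_sd["practice"]
        d_test = (block_mean["test_B"] - block_mean["test_A"]) / pair_sd["test"]
    if direction == "A-B":
        d_practice = -d_practice
        d_test = -d_test
    dscore = (d_practice + d_test) / 2.0

    p_block = (
        df.groupby(["participant", "block_role"], sort=False)["correct"]
        .mean()
        .unstack("block_role")
        .reindex(index=participants, columns=list(BLOCK_ROLES))
    )
    p_pair = (
        df.groupby(["participant", "pair"], sort=False)["correct"]
        .mean()
        .unstack("pair")
        .reindex(index=participants, columns=["practice", "test"])
    )
    p_cond = (
        df.groupby(["participant", "condition"], sort=False)["correct"]
        .mean()
        .unstack("condition")
        .reindex(index=participants, columns=["MappingA", "MappingB"])
    )
    p_tot = df.groupby("participant", sort=False)["correct"].mean().reindex(participants)
    mean_tot = (
        df.groupby("participant", sort=False)["lat_inf"].agg(_strict_mean).reindex(participants)
    )

    out = pd.DataFrame(index=pd.Index(participants, name="participant"))
    out["mean.tot"] = mean_tot
    out["p_correct_block.practice.MappingA"] = p_block["practice_A"]
    out["p_correct_block.practice.MappingB"] = p_block["practice_B"]
    out["p_correct_block.test.MappingA"] = p_block["test_A"]
    out["p_correct_block.test.MappingB"] = p_block["test_B"]
    out["p_correct_bpool.practice"] = p_pair["practice"]
    out["p_correct_bpool.test"] = p_pair["test"]
    out["prop_correct_cond_MappingA"] = p_cond["MappingA"]
    out["prop_correct_cond_MappingB"] = p_cond["MappingB"]
    out["p_correct_tot"] = p_tot
    out["d_practice"] = d_practice
    out["d_test"] = d_test
    out["dscore"] = dscore
    out["reason"] = _undefined_reasons(df, alg, participants)
    return out


def score_participant(
    trials: TrialTable,
    algorithm: Union[str, int, AlgorithmSpec],
    direction: str = "B-A",
) -> pd.Series:
    """Score a single participant's already-cleaned trials.

    Expects the cleaning filters (slow-trial removal and, where applicable,
    the lower-tail deletion) to have been applied; performs error inflation
    and the standardized-difference computation only.  Returns a Series with
    the score components, proportion-correct diagnostics, mean latency and
    effect-size label.
    """
    alg = get_algorithm(algorithm)
    _check_direction(direction)
    participants = trials.participants
    if len(participants) != 1:
        raise ValidationError(
            f"score_participant expects exactly one participant, got {len(participants)}"
        )
    row = _component_frame(trials, alg, direction).iloc[0].copy()
    effect = classify_effect_size(row["dscore"])
    row["effect_size"] = effect.label
    row["effect_sign"] = effect.sign
    row["algorithm"] = alg.id
    row["direction"] = direction
    return row


def score_dataset(
    trials: TrialTable,
    algorithm: Union[str, int, AlgorithmSpec],
    direction: str = "B-A",
    cleaning: CleaningConfig | None = None,
    return_report: bool = False,
):
    """Clean and score every participant; one output row per participant.

    Participants flagged for exclusion are scored and kept in the output
    (flagged in ``excluded_accuracy`` / ``excluded_speed``); participants
    whose score is undefined keep their row with missing values and a
    ``reason`` code.  The result is deterministic and invariant to row order
    within blocks.

    With ``return_report=True`` also returns the :class:`CleaningReport`.
    """
    alg = get_algorithm(algorithm)
    _check_direction(direction)
    if trials.data.empty:
        raise ValidationError("trial table is empty")
    participants = trials.participants

    cond_first = (
        trials.data.groupby("participant", sort=False)["condition"]
        .first()
        .reindex(participants)
    )
    cleaned, report = apply_cleaning(trials, alg, cleaning)
    comp = _component_frame(cleaned, alg, direction).reindex(participants)

    legend_a, legend_b = trials.roles.legend()
    out = pd.DataFrame({"participant": participants})
    out["n_trial"] = report.n_trial.to_numpy()
    out["slow10000"] = report.slow10000.to_numpy()
    out["num.300"] = report.num_300.to_numpy()
    out["num.400"] = report.num_400.to_numpy()
    for col in comp.columns:
        if col != "reason":
            out[col] = comp[col].to_numpy()
    out["cond_ord"] = cond_first.map(
        {"MappingA": "MappingA_first", "MappingB": "MappingB_first"}
    ).to_numpy()
    out["LegendMappingA"] = legend_a
    out["LegendMappingB"] = legend_b
    out["excluded_accuracy"] = report.excluded_accuracy.reindex(participants).to_numpy()
    out["excluded_speed"] = report.excluded_speed.reindex(participants).to_numpy()
    out["excluded"] = (out["excluded_accuracy"] | out["excluded_speed"]).to_numpy()
    out["reason"] = comp["reason"].to_numpy()
    effects = out["dscore"].map(classify_effect_size)
    out["effect_size"] = [e.label for e in effects]
    out["effect_sign"] = [e.sign for e in effects]
    out.attrs["algorithm"] = alg.id
    out.attrs["direction"] = direction
    if return_report:
        return out, report
    return out
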