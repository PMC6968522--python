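"""Synthetic IAT datasets with known ground truth.

Latencies follow an ex-Gaussian model — a Gaussian component (mu, sigma)
plus an exponential tail (tau) — the standard description of response-time
distributions.  The IAT effect is injected as a constant shift
``effect_delta`` added to every Mapping B trial: a positive delta makes
Mapping B slower, so the default-direction score — whose numerator is
M_B - M_A computed on latencies — has a positive expectation, and the mean
recovered D-score grows monotonically with the true shift.

Per-trial accuracy is Bernoulli with a condition-specific error rate.  With
``builtin_correction`` on, error-trial latencies are additionally increased
by ``correction_penalty_ms``, emulating administrations where an error must
be corrected before the task proceeds and the recorded latency includes
that correction time.  Optional contamination injects anticipatory
(< 300 ms) and lapse (> 10,000 ms) trials at given rates so the cleaning
filters have something to find.

Defaults describe a conventional desk-scale IAT study: 20 trials per
practice block and 40 per test block, mu = 600 ms, sigma = 100 ms,
tau = 150 ms, a 100 ms condition shift (a moderate implicit effect), 5%
errors per condition, no contamination.  The per-participant condition
order (Mapping A first or Mapping B first) is counterbalanced at random.
Identical config + seed reproduce the dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cleaning import CleaningConfig
from .errors import ValidationError
from .io import DEFAULT_LABELS, REQUIRED_COLUMNS, BlockRoleMap, validate_trials
from .scoring import ALGORITHMS, score_dataset


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic IAT generator (times in milliseconds)."""

    n_participants: int = 50
    trials_practice: int = 20
    trials_test: int = 40
    mu: float = 600.0
    sigma: float = 100.0
    tau: float = 150.0
    effect_delta: float = 100.0
    error_rate_A: float = 0.05
    error_rate_B: float = 0.05
    builtin_correction: bool = False
    correction_penalty_ms: float = 400.0
    fast_trial_rate: float = 0.0
    slow_trial_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_practice < 1 or self.trials_test < 1:
            raise ValidationError("participant and trial counts must be >= 1")
        if self.sigma <= 0 or self.tau <= 0:
            raise ValidationError("sigma and tau must be > 0")
        for name in ("error_rate_A", "error_rate_B", "fast_trial_rate", "slow_trial_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.fast_trial_rate + self.slow_trial_rate > 1.0:
            raise ValidationError("fast_trial_rate + slow_trial_rate must be <= 1")

    def ground_truth(self) -> dict:
        """Generator parameters as a plain dict (the sidecar metadata)."""
        return dataclasses.asdict(self)


_ROLE_OF_LABEL = dict(zip(DEFAULT_LABELS, ("practice_A", "test_A", "practice_B", "test_B")))
_A_FIRST = ("practiceMappingA", "testMappingA", "practiceMappingB", "testMappingB")
_B_FIRST = ("practiceMappingB", "testMappingB", "practiceMappingA", "testMappingA")


def generate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one synthetic dataset in the four-column input schema.

    Returns ``(trials, ground_truth)``: a DataFrame with columns
    ``participant, block, latency, correct`` (latencies rounded to whole
    milliseconds) and the dict of true generator parameters.
    """
    rng = np.random.default_rng(config.seed)
    n_per_block = {
        "practiceMappingA": config.trials_practice,
        "practiceMappingB": config.trials_practice,
        "testMappingA": config.trials_test,
        "testMappingB": config.trials_test,
    }
    rows: list[tuple] = []
    width = len(str(config.n_participants))
    for i in range(config.n_participants):
        pid = f"P{i + 1:0{width}d}"
        order = _A_FIRST if rng.random() < 0.5 else _B_FIRST
        for label in order:
            n = n_per_block[label]
            is_a = label.endswith("MappingA")
            lat = (
                config.mu
                + config.sigma * rng.standard_normal(n)
                + rng.exponential(config.tau, size=n)
            )
            if not is_a:
                lat = lat + config.effect_delta
            err_rate = config.error_rate_A if is_a else config.error_rate_B
            correct = (rng.random(n) >= err_rate).astype(int)
            if config.builtin_correction:
                lat = lat + (correct == 0) * config.correction_penalty_ms
            # contamination replaces the latency outright
            u = rng.random(n)
            fast = u < config.fast_trial_rate
            slow = (~fast) & (u < config.fast_trial_rate + config.slow_trial_rate)
            lat[fast] = rng.uniform(50.0, 299.0, size=int(fast.sum()))
            lat[slow] = rng.uniform(10_001.0, 15_000.0, size=int(slow.sum()))
            lat = np.maximum(np.round(lat), 0.0)
            for j in range(n):
                rows.append((pid, label, float(lat[j]), int(correct[j])))
    trials = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return trials, config.ground_truth()


def write_dataset(
    trials: pd.DataFrame,
    path: Union[str, Path],
    ground_truth: Optional[dict] = None,
) -> None:
    """Write the trials CSV; ground truth goes to a ``.truth.json`` sidecar."""
    path = Path(path)
    trials.to_csv(path, index=False)
    if ground_truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(ground_truth, indent=2) + "\n")


def simulated_trial_table(config: SimulationConfig):
    """Generate and validate in one step; returns a ready-to-score TrialTable."""
    trials, _ = generate_dataset(config)
    return validate_trials(
        trials, BlockRoleMap.default(), builtin_corrected=config.builtin_correction
    )


def recovery_suite(
    deltas: Sequence[float],
    config: SimulationConfig,
    algorithms: Sequence[str] = tuple(ALGORITHMS),
    cleaning: Optional[CleaningConfig] = None,
    check_monotone: bool = True,
) -> pd.DataFrame:
    """Mean recovered D-score per algorithm across a grid of true shifts.

    For each delta a fresh dataset is generated (seed offset by the delta's
    position so draws are independent), scored with every requested
    algorithm, and the mean D-score over participants recorded.  With
    ``check_monotone`` a non-monotone column raises — larger true shifts
    must yield larger mean scores.
    """
    if len(deltas) < 2:
        raise ValidationError("recovery_suite needs at least two deltas")
    rows = []
    for k, delta in enumerate(deltas):
        cfg = dataclasses.replace(config, effect_delta=float(delta), seed=config.seed + k)
        table = simulated_trial_table(cfg)
        row = {"delta": float(delta)}
        for alg in algorithms:
            results = score_dataset(table, alg, cleaning=cleaning)
            row[alg] = float(results["dscore"].mean())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("delta")
    if check_monotone:
        for alg in algorithms:
            v = out[alg].to_numpy()
            if not np.all(np.diff(v) >= 0):
                raise ValidationError(
                    f"mean D-score for {alg} is not monotone in the true shift: "
                    f"{v.tolist()}"
                )
    return out


def load_example_dataset() -> tuple[pd.DataFrame, dict]:
    """Load the small synthetic example dataset packaged with iatdscore.

    The file was produced by :func:`generate_dataset` with a fixed seed and
    plays the role of a demo dataset; it contains no real participant data.
    Returns the trials DataFrame and the generator ground truth.
    """
    from importlib import resources

    base = resources.files("iatdscore").joinpath("data")
    with resources.as_file(base.joinpath("synthetic_example_iat.csv")) as p:
        trials = pd.read_csv(p, dtype={"participant": str, "block": str})
    truth = json.loads(base.joinpath("synthetic_example_iat.truth.json").read_text())
    return trials, truth
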