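"""Reading, validating and writing trial-level IAT CSV files.

The exchange format is a plain comma-separated file with one row per trial
and four required columns:

``participant``
    opaque participant identifier (read as a string),
``block``
    free-text label of one of the four critical IAT blocks (the pure
    practice blocks must already have been removed),
``latency``
    response time in milliseconds,
``correct``
    response accuracy, ``0`` = incorrect, ``1`` = correct.

Column order is irrelevant and extra columns are ignored.  The four block
labels are mapped onto the roles ``practice_A``, ``test_A``, ``practice_B``
and ``test_B`` via a :class:`BlockRoleMap`; the Mapping A / Mapping B
condition of every trial follows from that role.

The results file written by :func:`write_results_csv` reproduces the app's
downloadable-file schema verbatim, including the algorithm-numbered score
columns (``dscore.3`` for algorithm D3 and so on).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

REQUIRED_COLUMNS = ("participant", "block", "latency", "correct")

#: The four block roles, in canonical order.
BLOCK_ROLES = ("practice_A", "test_A", "practice_B", "test_B")

CONDITION_OF_ROLE = {
    "practice_A": "MappingA",
    "test_A": "MappingA",
    "practice_B": "MappingB",
    "test_B": "MappingB",
}

#: Downloadable-file column names in order; ``{n}`` is the algorithm number.
RESULTS_COLUMNS_TEMPLATE = (
    "participant",
    "n_trial",
    "slow10000",
    "num.300",
    "num.400",
    "mean.tot",
    "p_correct_block.practice.MappingA",
    "p_correct_block.practice.MappingB",
    "p_correct_block.test.MappingA",
    "p_correct_block.test.MappingB",
    "p_correct_bpool.practice",
    "p_correct_bpool.test",
    "prop_correct_cond_MappingA",
    "prop_correct_cond_MappingB",
    "p_correct_tot",
    "d_practice.{n}",
    "d_test.{n}",
    "dscore.{n}",
    "cond_ord",
    "LegendMappingA",
    "LegendMappingB",
)

#: Default raw block labels, used by the template and the synthetic generator.
DEFAULT_LABELS = (
    "practiceMappingA",
    "testMappingA",
    "practiceMappingB",
    "testMappingB",
)


def results_columns(algorithm_number: int) -> list[str]:
    """Return the exact results-file header for one algorithm number."""
    return [c.format(n=algorithm_number) for c in RESULTS_COLUMNS_TEMPLATE]


def _algorithm_number(algorithm) -> int:
    """Accept an AlgorithmSpec, an int 1-6, or a string like ``"D3"``."""
    if hasattr(algorithm, "number"):
        n = int(algorithm.number)
    elif isinstance(algorithm, int):
        n = algorithm
    else:
        s = str(algorithm).strip().upper()
        if s.startswith("D"):
            s = s[1:]
        try:
            n = int(s)
        except ValueError:
            raise ValidationError(f"unrecognized algorithm: {algorithm!r}") from None
    if not 1 <= n <= 6:
        raise ValidationError(f"algorithm number out of range 1-6: {n}")
    return n


def default_results_filename(algorithm) -> str:
    """Default name of the downloadable results file, e.g. ``ShinyAPPDscore3.csv``."""
    return f"ShinyAPPDscore{_algorithm_number(algorithm)}.csv"


@dataclass(frozen=True)
class BlockRoleMap:
    """Assignment of the four raw block labels to block roles.

    ``practice_A``/``test_A`` together form the Mapping A condition,
    ``practice_B``/``test_B`` the Mapping B condition.  Labels must be
    pairwise distinct and must jointly cover exactly the labels present in
    the data (checked in :func:`validate_trials`).
    """

    practice_A: str
    test_A: str
    practice_B: str
    test_B: str

    def __post_init__(self) -> None:
        if len(set(self.labels)) != 4:
            raise ValidationError(
                f"the four block labels must be pairwise distinct, got {self.labels}"
            )

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.practice_A, self.test_A, self.practice_B, self.test_B)

    def role_of(self) -> dict[str, str]:
        """Mapping raw label -> block role."""
        return dict(zip(self.labels, BLOCK_ROLES))

    def swapped(self) -> "BlockRoleMap":
        """Exchange the Mapping A and Mapping B label assignments.

        Reverses the direction (and hence the interpretation) of the D-score.
        """
        return BlockRoleMap(
            practice_A=self.practice_B,
            test_A=self.test_B,
            practice_B=self.practice_A,
            test_B=self.test_A,
        )

    def legend(self) -> tuple[str, str]:
        """``(LegendMappingA, LegendMappingB)`` strings for the results file."""
        return (
            f"{self.practice_A}_and_{self.test_A}",
            f"{self.practice_B}_and_{self.test_B}",
        )

    @classmethod
    def default(cls) -> "BlockRoleMap":
        return cls(*DEFAULT_LABELS)


@dataclass(frozen=True, eq=False)
class TrialTable:
    """Validated trial-level records: the single currency of the pipeline.

    ``data`` holds one row per trial with columns ``participant``, ``block``,
    ``latency``, ``correct``, plus the derived ``block_role`` and
    ``condition``.  ``builtin_corrected`` flags whether latencies of error
    trials already include the time needed to correct the response (the
    built-in correction administration mode).
    """

    data: pd.DataFrame
    roles: BlockRoleMap
    builtin_corrected: bool = False

    @property
    def participants(self) -> np.ndarray:
        """Participant IDs in order of first appearance."""
        return self.data["participant"].unique()

    def with_data(self, data: pd.DataFrame) -> "TrialTable":
        """Same metadata, new trial rows."""
        return dataclasses.replace(self, data=data.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


def read_trials_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a comma-separated trial file into a raw-trial DataFrame.

    Column order in the file is irrelevant; extra columns are dropped.

    Raises
    ------
    SchemaError
        If any of the four required columns is absent (this is also the
        symptom of a wrong separator: the whole header reads as one column).
    ParseError
        If ``latency`` or ``correct`` contain non-numeric or missing values;
        the message points at the offending file line(s).
    """
    df = pd.read_csv(path, sep=",", dtype={"participant": str, "block": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing} in {path}; the file must be "
            "comma-separated with a header containing "
            "participant, block, latency, correct (in any order)"
        )
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["participant"] = df["participant"].astype(str)
    df["block"] = df["block"].astype(str)
    for col in ("latency", "correct"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            # header is file line 1, first data row line 2
            lines = (df.index[bad] + 2).tolist()
            shown = ", ".join(map(str, lines[:10]))
            more = "" if len(lines) <= 10 else f" (and {len(lines) - 10} more)"
            raise ParseError(
                f"column '{col}' has non-numeric or missing values at file "
                f"line(s) {shown}{more}"
            )
        df[col] = parsed
    return df


def validate_trials(
    raw: pd.DataFrame,
    roles: BlockRoleMap,
    builtin_corrected: bool = False,
) -> TrialTable:
    """Validate raw trials and annotate them with block roles and conditions.

    Checks, in order: required columns present; latencies finite and
    non-negative; accuracy codes restricted to {0, 1}; exactly four distinct
    block labels, covered one-to-one by ``roles``; every participant has
    trials in all four block roles.

    Raises :class:`SchemaError` or :class:`ValidationError` accordingly.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = raw.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["participant"] = df["participant"].astype(str)
    df["block"] = df["block"].astype(str)
    df["latency"] = pd.to_numeric(df["latency"])
    df["correct"] = pd.to_numeric(df["correct"])

    lat = df["latency"].to_numpy(float)
    if not np.isfinite(lat).all() or (lat < 0).any():
        raise ValidationError("latency must be finite and >= 0 (milliseconds)")

    values = set(df["correct"].unique().tolist())
    offending = sorted(v for v in values if v not in (0, 1))
    if offending:
        raise ValidationError(
            f"'correct' must contain only 0 (incorrect) and 1 (correct); "
            f"found {offending}"
        )
    df["correct"] = df["correct"].astype(int)

    labels = df["block"].unique().tolist()
    if len(labels) > 4:
        raise ValidationError(
            f"found {len(labels)} distinct block labels {sorted(labels)}; only "
            "the four critical blocks are allowed — pure practice blocks must "
            "be removed before scoring"
        )
    if len(labels) < 4:
        raise ValidationError(
            f"found only {len(labels)} distinct block labels {sorted(labels)}; "
            "the four critical blocks (practice/test x Mapping A/B) are required"
        )
    if set(roles.labels) != set(labels):
        raise ValidationError(
            f"block-role labels {sorted(roles.labels)} do not match the labels "
            f"present in the data {sorted(labels)}"
        )

    role_of = roles.role_of()
    df["block_role"] = df["block"].map(role_of)
    df["condition"] = df["block_role"].map(CONDITION_OF_ROLE)

    n_roles = df.groupby("participant", sort=False)["block_role"].nunique()
    incomplete = n_roles.index[n_roles < 4].tolist()
    if incomplete:
        raise ValidationError(
            "the D-score requires trials in all four blocks; participant(s) "
            f"missing one or more blocks: {incomplete}"
        )

    return TrialTable(
        data=df.reset_index(drop=True),
        roles=roles,
        builtin_corrected=bool(builtin_corrected),
    )


def read_and_validate(
    path: Union[str, Path],
    roles: BlockRoleMap | None = None,
    builtin_corrected: bool = False,
) -> TrialTable:
    """Convenience wrapper: :func:`read_trials_csv` then :func:`validate_trials`.

    With ``roles=None`` the default labels are assumed; if the file uses
    other labels, pass an explicit :class:`BlockRoleMap`.
    """
    raw = read_trials_csv(path)
    if roles is None:
        roles = BlockRoleMap.default()
    return validate_trials(raw, roles, builtin_corrected=builtin_corrected)


def write_template(path: Union[str, Path]) -> None:
    """Write a small illustrative CSV in the required input format."""
    rows = []
    latencies = {
        "practiceMappingA": (612, 844, 705),
        "testMappingA": (590, 688, 934),
        "practiceMappingB": (801, 1123, 766),
        "testMappingB": (955, 872, 1041),
    }
    for pid in ("subj01", "subj02"):
        for label, lats in latencies.items():
            for i, lat in enumerate(lats):
                # one plausible error trial per participant
                correct = 0 if (pid == "subj02" and label == "testMappingB" and i == 0) else 1
                rows.append((pid, label, lat, correct))
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


_INTERNAL_SCORE_COLUMNS = {"d_practice": "d_practice.{n}",
                           "d_test": "d_test.{n}",
                           "dscore": "dscore.{n}"}


def write_results_csv(results: pd.DataFrame, algorithm, path: Union[str, Path]) -> None:
    """Write a scored-results table in the downloadable-file schema.

    ``results`` is the frame produced by :func:`iatdscore.scoring.score_dataset`
    (score columns named ``d_practice``/``d_test``/``dscore``); they are
    renamed here with the algorithm number.  Participants flagged for
    exclusion are written like everyone else — exclusion only gates what the
    summary displays, never the file contents.
    """
    if results is None or len(results) == 0:
        raise ValidationError("results table is empty; nothing to write")
    n = _algorithm_number(algorithm)
    renames = {k: v.format(n=n) for k, v in _INTERNAL_SCORE_COLUMNS.items()}
    out = results.rename(columns=renames)
    cols = results_columns(n)
    missing = [c for c in cols if c not in out.columns]
    if missing:
        raise ValidationError(f"results table lacks required column(s): {missing}")
    out.loc[:, cols].to_csv(path, index=False)
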