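"""Shared builders for the test suite."""

import numpy as np
import pandas as pd

from iatdscore.io import BLOCK_ROLES, BlockRoleMap, validate_trials

DEFAULT_ROLES = BlockRoleMap.default()
LABEL_OF_ROLE = dict(zip(BLOCK_ROLES, DEFAULT_ROLES.labels))


def table_from_blocks(blocks_by_participant, builtin_corrected=False, roles=None):
    """Build a validated TrialTable from {pid: {role: [(latency, correct), ...]}}."""
    roles = roles or DEFAULT_ROLES
    label_of = dict(zip(BLOCK_ROLES, roles.labels))
    rows = []
    for pid, blocks in blocks_by_participant.items():
        for role in BLOCK_ROLES:
            for lat, cor in blocks[role]:
                rows.append((str(pid), label_of[role], float(lat), int(cor)))
    raw = pd.DataFrame(rows, columns=["participant", "block", "latency", "correct"])
    return validate_trials(raw, roles, builtin_corrected=builtin_corrected)


def random_blocks(rng, n_range=(2, 8), lat_range=(250, 1500), error_p=0.25):
    """One participant's random micro-blocks: mixed errors, latencies that
    straddle the 400 ms lower-tail threshold."""
    out = {}
    for role in BLOCK_ROLES:
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        lats = rng.integers(lat_range[0], lat_range[1] + 1, size=n).astype(float)
        cors = (rng.random(n) >= error_p).astype(int)
        out[role] = list(zip(lats.tolist(), cors.tolist()))
    return out


def swap_mapping_labels(table):
    """Re-validate the same rows with the Mapping A/B assignments exchanged.

    Mirrors the app's label switch: the underlying file (and row order) is
    untouched; only the role map flips.
    """
    raw = table.data[["participant", "block", "latency", "correct"]]
    return validate_trials(raw, table.roles.swapped(),
                           builtin_corrected=table.builtin_corrected)


def uniform_blocks(latency=700.0, correct=1, n=4):
    """Identical trials in all four blocks (degenerate, zero variance)."""
    return {role: [(latency, correct)] * n for role in BLOCK_ROLES}
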