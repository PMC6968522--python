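"""Independent brute-force D-score oracle.

A deliberately naive, loop-and-`statistics`-module transcription of the
scoring rules, written before and kept independent of the package's
vectorized implementation.  ``statistics.mean``/``stdev`` use exact
rational arithmetic internally, so agreement with the numpy path to 1e-12
is a genuine cross-check, not a tautology.
"""

import statistics

LOWER_TAIL_ALGS = {"D2", "D5", "D6"}
PENALTY_600 = {"D4", "D6"}
PENALTY_2SD = {"D3", "D5"}

ROLES = ("practice_A", "test_A", "practice_B", "test_B")


def oracle_score(blocks, algorithm, direction="B-A"):
    """Score one participant from raw per-block (latency, correct) pairs.

    ``blocks`` maps each of the four roles to a list of (latency, correct)
    tuples *before* any cleaning.  Applies: the > 10,000 ms removal, the
    algorithm's < 400 ms deletion, error inflation, and the standardized
    differences.  Returns (d_practice, d_test, dscore) with None where a
    component is undefined.
    """
    blocks = {r: [(l, c) for (l, c) in t if l <= 10_000] for r, t in blocks.items()}
    if algorithm in LOWER_TAIL_ALGS:
        blocks = {r: [(l, c) for (l, c) in t if l >= 400] for r, t in blocks.items()}

    treated = {}
    for role, t in blocks.items():
        if not t:
            treated[role] = None
            continue
        if algorithm in ("D1", "D2"):
            treated[role] = [l for (l, _) in t]
            continue
        if all(c == 1 for (_, c) in t):  # nothing to inflate
            treated[role] = [l for (l, _) in t]
            continue
        ok = [l for (l, c) in t if c == 1]
        if algorithm in PENALTY_600:
            if len(ok) < 1:
                treated[role] = None
                continue
            repl = statistics.mean(ok) + 600
        else:
            if len(ok) < 2:
                treated[role] = None
                continue
            repl = statistics.mean(ok) + 2 * statistics.stdev(ok)
        treated[role] = [l if c == 1 else repl for (l, c) in t]

    def component(role_a, role_b):
        a, b = treated[role_a], treated[role_b]
        if a is None or b is None:
            return None
        pooled = a + b
        if len(pooled) < 2:
            return None
        sd = statistics.stdev(pooled)
        if sd == 0:
            return None
        return (statistics.mean(b) - statistics.mean(a)) / sd

    d_practice = component("practice_A", "practice_B")
    d_test = component("test_A", "test_B")
    if d_practice is None or d_test is None:
        dscore = None
    else:
        dscore = (d_practice + d_test) / 2
    if direction == "A-B":
        d_practice = None if d_practice is None else -d_practice
        d_test = None if d_test is None else -d_test
        dscore = None if dscore is None else -dscore
    return d_practice, d_test, dscore
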