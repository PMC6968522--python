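"""The D-score core: inflation, pooled SD, components, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from iatdscore.errors import ValidationError
from iatdscore.scoring import (
    ALGORITHMS,
    classify_effect_size,
    d_component,
    get_algorithm,
    inflate_errors,
    pooled_sd,
    score_dataset,
    score_participant,
)

from helpers import random_blocks, swap_mapping_labels, table_from_blocks, uniform_blocks
from oracle import oracle_score

# hand-verified fixture values
SD_500_700 = math.sqrt((100.0 ** 2 + 100.0 ** 2) / 1)  # sample SD of {500, 700}
POOLED_SD_FIXTURE = math.sqrt(80_000.0 / 3.0)  # {500,700} U {700,900}


class TestInflateErrors:
    def test_mean_plus_600_hand_value(self):
        out = inflate_errors([500, 700, 999], [1, 1, 0], "mean_plus_600")
        assert out[2] == pytest.approx(1200.0, abs=1e-12)
        assert out[:2].tolist() == [500.0, 700.0]

    def test_mean_plus_2sd_hand_value(self):
        out = inflate_errors([500, 700, 999], [1, 1, 0], "mean_plus_2sd")
        assert out[2] == pytest.approx(600.0 + 2 * SD_500_700, rel=1e-12)
        assert out[2] == pytest.approx(882.8427124746, abs=1e-6)

    def test_builtin_is_identity(self):
        lats = [512.0, 733.0, 945.0]
        out = inflate_errors(lats, [1, 0, 0], "builtin")
        assert out.tolist() == lats

    def test_no_correct_trials_yields_nan(self):
        out = inflate_errors([500, 700], [0, 0], "mean_plus_600")
        assert np.isnan(out).all()

    def test_single_correct_trial_undefined_for_2sd(self):
        out = inflate_errors([500, 700], [1, 0], "mean_plus_2sd")
        assert not np.isnan(out[0]) and np.isnan(out[1])


class TestPooledSd:
    def test_hand_value(self):
        assert pooled_sd([500, 700], [700, 900]) == pytest.approx(
            POOLED_SD_FIXTURE, rel=1e-12
        )
        assert pooled_sd([500, 700], [700, 900]) == pytest.approx(163.299316, abs=1e-5)

    def test_symmetric(self):
        assert pooled_sd([500, 700], [700, 900]) == pooled_sd([700, 900], [500, 700])

    def test_zero_variance_undefined(self):
        assert math.isnan(pooled_sd([700, 700], [700, 700]))


class TestDComponent:
    def test_hand_value(self):
        d = d_component([500, 700], [700, 900])
        assert d == pytest.approx(200.0 / POOLED_SD_FIXTURE, rel=1e-12)
        assert d == pytest.approx(1.224744871, abs=1e-8)

    def test_direction_reversal_negates(self):
        d = d_component([500, 700], [700, 900])
        assert d_component([500, 700], [700, 900], direction="A-B") == -d

    def test_identical_blocks_score_zero(self):
        assert d_component([500, 700, 900], [500, 700, 900]) == 0.0


class TestClassifyEffectSize:
    @pytest.mark.parametrize(
        "d,label,sign",
        [
            (0.0, "negligible", 0),
            (0.14, "negligible", 1),
            (0.15, "slight", 1),
            (-0.34, "slight", -1),
            (-0.40, "moderate", -1),
            (0.64, "moderate", 1),
            (0.65, "strong", 1),
            (0.70, "strong", 1),
            (float("nan"), "undefined", 0),
        ],
    )
    def test_band_edges(self, d, label, sign):
        assert classify_effect_size(d) == (label, sign)


class TestScoreParticipant:
    def test_dscore_is_mean_of_components(self, random_table):
        results = score_dataset(random_table, "D4")
        defined = results.dropna(subset=["d_practice", "d_test"])
        np.testing.assert_allclose(
            defined["dscore"], (defined["d_practice"] + defined["d_test"]) / 2,
            rtol=0, atol=1e-15,
        )

    def test_symmetric_blocks_score_zero(self):
        blocks = {r: [(500.0, 1), (700.0, 1), (900.0, 1)]
                  for r in ("practice_A", "test_A", "practice_B", "test_B")}
        table = table_from_blocks({"p": blocks})
        row = score_participant(table, "D3")
        assert row["dscore"] == 0.0

    def test_micro_fixture_matches_oracle_all_algorithms(self):
        blocks = {
            "practice_A": [(520.0, 1), (680.0, 0)],
            "test_A": [(430.0, 1), (810.0, 1)],
            "practice_B": [(750.0, 1), (940.0, 1)],
            "test_B": [(390.0, 0), (1020.0, 1)],
        }
        table = table_from_blocks({"p": blocks})
        for alg in ALGORITHMS:
            results = score_dataset(table, alg)
            dp, dt, d = oracle_score(blocks, alg)
            for got, want in [
                (results["d_practice"].iloc[0], dp),
                (results["d_test"].iloc[0], dt),
                (results["dscore"].iloc[0], d),
            ]:
                if want is None:
                    assert np.isnan(got), alg
                else:
                    assert got == pytest.approx(want, abs=1e-12), alg

    def test_zero_variance_participant_undefined_with_reason(self):
        table = table_from_blocks({"p": uniform_blocks()})
        results = score_dataset(table, "D1")
        assert np.isnan(results["dscore"].iloc[0])
        assert "zero_variance" in results["reason"].iloc[0]

    def test_all_error_block_undefined_for_ex_post(self):
        blocks = uniform_blocks()
        blocks["practice_A"] = [(600.0, 0), (650.0, 0)]
        blocks["practice_B"] = [(700.0, 1), (820.0, 1)]
        table = table_from_blocks({"p": blocks})
        results = score_dataset(table, "D4")
        assert np.isnan(results["d_practice"].iloc[0])
        assert "no_correct_trials:practice_A" in results["reason"].iloc[0]

    def test_multiple_participants_rejected(self, small_table):
        with pytest.raises(ValidationError):
            score_participant(small_table, "D3")


class TestScoreDataset:
    def test_row_count_preserved_under_exclusion(self, random_table):
        from iatdscore.cleaning import CleaningConfig

        results = score_dataset(
            random_table, "D3",
            cleaning=CleaningConfig(accuracy_cleaning=True, speed_cleaning=True),
        )
        assert len(results) == len(random_table.participants)

    def test_row_order_within_blocks_irrelevant(self, small_table):
        shuffled = small_table.with_data(
            small_table.data.sample(frac=1, random_state=7)
        )
        a = score_dataset(small_table, "D6").set_index("participant")
        b = score_dataset(shuffled, "D6").set_index("participant")
        for col in ("d_practice", "d_test", "dscore", "mean.tot"):
            np.testing.assert_allclose(a[col], b.loc[a.index, col], rtol=1e-12)

    def test_deterministic(self, random_table):
        a = score_dataset(random_table, "D5")
        b = score_dataset(random_table, "D5")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_table_rejected(self, small_table):
        with pytest.raises(ValidationError):
            score_dataset(small_table.with_data(small_table.data.iloc[0:0]), "D1")

    def test_component_bound_for_equal_block_sizes(self, rng):
        # pooled SD dominates half the mean gap: |d| <= 2 sqrt(n/(n-1))
        for _ in range(20):
            n = int(rng.integers(2, 9))
            a = rng.uniform(400, 2000, n)
            b = rng.uniform(400, 2000, n)
            d = d_component(a, b)
            assert abs(d) <= 2 * math.sqrt((2 * n) / (2 * n - 1)) + 1e-12


# -- property tests ---------------------------------------------------------

def _blocks_strategy():
    trial = st.tuples(
        st.floats(min_value=420, max_value=9000, allow_nan=False),
        st.integers(min_value=0, max_value=1),
    )
    block = st.lists(trial, min_size=2, max_size=6)
    return st.fixed_dictionaries(
        {r: block for r in ("practice_A", "test_A", "practice_B", "test_B")}
    )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(blocks=_blocks_strategy(), alg=st.sampled_from(sorted(ALGORITHMS)))
def test_label_swap_negates_scores_exactly(blocks, alg):
    """Swapping the Mapping A/B role assignment flips every score's sign bit."""
    table = table_from_blocks({"p": blocks})
    swapped = swap_mapping_labels(table)
    a = score_dataset(table, alg)
    b = score_dataset(swapped, alg)
    for col in ("d_practice", "d_test", "dscore"):
        x, y = a[col].iloc[0], b[col].iloc[0]
        assert (np.isnan(x) and np.isnan(y)) or x == -y


@settings(max_examples=30, derandomize=True, deadline=None)
@given(blocks=_blocks_strategy(), alg=st.sampled_from(sorted(ALGORITHMS)))
def test_direction_flag_negates_scores_exactly(blocks, alg):
    table = table_from_blocks({"p": blocks})
    a = score_dataset(table, alg, direction="B-A")
    b = score_dataset(table, alg, direction="A-B")
    for col in ("d_practice", "d_test", "dscore"):
        x, y = a[col].iloc[0], b[col].iloc[0]
        assert (np.isnan(x) and np.isnan(y)) or x == -y


@settings(max_examples=25, derandomize=True, deadline=None)
@given(blocks=_blocks_strategy(), shift=st.floats(min_value=0, max_value=500))
def test_shift_invariance(blocks, shift):
    """Adding a constant (no threshold crossings) leaves all six scores put."""
    table = table_from_blocks({"p": blocks})
    shifted = table_from_blocks({
        "p": {r: [(l + shift, c) for l, c in t] for r, t in blocks.items()}
    })
    for alg in ALGORITHMS:
        a = score_dataset(table, alg)["dscore"].iloc[0]
        b = score_dataset(shifted, alg)["dscore"].iloc[0]
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_scale_invariance_holds_only_without_fixed_penalty(rng):
    """x2 scaling (no threshold crossings) preserves D1/D3/D5 and breaks D4/D6."""
    blocks = {}
    for role in ("practice_A", "test_A", "practice_B", "test_B"):
        lats = rng.uniform(450, 2000, 6)
        cors = [1, 1, 1, 1, 0, 1]
        blocks[role] = list(zip(lats.tolist(), cors))
    table = table_from_blocks({"p": blocks})
    scaled = table_from_blocks({
        "p": {r: [(l * 2.0, c) for l, c in t] for r, t in blocks.items()}
    })
    for alg in ("D1", "D3", "D5"):
        a = score_dataset(table, alg)["dscore"].iloc[0]
        b = score_dataset(scaled, alg)["dscore"].iloc[0]
        assert a == pytest.approx(b, rel=1e-9)
    for alg in ("D4", "D6"):
        a = score_dataset(table, alg)["dscore"].iloc[0]
        b = score_dataset(scaled, alg)["dscore"].iloc[0]
        assert a != pytest.approx(b, rel=1e-6)
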