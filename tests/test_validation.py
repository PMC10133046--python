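import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from noticelink.pipeline import RegistryIndex, ResolverConfig
from noticelink.records_io import LinkResult
from noticelink.synthetic import GeneratorConfig, generate_dataset
from noticelink.validation import evaluate, evaluate_with_reference, midp_mcnemar

# ---------------------------------------------------------------------------
# Exhaustive mid-p oracle: enumerate all 2^n discordance outcomes.
# ---------------------------------------------------------------------------

def oracle_midp(b: int, c: int) -> float:
    n = b + c
    if n == 0:
        return 1.0
    m = max(b, c)
    at_least = at_exact = 0
    for outcome in itertools.product((0, 1), repeat=n):
        k = sum(outcome)  # wins of the designated method among discordant pairs
        if k >= m:
            at_least += 1
        if k == m:
            at_exact += 1
    p_ge = at_least / 2 ** n
    p_eq = at_exact / 2 ** n
    return min(1.0, 2 * p_ge - p_eq)


def flags_for(b: int, c: int, concordant: int = 3):
    a = [True] * b + [False] * c + [True] * concordant
    other = [False] * b + [True] * c + [True] * concordant
    return a, other


class TestMidpMcnemar:
    def test_five_zero(self):
        result = midp_mcnemar(*flags_for(5, 0))
        assert result.b == 5 and result.c == 0
        assert result.midp == pytest.approx(0.03125, abs=1e-12)

    @pytest.mark.parametrize("split", [1, 2, 5])
    def test_equal_split_is_one(self, split):
        assert midp_mcnemar(*flags_for(split, split)).midp == pytest.approx(1.0)

    def test_no_discordance(self):
        result = midp_mcnemar([True, False], [True, False])
        assert result.midp == 1.0 and result.b == 0 and result.c == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            midp_mcnemar([True], [True, False])

    def test_exhaustive_oracle_up_to_12(self):
        for n in range(0, 13):
            for b in range(n + 1):
                c = n - b
                got = midp_mcnemar(*flags_for(b, c)).midp
                assert got == pytest.approx(oracle_midp(b, c), abs=1e-10), (b, c)

    @given(st.integers(0, 15), st.integers(0, 15))
    def test_symmetric_under_method_swap(self, b, c):
        fa, fb = flags_for(b, c)
        assert midp_mcnemar(fa, fb).midp == pytest.approx(
            midp_mcnemar(fb, fa).midp
        )

    @given(st.integers(0, 20), st.integers(0, 20))
    def test_strictly_below_classical_exact(self, b, c):
        n = b + c
        if n == 0:
            return
        m = max(b, c)
        classical = 2 * sum(
            math.comb(n, k) for k in range(m, n + 1)
        ) / 2 ** n  # uncapped classical exact p
        assert midp_mcnemar(*flags_for(b, c)).midp < classical


# ---------------------------------------------------------------------------
# The four-test evaluation on a hand-computed six-item fixture.
# ---------------------------------------------------------------------------

@pytest.fixture
def six_item_links():
    return [
        LinkResult("N1", "er", device_id="101", score=100, accepted_threshold=95),
        LinkResult("N2", "er", device_id="105", score=100, accepted_threshold=95),
        LinkResult("N3", "er", device_id="102", score=95, accepted_threshold=95),
        LinkResult("N4", "er", device_id="103", score=80, accepted_threshold=80),
        LinkResult("N5", "unmatched", failure_reason="below_floor"),
        LinkResult("N6", "er", device_id="106", score=100, accepted_threshold=95),
    ]


@pytest.fixture
def six_item_reference():
    return [("N1", "101"), ("N2", "101"), ("N3", "101"),
            ("N4", "101"), ("N5", "104"), ("N6", "106")]


class TestEvaluate:
    def test_hand_computed_accuracies(self, six_device_registry, six_item_links,
                                      six_item_reference):
        report = evaluate(six_item_links, six_item_reference,
                          RegistryIndex(six_device_registry))
        assert report.n_reference == 6
        # N1, N2, N3 hit Acme devices; N4 hits Beta; N5 unmatched; N6 correct
        assert report.manufacturer_accuracy == pytest.approx(4 / 6)
        assert report.id_accuracy == pytest.approx(2 / 6)
        # N6's true code is only depth 3, so it cannot be correct at level 4
        assert report.emdn_accuracy_by_level == {
            1: pytest.approx(5 / 6), 2: pytest.approx(4 / 6),
            3: pytest.approx(4 / 6), 4: pytest.approx(2 / 6),
        }
        assert report.n_wrong_id == 4
        assert report.conditional_emdn_accuracy_by_level == {
            1: pytest.approx(3 / 4), 2: pytest.approx(2 / 4),
            3: pytest.approx(2 / 4), 4: pytest.approx(1 / 4),
        }

    def test_duplicate_registration_pattern(self, six_device_registry,
                                            six_item_links, six_item_reference):
        # N2 hit the re-registration of its true device: id wrong, codes right
        report = evaluate(six_item_links, six_item_reference,
                          RegistryIndex(six_device_registry))
        flags = report.per_item_flags["N2"]
        assert not flags["id"]
        assert flags["manufacturer"]
        assert all(flags[f"emdn_level_{k}"] for k in (1, 2, 3, 4))

    def test_all_correct(self, six_device_registry):
        links = [LinkResult("N1", "er", device_id="101", score=100,
                            accepted_threshold=95)]
        report = evaluate(links, [("N1", "101")], RegistryIndex(six_device_registry))
        assert report.manufacturer_accuracy == 1.0
        assert report.id_accuracy == 1.0
        assert all(v == 1.0 for v in report.emdn_accuracy_by_level.values())
        assert all(v is None
                   for v in report.conditional_emdn_accuracy_by_level.values())

    def test_level_accuracy_non_increasing(self, six_device_registry,
                                           six_item_links, six_item_reference):
        report = evaluate(six_item_links, six_item_reference,
                          RegistryIndex(six_device_registry))
        levels = [report.emdn_accuracy_by_level[k] for k in (1, 2, 3, 4)]
        assert levels == sorted(levels, reverse=True)

    def test_empty_reference_is_error(self, six_device_registry):
        with pytest.raises(ValueError):
            evaluate([], [], RegistryIndex(six_device_registry))

    def test_unknown_reference_id_is_error(self, six_device_registry):
        with pytest.raises(ValueError, match="999"):
            evaluate([], [("N1", "999")], RegistryIndex(six_device_registry))


class TestEvaluateWithReference:
    def test_clean_data_full_protocol(self):
        config = GeneratorConfig(n_manufacturers=15, notice_count=60,
                                 bdrmd_fraction=1.0, seed=11)
        registry, notices, truth, _ = generate_dataset(config)
        report, links = evaluate_with_reference(
            notices, RegistryIndex(registry), ResolverConfig(method="cos")
        )
        assert report.n_reference == 60
        # identifiers were hidden, so every link went through entity resolution
        assert all(link.provenance in ("er", "unmatched") for link in links)
        assert report.id_accuracy == 1.0
        assert report.manufacturer_accuracy == 1.0
        assert all(v == 1.0 for v in report.emdn_accuracy_by_level.values())

    def test_no_reference_subset_is_error(self):
        config = GeneratorConfig(n_manufacturers=5, notice_count=10,
                                 bdrmd_fraction=0.0, seed=1)
        registry, notices, _, _ = generate_dataset(config)
        with pytest.raises(ValueError):
            evaluate_with_reference(notices, RegistryIndex(registry))
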