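import random
from functools import lru_cache

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noticelink.device_match import (
    DeviceMatch,
    ThresholdSchedule,
    find_best_device,
    levenshtein,
    ratio,
    score_pair,
    token_set_ratio,
)
from noticelink.records_io import DeviceRecord, NoticeRecord

# ---------------------------------------------------------------------------
# Independent oracles: plain recursive edit distances.
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def oracle_levenshtein(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        oracle_levenshtein(a[1:], b) + 1,
        oracle_levenshtein(a, b[1:]) + 1,
        oracle_levenshtein(a[1:], b[1:]) + (a[0] != b[0]),
    )


@lru_cache(maxsize=None)
def oracle_indel(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    best = min(oracle_indel(a[1:], b) + 1, oracle_indel(a, b[1:]) + 1)
    if a[0] == b[0]:
        best = min(best, oracle_indel(a[1:], b[1:]))
    return best


def oracle_ratio(a: str, b: str) -> int:
    lensum = len(a) + len(b)
    if lensum == 0:
        return 100
    return int(100 * (lensum - oracle_indel(a, b)) / lensum + 0.5)


short = st.text(alphabet="ab", max_size=6)
words = st.text(alphabet="abcdefg", min_size=1, max_size=5)
phrases = st.lists(words, min_size=0, max_size=5).map(" ".join)


class TestLevenshtein:
    def test_kitten_sitting(self):
        assert levenshtein("kitten", "sitting") == 3

    def test_identity(self):
        assert levenshtein("alpha", "alpha") == 0

    def test_pure_insertions(self):
        assert levenshtein("", "abc") == 3

    @given(short, short)
    def test_matches_oracle(self, a, b):
        assert levenshtein(a, b) == oracle_levenshtein(a, b)

    @given(short, short, short)
    def test_metric_properties(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert levenshtein(a, b) + levenshtein(b, c) >= levenshtein(a, c)
        assert (levenshtein(a, b) == 0) == (a == b)


class TestRatio:
    @pytest.mark.parametrize("a,b,expected", [
        ("alpha", "alpha", 100),
        ("ab", "cd", 0),
        ("ab", "ac", 50),
        ("", "", 100),
    ])
    def test_examples(self, a, b, expected):
        assert ratio(a, b) == expected

    @given(short, short)
    def test_matches_oracle(self, a, b):
        assert ratio(a, b) == oracle_ratio(a, b)

    @given(short, short)
    def test_bounds_and_symmetry(self, a, b):
        assert 0 <= ratio(a, b) <= 100
        assert ratio(a, b) == ratio(b, a)


class TestTokenSetRatio:
    def test_subset_scores_100(self):
        assert token_set_ratio("alpha", "alpha beta gamma") == 100

    def test_order_invariant(self):
        assert token_set_ratio("alpha beta", "beta alpha") == 100

    def test_disjoint_single_words_equal_oracle(self):
        # s0 empty, remainders "aaa" and "bbb": best of the three pairings
        a, b = "aaa", "bbb"
        expected = max(oracle_ratio("", a), oracle_ratio("", b), oracle_ratio(a, b))
        assert token_set_ratio(a, b) == expected

    @given(phrases, phrases)
    def test_symmetric(self, a, b):
        assert token_set_ratio(a, b) == token_set_ratio(b, a)

    @given(phrases)
    def test_duplication_invariant(self, a):
        assert token_set_ratio(a, " ".join(a.split() * 2)) == 100

    @given(phrases, phrases)
    def test_containment_scores_100(self, a, b):
        merged = " ".join(sorted(set(a.split()) | set(b.split())))
        assert token_set_ratio(a, merged) == 100 or not a.split()
        if a.split():
            assert token_set_ratio(a, a) == 100

    @given(phrases, phrases)
    def test_matches_three_way_definition(self, a, b):
        sa, sb = set(a.split()), set(b.split())
        common = sorted(sa & sb)
        ra, rb = sorted(sa - sb), sorted(sb - sa)
        s0, s1, s2 = (" ".join(common), " ".join(common + ra), " ".join(common + rb))
        expected = max(ratio(s0, s1), ratio(s0, s2), ratio(s1, s2))
        assert token_set_ratio(a, b) == expected


class TestScorePair:
    def make(self, device_name, commercial, d_commercial, d_catalogue):
        notice = NoticeRecord("SN-1", "m", device_name, commercial)
        device = DeviceRecord("1", "m", d_catalogue, d_commercial)
        return notice, device

    def test_both_pairs_empty(self):
        notice, device = self.make("", "", "", "")
        assert score_pair(notice, device) == (0, "device_vs_commercial")

    def test_device_name_identity_wins(self):
        notice, device = self.make("alpha monitor", "unrelated", "alpha monitor", "zz")
        score, pair = score_pair(notice, device)
        assert score == 100 and pair == "device_vs_commercial"

    def test_catalogue_pair_can_win(self):
        notice, device = self.make("nothing shared", "code AB12", "other name", "AB12")
        score, pair = score_pair(notice, device)
        assert score == 100 and pair == "commercial_vs_catalogue"

    @given(phrases, phrases, phrases, phrases)
    def test_max_of_both_pairs(self, nd, nc, dc, dcat):
        notice, device = self.make(nd, nc, dc, dcat)
        expected = max(
            token_set_ratio(nd, dc) if nd and dc else 0,
            token_set_ratio(nc, dcat) if nc and dcat else 0,
        )
        assert score_pair(notice, device)[0] == expected


class TestThresholdSchedule:
    def test_default_walk(self):
        assert ThresholdSchedule().thresholds() == [95, 90, 85, 80, 75, 70, 65, 60]

    def test_invalid(self):
        with pytest.raises(ValueError):
            ThresholdSchedule(step=0)
        with pytest.raises(ValueError):
            ThresholdSchedule(start=50, floor=60)


class TestFindBestDevice:
    def device(self, pid, name, code="X1"):
        return DeviceRecord(pid, "m", code, name)

    def notice(self, name):
        return NoticeRecord("SN-1", "m", name, "")

    def test_highest_scorer_at_first_threshold(self):
        # two near-identical candidates: scores 97ish and 96ish
        notice = self.notice("alpha beta gamma delta epsilon zeta")
        d1 = self.device("2", "alpha beta gamma delta epsilon zeta")  # 100
        d2 = self.device("1", "alpha beta gamma delta epsilon")       # subset -> 100
        match = find_best_device(notice, [d1, d2])
        assert match.accepted_threshold == 95
        assert match.device_id == "1"  # tie at 100 broken by smallest id

    def test_all_below_floor_is_none(self):
        notice = self.notice("qqq www eee")
        assert find_best_device(notice, [self.device("1", "zzz xxx yyy")]) is None

    def test_schedule_arithmetic(self):
        # single disjoint tokens sharing a 5-char prefix: ratio 71
        notice = self.notice("abcdefg")
        candidate = self.device("1", "abcdexy")
        score, _ = score_pair(notice, candidate)
        assert 70 <= score < 75
        match = find_best_device(notice, [candidate])
        assert match.score == score
        assert match.accepted_threshold == 70

    def test_empty_candidates(self):
        assert find_best_device(self.notice("alpha"), []) is None

    def test_loop_equivalence_randomized(self):
        # iterative schedule == single max-then-floor on random instances
        rng = random.Random(42)
        vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta"]
        for _ in range(300):
            notice = self.notice(" ".join(rng.sample(vocab, rng.randint(1, 4))))
            candidates = [
                self.device(str(pid), " ".join(rng.sample(vocab, rng.randint(1, 4))))
                for pid in rng.sample(range(1, 50), rng.randint(1, 8))
            ]
            match = find_best_device(notice, candidates)
            scores = {d.progressive_id: score_pair(notice, d)[0] for d in candidates}
            best = max(scores.values())
            if best < 60:
                assert match is None
            else:
                winners = sorted(
                    (int(pid) for pid, s in scores.items() if s == best)
                )
                assert match.device_id == str(winners[0])
                assert match.score == best
                # accepted threshold is the first schedule step at/below the score
                assert match.accepted_threshold == max(
                    t for t in ThresholdSchedule().thresholds() if t <= best
                )
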