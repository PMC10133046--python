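"""Phase-2 entity resolution: fuzzy matching of notice fields against devices.

Similarity is an integer score in 0..100 built on edit distance.  ``ratio``
normalizes an edit distance in which substitutions cost 2 (so it reduces to
an insert/delete distance); ``token_set_ratio`` makes the score robust to
token order and repetition by comparing the sorted common tokens against
each side's sorted remainder and keeping the best of the three pairings.
Candidate devices come from the phase-1 manufacturer block; acceptance uses
a descending threshold schedule (95, 90, ..., 60) and picks the
highest-scoring candidate at the first threshold any candidate clears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .records_io import DeviceRecord, NoticeRecord
from .textprep import normalize

__all__ = [
    "DeviceMatch",
    "ThresholdSchedule",
    "levenshtein",
    "ratio",
    "token_set_ratio",
    "score_pair",
    "find_best_device",
]


@dataclass(frozen=True)
class ThresholdSchedule:
    """Descending acceptance schedule for the phase-2 loop."""

    start: int = 95
    step: int = 5
    floor: int = 60

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.start < self.floor:
            raise ValueError("start must be >= floor")

    def thresholds(self) -> list[int]:
        return list(range(self.start, self.floor - 1, -self.step))


@dataclass(frozen=True)
class DeviceMatch:
    """An accepted phase-2 match for one notice."""

    notice_ref: str
    device_id: str
    score: int
    accepted_threshold: int
    field_pair: str  # "device_vs_commercial" | "commercial_vs_catalogue"


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertion, deletion, substitution)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(min(
                previous[j] + 1,          # deletion
                current[j - 1] + 1,       # insertion
                previous[j - 1] + (ca != cb),  # substitution
            ))
        previous = current
    return previous[-1]


def _indel_distance(a: str, b: str) -> int:
    """Edit distance with substitution cost 2 (equivalently insert/delete only)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    # lensum - 2 * LCS, computed by LCS dynamic programming on two rows
    previous = [0] * (len(b) + 1)
    for ca in a:
        current = [0]
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                current.append(previous[j - 1] + 1)
            else:
                current.append(max(previous[j], current[j - 1]))
        previous = current
    return len(a) + len(b) - 2 * previous[-1]


def ratio(a: str, b: str) -> int:
    """Normalized similarity in 0..100.

    With ``d2`` the substitution-cost-2 edit distance and ``L`` the summed
    length, the score is ``round(100 * (L - d2) / L)`` (rounding half up);
    two empty strings score 100.
    """
    lensum = len(a) + len(b)
    if lensum == 0:
        return 100
    d2 = _indel_distance(a, b)
    return int(100.0 * (lensum - d2) / lensum + 0.5)


def token_set_ratio(a: str, b: str) -> int:
    """Order- and repetition-insensitive fuzzy score in 0..100.

    Inputs should be normalized.  Tokens are de-duplicated as sets; with
    ``I`` the sorted common tokens and ``Ra``/``Rb`` each side's sorted
    remainder, the score is the best ``ratio`` among (I, I+Ra), (I, I+Rb)
    and (I+Ra, I+Rb).  100 whenever one token set contains the other.
    """
    tokens_a = set(a.split())
    tokens_b = set(b.split())
    common = sorted(tokens_a & tokens_b)
    rest_a = sorted(tokens_a - tokens_b)
    rest_b = sorted(tokens_b - tokens_a)
    if not rest_a or not rest_b:
        # one set contains the other: s0 equals s1 or s2, so the max is 100
        return 100
    s0 = " ".join(common)
    s1 = " ".join(common + rest_a)
    s2 = " ".join(common + rest_b)
    return max(ratio(s0, s1), ratio(s0, s2), ratio(s1, s2))


def score_pair(
    notice: NoticeRecord,
    device: DeviceRecord,
    prenormalized: Optional[tuple[str, str, str, str]] = None,
) -> tuple[int, str]:
    """Best field-pair score between a notice and a device.

    Two comparisons are made — the notice's device name against the
    registry's commercial name, and the notice's commercial name against the
    registry's catalogue code — and the larger score wins.  A pair with an
    empty side contributes 0.  *prenormalized* may carry
    ``(notice_device, notice_commercial, device_commercial, device_catalogue)``
    already normalized, to avoid repeated normalization in batch runs.
    """
    if prenormalized is None:
        n_device = normalize(notice.device)
        n_commercial = normalize(notice.commercial_name)
        d_commercial = normalize(device.commercial_name)
        d_catalogue = normalize(device.catalogue_code)
    else:
        n_device, n_commercial, d_commercial, d_catalogue = prenormalized

    score_name = (
        token_set_ratio(n_device, d_commercial) if n_device and d_commercial else 0
    )
    score_code = (
        token_set_ratio(n_commercial, d_catalogue) if n_commercial and d_catalogue else 0
    )
    if score_code > score_name:
        return score_code, "commercial_vs_catalogue"
    return score_name, "device_vs_commercial"


def _id_sort_key(progressive_id: str):
    # numeric when possible so "99" sorts before "100"
    return (0, int(progressive_id)) if progressive_id.isdigit() else (1, progressive_id)


def find_best_device(
    notice: NoticeRecord,
    candidates: Sequence[DeviceRecord],
    schedule: ThresholdSchedule = ThresholdSchedule(),
    device_norms: Optional[Sequence[tuple[str, str]]] = None,
) -> Optional[DeviceMatch]:
    """Walk the threshold schedule and return the accepted match, if any.

    Candidates are scored once; the schedule descends from ``start`` by
    ``step`` until some candidate reaches the current threshold, at which
    point the highest-scoring candidate is selected (ties broken by the
    smallest progressive id).  Returns ``None`` when no candidate ever
    reaches the floor — extensionally this is max-then-floor, but the loop
    mirrors the operational definition.

    *device_norms*, aligned with *candidates*, may carry each device's
    normalized ``(commercial_name, catalogue_code)`` to avoid re-normalizing
    in batch runs.
    """
    if not candidates:
        return None
    n_device = normalize(notice.device)
    n_commercial = normalize(notice.commercial_name)
    if device_norms is None:
        device_norms = [
            (normalize(d.commercial_name), normalize(d.catalogue_code))
            for d in candidates
        ]
    scored = [
        (score_pair(notice, device, (n_device, n_commercial, d_comm, d_cat)), device)
        for device, (d_comm, d_cat) in zip(candidates, device_norms)
    ]
    for threshold in schedule.thresholds():
        reaching = [(sp, device) for sp, device in scored if sp[0] >= threshold]
        if reaching:
            (best_score, field_pair), best_device = min(
                reaching,
                key=lambda item: (-item[0][0], _id_sort_key(item[1].progressive_id)),
            )
            return DeviceMatch(
                notice_ref=notice.reference_number,
                device_id=best_device.progressive_id,
                score=best_score,
                accepted_threshold=threshold,
                field_pair=field_pair,
            )
    return None
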