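"""Hierarchical device-nomenclature codes (EMDN/CND style).

A code is one category letter followed by up to six two-digit pairs, giving
at most seven hierarchical levels (category, group, then progressively finer
types).  ``agreement_depth`` measures how many consecutive levels two codes
share, which is the unit of account for level-wise linkage accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EMDNCode", "EMDNFormatError", "parse_emdn", "agreement_depth", "MAX_DEPTH"]

MAX_DEPTH = 7


class EMDNFormatError(ValueError):
    """Raised when a string does not parse as a nomenclature code."""


@dataclass(frozen=True)
class EMDNCode:
    """A parsed hierarchical nomenclature code.

    ``level_prefixes[0]`` is the category letter; each subsequent prefix
    extends the previous one by exactly two digits.  ``depth`` equals
    ``len(level_prefixes)`` and never exceeds 7.
    """

    raw: str
    category: str
    level_prefixes: tuple[str, ...]

    @property
    def depth(self) -> int:
        return len(self.level_prefixes)

    def prefix_at(self, level: int) -> str:
        """Prefix at 1-based *level*, capped at this code's depth."""
        return self.level_prefixes[min(level, self.depth) - 1]

    def truncate(self, level: int) -> "EMDNCode":
        """Code truncated to at most *level* levels."""
        if level < 1:
            raise ValueError("level must be >= 1")
        prefixes = self.level_prefixes[:level]
        return EMDNCode(raw=prefixes[-1], category=self.category, level_prefixes=prefixes)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.level_prefixes[-1]


def parse_emdn(code: str) -> EMDNCode:
    """Parse *code* into an :class:`EMDNCode`.

    The grammar is one letter followed by 0..6 two-digit pairs; input is
    trimmed and uppercased first.  Raises :class:`EMDNFormatError` on an
    empty string, a non-letter lead character, an odd number of trailing
    digits, a non-digit tail, or more than seven levels.
    """
    cleaned = code.strip().upper()
    if not cleaned:
        raise EMDNFormatError("empty nomenclature code")
    head, tail = cleaned[0], cleaned[1:]
    if not ("A" <= head <= "Z"):
        raise EMDNFormatError(f"code must start with a category letter: {code!r}")
    if not tail.isdigit() and tail != "":
        raise EMDNFormatError(f"code tail must be digits: {code!r}")
    if len(tail) % 2 != 0:
        raise EMDNFormatError(f"odd number of digits in code: {code!r}")
    n_pairs = len(tail) // 2
    if 1 + n_pairs > MAX_DEPTH:
        raise EMDNFormatError(f"code deeper than {MAX_DEPTH} levels: {code!r}")
    prefixes = [head]
    for i in range(n_pairs):
        prefixes.append(head + tail[: 2 * (i + 1)])
    return EMDNCode(raw=cleaned, category=head, level_prefixes=tuple(prefixes))


def agreement_depth(a: EMDNCode, b: EMDNCode) -> int:
    """Number of consecutive levels on which *a* and *b* agree (0..7).

    0 when the category letters differ; bounded above by the shallower
    code's depth; symmetric.
    """
    depth = 0
    for pa, pb in zip(a.level_prefixes, b.level_prefixes):
        if pa != pb:
            break
        depth += 1
    return depth
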