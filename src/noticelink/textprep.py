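"""Text preprocessing operators applied before any similarity computation.

The cleaning chain is deliberately small: punctuation removal, removal of
extra spaces and special characters, lowercasing, word tokenization and an
optional part-of-speech pass.  Stemming and lemmatization are deliberately
omitted — the processed text consists almost entirely of company and product
names, for which vocabulary normalization is inappropriate.
"""

from __future__ import annotations

import re
import string
import unicodedata
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

__all__ = [
    "TokenizedText",
    "remove_punctuation",
    "clean_spaces_specials",
    "lowercase",
    "normalize",
    "tokenize",
    "pos_tag",
    "LexiconTagger",
    "strip_company_suffix",
    "DEFAULT_PUNCTUATION",
    "DEFAULT_SPECIALS",
    "DEFAULT_LEGAL_SUFFIXES",
    "load_wordlist",
]

#: ASCII punctuation removed by :func:`remove_punctuation`.
DEFAULT_PUNCTUATION = frozenset(string.punctuation)

#: Characters treated as "special" by :func:`clean_spaces_specials`.  The
#: canonical member is ``*``; any other non-alphanumeric symbol character
#: (Unicode category ``S*``) is removed as well.
DEFAULT_SPECIALS = frozenset("*")

#: Legal-form suffixes stripped from the tail of company names.
DEFAULT_LEGAL_SUFFIXES = frozenset(
    {
        "spa", "srl", "snc", "gmbh", "ag", "sa", "inc", "ltd", "llc",
        "co", "corp", "bv", "nv", "plc", "kg", "sarl",
    }
)

_WORD_OR_PUNCT = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_WS_RUN = re.compile(r"\s+")


@dataclass
class TokenizedText:
    """A string together with its normalized form and token stream."""

    original: str
    normalized: str
    tokens: list[str]
    pos_tags: Optional[list[tuple[str, str]]] = field(default=None)


def remove_punctuation(text: str, punctuation: frozenset[str] = DEFAULT_PUNCTUATION) -> str:
    """Remove every character belonging to *punctuation*; keep all others in order."""
    return "".join(ch for ch in text if ch not in punctuation)


def _is_special(ch: str, specials: frozenset[str]) -> bool:
    if ch in specials:
        return True
    # symbol characters outside the configured set ($, ©, ™, …) are specials too
    return unicodedata.category(ch).startswith("S")


def clean_spaces_specials(text: str, specials: frozenset[str] = DEFAULT_SPECIALS) -> str:
    """Drop special characters, collapse whitespace runs and trim the ends."""
    kept = "".join(ch for ch in text if not _is_special(ch, specials))
    return _WS_RUN.sub(" ", kept).strip()


def lowercase(text: str) -> str:
    """Convert all characters to lowercase."""
    return text.lower()


def normalize(
    text: str,
    punctuation: frozenset[str] = DEFAULT_PUNCTUATION,
    specials: frozenset[str] = DEFAULT_SPECIALS,
) -> str:
    """Full cleaning chain: punctuation-free, space-collapsed, lowercase.

    Idempotent: ``normalize(normalize(x)) == normalize(x)``.
    """
    return lowercase(clean_spaces_specials(remove_punctuation(text, punctuation), specials))


def tokenize(text: str) -> list[str]:
    """Split *text* into word tokens plus standalone punctuation tokens.

    On normalized text (which carries no punctuation) this reduces to
    whitespace splitting.
    """
    return _WORD_OR_PUNCT.findall(text)


# ---------------------------------------------------------------------------
# POS tagging — pluggable with a deterministic bundled default.
# ---------------------------------------------------------------------------

#: Small bundled lexicon (lowercased lookup) sufficient for the cleaning-chain
#: fixtures and for deterministic tests.  Penn-style tags.
_BUNDLED_LEXICON: dict[str, str] = {
    "my": "PRP$", "your": "PRP$", "his": "PRP$", "her": "PRP$", "its": "PRP$",
    "our": "PRP$", "their": "PRP$",
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "and": "CC", "or": "CC", "but": "CC",
    "of": "IN", "in": "IN", "on": "IN", "for": "IN", "with": "IN", "by": "IN",
    "to": "TO", "not": "RB",
    "pen": "NN", "device": "NN", "notice": "NN", "recall": "NN",
    "manufacturer": "NN", "company": "NN", "system": "NN", "monitor": "NN",
    "red": "JJ", "blue": "JJ", "green": "JJ", "new": "JJ", "medical": "JJ",
    "safe": "JJ",
}

#: Ordered suffix rules applied when a token is not in the lexicon.
_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("ing", "VBG"),
    ("ed", "VBD"),
    ("ly", "RB"),
    ("ness", "NN"),
    ("tion", "NN"),
    ("s", "NNS"),
)


class LexiconTagger:
    """Deterministic tagger: lexicon lookup, then suffix rules, then defaults.

    Punctuation tokens are tagged with themselves (Penn convention for
    sentence-final punctuation collapses to the token here) and digit tokens
    as ``CD``.
    """

    def __init__(self, lexicon: Optional[dict[str, str]] = None):
        self.lexicon = dict(_BUNDLED_LEXICON if lexicon is None else lexicon)

    def __call__(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        return [(tok, self._tag(tok)) for tok in tokens]

    def _tag(self, token: str) -> str:
        low = token.lower()
        if low in self.lexicon:
            return self.lexicon[low]
        if not any(ch.isalnum() for ch in token):
            return token
        if token.replace(".", "").replace(",", "").isdigit():
            return "CD"
        for suffix, tag in _SUFFIX_RULES:
            if len(low) > len(suffix) + 1 and low.endswith(suffix):
                return tag
        return "NNP" if token[:1].isupper() else "NN"


def pos_tag(
    tokens: Sequence[str],
    backend: Optional[Callable[[Sequence[str]], list[tuple[str, str]]]] = None,
) -> list[tuple[str, str]]:
    """Tag *tokens* with Penn-style part-of-speech tags.

    *backend* is any callable mapping a token sequence to ``(token, tag)``
    pairs; the default is the bundled :class:`LexiconTagger`.

    Raises :class:`TypeError` if a non-callable backend is supplied.
    """
    if not tokens:
        return []
    if backend is None:
        backend = LexiconTagger()
    if not callable(backend):
        raise TypeError("pos_tag backend must be callable")
    tags = backend(tokens)
    if len(tags) != len(tokens):
        raise ValueError("backend returned %d tags for %d tokens" % (len(tags), len(tokens)))
    return tags


def strip_company_suffix(
    name: str, suffixes: frozenset[str] = DEFAULT_LEGAL_SUFFIXES
) -> str:
    """Strip trailing legal-form tokens (``srl``, ``gmbh``, …) from *name*.

    *name* is expected to be normalized already.  Suffix tokens are removed
    repeatedly from the end, but the name is never emptied: at least one
    token always survives.
    """
    tokens = name.split()
    while len(tokens) > 1 and tokens[-1] in suffixes:
        tokens.pop()
    return " ".join(tokens)


def load_wordlist(path: str) -> frozenset[str]:
    """Read a one-entry-per-line config file (suffix lists, character sets)."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())
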