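"""Shared text primitives: tokenization, phrase matching, percentage rounding.

All matching in the toolkit is case-insensitive and punctuation-insensitive:
text is reduced to a lowercase token sequence before comparison. Tokens are
maximal runs of letters/digits, with internal hyphens kept (``b-type`` is one
token). No stemming and no truncation is ever applied.
"""

from __future__ import annotations

import re
import unicodedata
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from typing import Sequence

_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def normalize(text: str) -> str:
    """NFC-compose unicode; used on ingest so equal-looking strings compare equal."""
    return unicodedata.normalize("NFC", text)


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; splits on anything that is not a letter, digit
    or internal hyphen."""
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


@lru_cache(maxsize=65536)
def _cached_tokens(text: str) -> tuple[str, ...]:
    return tuple(tokenize(text))


def token_key(text: str) -> tuple[str, ...]:
    """Cached token tuple for a (typically short, repeated) string."""
    return _cached_tokens(text)


def contains_sequence(haystack: Sequence[str], needle: Sequence[str]) -> bool:
    """True iff ``needle`` occurs as a contiguous subsequence of ``haystack``."""
    n, h = len(needle), len(haystack)
    if n == 0 or n > h:
        return False
    first = needle[0]
    for i in range(h - n + 1):
        if haystack[i] == first and list(haystack[i : i + n]) == list(needle):
            return True
    return False


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, half-up — the rounding used in all reports."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, 1)
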