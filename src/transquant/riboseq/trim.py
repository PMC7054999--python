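"""Read trimming: 3' adapter removal and random-nucleotide stripping.

Library wrappers add four random nucleotides to each end of the insert and a
fixed 3' adapter.  The adapter is located by its longest prefix of at least
six nucleotides occurring in the read (leftmost occurrence of the longest
matching prefix); everything from the match on is removed.  The four random
nucleotides are then stripped from both ends, and the insert is kept only if
its length falls within the size-selection window.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TrimResult:
    sequence: str | None
    accepted: bool
    reason: str            # ok | no_adapter | too_short | too_long
    adapter_found: bool


def trim_read(raw: str, adapter: str, n_random: int = 4,
              min_len: int = 15, max_len: int = 45,
              min_adapter_match: int = 6) -> TrimResult:
    """Trim one raw read; see the module docstring for the rule."""
    if not raw:
        raise ValueError("empty read")
    cut = -1
    for k in range(len(adapter), min_adapter_match - 1, -1):
        idx = raw.find(adapter[:k])
        if idx >= 0:
            cut = idx
            break
    adapter_found = cut >= 0
    body = raw[:cut] if adapter_found else raw
    if len(body) < 2 * n_random + min_len:
        return TrimResult(None, False, "too_short", adapter_found)
    insert = body[n_random:len(body) - n_random] if n_random else body
    if len(insert) < min_len:
        return TrimResult(None, False, "too_short", adapter_found)
    if len(insert) > max_len:
        return TrimResult(None, False, "too_long", adapter_found)
    reason = "ok" if adapter_found else "no_adapter"
    return TrimResult(insert, True, reason, adapter_found)
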