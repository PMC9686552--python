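"""Exact/1-substitution window lookup for short tags against reference sets.

For 18-26 nt tags, scanning every reference window is quadratic; instead we
index all reference windows of the relevant lengths and look up the tag and
its single-substitution variants.  Results are identical to an exhaustive
window scan (tested against one).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

_BASES = "ACGT"


def one_sub_variants(sequence: str) -> Iterable[str]:
    """All sequences at Hamming distance exactly 1 (substitutions only)."""
    for i, original in enumerate(sequence):
        for base in _BASES:
            if base != original:
                yield sequence[:i] + base + sequence[i + 1 :]


class WindowIndex:
    """Index of all fixed-length windows of a set of reference sequences."""

    def __init__(self, sequences: Mapping[str, str], min_len: int, max_len: int):
        self.min_len = min_len
        self.max_len = max_len
        self._index: dict[int, dict[str, list[tuple[str, int]]]] = {
            length: defaultdict(list) for length in range(min_len, max_len + 1)
        }
        for ref_id, seq in sequences.items():
            for length in range(min_len, min(max_len, len(seq)) + 1):
                table = self._index[length]
                for start in range(len(seq) - length + 1):
                    table[seq[start : start + length]].append((ref_id, start))

    def exact(self, tag: str) -> list[tuple[str, int]]:
        table = self._index.get(len(tag))
        if table is None:
            return []
        return list(table.get(tag, ()))

    def within_one(self, tag: str) -> list[tuple[str, int, int]]:
        """All (ref_id, start, mismatches) with mismatches <= 1."""
        table = self._index.get(len(tag))
        if table is None:
            return []
        hits: dict[tuple[str, int], int] = {}
        for ref_id, start in table.get(tag, ()):
            hits[(ref_id, start)] = 0
        for variant in one_sub_variants(tag):
            for ref_id, start in table.get(variant, ()):
                hits.setdefault((ref_id, start), 1)
        return sorted((ref_id, start, mism) for (ref_id, start), mism in hits.items())

    def has_within_one(self, tag: str) -> bool:
        table = self._index.get(len(tag))
        if table is None:
            return False
        if tag in table:
            return True
        return any(variant in table for variant in one_sub_variants(tag))
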