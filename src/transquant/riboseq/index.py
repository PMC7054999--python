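"""Exact-match substring index over a set of reference sequences.

A seed-and-verify index: every k-mer (k = the minimum queryable read length)
of every reference is hashed to its (transcript, position) occurrences; a
query looks up its first k-mer and verifies the full read at each candidate
position.  Queries return *all* exact occurrences.  The index tolerates zero
mismatches by design: it stands in for a short-read aligner in a pipeline
whose computation of record is counting and normalization, not alignment.
"""

from __future__ import annotations

from typing import Mapping


class ExactMatchIndex:
    def __init__(self, sequences: Mapping[str, str], k: int = 15):
        if k < 1:
            raise ValueError("k must be positive")
        ids = list(sequences)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids")
        self.k = k
        self._seqs = dict(sequences)
        self._kmers: dict[str, list] = {}
        for tid, seq in self._seqs.items():
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i:i + k], []).append((tid, i))

    def query(self, read: str) -> list[tuple[str, int]]:
        """All (transcript id, start) exact occurrences of ``read``."""
        n = len(read)
        if n < self.k:
            # shorter than the seed: fall back to a direct scan
            hits = []
            for tid, seq in self._seqs.items():
                start = seq.find(read)
                while start >= 0:
                    hits.append((tid, start))
                    start = seq.find(read, start + 1)
            return hits
        hits = []
        for tid, pos in self._kmers.get(read[:self.k], ()):
            if self._seqs[tid][pos:pos + n] == read:
                hits.append((tid, pos))
        return hits

    def __contains__(self, read: str) -> bool:
        return bool(self.query(read))
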