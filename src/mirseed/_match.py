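"""Vectorized ungapped substring matching with a mismatch budget.

References are packed into one byte array separated by sentinel runs; a
query of length L is compared against every length-L window at once with
NumPy, and hits spanning a reference boundary are rejected by position.
This is exact for any mismatch budget (unlike seed-and-extend heuristics)
and fast enough for desk-scale catalogs.
"""

from __future__ import annotations

import numpy as np

_SENTINEL = ord("#")


class UngappedIndex:
    def __init__(self, seqs: list[str], ids: list[str]):
        if len(seqs) != len(ids):
            raise ValueError("seqs and ids length mismatch")
        self.ids = list(ids)
        sep = "#" * 40  # longer than any query
        blob = sep.join(seqs)
        self._arr = np.frombuffer(blob.encode("ascii"), dtype=np.uint8)
        self._starts = np.zeros(len(seqs), dtype=np.int64)
        pos = 0
        for k, s in enumerate(seqs):
            self._starts[k] = pos
            pos += len(s) + len(sep)
        self._lengths = np.array([len(s) for s in seqs], dtype=np.int64)

    def hits(self, query: str, max_mm: int) -> list[tuple[int, int, int]]:
        """All (ref_index, offset, mismatches) with the query fully inside
        a reference, ungapped, at most ``max_mm`` substitutions."""
        q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        L = len(q)
        if L == 0 or L > self._arr.size:
            return []
        windows = np.lib.stride_tricks.sliding_window_view(self._arr, L)
        mm = (windows != q).sum(axis=1)
        positions = np.nonzero(mm <= max_mm)[0]
        out = []
        for p in positions.tolist():
            k = int(np.searchsorted(self._starts, p, side="right")) - 1
            offset = p - int(self._starts[k])
            if offset + L <= int(self._lengths[k]):
                out.append((k, offset, int(mm[p])))
        return out

    def has_hit(self, query: str, max_mm: int) -> bool:
        return bool(self.hits(query, max_mm))
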