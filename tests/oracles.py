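"""Independent brute-force oracles used to check the fast implementations.

These deliberately use naive, dictionary/boolean-mask level algorithms and
share no code with the package paths they verify.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def dict_kmer_counts(sequence: str, k: int) -> Dict[str, int]:
    """Canonical k-mer counts by literal dictionary counting."""
    counts: Dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i:i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        canon = min(kmer, revcomp(kmer))
        counts[canon] = counts.get(canon, 0) + 1
    return counts


def mask_union(intervals: Sequence[Tuple[int, int]], length: int,
               max_gap: int) -> List[Tuple[int, int]]:
    """Interval union with gap bridging via an explicit boolean mask."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    # bridge gaps <= max_gap between covered runs
    runs = _runs(mask)
    for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
        if s2 - e1 <= max_gap:
            mask[e1:s2] = True
    return _runs(mask)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    out = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def brute_force_tir(sequence: str, window: int, min_len: int,
                    max_mismatch_frac: float,
                    ) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """All-pairs scan for the best terminal inverted repeat.

    Enumerates every (prefix offset, suffix offset) pair and every length,
    maximizing matches - mismatches subject to the length and mismatch
    constraints; ties go to the longer, then 5'-most pair. Only feasible for
    short sequences.
    """
    L = len(sequence)
    P = sequence[:window]
    Q = revcomp(sequence[L - window:])
    best = None  # key: (score, length, -i, -q)
    for i in range(window):
        for q in range(window):
            n = window - max(i, q)
            if n < min_len:
                continue
            matches = np.frombuffer(P[i:i + n].encode(), dtype="S1") == \
                np.frombuffer(Q[q:q + n].encode(), dtype="S1")
            mism = np.cumsum(~matches)
            for length in range(min_len, n + 1):
                m = int(mism[length - 1])
                if m > max_mismatch_frac * length + 1e-12:
                    continue
                score = length - 2 * m
                key = (score, length, -i, -q)
                if best is None or key > best[0]:
                    best = (key, i, q, length)
    if best is None:
        return None
    _, i, q, length = best
    return (i, i + length), (L - q - length, L - q)


def brute_force_n50(lengths: Sequence[int]) -> int:
    """N50 by sorted prefix sums."""
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    raise ValueError("empty length list")


def overlap_count(fragments: Sequence[Tuple[str, int, int]],
                  loci: Sequence[Tuple[str, int, int, str]]) -> Tuple[int, int]:
    """(loci overlapping any fragment, distinct keys) by direct comparison."""
    n, keys = 0, set()
    for scaf, s, e, key in loci:
        if any(fs == scaf and s < fe and e > fs_start
               for fs, fs_start, fe in fragments):
            n += 1
            keys.add(key)
    return n, len(keys)
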