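"""Viral fragment assembly and annotation.

Marker hits (the output of an upstream homology screen, consumed as input)
are merged into viral fragments per clade; fragments get a marker tally
(including the >=3-of-9 giant-virus eligibility rule), a per-scaffold viral
fraction with the >90% "nearly entirely viral" flag, a completeness estimate
against per-clade reference genome lengths with the >=90% (near-)complete
call, and terminal-inverted-repeat (TIR) coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic import NINE_NCLDV_MARKERS, reverse_complement

#: Default complete-genome reference lengths (bp) per clade. The two
#: Gezel-like clades share the midpoint of the 19.5-29.5 kb complete-genome
#: range; the miniature PLV2 genomes use the midpoint of 14.6-15.6 kb; the
#: giant-virus reference is the ~400 kb complete genome. CHeCME boundaries
#: are not defined well enough for a completeness call (None = not
#: applicable).
DEFAULT_CLADE_REFS: Dict[str, Optional[int]] = {
    "PLVA": 24_500,
    "PLVB": 24_500,
    "PLV2": 15_100,
    "NCLDV": 400_000,
    "CHeCME": None,
}

NEAR_COMPLETE_MIN = 0.9        # "at least 90% of the reference length", inclusive
NEARLY_ENTIRELY_VIRAL = 0.9    # scaffold viral fraction > 90%


@dataclass
class ViralFragment:
    scaffold: str
    start: int
    end: int
    clade: str
    marker_names: Counter = field(default_factory=Counter)
    fragment_id: str = ""
    completeness: Optional[float] = None
    near_complete: Optional[bool] = None
    tirs: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Hit merging


def merge_hits(hits: pd.DataFrame, max_gap: int = 2000,
               scaffold_lengths: Optional[Mapping[str, int]] = None,
               by_clade: bool = True,
               ) -> Tuple[List[ViralFragment], List[str]]:
    """Merge hit intervals into fragments, bridging gaps <= ``max_gap``.

    By default hits are merged within each clade so that a small element
    nested inside a larger one of a different clade stays a separate
    fragment. With ``by_clade=False`` all hits merge together and each
    fragment's clade is the score-weighted plurality of its member hits
    (ties broken by the highest single hit score).

    Hits exceeding scaffold bounds (when lengths are given) are rejected;
    returns (fragments, warnings).
    """
    warnings: List[str] = []
    rows = []
    for row in hits.itertuples(index=False):
        if row.start >= row.end:
            warnings.append(f"rejected hit {row.marker} on {row.scaffold}: "
                            f"empty interval [{row.start},{row.end})")
            continue
        if scaffold_lengths is not None:
            if row.scaffold not in scaffold_lengths:
                warnings.append(f"rejected hit {row.marker}: unknown scaffold "
                                f"{row.scaffold}")
                continue
            if row.start < 0 or row.end > scaffold_lengths[row.scaffold]:
                warnings.append(f"rejected hit {row.marker} on {row.scaffold}: "
                                f"[{row.start},{row.end}) exceeds scaffold bounds")
                continue
        rows.append(row)

    def _group_key(row):
        return (row.scaffold, row.clade) if by_clade else (row.scaffold,)

    groups: Dict[tuple, list] = {}
    for row in rows:
        groups.setdefault(_group_key(row), []).append(row)

    fragments: List[ViralFragment] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: (r.start, r.end))
        cur: List = [members[0]]
        cur_end = members[0].end
        for row in members[1:]:
            if row.start - cur_end <= max_gap:
                cur.append(row)
                cur_end = max(cur_end, row.end)
            else:
                fragments.append(_build_fragment(cur))
                cur, cur_end = [row], row.end
        fragments.append(_build_fragment(cur))

    fragments.sort(key=lambda f: (f.scaffold, f.start, f.clade))
    counts: Counter = Counter()
    for frag in fragments:
        counts[frag.clade] += 1
        frag.fragment_id = f"{frag.clade}_frag_{counts[frag.clade]:04d}"
    return fragments, warnings


def _build_fragment(members: list) -> ViralFragment:
    start = min(r.start for r in members)
    end = max(r.end for r in members)
    clade_scores: Dict[str, float] = {}
    clade_best: Dict[str, float] = {}
    for r in members:
        clade_scores[r.clade] = clade_scores.get(r.clade, 0.0) + float(r.score)
        clade_best[r.clade] = max(clade_best.get(r.clade, -np.inf), float(r.score))
    clade = max(clade_scores, key=lambda c: (clade_scores[c], clade_best[c], c))
    return ViralFragment(members[0].scaffold, start, end, clade,
                         Counter(r.marker for r in members))


# ---------------------------------------------------------------------------
# Per-scaffold viral fraction


def viral_fraction(scaffold_length: int,
                   fragments: Sequence[ViralFragment]) -> Tuple[float, bool]:
    """(union of fragment lengths / scaffold length, nearly-entirely-viral flag)."""
    if scaffold_length <= 0:
        raise ValueError("scaffold_length must be positive")
    covered = _union_length([(f.start, f.end) for f in fragments])
    frac = covered / scaffold_length
    return frac, frac > NEARLY_ENTIRELY_VIRAL


def _union_length(intervals: Sequence[Tuple[int, int]]) -> int:
    total, prev_end = 0, None
    for s, e in sorted(intervals):
        if prev_end is None or s > prev_end:
            total += e - s
            prev_end = e
        elif e > prev_end:
            total += e - prev_end
            prev_end = e
    return total


# ---------------------------------------------------------------------------
# Nine-marker tally (giant-virus phylogenetic eligibility)


@dataclass
class NineMarkerTally:
    applicable: bool
    count: Optional[int] = None
    eligible: Optional[bool] = None


def tally_nine_markers(fragment: ViralFragment,
                       nine_markers: Sequence[str] = NINE_NCLDV_MARKERS,
                       min_markers: int = 3) -> NineMarkerTally:
    """Count distinct core giant-virus markers; eligible iff count >= 3."""
    if fragment.clade != "NCLDV":
        return NineMarkerTally(applicable=False)
    present = set(fragment.marker_names) & set(nine_markers)
    return NineMarkerTally(True, len(present), len(present) >= min_markers)


# ---------------------------------------------------------------------------
# Completeness


def completeness(fragment: ViralFragment,
                 refs: Mapping[str, Optional[int]] = DEFAULT_CLADE_REFS,
                 ) -> Tuple[Optional[float], Optional[bool]]:
    """fragment length / clade reference length; near-complete iff >= 0.9.

    Values above 1 are reported as-is. A clade mapped to None (no defined
    complete-element length) yields (None, None); a clade absent from the
    reference table is an error.
    """
    if fragment.clade not in refs:
        raise KeyError(
            f"no reference genome length for clade {fragment.clade!r}; "
            f"add it to the clade reference table")
    ref = refs[fragment.clade]
    if ref is None:
        return None, None
    frac = fragment.length / ref
    fragment.completeness = frac
    fragment.near_complete = frac >= NEAR_COMPLETE_MIN
    return frac, fragment.near_complete


# ---------------------------------------------------------------------------
# Terminal inverted repeats


def detect_tirs(sequence: str, window: int = 1000, min_len: int = 50,
                max_mismatch_frac: float = 0.1,
                ) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Find the best terminal inverted repeat pair, or None.

    Searches for a prefix substring within ``window`` of the 5' terminus
    whose reverse complement occurs within ``window`` of the 3' terminus,
    ungapped, length >= ``min_len`` and mismatch fraction <=
    ``max_mismatch_frac``. Among candidates the pair maximizing
    (matches - mismatches) wins, ties going to the longer, then the
    5'-most pair. Returns ((p_start, p_end), (s_start, s_end)) in sequence
    coordinates, or None.
    """
    L = len(sequence)
    if L < 2 * window:
        raise ValueError(f"sequence length {L} is shorter than 2*window={2 * window}")
    P = np.frombuffer(sequence[:window].encode(), dtype="S1")
    Q = np.frombuffer(reverse_complement(sequence[L - window:]).encode(), dtype="S1")

    best = None  # (score, length, i, q)
    for d in range(-(window - 1), window):
        i0, q0 = max(d, 0), max(-d, 0)
        n = window - max(i0, q0)
        if n < min_len:
            continue
        m = (P[i0:i0 + n] == Q[q0:q0 + n])
        cand = _best_segment(m, min_len, max_mismatch_frac)
        if cand is None:
            continue
        score, length, off = cand
        key = (score, length, -(i0 + off), -(q0 + off))
        if best is None or key > best[0]:
            best = (key, i0 + off, q0 + off, length)
    if best is None:
        return None
    _, i, q, length = best
    prefix = (i, i + length)
    suffix = (L - q - length, L - q)
    return prefix, suffix


def _best_segment(match: np.ndarray, min_len: int,
                  max_mismatch_frac: float) -> Optional[Tuple[int, int, int]]:
    """Best ungapped segment of a boolean match vector.

    Maximizes matches - mismatches over segments with length >= min_len and
    mismatches <= max_mismatch_frac * length (ties resolved toward the
    longer, leftmost segment). Returns (score, length, offset) or None.
    Vectorized max-sum-segment scan; if the unconstrained optimum violates
    the mismatch budget, falls back to the best valid min_len-anchored
    window greedily extended.
    """
    n = len(match)
    w = np.where(match, 1, -1)
    cum = np.concatenate([[0], np.cumsum(w)])
    mism = np.concatenate([[0], np.cumsum(~match)])

    def _valid(a: int, b: int) -> bool:
        length = b - a
        return (length >= min_len
                and (mism[b] - mism[a]) <= max_mismatch_frac * length + 1e-12)

    # Max-sum segment: for each end b, the best start is the first index
    # achieving the running minimum of cum (first occurrence -> longest
    # segment on ties).
    run_min = np.minimum.accumulate(cum[:-1])
    is_new_min = cum[:-1] < np.concatenate([[np.inf], run_min[:-1]])
    amin = np.maximum.accumulate(np.where(is_new_min, np.arange(n), 0))
    scores = cum[1:] - run_min
    # argmax score; among equal scores prefer the larger length (amin is
    # already the leftmost start for each end)
    best_score = scores.max()
    tied = np.where(scores == best_score)[0]
    lengths = (tied + 1) - amin[tied]
    b = int(tied[np.argmax(lengths)] + 1)
    a = int(amin[b - 1])
    if _valid(a, b):
        return int(cum[b] - cum[a]), b - a, a

    # Fallback: best valid window of exactly min_len, then greedy extension.
    if n < min_len:
        return None
    a_arr = np.arange(0, n - min_len + 1)
    win_scores = cum[a_arr + min_len] - cum[a_arr]
    win_valid = (mism[a_arr + min_len] - mism[a_arr]) <= (
        max_mismatch_frac * min_len + 1e-12)
    if not win_valid.any():
        return None
    masked = np.where(win_valid, win_scores, -np.inf)
    a = int(np.argmax(masked))
    b_arr = np.arange(a + min_len, n + 1)
    ext_scores = cum[b_arr] - cum[a]
    ext_valid = (mism[b_arr] - mism[a]) <= (
        max_mismatch_frac * (b_arr - a) + 1e-12)
    masked_ext = np.where(ext_valid, ext_scores, -np.inf)
    best = masked_ext.max()
    # prefer the longest end among score ties
    b = int(b_arr[np.where(masked_ext == best)[0][-1]])
    return int(cum[b] - cum[a]), b - a, a


# ---------------------------------------------------------------------------
# Per-clade census


def census(fragments: Sequence[ViralFragment],
           refs: Optional[Mapping[str, Optional[int]]] = DEFAULT_CLADE_REFS,
           mcp_names: Sequence[str] = ("MCP", "HK97-MCP"),
           ) -> pd.DataFrame:
    """Per-clade summary: total bp covered, MCP hit count, near-complete count.

    When a fragment of one clade lies entirely inside a fragment of another
    clade (a nested insertion), the inner fragment's span is subtracted from
    the outer clade's coverage, so an interrupted element contributes only
    its own (net) sequence.
    """
    clades = sorted({f.clade for f in fragments})
    rows = []
    for clade in clades:
        own = [f for f in fragments if f.clade == clade]
        total = sum(f.length for f in own)
        for f in own:
            for g in fragments:
                if (g.clade != clade and g.scaffold == f.scaffold
                        and g.start >= f.start and g.end <= f.end
                        and g.length < f.length):
                    total -= g.length
        n_mcp = sum(sum(f.marker_names[m] for m in mcp_names) for f in own)
        if refs is not None:
            n_complete = 0
            for f in own:
                frac, near = completeness(f, refs)
                n_complete += bool(near)
        else:
            n_complete = sum(bool(f.near_complete) for f in own)
        rows.append((clade, total, n_mcp, n_complete))
    return pd.DataFrame(rows, columns=["clade", "total_bp", "n_mcp", "n_near_complete"])


# ---------------------------------------------------------------------------
# Output helpers


def fragments_bed_rows(fragments: Sequence[ViralFragment]):
    for f in fragments:
        score = int(round(1000 * f.completeness)) if f.completeness is not None else 0
        yield (f.scaffold, f.start, f.end, f"{f.clade}:{f.fragment_id}", score, ".")


def fragments_gff_features(fragments: Sequence[ViralFragment]) -> List[dict]:
    feats = []
    for f in fragments:
        feats.append({"scaffold": f.scaffold, "start": f.start, "end": f.end,
                      "type": "viral_fragment", "id": f.fragment_id,
                      "attributes": {"clade": f.clade}})
        for i, name in enumerate(sorted(f.marker_names.elements()), 1):
            feats.append({"scaffold": f.scaffold, "start": f.start, "end": f.end,
                          "type": "marker_evidence",
                          "id": f"{f.fragment_id}.m{i}",
                          "parent": f.fragment_id,
                          "attributes": {"marker": name}})
    return feats


def fragments_from_truth(truth) -> List[ViralFragment]:
    """Build fragments directly from a generator TruthSet (oracle path)."""
    frags = []
    for e in truth.elements:
        frags.append(ViralFragment(
            e.scaffold, e.start, e.end, e.clade,
            Counter(name for name, _, _ in e.markers),
            fragment_id=e.element_id, tirs=e.tirs))
    return frags
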