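"""Endogenization evidence per viral fragment.

An integrated, single-copy viral element should sit at ~1x relative depth
(region depth over the assembly-wide median scaffold depth), be flanked by
host sequence of distinctly higher GC, be transcriptionally silent, and keep
a stable relative abundance between read datasets taken years apart. An
episome or active virus instead shows elevated depth on a (nearly) entirely
viral scaffold with no host flanks. This module computes those quantities
and synthesizes them into an integration call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .regions import ViralFragment, NEARLY_ENTIRELY_VIRAL
from .synthetic import gc_content

#: The "<2-fold" band: a region whose depth is within a factor of two of the
#: assembly median is treated as being in a 1:1 ratio with the host genome.
STABLE_BAND = (0.5, 2.0)


@dataclass
class FragmentDiagnostics:
    fragment_id: str
    scaffold: str
    rel_depth: float
    windowed_rel_depth: np.ndarray
    delta_gc: Optional[float]          # percentage points, flank minus fragment
    flank_host_gene: bool
    n_transcript_loci: int
    n_distinct_transcripts: int
    temporal_ratio: Optional[float]
    scaffold_viral_fraction: float
    call: str = ""                     # endogenized | ambiguous | episomal-like


# ---------------------------------------------------------------------------
# Depth


def assembly_median_depth(tracks: Mapping[str, np.ndarray]) -> float:
    """Median over per-scaffold median depths (scaffolds weighted equally)."""
    if not tracks:
        raise ValueError("no depth tracks given")
    return float(np.median([np.median(t) for t in tracks.values()]))


def relative_depth(fragment: ViralFragment, track: Mapping[str, np.ndarray],
                   window: int = 1000,
                   assembly_median: Optional[float] = None,
                   ) -> Tuple[float, np.ndarray]:
    """(median fragment depth / assembly median, per-window mean profile).

    The scalar uses the median within the fragment to resist uneven read
    recruitment; the windowed profile uses means for smoothness. Both are
    normalized by the assembly-wide median scaffold depth.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    if fragment.scaffold not in track:
        raise KeyError(f"no depth track for scaffold {fragment.scaffold}")
    depths = track[fragment.scaffold]
    if fragment.end > len(depths):
        raise ValueError(
            f"fragment {fragment.fragment_id} [{fragment.start},{fragment.end}) "
            f"exceeds the depth track ({len(depths)} bp)")
    if assembly_median is None:
        assembly_median = assembly_median_depth(track)
    seg = depths[fragment.start:fragment.end]
    rel = float(np.median(seg)) / assembly_median
    n_win = max(1, len(seg) // window)
    means = [seg[i * window: (i + 1) * window if i < n_win - 1 else len(seg)].mean()
             for i in range(n_win)]
    return rel, np.asarray(means) / assembly_median


# ---------------------------------------------------------------------------
# GC differential


def gc_differential(fragment: ViralFragment, scaffold_seq: str,
                    other_fragments: Sequence[ViralFragment] = (),
                    flank_len: int = 5000, min_flank_used: int = 500,
                    ) -> Optional[float]:
    """GC%(usable flank) - GC%(fragment), in percentage points; None if the
    usable flank (excluding other viral fragments and scaffold ends) is
    shorter than ``min_flank_used``.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    L = len(scaffold_seq)
    blocked = [(f.start, f.end) for f in other_fragments
               if f is not fragment and f.scaffold == fragment.scaffold]
    flank_parts: List[str] = []
    for lo, hi in ((max(0, fragment.start - flank_len), fragment.start),
                   (fragment.end, min(L, fragment.end + flank_len))):
        mask = np.ones(hi - lo, dtype=bool)
        for s, e in blocked:
            s, e = max(s, lo), min(e, hi)
            if e > s:
                mask[s - lo:e - lo] = False
        part = scaffold_seq[lo:hi]
        flank_parts.append("".join(c for c, keep in zip(part, mask) if keep))
    flank = "".join(flank_parts)
    if len(flank) < min_flank_used:
        return None
    frag_seq = scaffold_seq[fragment.start:fragment.end]
    return 100.0 * (gc_content(flank) - gc_content(frag_seq))


# ---------------------------------------------------------------------------
# Viral fraction vs depth correlation


def scaffold_fraction_depth_table(genome: Mapping[str, str],
                                  fragments: Sequence["ViralFragment"],
                                  track: Mapping[str, np.ndarray],
                                  ) -> pd.DataFrame:
    """Per-scaffold viral fraction and relative depth, for the
    fraction-vs-depth correlation.

    Relative depth here is the scaffold's mean depth over the assembly
    median (a continuous summary; the per-fragment diagnostic uses the
    median instead).
    """
    from .regions import viral_fraction
    med = assembly_median_depth(track)
    rows = []
    for name in sorted({f.scaffold for f in fragments}):
        frac, _ = viral_fraction(len(genome[name]),
                                 [f for f in fragments if f.scaffold == name])
        rows.append({"scaffold": name, "viral_fraction": frac,
                     "rel_depth": float(track[name].mean()) / med})
    return pd.DataFrame(rows)


@dataclass
class CorrelationSummary:
    rho: Optional[float]
    p_value: Optional[float]
    n: int
    n_permutations: int = 0


def fraction_depth_correlation(table: pd.DataFrame, n_permutations: int = 999,
                               seed: int = 0) -> CorrelationSummary:
    """Spearman correlation between per-scaffold viral fraction and relative
    depth, with a permutation significance summary.

    ``table`` needs columns ``viral_fraction`` and ``rel_depth``, one row per
    scaffold carrying fragments. Fewer than 3 rows, or a constant column,
    yields rho=None (not applicable).
    """
    frac = table["viral_fraction"].to_numpy(dtype=float)
    depth = table["rel_depth"].to_numpy(dtype=float)
    n = len(frac)
    if n < 3 or np.ptp(frac) == 0 or np.ptp(depth) == 0:
        return CorrelationSummary(None, None, n)
    rho = float(stats.spearmanr(frac, depth).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stats.spearmanr(frac, rng.permutation(depth)).statistic
    p = (1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / (1 + n_permutations)
    return CorrelationSummary(rho, float(p), n, n_permutations)


# ---------------------------------------------------------------------------
# Transcript silence


def transcript_silence(fragments: Sequence[ViralFragment],
                       loci: pd.DataFrame) -> Tuple[int, int]:
    """(loci overlapping any fragment by >= 1 bp, distinct identity keys among them).

    ``loci`` is BED6-shaped with the sequence-identity key in ``name``.
    (0, 0) means the fragment set is transcriptionally silent.
    """
    by_scaffold: Dict[str, List[Tuple[int, int]]] = {}
    for f in fragments:
        by_scaffold.setdefault(f.scaffold, []).append((f.start, f.end))
    n_loci = 0
    keys = set()
    for row in loci.itertuples(index=False):
        for s, e in by_scaffold.get(row.scaffold, ()):
            if row.start < e and row.end > s:
                n_loci += 1
                keys.add(row.name)
                break
    return n_loci, len(keys)


# ---------------------------------------------------------------------------
# Temporal stability


def temporal_stability(fragment: ViralFragment,
                       track_a: Mapping[str, np.ndarray],
                       track_b: Mapping[str, np.ndarray],
                       stable_band: Tuple[float, float] = STABLE_BAND,
                       ) -> Tuple[Optional[float], Optional[bool]]:
    """Ratio of relative depths between two datasets (B over A), each
    normalized by its own assembly median; stable iff the ratio lies inside
    ``stable_band``. (None, None) when the fragment has zero depth in A.
    """
    rel_a, _ = relative_depth(fragment, track_a)
    rel_b, _ = relative_depth(fragment, track_b)
    if rel_a == 0:
        return None, None
    ratio = rel_b / rel_a
    return ratio, stable_band[0] <= ratio <= stable_band[1]


# ---------------------------------------------------------------------------
# Integration call


def integration_call(rel_depth: float, delta_gc: Optional[float],
                     flank_host_gene: bool, scaffold_viral_fraction: float,
                     stable_band: Tuple[float, float] = STABLE_BAND) -> str:
    """Synthesize the evidence into endogenized / episomal-like / ambiguous.

    Endogenized: depth within the <2-fold band of the assembly median AND
    host context on at least one side (a usable flank with a computable GC
    differential, or an annotated host gene in the flank). Episomal-like: a
    nearly entirely viral scaffold at >2x depth. Anything else: ambiguous.
    """
    lo, hi = stable_band
    has_host_context = delta_gc is not None or flank_host_gene
    if lo <= rel_depth <= hi and has_host_context:
        return "endogenized"
    if scaffold_viral_fraction > NEARLY_ENTIRELY_VIRAL and rel_depth > hi:
        return "episomal-like"
    return "ambiguous"


# ---------------------------------------------------------------------------
# Cohort driver


def diagnose_fragments(fragments: Sequence[ViralFragment],
                       genome: Mapping[str, str],
                       track_a: Mapping[str, np.ndarray],
                       track_b: Optional[Mapping[str, np.ndarray]] = None,
                       transcripts: Optional[pd.DataFrame] = None,
                       host_gene_flanks: Optional[pd.DataFrame] = None,
                       flank_len: int = 5000, min_flank_used: int = 500,
                       window: int = 1000) -> List[FragmentDiagnostics]:
    """Run the full evidence suite for every fragment (scaffold-order invariant)."""
    med_a = assembly_median_depth(track_a)
    med_b = assembly_median_depth(track_b) if track_b else None
    from .regions import viral_fraction
    frac_by_scaffold = {
        name: viral_fraction(len(genome[name]),
                             [f for f in fragments if f.scaffold == name])[0]
        for name in sorted({f.scaffold for f in fragments})
    }
    out: List[FragmentDiagnostics] = []
    for f in sorted(fragments, key=lambda f: (f.scaffold, f.start, f.clade)):
        rel, profile = relative_depth(f, track_a, window, med_a)
        dgc = gc_differential(f, genome[f.scaffold], fragments,
                              flank_len, min_flank_used)
        host_gene = False
        if host_gene_flanks is not None:
            for row in host_gene_flanks.itertuples(index=False):
                if (row.scaffold == f.scaffold
                        and row.start < f.end + flank_len
                        and row.end > f.start - flank_len
                        and not (row.start >= f.start and row.end <= f.end)):
                    host_gene = True
                    break
        n_loci, n_distinct = (0, 0)
        if transcripts is not None:
            n_loci, n_distinct = transcript_silence([f], transcripts)
        ratio = None
        if track_b is not None:
            rel_b, _ = relative_depth(f, track_b, window, med_b)
            ratio = rel_b / rel if rel > 0 else None
        diag = FragmentDiagnostics(
            fragment_id=f.fragment_id, scaffold=f.scaffold, rel_depth=rel,
            windowed_rel_depth=profile, delta_gc=dgc, flank_host_gene=host_gene,
            n_transcript_loci=n_loci, n_distinct_transcripts=n_distinct,
            temporal_ratio=ratio,
            scaffold_viral_fraction=frac_by_scaffold[f.scaffold])
        diag.call = integration_call(rel, dgc, host_gene,
                                     diag.scaffold_viral_fraction)
        out.append(diag)
    return out


def diagnostics_table(diags: Sequence[FragmentDiagnostics]) -> pd.DataFrame:
    rows = []
    for d in diags:
        rows.append({
            "fragment_id": d.fragment_id, "scaffold": d.scaffold,
            "rel_depth": d.rel_depth, "delta_gc": d.delta_gc,
            "flank_host_gene": d.flank_host_gene,
            "n_transcript_loci": d.n_transcript_loci,
            "n_distinct_transcripts": d.n_distinct_transcripts,
            "temporal_ratio": d.temporal_ratio,
            "scaffold_viral_fraction": d.scaffold_viral_fraction,
            "call": d.call,
        })
    return pd.DataFrame(rows)
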