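"""Element-level evaluation of predicted fragments against a planted truth.

One shared definition for tests and scripts: a planted element is recalled
when fragments of its clade cover at least ``min_cov`` of its span; a
predicted fragment is a true positive when at least ``min_cov`` of its
length lies inside same-clade truth elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .regions import ViralFragment
from .synthetic import TruthSet


@dataclass
class RecoveryReport:
    recall: float
    precision: float
    n_truth: int
    n_fragments: int
    exact_boundaries: int  # fragments equal to a truth element's exact span


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def evaluate_recovery(truth: TruthSet, fragments: Sequence[ViralFragment],
                      min_cov: float = 0.8) -> RecoveryReport:
    frag_by_key: Dict[Tuple[str, str], List[ViralFragment]] = {}
    for f in fragments:
        frag_by_key.setdefault((f.scaffold, f.clade), []).append(f)

    recalled = 0
    for e in truth.elements:
        covered = sum(_overlap((e.start, e.end), (f.start, f.end))
                      for f in frag_by_key.get((e.scaffold, e.clade), []))
        if covered >= min_cov * e.length:
            recalled += 1

    true_pos = 0
    exact = 0
    for f in fragments:
        inside = 0
        for e in truth.elements:
            if e.scaffold == f.scaffold and e.clade == f.clade:
                inside += _overlap((e.start, e.end), (f.start, f.end))
                if (e.start, e.end) == (f.start, f.end):
                    exact += 1
        if f.length > 0 and inside >= min_cov * f.length:
            true_pos += 1

    n_truth = len(truth.elements)
    n_frag = len(fragments)
    return RecoveryReport(
        recall=recalled / n_truth if n_truth else 1.0,
        precision=true_pos / n_frag if n_frag else 1.0,
        n_truth=n_truth, n_fragments=n_frag, exact_boundaries=exact)
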