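"""Seed-controlled generator for host genomes with planted viral elements.

The generator emulates the situation in a repeat-rich algal assembly carrying
endogenized viral elements: a multi-scaffold host at a base GC content,
planted elements at a shifted (by default lower) GC, terminal inverted
repeats (TIRs) at element boundaries, nested insertions (a small element
interrupting a larger one), single- vs multi-copy depth signatures with
Poisson counting noise, marker-hit tables standing in for a homology search,
transcript loci, and polyploid biallelic SNP allele counts.

Everything is driven by explicit integer seeds; identical seeds give
byte-identical outputs. Coordinates are 0-based, half-open. The ``TruthSet``
records every planted feature and is the oracle downstream tests compare
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CLADES = ("PLVA", "PLVB", "PLV2", "NCLDV", "CHeCME")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: The nine core phylogenetic markers screened for in giant-virus (NCLDV)
#: fragments. User-overridable wherever it is consumed.
NINE_NCLDV_MARKERS = (
    "RNAPL", "RNAPS", "TFIIS", "VLTF3", "MCP", "pPolB", "A32", "D5", "RNR",
)

#: Per-clade gene vocabularies used by the default marker layout.
CLADE_MARKER_VOCAB: Dict[str, Tuple[str, ...]] = {
    "PLVA": ("MCP", "mCP", "A32", "pPolB", "Yrec", "DUF2190"),
    "PLVB": ("MCP", "mCP", "A32", "TVpol-SH3", "DDE", "pgvv05"),
    "PLV2": ("MCP", "mCP", "A32", "Tlr6F", "lipase", "pPolB"),
    "NCLDV": NINE_NCLDV_MARKERS + ("penton", "mCP"),
    "CHeCME": ("heliorhodopsin", "HK97-MCP", "SF1-helicase", "portal", "lipase"),
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous (ACGT) bases."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    acgt = np.isin(arr, _BASES)
    n = int(acgt.sum())
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return int(np.isin(arr, np.frombuffer(b"GC", dtype="S1")).sum()) / n


# ---------------------------------------------------------------------------
# Specs and truth bookkeeping


@dataclass(frozen=True)
class HostGenomeSpec:
    """Parameters of the synthetic host assembly."""

    n_scaffolds: int
    length_range: Tuple[int, int]
    base_gc: float
    seed: int

    def validate(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        lo, hi = self.length_range
        if lo < 1000 or hi < lo:
            raise ValueError("length_range must satisfy 1000 <= min <= max")
        if not 0.0 <= self.base_gc <= 1.0:
            raise ValueError(f"base_gc must be in [0, 1], got {self.base_gc}")


@dataclass
class PlantSpec:
    """One viral element to plant.

    ``gc_offset`` is in percentage points relative to the host base GC
    (negative = GC-poorer than host, the default expectation for these
    elements). ``markers`` are (name, offset_bp, length_bp) triples relative
    to the element start; ``copy_number`` is the genomic copy number the
    depth simulator realizes as a coverage multiplier. ``nested_in`` points
    at the index of an earlier plant this element interrupts.
    ``whole_scaffold`` plants the element across an entire scaffold
    (episome-like layout).
    """

    clade: str
    length_bp: int
    gc_offset: float = -10.0
    tir_len: int = 0
    markers: Optional[List[Tuple[str, int, int]]] = None
    copy_number: int = 1
    nested_in: Optional[int] = None
    whole_scaffold: bool = False

    def validate(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}; expected one of {CLADES}")
        if self.length_bp < 1:
            raise ValueError("length_bp must be positive")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.tir_len < 0 or 2 * self.tir_len >= self.length_bp:
            raise ValueError("tir_len must satisfy 0 <= 2*tir_len < length_bp")
        for name, off, mlen in self.markers or []:
            if off < 0 or off + mlen > self.length_bp:
                raise ValueError(f"marker {name!r} does not fit inside the element")


def default_marker_layout(clade: str, length_bp: int,
                          marker_len: int = 900, gap: int = 500,
                          ) -> List[Tuple[str, int, int]]:
    """Tile an element with gene-like marker intervals.

    Markers start at the element's first base and the final marker ends at its
    last base, emulating the gene-dense layout of these viral elements; names
    cycle through the clade's vocabulary (for NCLDV the nine core markers come
    first, so any element long enough carries all nine).
    """
    vocab = CLADE_MARKER_VOCAB[clade]
    if length_bp < marker_len:
        return [(vocab[0], 0, length_bp)]
    layout: List[Tuple[str, int, int]] = []
    pos, i = 0, 0
    while pos + marker_len <= length_bp:
        layout.append((vocab[i % len(vocab)], pos, marker_len))
        pos += marker_len + gap
        i += 1
    last_start = length_bp - marker_len
    if layout[-1][1] < last_start:
        layout.append((vocab[i % len(vocab)], last_start, marker_len))
    return layout


@dataclass
class PlantedElement:
    """Truth record for one planted element (all coordinates scaffold-absolute)."""

    element_id: str
    scaffold: str
    start: int
    end: int
    clade: str
    copy_number: int
    gc_offset: float
    tirs: Optional[Tuple[Tuple[int, int], Tuple[int, int]]]
    markers: List[Tuple[str, int, int]]
    parent: Optional[int] = None  # index into TruthSet.elements

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Ledger of everything the generator planted; the oracle for every test."""

    elements: List[PlantedElement] = field(default_factory=list)
    ploidy: Optional[int] = None
    mean_depths: List[float] = field(default_factory=list)

    def elements_on(self, scaffold: str) -> List[PlantedElement]:
        return [e for e in self.elements if e.scaffold == scaffold]

    def net_span(self, index: int) -> int:
        """Element length minus the lengths of elements nested inside it."""
        elem = self.elements[index]
        inserted = sum(e.length for i, e in enumerate(self.elements) if e.parent == index)
        return elem.length - inserted

    def copy_number_track(self, scaffold: str, length: int) -> np.ndarray:
        """Per-base copy number; children override their parents."""
        track = np.ones(length, dtype=np.int64)
        order = sorted(range(len(self.elements)),
                       key=lambda i: 0 if self.elements[i].parent is None else 1)
        for i in order:
            e = self.elements[i]
            if e.scaffold == scaffold:
                track[e.start:e.end] = e.copy_number
        return track

    def element_bed_rows(self):
        for e in self.elements:
            yield (e.scaffold, e.start, e.end, f"{e.clade}:{e.element_id}", 0, ".")

    def marker_bed_rows(self):
        for e in self.elements:
            for name, s, t in e.markers:
                yield (e.scaffold, s, t, f"{e.clade}:{e.element_id}:{name}", 0, "+")

    def tir_bed_rows(self):
        for e in self.elements:
            if e.tirs is not None:
                for (s, t), tag in zip(e.tirs, ("tirL", "tirR")):
                    yield (e.scaffold, s, t, f"{e.clade}:{e.element_id}:{tag}", 0, ".")


# ---------------------------------------------------------------------------
# Sequence generation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    gc = min(max(gc, 0.0), 1.0)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def generate_host(spec: HostGenomeSpec) -> Dict[str, str]:
    """Generate the host assembly: i.i.d. bases with P(G or C) = base_gc."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    widths = max(5, len(str(spec.n_scaffolds)))
    genome: Dict[str, str] = {}
    for i in range(spec.n_scaffolds):
        length = int(rng.integers(lo, hi + 1))
        genome[f"scaffold_{i + 1:0{widths}d}"] = _random_sequence(rng, length, spec.base_gc)
    return genome


def _free_gaps(length: int, occupied: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    gaps, prev = [], 0
    for s, e in sorted(occupied):
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        gaps.append((prev, length))
    return gaps


def plant_elements(genome: Mapping[str, str], plants: Sequence[PlantSpec],
                   seed: int, min_flank: int = 2000,
                   base_gc: Optional[float] = None,
                   ) -> Tuple[Dict[str, str], TruthSet]:
    """Overwrite genomic segments with viral-element sequence; return truth.

    Elements are placed with at least ``min_flank`` bases of clearance from
    scaffold ends and from each other (whole-scaffold plants excepted).
    Element sequence is i.i.d. at ``base_gc + gc_offset`` percentage points;
    TIRs are exact reverse complements at the two termini. Nested plants are
    placed in a gap between their parent's markers and recorded with a parent
    pointer.
    """
    rng = np.random.default_rng(seed)
    new_genome = dict(genome)
    if base_gc is None:
        base_gc = gc_content("".join(genome.values()))
    occupied: Dict[str, List[Tuple[int, int]]] = {name: [] for name in genome}
    truth = TruthSet()
    counts: Dict[str, int] = {}

    for idx, plant in enumerate(plants):
        plant.validate()
        if plant.nested_in is not None:
            scaffold, start = _place_nested(plant, truth, rng)
        elif plant.whole_scaffold:
            candidates = sorted(name for name, ivs in occupied.items()
                                if not ivs and len(new_genome[name]) >= plant.length_bp)
            if not candidates:
                raise ValueError(f"no free scaffold can hold whole-scaffold plant {idx}")
            scaffold = candidates[int(rng.integers(len(candidates)))]
            start = 0
            plant = PlantSpec(**{**plant.__dict__,
                                 "length_bp": len(new_genome[scaffold]),
                                 "markers": plant.markers})
        else:
            scaffold, start = _place_free(plant, new_genome, occupied, min_flank, rng)

        end = start + plant.length_bp
        seq = _random_sequence(rng, plant.length_bp, base_gc + plant.gc_offset / 100.0)
        tirs = None
        if plant.tir_len > 0:
            left = seq[:plant.tir_len]
            seq = seq[:plant.length_bp - plant.tir_len] + reverse_complement(left)
            tirs = ((start, start + plant.tir_len), (end - plant.tir_len, end))
        new_genome[scaffold] = (new_genome[scaffold][:start] + seq
                                + new_genome[scaffold][end:])

        markers = plant.markers
        if markers is None:
            markers = default_marker_layout(plant.clade, plant.length_bp)
        abs_markers = [(name, start + off, start + off + mlen)
                       for name, off, mlen in markers]
        counts[plant.clade] = counts.get(plant.clade, 0) + 1
        truth.elements.append(PlantedElement(
            element_id=f"{plant.clade}_{counts[plant.clade]:03d}",
            scaffold=scaffold, start=start, end=end, clade=plant.clade,
            copy_number=plant.copy_number, gc_offset=plant.gc_offset,
            tirs=tirs, markers=abs_markers, parent=plant.nested_in,
        ))
        occupied[scaffold].append((start, end))
    return new_genome, truth


def _place_free(plant: PlantSpec, genome: Mapping[str, str],
                occupied: Dict[str, List[Tuple[int, int]]],
                min_flank: int, rng: np.random.Generator) -> Tuple[str, int]:
    slots: List[Tuple[str, int, int]] = []  # (scaffold, first_start, n_starts)
    total = 0
    for name in sorted(genome):
        for g0, g1 in _free_gaps(len(genome[name]), occupied[name]):
            lo = g0 + min_flank
            hi = g1 - min_flank - plant.length_bp
            if hi >= lo:
                slots.append((name, lo, hi - lo + 1))
                total += hi - lo + 1
    if total == 0:
        raise ValueError(
            f"no scaffold has room for a {plant.length_bp} bp element "
            f"with {min_flank} bp flanks")
    r = int(rng.integers(total))
    for name, lo, n in slots:
        if r < n:
            return name, lo + r
        r -= n
    raise AssertionError("unreachable")


def _place_nested(plant: PlantSpec, truth: TruthSet,
                  rng: np.random.Generator) -> Tuple[str, int]:
    parent = truth.elements[plant.nested_in]
    blocked = [(s, t) for _, s, t in parent.markers]
    if parent.tirs is not None:
        blocked.extend(parent.tirs)
    blocked = [(s - parent.start, t - parent.start) for s, t in blocked]
    starts: List[Tuple[int, int]] = []
    total = 0
    for g0, g1 in _free_gaps(parent.length, blocked):
        hi = g1 - plant.length_bp
        if hi >= g0:
            starts.append((g0, hi - g0 + 1))
            total += hi - g0 + 1
    if total == 0:
        # no marker-free gap large enough: the insert interrupts parent
        # genes; overlapped parent markers are dropped from the truth
        lo = 0 if parent.tirs is None else parent.tirs[0][1] - parent.start
        hi = (parent.length if parent.tirs is None
              else parent.tirs[1][0] - parent.start) - plant.length_bp
        if hi < lo:
            raise ValueError(
                f"parent element {parent.element_id} is too short for a "
                f"{plant.length_bp} bp nested plant")
        start = parent.start + lo + int(rng.integers(hi - lo + 1))
        end = start + plant.length_bp
        parent.markers = [(n_, s, t) for n_, s, t in parent.markers
                          if t <= start or s >= end]
        return parent.scaffold, start
    r = int(rng.integers(total))
    for lo, n in starts:
        if r < n:
            return parent.scaffold, parent.start + lo + r
        r -= n
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Depth simulation


def simulate_depth(genome: Mapping[str, str], truth: TruthSet, mean_depth: float,
                   n_datasets: int = 2, drift: float = 0.0, seed: int = 0,
                   ) -> List[Dict[str, np.ndarray]]:
    """Per-base Poisson depth tracks, one dict per read dataset.

    depth ~ Poisson(mean_depth * copy_number(position) * dataset_factor) with
    dataset_factor = 1 + drift * dataset_index (dataset 1 is the reference).
    Realized per-dataset genome-wide means are recorded in
    ``truth.mean_depths``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    tracks: List[Dict[str, np.ndarray]] = []
    truth.mean_depths = []
    for d in range(n_datasets):
        factor = 1.0 + drift * d
        per_scaffold: Dict[str, np.ndarray] = {}
        total, nbases = 0, 0
        for name in genome:
            cn = truth.copy_number_track(name, len(genome[name]))
            lam = mean_depth * factor * cn
            track = rng.poisson(lam)
            per_scaffold[name] = track
            total += int(track.sum())
            nbases += len(track)
        tracks.append(per_scaffold)
        truth.mean_depths.append(total / nbases)
    return tracks


# ---------------------------------------------------------------------------
# Marker-hit simulation (stands in for an upstream homology search)


def simulate_marker_hits(truth: TruthSet, scaffold_lengths: Mapping[str, int],
                         fpr: float = 0.0, fnr: float = 0.0,
                         jitter_bp: int = 0, seed: int = 0) -> pd.DataFrame:
    """Emit a hit table: one jittered hit per planted marker, plus noise.

    Each true marker is dropped with probability ``fnr``; surviving endpoints
    are jittered independently, uniformly in ±``jitter_bp``, and clipped to
    the scaffold. Spurious hits are added per scaffold at Poisson rate
    ``fpr`` with clade ``unknown``.
    """
    if not (0 <= fpr < 1 and 0 <= fnr <= 1):
        raise ValueError("fpr must be in [0,1) and fnr in [0,1]")
    rng = np.random.default_rng(seed)
    rows = []
    for elem in truth.elements:
        scaf_len = scaffold_lengths[elem.scaffold]
        for name, s, t in elem.markers:
            if fnr > 0 and rng.random() < fnr:
                continue
            if jitter_bp > 0:
                s = s + int(rng.integers(-jitter_bp, jitter_bp + 1))
                t = t + int(rng.integers(-jitter_bp, jitter_bp + 1))
            s, t = max(0, min(s, t)), min(scaf_len, max(s, t))
            if t <= s:
                t = min(scaf_len, s + 1)
            rows.append((elem.scaffold, s, t, "+", name, elem.clade,
                         round(float(rng.uniform(50, 100)), 1)))
    if fpr > 0:
        for name in sorted(scaffold_lengths):
            for _ in range(int(rng.poisson(fpr))):
                length = int(rng.integers(300, 901))
                scaf_len = scaffold_lengths[name]
                if scaf_len <= length:
                    continue
                s = int(rng.integers(0, scaf_len - length))
                rows.append((name, s, s + length, "+", "spurious", "unknown",
                             round(float(rng.uniform(20, 50)), 1)))
    from .io import HITS_COLUMNS
    return pd.DataFrame(rows, columns=HITS_COLUMNS)


# ---------------------------------------------------------------------------
# Transcript loci


def simulate_transcript_loci(truth: TruthSet, scaffold_lengths: Mapping[str, int],
                             n_element_loci: int, n_distinct: int,
                             n_background: int = 0, locus_len: int = 500,
                             seed: int = 0) -> pd.DataFrame:
    """Transcript alignment loci (BED6-shaped), name = sequence-identity key.

    ``n_element_loci`` loci fall inside planted elements and share
    ``n_distinct`` identity keys; ``n_background`` loci land anywhere.
    """
    rng = np.random.default_rng(seed)
    rows = []
    if n_element_loci > 0 and not truth.elements:
        raise ValueError("cannot place element loci without planted elements")
    for i in range(n_element_loci):
        elem = truth.elements[int(rng.integers(len(truth.elements)))]
        width = min(locus_len, elem.length)
        s = elem.start + int(rng.integers(0, elem.length - width + 1))
        key = f"tcluster_{(i % max(n_distinct, 1)) + 1:03d}"
        rows.append((elem.scaffold, s, s + width, key, 0, "+"))
    names = sorted(scaffold_lengths)
    for i in range(n_background):
        name = names[int(rng.integers(len(names)))]
        scaf_len = scaffold_lengths[name]
        width = min(locus_len, scaf_len - 1)
        s = int(rng.integers(0, scaf_len - width))
        rows.append((name, s, s + width, f"bg_{i + 1:03d}", 0, "+"))
    from .io import BED6_COLUMNS
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


# ---------------------------------------------------------------------------
# Polyploid SNP allele counts


def simulate_allele_counts(ploidy: int, n_snps: int, depth: int,
                           error_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Biallelic SNP read counts for a genome of the given ploidy.

    Per site the true alternate-allele dosage k is uniform on 1..ploidy-1 and
    alt_count ~ Binomial(depth, p) with p = (k/ploidy)(1-e) + (1-k/ploidy)e,
    e being the per-read error rate.
    """
    if ploidy <= 1:
        raise ValueError("ploidy must be >= 2: a haploid genome has no "
                         "heterozygous sites to draw allele frequencies from")
    if depth < 1 or n_snps < 0:
        raise ValueError("depth must be >= 1 and n_snps >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    k = rng.integers(1, ploidy, size=n_snps)
    p = (k / ploidy) * (1 - error_rate) + (1 - k / ploidy) * error_rate
    alt = rng.binomial(depth, p)
    from .io import ALLELE_COLUMNS
    return pd.DataFrame({
        "scaffold": "snp_scaffold",
        "pos": np.arange(1, n_snps + 1),
        "ref_count": depth - alt,
        "alt_count": alt,
    }, columns=ALLELE_COLUMNS)
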