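"""Peak-to-gene assignment and target-class decomposition.

A peak is assigned to a gene when its representative point (summit, else
midpoint) falls inside the gene's strand-aware composite window: a promoter
stretch upstream of the TSS, the gene body, and a short downstream stretch
past the TES. Offsets are measured from the TSS in transcription direction,
so a promoter point has a negative offset regardless of strand.

Sub-window boundaries are half-open on the downstream edge::

    promoter   : offset in [-promoter_bp, 0)
    body       : offset in [0, L)          with L = |TES - TSS|
    three_prime: offset in [L, L + downstream_bp)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import ValidationError, UsageError
from .io import GeneModel, PeakSet

__all__ = [
    "PeakHit",
    "TargetAssignment",
    "TargetClasses",
    "assign_peaks_to_genes",
    "classify_targets",
]

REGION_PROMOTER = "promoter"
REGION_BODY = "body"
REGION_THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class PeakHit:
    """One peak assigned to one gene: which sub-window its representative
    point fell into and the strand-aware signed offset from the TSS."""

    peak_id: str
    region: str
    offset: int


@dataclass
class TargetAssignment:
    """Per-gene lists of assigned peaks for one factor."""

    factor_label: str
    hits: dict[str, list[PeakHit]] = field(default_factory=dict)
    n_skipped_chroms: int = 0

    @property
    def target_genes(self) -> set[str]:
        return set(self.hits)

    def offsets(self, gene_id: str) -> list[int]:
        return [h.offset for h in self.hits[gene_id]]

    def n_assigned(self) -> int:
        return sum(len(v) for v in self.hits.values())


@dataclass
class TargetClasses:
    """Decomposition of two factors' target gene sets.

    ``shared`` is the intersection; ``a_only``/``b_only`` the set
    differences; ``shared_fraction_a`` = |shared| / |targets(A)| (and
    likewise for B) — the headline "fraction of each factor's targets that
    are co-bound".
    """

    a_only: set[str]
    b_only: set[str]
    shared: set[str]
    universe_size: int

    @property
    def n_a(self) -> int:
        return len(self.a_only) + len(self.shared)

    @property
    def n_b(self) -> int:
        return len(self.b_only) + len(self.shared)

    @property
    def shared_fraction_a(self) -> float:
        return len(self.shared) / self.n_a if self.n_a else float("nan")

    @property
    def shared_fraction_b(self) -> float:
        return len(self.shared) / self.n_b if self.n_b else float("nan")


def _offset(gene: GeneModel, point: int) -> int:
    """Signed strand-aware offset of a genomic point from the gene's TSS."""
    return point - gene.tss if gene.strand == "+" else gene.tss - point


def _region_for_offset(offset: int, body_len: int, promoter_bp: int, downstream_bp: int) -> str | None:
    if -promoter_bp <= offset < 0:
        return REGION_PROMOTER
    if 0 <= offset < body_len:
        return REGION_BODY
    if body_len <= offset < body_len + downstream_bp:
        return REGION_THREE_PRIME
    return None


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: list[GeneModel],
    promoter_bp: int = 5000,
    downstream_bp: int = 1000,
    policy: str = "nearest_tss",
) -> TargetAssignment:
    """Assign each peak's representative point to gene windows.

    Under ``policy="nearest_tss"`` a point inside several genes' windows is
    assigned only to the gene minimizing ``|point - TSS|`` (ties broken by
    lexicographic gene_id); under ``policy="all"`` every containing gene
    receives the peak. Peaks on chromosomes absent from the annotation are
    skipped with a warning carrying the count.
    """
    if policy not in ("nearest_tss", "all"):
        raise UsageError(f"unknown assignment policy {policy!r}")
    if not genes:
        raise ValidationError("empty gene collection")

    by_id: dict[str, GeneModel] = {}
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.gene_id in by_id:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        by_id[g.gene_id] = g
        pad = promoter_bp + downstream_bp + 1
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start - pad, g.end + pad, g.gene_id)

    result = TargetAssignment(factor_label=peaks.factor_label)
    n_skipped = 0
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            n_skipped += 1
            continue
        point = peak.point
        candidates: list[tuple[int, str, str, int]] = []  # (|offset from tss|, gene_id, region, offset)
        for iv in tree.at(point):
            gene = by_id[iv.data]
            off = _offset(gene, point)
            body_len = abs(gene.tes - gene.tss)
            region = _region_for_offset(off, body_len, promoter_bp, downstream_bp)
            if region is not None:
                candidates.append((abs(off), gene.gene_id, region, off))
        if not candidates:
            continue
        if policy == "nearest_tss":
            candidates = [min(candidates, key=lambda c: (c[0], c[1]))]
        for _, gid, region, off in candidates:
            result.hits.setdefault(gid, []).append(
                PeakHit(peak_id=peak.peak_id, region=region, offset=off)
            )
    # deterministic ordering regardless of peak input order
    for gid in result.hits:
        result.hits[gid].sort(key=lambda h: (h.offset, h.peak_id))
    result.hits = dict(sorted(result.hits.items()))
    result.n_skipped_chroms = n_skipped
    if n_skipped:
        warnings.warn(
            f"{peaks.factor_label}: skipped {n_skipped} peak(s) on chromosomes absent "
            "from the annotation",
            stacklevel=2,
        )
    return result


def classify_targets(
    assign_a: TargetAssignment,
    assign_b: TargetAssignment,
    universe: set[str],
) -> TargetClasses:
    """Decompose two factors' target sets into A-only / B-only / shared.

    ``universe`` is the set of genes both ChIP experiments could in principle
    have hit (the annotation); it must contain every target.
    """
    ta, tb = assign_a.target_genes, assign_b.target_genes
    stray = (ta | tb) - universe
    if stray:
        raise ValidationError(
            f"target gene(s) absent from universe: {sorted(stray)[:5]}"
        )
    shared = ta & tb
    return TargetClasses(
        a_only=ta - shared,
        b_only=tb - shared,
        shared=shared,
        universe_size=len(universe),
    )
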