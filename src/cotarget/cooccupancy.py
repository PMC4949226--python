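"""Co-occupancy statistics.

Three questions about two factors' binding:

1. Do they share more target genes than chance? — upper-tail hypergeometric
   test on the overlap of the two target sets, computed in log space so that
   extremely small probabilities (far below the smallest positive float)
   remain representable as log10 values.

2. Do they bind closer together on shared promoters than chance? — observed
   inter-peak distances on shared genes versus a permutation null built by
   re-pairing each shared gene's factor-A peaks with the factor-B peaks of a
   *different* randomly drawn shared gene ("random target promoters").
   Re-pairing operates on TSS-relative offsets so distances stay comparable
   across genes; the null preserves each factor's marginal positional
   distribution and destroys only the within-promoter coupling.

3. Where do they bind along a metagene? — peak-density histogram over
   fixed-width promoter and downstream bins plus a length-normalized gene
   body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import UsageError, ValidationError
from .io import GeneModel
from .targets import TargetAssignment

__all__ = [
    "OverlapStat",
    "DistancePair",
    "ProximityResult",
    "MetageneProfile",
    "hypergeometric_overlap",
    "interpeak_distances",
    "fraction_within",
    "proximity_permutation_test",
    "metagene_profile",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class OverlapStat:
    """Hypergeometric overlap of two target sets in one gene universe."""

    n_a: int
    n_b: int
    n_shared: int
    universe_size: int
    log10_p_upper: float
    fold_enrichment: float

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.universe_size


@dataclass(frozen=True)
class DistancePair:
    """One shared gene's closest cross-factor peak pair."""

    gene_id: str
    peak_id_a: str
    peak_id_b: str
    distance: int


@dataclass
class ProximityResult:
    observed: list[DistancePair]
    statistic_name: str
    observed_statistic: float
    null_statistics: np.ndarray
    p_empirical: float
    n_permutations: int
    threshold_bp: int
    seed: int


@dataclass
class MetageneProfile:
    """Per-bin peak counts/densities along promoter | body | 3' regions."""

    promoter_bp: int
    n_promoter_bins: int
    n_body_bins: int
    downstream_bp: int
    n_downstream_bins: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_skipped: dict[str, int] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.n_promoter_bins + self.n_body_bins + self.n_downstream_bins

    @property
    def densities(self) -> dict[str, np.ndarray]:
        out = {}
        for label, c in self.counts.items():
            total = c.sum()
            out[label] = c / total if total > 0 else c.astype(float)
        return out

    def bin_labels(self) -> list[str]:
        labels = []
        w = self.promoter_bp / self.n_promoter_bins
        for i in range(self.n_promoter_bins):
            labels.append(f"promoter:{-self.promoter_bp + i * w:.0f}")
        for i in range(self.n_body_bins):
            labels.append(f"body:{i / self.n_body_bins:.3f}")
        w = self.downstream_bp / self.n_downstream_bins
        for i in range(self.n_downstream_bins):
            labels.append(f"three_prime:+{i * w:.0f}")
        return labels


# ---------------------------------------------------------------------------
# Overlap significance
# ---------------------------------------------------------------------------


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n), via log-gamma."""

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(K, k) + lchoose(N - K, n - k) - lchoose(N, n)


def hypergeometric_overlap(
    n_a: int, n_b: int, n_shared: int, universe_size: int
) -> OverlapStat:
    """Upper-tail hypergeometric test of target-set overlap.

    Returns P(X >= n_shared) for X ~ Hypergeometric(universe_size, n_a, n_b)
    as a log10 value, plus fold enrichment observed/expected. Symmetric in
    (n_a, n_b). Computed by log-sum-exp over the exact pmf terms, so p-values
    like 1e-90 and far smaller are exact in log space.
    """
    N, K, n, k = universe_size, n_a, n_b, n_shared
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"need n_a, n_b in [0, universe]: ({K}, {n}, N={N})")
    k_min = max(0, K + n - N)
    k_max = min(K, n)
    if not (k_min <= k <= k_max):
        raise ValidationError(
            f"impossible overlap {k}: must lie in [{k_min}, {k_max}] "
            f"for n_a={K}, n_b={n}, universe={N}"
        )
    if k == k_min:
        log10_p = 0.0
    else:
        ks = np.arange(k, k_max + 1)
        log10_p = float(logsumexp(_log_hypergeom_pmf(ks, N, K, n)) / _LN10)
        log10_p = min(log10_p, 0.0)
    expected = K * n / N if N else float("nan")
    fold = k / expected if expected > 0 else float("nan")
    return OverlapStat(
        n_a=K,
        n_b=n,
        n_shared=k,
        universe_size=N,
        log10_p_upper=log10_p,
        fold_enrichment=fold,
    )


# ---------------------------------------------------------------------------
# Inter-peak distances and the random-target-promoter null
# ---------------------------------------------------------------------------


def _gene_offsets(
    assign: TargetAssignment, shared: set[str]
) -> dict[str, list[tuple[int, str]]]:
    out: dict[str, list[tuple[int, str]]] = {}
    missing = sorted(g for g in shared if g not in assign.hits)
    if missing:
        raise ValidationError(
            f"shared gene(s) lacking a {assign.factor_label} peak: {missing[:5]}"
        )
    for g in sorted(shared):
        out[g] = [(h.offset, h.peak_id) for h in assign.hits[g]]
    return out


def interpeak_distances(
    assign_a: TargetAssignment,
    assign_b: TargetAssignment,
    shared: set[str],
    pairing: str = "nearest",
) -> list[DistancePair]:
    """Cross-factor inter-peak distances on shared genes.

    Distances are |representative point A - representative point B|; since
    both offsets are measured from the same TSS in the same orientation this
    equals the absolute offset difference. Under ``pairing="nearest"`` one
    pair per gene (the minimizing pair, ties broken by peak ids); under
    ``"all_pairs"`` every cross-factor combination.
    """
    if pairing not in ("nearest", "all_pairs"):
        raise UsageError(f"unknown pairing {pairing!r}")
    offs_a = _gene_offsets(assign_a, shared)
    offs_b = _gene_offsets(assign_b, shared)
    pairs: list[DistancePair] = []
    for g in sorted(shared):
        combos = [
            (abs(oa - ob), pa, pb)
            for (oa, pa) in offs_a[g]
            for (ob, pb) in offs_b[g]
        ]
        if pairing == "nearest":
            combos = [min(combos)]
        for d, pa, pb in combos:
            pairs.append(DistancePair(gene_id=g, peak_id_a=pa, peak_id_b=pb, distance=d))
    return pairs


def fraction_within(pairs: list[DistancePair], threshold_bp: int) -> float:
    """Fraction of pairs at distance <= threshold_bp."""
    if not pairs:
        raise ValidationError("no distance pairs")
    return sum(p.distance <= threshold_bp for p in pairs) / len(pairs)


def _nearest_distance(offs_a: list[tuple[int, str]], offs_b: list[tuple[int, str]]) -> int:
    return min(abs(oa - ob) for oa, _ in offs_a for ob, _ in offs_b)


def proximity_permutation_test(
    assign_a: TargetAssignment,
    assign_b: TargetAssignment,
    shared: set[str],
    statistic: str = "median",
    threshold_bp: int = 200,
    n_permutations: int = 999,
    seed: int = 0,
) -> ProximityResult:
    """Permutation test for closer-than-chance co-binding on shared genes.

    Each permutation re-pairs gene g's factor-A peaks with the factor-B peaks
    of a different, uniformly drawn shared gene (self-pairing excluded; a
    derangement is not enforced) and recomputes nearest cross-promoter
    distances on TSS-relative offsets. The empirical p-value uses the
    add-one (1+b)/(1+m) estimator: lower tail for ``median`` (closer than
    chance), upper tail for ``fraction_within``.
    """
    if statistic not in ("median", "fraction_within"):
        raise UsageError(f"unknown statistic {statistic!r}")
    if n_permutations < 1:
        raise UsageError("n_permutations must be >= 1")
    if len(shared) < 5:
        raise ValidationError(
            f"need >= 5 shared genes for a usable null, got {len(shared)}"
        )
    observed_pairs = interpeak_distances(assign_a, assign_b, shared, pairing="nearest")

    genes = sorted(shared)
    offs_a = _gene_offsets(assign_a, shared)
    offs_b = _gene_offsets(assign_b, shared)
    obs_dists = np.array([p.distance for p in observed_pairs], dtype=float)

    def stat(d: np.ndarray) -> float:
        if statistic == "median":
            return float(np.median(d))
        return float(np.mean(d <= threshold_bp))

    observed_statistic = stat(obs_dists)
    n = len(genes)
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_permutations)
    for m in range(n_permutations):
        # partner index uniform over the other n-1 genes
        partners = rng.integers(0, n - 1, size=n)
        partners = partners + (partners >= np.arange(n))
        d = np.array(
            [
                _nearest_distance(offs_a[genes[i]], offs_b[genes[j]])
                for i, j in enumerate(partners)
            ],
            dtype=float,
        )
        null_stats[m] = stat(d)

    if statistic == "median":
        b = int(np.sum(null_stats <= observed_statistic))
    else:
        b = int(np.sum(null_stats >= observed_statistic))
    p = (1 + b) / (n_permutations + 1)
    return ProximityResult(
        observed=observed_pairs,
        statistic_name=statistic,
        observed_statistic=observed_statistic,
        null_statistics=null_stats,
        p_empirical=p,
        n_permutations=n_permutations,
        threshold_bp=threshold_bp,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Metagene profile
# ---------------------------------------------------------------------------


def metagene_profile(
    assignments: list[TargetAssignment] | TargetAssignment,
    genes: list[GeneModel],
    promoter_bp: int = 5000,
    n_promoter_bins: int = 50,
    n_body_bins: int = 40,
    downstream_bp: int = 1000,
    n_downstream_bins: int = 10,
) -> MetageneProfile:
    """Bin assigned peak points along promoter | scaled gene body | 3' end.

    Promoter and 3' bins have fixed width in bp; body positions are rescaled
    to [0, 1) by (point - TSS)/(TES - TSS), strand-aware. Genes with
    TES == TSS are skipped (counted per factor). Points outside the layout
    (e.g. a wider assignment window than the profile's) are likewise counted
    as skipped.
    """
    if min(n_promoter_bins, n_body_bins, n_downstream_bins) < 1:
        raise UsageError("all bin counts must be >= 1")
    if isinstance(assignments, TargetAssignment):
        assignments = [assignments]
    by_id = {g.gene_id: g for g in genes}
    profile = MetageneProfile(
        promoter_bp=promoter_bp,
        n_promoter_bins=n_promoter_bins,
        n_body_bins=n_body_bins,
        downstream_bp=downstream_bp,
        n_downstream_bins=n_downstream_bins,
    )
    prom_w = promoter_bp / n_promoter_bins
    down_w = downstream_bp / n_downstream_bins
    for assign in assignments:
        counts = np.zeros(profile.n_bins, dtype=int)
        skipped = 0
        for gid, hits in assign.hits.items():
            gene = by_id.get(gid)
            if gene is None:
                skipped += len(hits)
                continue
            body_len = abs(gene.tes - gene.tss)
            if body_len == 0:  # body rescaling undefined
                skipped += len(hits)
                continue
            for h in hits:
                o = h.offset
                if -promoter_bp <= o < 0:
                    idx = int((o + promoter_bp) // prom_w)
                    idx = min(idx, n_promoter_bins - 1)
                elif 0 <= o < body_len:
                    idx = n_promoter_bins + int(o / body_len * n_body_bins)
                elif body_len <= o < body_len + downstream_bp:
                    idx = n_promoter_bins + n_body_bins + int((o - body_len) // down_w)
                    idx = min(idx, profile.n_bins - 1)
                else:
                    skipped += 1
                    continue
                counts[idx] += 1
        profile.counts[assign.factor_label] = counts
        profile.n_skipped[assign.factor_label] = skipped
    return profile
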