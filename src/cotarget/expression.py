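"""Integration of differential-expression experiments over target classes.

Covers: multi-experiment merging with significance filtering, fold-change
clamping for display-scale comparisons, sign-concordance testing between two
contrasts (with explicit per-column sign conventions so loss-of-function
contrasts can be flipped rather than guessed), average-linkage hierarchical
clustering, a gene set enrichment analysis (GSEA) engine built on the
weighted Kolmogorov–Smirnov running sum with gene-set permutation, and
Livak-convention qPCR quantification helpers (2^-ddCt relative expression
and ChIP fold enrichment against an input control and a control region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import binomtest

from .errors import UsageError, ValidationError
from .io import ExpressionRecord

__all__ = [
    "FoldChangeMatrix",
    "ConcordanceResult",
    "EnrichmentResult",
    "Dendrogram",
    "merge_experiments",
    "clamp_fold_changes",
    "sign_concordance",
    "gsea_enrichment_score",
    "gsea_significance",
    "hierarchical_cluster",
    "relative_expression",
    "chip_fold_enrichment",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeMatrix:
    """Genes x experiments matrices of log2 fold changes and p-values."""

    values: pd.DataFrame
    pvalues: pd.DataFrame
    clamp_limit: float | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def experiments(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ConcordanceResult:
    """Sign agreement between two convention-adjusted experiment columns."""

    n_total: int
    n_concordant: int
    n_discordant: int
    binomial_p_two_sided: float

    @property
    def fraction_concordant(self) -> float:
        n = self.n_concordant + self.n_discordant
        return self.n_concordant / n if n else float("nan")


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge list (scipy node indexing: leaves are
    0..n-1, internal node k is created by merge k-n) and leaf order."""

    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[str, ...]


# ---------------------------------------------------------------------------
# Merging and filtering
# ---------------------------------------------------------------------------


def merge_experiments(
    tables: Sequence,
    alpha: float = 0.05,
    policy: str = "all_significant",
) -> FoldChangeMatrix:
    """Merge per-experiment DE tables into one gene x experiment matrix.

    ``tables`` may be a flat collection of :class:`ExpressionRecord` (grouped
    by their ``experiment_id``) or a list of per-experiment collections.
    Under ``all_significant`` a gene is retained iff it has p < alpha in
    every experiment (genes missing from any experiment are dropped); under
    ``any_significant`` iff p < alpha in at least one (missing entries are
    kept as NaN).
    """
    if not (0.0 < alpha < 1.0):
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    if policy not in ("all_significant", "any_significant"):
        raise UsageError(f"unknown policy {policy!r}")
    records: list[ExpressionRecord] = []
    for item in tables:
        if isinstance(item, ExpressionRecord):
            records.append(item)
        else:
            records.extend(item)
    if not records:
        raise ValidationError("no expression records supplied")
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "experiment_id": [r.experiment_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
        }
    )
    dup = df.duplicated(subset=["gene_id", "experiment_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate record for gene {row.gene_id!r} in experiment {row.experiment_id!r}"
        )
    values = df.pivot(index="gene_id", columns="experiment_id", values="log2fc")
    pvals = df.pivot(index="gene_id", columns="experiment_id", values="p_value")
    sig = pvals < alpha  # NaN compares False
    if policy == "all_significant":
        keep = sig.all(axis=1) & pvals.notna().all(axis=1)
    else:
        keep = sig.any(axis=1)
    values, pvals = values[keep].sort_index(), pvals[keep].sort_index()
    return FoldChangeMatrix(values=values, pvalues=pvals)


def clamp_fold_changes(matrix: FoldChangeMatrix, limit: float = 2.0) -> FoldChangeMatrix:
    """Clamp log2 fold changes to +/- limit (display-scale rescaling)."""
    if limit <= 0:
        raise UsageError(f"clamp limit must be > 0, got {limit}")
    return FoldChangeMatrix(
        values=matrix.values.clip(lower=-limit, upper=limit),
        pvalues=matrix.pvalues.copy(),
        clamp_limit=limit,
    )


def sign_concordance(
    matrix: FoldChangeMatrix,
    col_x: str,
    col_y: str,
    sign_convention: tuple[int, int] = (1, 1),
) -> ConcordanceResult:
    """Count genes whose convention-adjusted fold-change signs agree.

    ``sign_convention`` multiplies each column by +1 or -1 before comparing,
    so e.g. a loss-of-function contrast can be flipped and an "inverse
    correlation" between raw columns counts as concordant regulation. Zeros
    are excluded from both counts. Significance is an exact two-sided
    binomial test of the concordant count against 0.5.
    """
    for c in (col_x, col_y):
        if c not in matrix.values.columns:
            raise ValidationError(f"experiment column {c!r} not in matrix")
    mx, my = sign_convention
    if mx not in (1, -1) or my not in (1, -1):
        raise UsageError("sign_convention entries must be +1 or -1")
    sub = matrix.values[[col_x, col_y]].dropna()
    sx = np.sign(mx * sub[col_x].to_numpy())
    sy = np.sign(my * sub[col_y].to_numpy())
    nonzero = (sx != 0) & (sy != 0)
    n_conc = int(np.sum(nonzero & (sx == sy)))
    n_disc = int(np.sum(nonzero & (sx != sy)))
    if n_conc + n_disc == 0:
        raise ValidationError("no nonzero fold-change pairs to compare")
    p = binomtest(n_conc, n_conc + n_disc, 0.5, alternative="two-sided").pvalue
    return ConcordanceResult(
        n_total=len(sub),
        n_concordant=n_conc,
        n_discordant=n_disc,
        binomial_p_two_sided=float(p),
    )


# ---------------------------------------------------------------------------
# GSEA engine
# ---------------------------------------------------------------------------


def _hit_weights(abs_scores_pow: np.ndarray, hit_pos: np.ndarray) -> np.ndarray:
    w = abs_scores_pow[hit_pos]
    total = w.sum()
    if total == 0:  # all hit scores zero: fall back to equal weights
        return np.full(len(hit_pos), 1.0 / len(hit_pos))
    return w / total


def _es_from_hits(abs_scores_pow: np.ndarray, hit_pos: np.ndarray, n: int) -> float:
    """Enrichment score from hit positions only, O(|set|) after sorting.

    The running sum rises at hits and decays linearly on misses, so its
    maximum is attained immediately after some hit and its minimum
    immediately before some hit (or 0 at the boundaries). Ties between the
    positive and negative extreme break toward the positive deviation.
    """
    hit_pos = np.sort(hit_pos)
    w = _hit_weights(abs_scores_pow, hit_pos)
    cum = np.cumsum(w)
    d = 1.0 / (n - len(hit_pos))
    j = np.arange(1, len(hit_pos) + 1)
    after = cum - (hit_pos + 1 - j) * d
    before = np.concatenate(([0.0], cum[:-1])) - (hit_pos - j + 1) * d
    max_dev = max(after.max(), 0.0)
    min_dev = min(before.min(), 0.0)
    # ties within numerical tolerance break toward the positive deviation
    es = float(max_dev if max_dev >= -min_dev - 1e-12 else min_dev)
    return float(np.clip(es, -1.0, 1.0))


def gsea_enrichment_score(
    ranked: Sequence[tuple[str, float]],
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[float]]:
    """Weighted Kolmogorov–Smirnov enrichment score and full running sum.

    ``ranked`` is the ranking itself: (gene, score) pairs already ordered
    (conventionally best-to-worst; the input order is trusted, never
    re-sorted). The running sum increments by |score|^w / sum(|score|^w over
    set members) at members and decrements by 1/(N - |S|) otherwise; the ES
    is the signed deviation of maximum magnitude.
    """
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    n = len(genes)
    if len(set(genes)) != n:
        raise ValidationError("ranked gene list contains duplicates")
    members = gene_set & set(genes)
    if not members:
        raise ValidationError("gene set has no members in the ranking")
    if len(members) == n:
        raise ValidationError("gene set equals the whole ranking")
    hit = np.array([g in members for g in genes])
    abs_pow = np.abs(scores) ** weight_exponent
    hit_pos = np.flatnonzero(hit)
    w = _hit_weights(abs_pow, hit_pos)
    steps = np.full(n, -1.0 / (n - len(hit_pos)))
    steps[hit_pos] = w
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    max_dev, min_dev = max(running[i_max], 0.0), min(running[i_min], 0.0)
    es = float(np.clip(max_dev if max_dev >= -min_dev - 1e-12 else min_dev, -1.0, 1.0))
    return es, running.tolist()


def _leading_edge(
    genes: Sequence[str], hit_pos: np.ndarray, running: np.ndarray, es: float
) -> tuple[str, ...]:
    if es >= 0:
        peak = int(np.argmax(running))
        return tuple(genes[i] for i in hit_pos if i <= peak)
    trough = int(np.argmin(running))
    return tuple(genes[i] for i in hit_pos if i >= trough)


def gsea_significance(
    ranked: Sequence[tuple[str, float]],
    gene_sets: Mapping[str, set[str]],
    n_permutations: int = 1000,
    permutation_type: str = "gene_set",
    seed: int = 0,
    weight_exponent: float = 1.0,
    fdr_method: str = "gsea",
) -> list[EnrichmentResult]:
    """ES, NES, nominal p and FDR q for each gene set.

    The null distribution per set comes from random gene sets of matched
    size drawn from the ranking (gene-set permutation). NES = ES divided by
    the mean |null ES| of the same sign; nominal p is the same-sign null
    exceedance with add-one smoothing. FDR q follows the sign-stratified
    pooled-NES scheme of the original GSEA procedure; ``fdr_method="bh"``
    applies Benjamini–Hochberg to the nominal p-values instead.
    """
    if permutation_type != "gene_set":
        raise UsageError(f"unsupported permutation type {permutation_type!r}")
    if fdr_method not in ("gsea", "bh"):
        raise UsageError(f"unknown fdr_method {fdr_method!r}")
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    n = len(genes)
    abs_pow = np.abs(scores) ** weight_exponent
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(gene_sets))

    set_ids = list(gene_sets)
    es_obs: list[float] = []
    nes_obs: list[float] = []
    p_nom: list[float] = []
    leading: list[tuple[str, ...]] = []
    null_nes_all: list[np.ndarray] = []
    for sid, child in zip(set_ids, children):
        members = gene_sets[sid] & set(genes)
        if len(members) > n / 2:
            warnings.warn(
                f"gene set {sid!r} covers more than half the ranking; "
                "the matched-size null is unstable",
                stacklevel=2,
            )
        es, running = gsea_enrichment_score(ranked, members, weight_exponent)
        hit_pos = np.flatnonzero(np.array([g in members for g in genes]))
        rng = np.random.default_rng(child)
        null = np.empty(n_permutations)
        for m in range(n_permutations):
            pos = rng.choice(n, size=len(members), replace=False)
            null[m] = _es_from_hits(abs_pow, pos, n)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
            p = (1 + np.sum(same >= es)) / (1 + len(same))
            nes = es / same.mean() if len(same) else float("nan")
        else:
            same = neg_null
            p = (1 + np.sum(same <= es)) / (1 + len(same))
            nes = es / np.abs(same).mean() if len(same) else float("nan")
        null_nes = np.where(
            null >= 0,
            null / pos_null.mean() if len(pos_null) else np.nan,
            null / np.abs(neg_null).mean() if len(neg_null) else np.nan,
        )
        es_obs.append(es)
        nes_obs.append(float(nes))
        p_nom.append(float(p))
        leading.append(_leading_edge(genes, hit_pos, np.asarray(running), es))
        null_nes_all.append(null_nes[~np.isnan(null_nes)])

    if fdr_method == "bh":
        order = np.argsort(p_nom)
        q = np.empty(len(p_nom))
        prev = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = len(p_nom) - rank
            prev = min(prev, p_nom[idx] * len(p_nom) / i)
            q[idx] = prev
        fdr = list(q)
    else:
        pooled = np.concatenate(null_nes_all) if null_nes_all else np.array([])
        obs = np.array(nes_obs)
        fdr = []
        for nes in nes_obs:
            if np.isnan(nes):
                fdr.append(float("nan"))
                continue
            if nes >= 0:
                n_null_side = max(int(np.sum(pooled >= 0)), 1)
                num = np.sum(pooled >= nes) / n_null_side
                n_obs_side = max(int(np.sum(obs >= 0)), 1)
                den = np.sum(obs >= nes) / n_obs_side
            else:
                n_null_side = max(int(np.sum(pooled < 0)), 1)
                num = np.sum(pooled <= nes) / n_null_side
                n_obs_side = max(int(np.sum(obs < 0)), 1)
                den = np.sum(obs <= nes) / n_obs_side
            fdr.append(float(min(1.0, num / den)) if den > 0 else 1.0)

    return [
        EnrichmentResult(
            gene_set_id=sid,
            es=es_obs[i],
            nes=nes_obs[i],
            p_nominal=p_nom[i],
            fdr_q=fdr[i],
            leading_edge=leading[i],
            n_permutations=n_permutations,
            seed=seed,
        )
        for i, sid in enumerate(set_ids)
    ]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def hierarchical_cluster(
    matrix: FoldChangeMatrix,
    axis: str = "genes",
    linkage_method: str = "average",
    metric: str = "one_minus_pearson",
) -> Dendrogram:
    """Agglomerative average-linkage clustering of the fold-change rows."""
    if axis != "genes":
        raise UsageError("only axis='genes' is supported")
    if linkage_method != "average":
        raise UsageError("only average linkage is supported")
    if metric not in ("one_minus_pearson", "euclidean"):
        raise UsageError(f"unknown metric {metric!r}")
    data = matrix.values.dropna()
    if len(data) < 2:
        raise ValidationError("need >= 2 complete rows to cluster")
    X = data.to_numpy(dtype=float)
    if metric == "one_minus_pearson":
        sd = X.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if len(flat):
            raise ValidationError(
                f"constant row under correlation metric: gene {data.index[flat[0]]!r}"
            )
        dists = pdist(X, metric="correlation")
    else:
        dists = pdist(X, metric="euclidean")
    Z = linkage(dists, method="average")
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    order = tuple(data.index[i] for i in leaves_list(Z))
    return Dendrogram(merges=merges, leaf_order=order)


# ---------------------------------------------------------------------------
# qPCR quantification helpers (Livak 2^-ddCt convention)
# ---------------------------------------------------------------------------


def relative_expression(
    ct_target: float,
    ct_reference: float,
    ct_target_cal: float,
    ct_reference_cal: float,
) -> float:
    """Relative expression 2^-ddCt: target normalized to a reference gene and
    to a calibrator sample."""
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return float(2.0 ** (-ddct))


def chip_fold_enrichment(
    ct_ip_target: float,
    ct_input_target: float,
    ct_ip_control: float,
    ct_input_control: float,
) -> float:
    """ChIP-qPCR fold enrichment: IP/input at the target region normalized by
    IP/input at a non-bound control region."""
    target = 2.0 ** (-(ct_ip_target - ct_input_target))
    control = 2.0 ** (-(ct_ip_control - ct_input_control))
    return float(target / control)
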