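"""Synthetic genomes, peak sets, expression tables and genotype panels with
planted, recorded truth.

The generators emulate the statistical structure the pipeline is built to
detect: two ChIP peak sets with a controllable shared-target fraction and a
controllable inter-peak distance law on shared promoters (factor B's offset
= factor A's offset + Normal(0, sigma) — or an independent uniform draw when
``sigma_shared_bp=None``, which is exactly the "random target promoter"
null); DE tables with planted effect sizes and cross-experiment sign
concordance; and genotype panels with planted interdependent / additive /
not-coactivated modes.

Every generator is deterministic under its seed. A master seed fans out to
per-component child seeds via ``numpy.random.SeedSequence([seed, k])`` with
a fixed component index ``k``, so components can be regenerated
independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .io import ExpressionRecord, GeneModel, GenotypePanel, Peak, PeakSet

__all__ = [
    "SimTruth",
    "simulate_genome",
    "simulate_cooccupancy",
    "simulate_expression",
    "simulate_genotype_panels",
]

# component indices for seed fan-out
_SEED_GENOME = 0
_SEED_COOCCUPANCY = 1
_SEED_EXPRESSION = 2
_SEED_PANELS = 3


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(component)]))


@dataclass
class SimTruth:
    """Planted ground truth, serialized alongside generated outputs."""

    seed: int
    gene_ids: list[str] = field(default_factory=list)
    shared: list[str] = field(default_factory=list)
    a_only: list[str] = field(default_factory=list)
    b_only: list[str] = field(default_factory=list)
    sigma_shared_bp: float | None = None
    promoter_bp: int = 5000
    effect_log2: float | None = None
    concordance_prob: float | None = None
    noise_sd: float | None = None
    gene_modes: dict[str, str] = field(default_factory=dict)

    @property
    def targets_a(self) -> set[str]:
        return set(self.a_only) | set(self.shared)

    @property
    def targets_b(self) -> set[str]:
        return set(self.b_only) | set(self.shared)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_genome(
    n_genes: int,
    n_chroms: int = 2,
    gene_length_law: tuple[int, int] = (1000, 3000),
    intergenic_law: tuple[int, int] = (10500, 15000),
    seed: int = 0,
) -> list[GeneModel]:
    """Non-overlapping genes with random strands laid out chromosome by
    chromosome.

    The default intergenic spacing exceeds two facing 5 kb promoter windows
    plus the downstream window, so neighboring composite windows never
    overlap and noiseless assignment is unambiguous.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if gene_length_law[0] <= 0 or gene_length_law[0] > gene_length_law[1]:
        raise ValidationError(f"bad gene_length_law {gene_length_law}")
    if intergenic_law[0] <= 0 or intergenic_law[0] > intergenic_law[1]:
        raise ValidationError(f"bad intergenic_law {intergenic_law}")
    if n_genes * (gene_length_law[1] + intergenic_law[1]) > 2**53:
        raise ValidationError("genome layout would overflow coordinate space")
    rng = _rng(seed, _SEED_GENOME)
    per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0)
                 for c in range(n_chroms)]
    genes: list[GeneModel] = []
    idx = 1
    width = len(str(n_genes))
    for c, count in enumerate(per_chrom, start=1):
        pos = 6000  # leading pad so the first promoter window fits
        for _ in range(count):
            pos += int(rng.integers(intergenic_law[0], intergenic_law[1] + 1))
            length = int(rng.integers(gene_length_law[0], gene_length_law[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"SIMG{idx:0{width}d}",
                    chrom=f"chr{c}",
                    strand=strand,
                    start=pos,
                    end=pos + length,
                )
            )
            pos += length
            idx += 1
    return genes


def simulate_cooccupancy(
    genes: list[GeneModel],
    n_targets_a: int,
    n_targets_b: int,
    n_shared: int,
    sigma_shared_bp: float | None = 50.0,
    promoter_bp: int = 5000,
    peak_width: int = 200,
    with_summits: bool = True,
    seed: int = 0,
) -> tuple[PeakSet, PeakSet, SimTruth]:
    """Plant two factors' target sets with a controlled overlap and a
    controlled inter-peak distance law on shared promoters.

    Each target gene receives one peak whose representative point sits at a
    uniform offset within the promoter window. On shared genes factor B's
    offset is factor A's offset plus Normal(0, sigma_shared_bp) truncated to
    the window; ``sigma_shared_bp=None`` draws B's offset independently
    (no planted proximity — the calibration null). Peaks are fixed-width
    intervals centered on the point, with summits unless
    ``with_summits=False`` (exercising the midpoint fallback; the width is
    even so midpoint == planted point either way).
    """
    if not (0 <= n_shared <= min(n_targets_a, n_targets_b)):
        raise ValidationError("need n_shared <= min(n_targets_a, n_targets_b)")
    n_union = n_targets_a + n_targets_b - n_shared
    if n_union > len(genes):
        raise ValidationError(
            f"need {n_union} distinct target genes but only {len(genes)} genes"
        )
    rng = _rng(seed, _SEED_COOCCUPANCY)
    ids = [g.gene_id for g in genes]
    chosen = rng.choice(len(genes), size=n_union, replace=False)
    shared_idx = chosen[:n_shared]
    a_only_idx = chosen[n_shared : n_targets_a]
    b_only_idx = chosen[n_targets_a :]
    by_id = {g.gene_id: g for g in genes}

    # margin keeps the peak interval and truncated offsets inside the window
    lo, hi = -(promoter_bp - peak_width), -peak_width

    def draw_offset() -> int:
        return int(rng.integers(lo, hi + 1))

    def make_peak(label: str, k: int, gene: GeneModel, offset: int) -> Peak:
        point = gene.tss + offset if gene.strand == "+" else gene.tss - offset
        half = peak_width // 2
        return Peak(
            chrom=gene.chrom,
            start=point - half,
            end=point + half,
            peak_id=f"{label}_peak_{k}",
            summit=point if with_summits else None,
            score=float(np.round(rng.uniform(1, 100), 3)),
        )

    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    ka = kb = 0
    offsets_a_shared: dict[str, int] = {}
    for i in shared_idx:
        gene = by_id[ids[i]]
        oa = draw_offset()
        offsets_a_shared[gene.gene_id] = oa
        ka += 1
        peaks_a.append(make_peak("A", ka, gene, oa))
        if sigma_shared_bp is None:
            ob = draw_offset()
        else:
            ob = int(round(oa + rng.normal(0.0, sigma_shared_bp)))
            ob = max(lo, min(hi, ob))
        kb += 1
        peaks_b.append(make_peak("B", kb, gene, ob))
    for i in a_only_idx:
        gene = by_id[ids[i]]
        ka += 1
        peaks_a.append(make_peak("A", ka, gene, draw_offset()))
    for i in b_only_idx:
        gene = by_id[ids[i]]
        kb += 1
        peaks_b.append(make_peak("B", kb, gene, draw_offset()))

    truth = SimTruth(
        seed=seed,
        gene_ids=ids,
        shared=sorted(ids[i] for i in shared_idx),
        a_only=sorted(ids[i] for i in a_only_idx),
        b_only=sorted(ids[i] for i in b_only_idx),
        sigma_shared_bp=sigma_shared_bp,
        promoter_bp=promoter_bp,
    )
    return (
        PeakSet(factor_label="A", peaks=peaks_a),
        PeakSet(factor_label="B", peaks=peaks_b),
        truth,
    )


def simulate_expression(
    truth: SimTruth,
    n_experiments: int = 2,
    effect_log2: float = 1.5,
    concordance_prob: float = 0.9,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> list[ExpressionRecord]:
    """Per-experiment DE tables with planted effects on shared targets.

    Each shared target carries a gene-level sign; experiment 1 reports that
    sign, every further experiment agrees with it with probability
    ``concordance_prob``. Values are the signed effect plus Normal(0,
    noise_sd) noise; non-targets are pure noise. P-values are two-sided
    z-tests of the value against the noise law, so with ``effect_log2=0``
    they are uniform by construction.
    """
    if not (0.0 <= concordance_prob <= 1.0):
        raise ValidationError("concordance_prob must be in [0, 1]")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    if n_experiments < 1:
        raise ValidationError("n_experiments must be >= 1")
    rng = _rng(seed, _SEED_EXPRESSION)
    shared = set(truth.shared)
    gene_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in sorted(shared)}
    records: list[ExpressionRecord] = []
    for e in range(1, n_experiments + 1):
        exp_id = f"exp{e}"
        for g in truth.gene_ids:
            mu = 0.0
            if g in shared:
                s = gene_sign[g]
                if e > 1 and rng.random() >= concordance_prob:
                    s = -s
                mu = s * effect_log2
            v = mu + rng.normal(0.0, noise_sd)
            p = 2.0 * norm.sf(abs(v) / noise_sd)
            records.append(
                ExpressionRecord(
                    gene_id=g, log2fc=float(v), p_value=float(min(p, 1.0)),
                    experiment_id=exp_id,
                )
            )
    truth.effect_log2 = effect_log2
    truth.concordance_prob = concordance_prob
    truth.noise_sd = noise_sd
    return records


def simulate_genotype_panels(
    gene_modes: dict[str, str],
    effects: tuple[float, float] = (1.5, 1.0),
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
) -> dict[str, GenotypePanel]:
    """Genotype panels realizing planted regulatory modes.

    ``effects = (single_drop, double_extra_drop)`` in log2 units:
    interdependent genes put both singles and the double at WT * 2^-single_drop;
    additive genes drop the double a further ``double_extra_drop``;
    not_coactivated genes stay at WT level. Replicates get multiplicative
    lognormal noise at coefficient of variation ``cv``.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    single_drop, double_extra = effects
    rng = _rng(seed, _SEED_PANELS)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    panels: dict[str, GenotypePanel] = {}
    for gid in sorted(gene_modes):
        mode = gene_modes[gid]
        if mode == "interdependent":
            levels = {"WT": 1.0, "mutA": 2.0**-single_drop,
                      "mutB": 2.0**-single_drop, "mutAB": 2.0**-single_drop}
        elif mode == "additive":
            levels = {"WT": 1.0, "mutA": 2.0**-single_drop,
                      "mutB": 2.0**-single_drop,
                      "mutAB": 2.0 ** -(single_drop + double_extra)}
        elif mode == "not_coactivated":
            levels = {g: 1.0 for g in GenotypePanel.REQUIRED}
        else:
            raise ValidationError(f"gene {gid}: unknown planted mode {mode!r}")
        meas = {
            g: [float(levels[g] * np.exp(rng.normal(0.0, sigma)))
                for _ in range(n_replicates)]
            for g in GenotypePanel.REQUIRED
        }
        panels[gid] = GenotypePanel(gene_id=gid, measurements=meas)
    return panels
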