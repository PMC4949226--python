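"""Regulatory-mode classification from WT / mutA / mutB / mutAB panels.

Two transcription factors that both activate a shared target can do so
*interdependently* (knocking out either one alone collapses expression as
far as knocking out both — each factor requires the other) or *additively*
(the double mutant drops significantly below both singles — independent
contributions). The classifier formalizes that verbal logic with one-sided
Welch t-tests on log2-transformed replicate values:

    not_coactivated : neither single mutant is significantly below WT
    additive        : the double is significantly below BOTH singles
    interdependent  : >=1 single below WT and the double below WT,
                      but not below both singles
    ambiguous       : a single is below WT yet the double is not —
                      a pattern inconsistent with joint activation

``residual_flag`` marks interdependent genes where the double is
significantly below exactly one single: the pattern expected when residual
paralog activity props expression up in one single mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import t as t_dist

from .errors import ValidationError
from .io import GenotypePanel

__all__ = ["ModeCall", "Contrast", "classify_mode", "classify_modes"]

LABELS = ("interdependent", "additive", "not_coactivated", "ambiguous")

# variance floor on the log2 scale: keeps t finite for near-constant replicates
_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class Contrast:
    """One Welch contrast: log2 effect estimate and one-sided p (first
    group below second)."""

    effect_log2: float
    p_less: float


@dataclass
class ModeCall:
    gene_id: str
    label: str
    residual_flag: bool
    contrasts: dict[str, Contrast] = field(default_factory=dict)


def _welch_less(x: np.ndarray, y: np.ndarray) -> Contrast:
    """One-sided Welch t-test of mean(x) < mean(y) on log2 values."""
    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    vx = max(x.var(ddof=1), _VAR_FLOOR)
    vy = max(y.var(ddof=1), _VAR_FLOOR)
    se2 = vx / nx + vy / ny
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(t_dist.cdf(t, df))
    return Contrast(effect_log2=float(mx - my), p_less=p)


def classify_mode(panel: GenotypePanel, alpha: float = 0.05) -> ModeCall:
    """Classify one gene's activation mode from its genotype panel.

    Replicate values (positive, WT-normalized relative expression) are
    log2-transformed; all contrasts are one-sided "below" tests at ``alpha``,
    uncorrected within the gene (planned contrasts). The call is invariant to
    swapping mutA and mutB and to rescaling all values by a common positive
    constant.
    """
    logs = {g: np.log2(np.asarray(panel.measurements[g], dtype=float))
            for g in GenotypePanel.REQUIRED}
    c = {
        "mutA_vs_WT": _welch_less(logs["mutA"], logs["WT"]),
        "mutB_vs_WT": _welch_less(logs["mutB"], logs["WT"]),
        "mutAB_vs_mutA": _welch_less(logs["mutAB"], logs["mutA"]),
        "mutAB_vs_mutB": _welch_less(logs["mutAB"], logs["mutB"]),
        "mutAB_vs_WT": _welch_less(logs["mutAB"], logs["WT"]),
    }
    a_down = c["mutA_vs_WT"].p_less < alpha
    b_down = c["mutB_vs_WT"].p_less < alpha
    ab_below_a = c["mutAB_vs_mutA"].p_less < alpha
    ab_below_b = c["mutAB_vs_mutB"].p_less < alpha
    ab_down = c["mutAB_vs_WT"].p_less < alpha

    residual = False
    if not (a_down or b_down):
        label = "not_coactivated"
    elif ab_below_a and ab_below_b:
        label = "additive"
    elif ab_down:
        label = "interdependent"
        residual = ab_below_a != ab_below_b
    else:
        label = "ambiguous"
    return ModeCall(gene_id=panel.gene_id, label=label, residual_flag=residual, contrasts=c)


def classify_modes(
    panels: dict[str, GenotypePanel], alpha: float = 0.05
) -> dict[str, ModeCall]:
    """Classify a collection of genes; deterministic over input order."""
    if not panels:
        raise ValidationError("no panels supplied")
    return {gid: classify_mode(panels[gid], alpha=alpha) for gid in sorted(panels)}
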