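"""Relative qPCR quantification (delta-delta-Ct) and reference stability."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

_EPS = 1e-12


def _condition_values(ct: pd.DataFrame, gene: str, condition: str) -> np.ndarray:
    sel = ct.loc[(ct["gene"] == gene) & (ct["condition"] == condition), "ct"]
    values = sel.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"no Ct values for gene {gene!r} in condition {condition!r}")
    if np.any(values <= 0):
        raise ValueError("Ct values must be positive")
    return values


def reference_stability(
    ct: pd.DataFrame, reference: str, conditions: tuple[str, str] = ("CO", "DS")
) -> tuple[float, float]:
    """Welch two-sample t-test on the reference gene's Ct between conditions.

    Returns ``(t_statistic, p_value)``; a large p supports using the gene
    as endogenous control. Zero replicate variance is guarded by a small
    epsilon so that perfectly separated constant vectors give p ~ 0 and
    identical vectors give t = 0, p = 1.
    """
    a = _condition_values(ct, reference, conditions[0])
    b = _condition_values(ct, reference, conditions[1])
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    va = a.var(ddof=1) / a.size + _EPS
    vb = b.var(ddof=1) / b.size + _EPS
    diff = a.mean() - b.mean()
    t_stat = diff / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return float(t_stat), min(1.0, p)


@dataclass
class FoldChangeResult:
    gene_id: str
    fold: float
    lo: float
    hi: float
    log2_fold: float
    sd_log2: float
    delta_delta_ct: float

    @property
    def direction(self) -> str:
        if self.fold > 1.0:
            return "up"
        if self.fold < 1.0:
            return "down"
        return "none"


def fold_change(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    conditions: tuple[str, str] = ("CO", "DS"),
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
) -> FoldChangeResult:
    """Relative expression of *target* in the second vs first condition.

    With both efficiencies at 2 this is the classic 2^-ddCt method: per
    condition dCt = mean Ct(target) - mean Ct(reference), ddCt is the
    second-minus-first condition difference and fold = 2^-ddCt. General
    efficiencies use fold = Et^(dCt_t) / Er^(dCt_r) with dCt taken
    first-minus-second per gene. Dispersion propagates the replicate SDs
    in quadrature on the log2 scale; the reported range is the fold at
    +/- one propagated SD.
    """
    if efficiency_target <= 1 or efficiency_reference <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    cond_a, cond_b = conditions
    stats = {}
    for gene in (target, reference):
        for cond in conditions:
            v = _condition_values(ct, gene, cond)
            stats[gene, cond] = (v.mean(), v.std(ddof=1) if v.size > 1 else 0.0)

    let, ler = math.log2(efficiency_target), math.log2(efficiency_reference)
    log2_fold = let * (stats[target, cond_a][0] - stats[target, cond_b][0]) - ler * (
        stats[reference, cond_a][0] - stats[reference, cond_b][0]
    )
    ddct = (stats[target, cond_b][0] - stats[reference, cond_b][0]) - (
        stats[target, cond_a][0] - stats[reference, cond_a][0]
    )
    sd_log2 = math.sqrt(
        let**2 * (stats[target, cond_a][1] ** 2 + stats[target, cond_b][1] ** 2)
        + ler**2 * (stats[reference, cond_a][1] ** 2 + stats[reference, cond_b][1] ** 2)
    )
    fold = 2.0**log2_fold
    return FoldChangeResult(
        gene_id=target,
        fold=fold,
        lo=2.0 ** (log2_fold - sd_log2),
        hi=2.0 ** (log2_fold + sd_log2),
        log2_fold=log2_fold,
        sd_log2=sd_log2,
        delta_delta_ct=ddct,
    )


def qpcr_table(
    ct: pd.DataFrame, reference: str, conditions: tuple[str, str] = ("CO", "DS")
) -> pd.DataFrame:
    """Fold-change table for every non-reference gene in the Ct table."""
    genes = sorted(set(ct["gene"]) - {reference})
    rows = []
    for gene in genes:
        r = fold_change(ct, gene, reference, conditions=conditions)
        rows.append(
            {
                "gene_id": gene,
                "fold": r.fold,
                "lo": r.lo,
                "hi": r.hi,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
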