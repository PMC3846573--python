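"""Hypergeometric pathway enrichment of differentially expressed genes.

With N annotated genes in the universe, n of them differentially
expressed, M annotated to a pathway and m of those differentially
expressed, the enrichment p-value is the hypergeometric upper tail

    p = P(X >= m) = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n).

Q-values are obtained by Benjamini-Hochberg adjustment across the tested
pathways; a pathway is reported as enriched when q < 0.05.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from tagdge.de import fdr_adjust

_EXACT_N_MAX = 200


def _validate_tuple(N: int, n: int, M: int, m: int) -> None:
    if min(N, n, M, m) < 0:
        raise ValueError("all arguments must be non-negative")
    if M > N or n > N:
        raise ValueError("M and n cannot exceed N")
    if m > min(M, n):
        raise ValueError("m cannot exceed min(M, n)")


def _log_comb(a: float, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_enrich_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail probability P(X >= m), X ~ Hypergeometric(N, M, n).

    Exact rational arithmetic is used for small universes (N <= 200); the
    log-gamma route with log-sum-exp covers large ones.
    """
    _validate_tuple(N, n, M, m)
    if m == 0:
        return 1.0
    lo = max(m, n + M - N)
    hi = min(M, n)
    if lo > hi:
        return 0.0
    if N <= _EXACT_N_MAX:
        total = sum(
            Fraction(math.comb(M, i) * math.comb(N - M, n - i)) for i in range(lo, hi + 1)
        )
        return float(total / math.comb(N, n))
    i = np.arange(lo, hi + 1, dtype=float)
    log_terms = _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, np.array([n]))
    peak = log_terms.max()
    return float(min(1.0, math.exp(peak) * np.exp(log_terms - peak).sum()))


def enrich_all(
    annotation: pd.DataFrame,
    universe: Iterable[str],
    degs: Iterable[str] | Mapping[str, str],
    q_cut: float = 0.05,
    low_power_m: int = 3,
) -> pd.DataFrame:
    """Test every pathway for DEG enrichment against the annotated background.

    *annotation* needs columns ``gene_id`` and ``pathway_id`` (optionally
    ``pathway_name``). The universe and DEG sets are intersected with the
    annotated genes to form N and n; per pathway, M and m count annotated
    members and DEG members. *degs* may be a mapping gene -> "up"/"down"
    to populate the per-direction columns. Results are sorted by total DEG
    count descending, then p ascending.
    """
    if annotation.empty:
        raise ValueError("empty pathway annotation")
    if "pathway_name" not in annotation.columns:
        annotation = annotation.assign(pathway_name=annotation["pathway_id"])
    universe = set(universe)
    if isinstance(degs, Mapping):
        direction = dict(degs)
        deg_set = set(direction)
    else:
        deg_set = set(degs)
        direction = {}
    if not deg_set <= universe:
        raise ValueError("DEG set must be a subset of the universe")

    annotated = set(annotation["gene_id"]) & universe
    N = len(annotated)
    deg_ann = deg_set & annotated
    n = len(deg_ann)

    rows = []
    for (pid, pname), group in annotation.groupby(["pathway_id", "pathway_name"], sort=True):
        members = set(group["gene_id"]) & annotated
        M = len(members)
        hit = members & deg_ann
        m_total = len(hit)
        m_up = sum(1 for g in hit if direction.get(g) == "up")
        m_down = sum(1 for g in hit if direction.get(g) == "down")
        p = hypergeom_enrich_p(N, n, M, m_total) if M else 1.0
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": pname,
                "background": M,
                "m_up": m_up,
                "m_down": m_down,
                "m_total": m_total,
                "p": p,
                "low_power": M < low_power_m,
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = fdr_adjust(result["p"].to_numpy())
    result["enriched"] = result["q"] < q_cut
    result = result.sort_values(
        ["m_total", "p", "pathway_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return result[
        [
            "pathway_id",
            "pathway_name",
            "background",
            "m_up",
            "m_down",
            "m_total",
            "p",
            "q",
            "enriched",
            "low_power",
        ]
    ]
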