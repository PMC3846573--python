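"""Two-library exact differential-expression test for tag counts.

For a gene with ``x`` tags among ``N1`` in the first library and ``y``
among ``N2`` in the second, the probability that it is equally expressed
in both samples is

    P(y|x) = (N2/N1)^y * (x+y)! / (x! y!) / (1 + N2/N1)^(x+y+1)

i.e. ``y | x`` follows a negative-binomial law with ``x+1`` successes and
success probability ``N1/(N1+N2)``. Two-sided p-values are built as twice
the smaller tail, capped at one; multiple testing is controlled by
Benjamini-Hochberg (or Benjamini-Yekutieli) adjustment, and genes are
called differentially expressed when the adjusted value and the |log2|
TPM ratio both pass their thresholds.

All probabilities are evaluated in log space via log-gamma so that counts
in the hundreds of thousands remain exact to near machine precision; tail
sums use compensated (exact float) summation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln


def _validate(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValueError("tag counts must be non-negative")
    if int(x) != x or int(y) != y:
        raise ValueError("tag counts must be integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def _log_pmf(x: int, ys: np.ndarray, n1: float, n2: float) -> np.ndarray:
    ratio = n2 / n1
    ys = np.asarray(ys, dtype=float)
    return (
        ys * math.log(ratio)
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * math.log1p(ratio)
    )


def ac_probability(x: int, y: int, n1: float, n2: float) -> float:
    """Probability of observing ``y`` given ``x`` under equal expression."""
    _validate(x, y, n1, n2)
    return float(np.exp(_log_pmf(x, np.array([y]), n1, n2))[0])


def _upper_tail_direct(x: int, y: int, n1: float, n2: float) -> float:
    """Sum P(y'|x) for y' >= y by forward summation until convergence."""
    q = n2 / (n1 + n2)
    # past this point terms decay at least geometrically with ratio ~q
    mode = q * (x + 1) / (1.0 - q)
    blocks: list[float] = []
    cur = y
    block = 512
    while True:
        ys = np.arange(cur, cur + block)
        terms = np.exp(_log_pmf(x, ys, n1, n2))
        s = float(terms.sum())
        blocks.append(s)
        total = math.fsum(blocks)
        cur += block
        if cur > mode and (s <= total * 1e-17 or terms[-1] == 0.0):
            return total


def two_sided_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided p-value: ``min(1, 2 * min(P(Y<=y), P(Y>=y)))``.

    The lower tail is a compensated sum of the pmf over ``0..y``. The upper
    tail uses the complement ``1 - P(Y<=y-1)`` while that is numerically
    safe (complement >= 0.5) and otherwise a direct forward summation from
    ``y``, which preserves relative accuracy for very small tails.
    """
    _validate(x, y, n1, n2)
    pmf = np.exp(_log_pmf(x, np.arange(0, y + 1), n1, n2))
    lower = min(1.0, math.fsum(pmf))
    lower_excl = math.fsum(pmf[:-1]) if y > 0 else 0.0
    if lower_excl <= 0.5:
        upper = 1.0 - lower_excl
    else:
        upper = _upper_tail_direct(x, y, n1, n2)
    return min(1.0, 2.0 * min(lower, upper))


def log2_ratio(x: int, y: int, n1: float, n2: float, floor: float = 0.001) -> float:
    """log2 of the TPM ratio (second vs first library) with a zero floor.

    Both TPM values are floored at *floor* before the ratio, guaranteeing a
    finite result when either count is zero. The floor never enters the
    test statistic, only this ratio.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    tpm1 = max(x / n1 * 1e6, floor)
    tpm2 = max(y / n2 * 1e6, floor)
    return math.log2(tpm2 / tpm1)


def fdr_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Step-up multiple-testing adjustment ("bh" default, "by" optional)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    if method == "by":
        scaled = scaled * np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValueError(f"unknown method: {method!r}")
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def classify_degs(
    frame: pd.DataFrame, fdr_cut: float = 0.001, lfc_cut: float = 1.0
) -> tuple[pd.DataFrame, dict]:
    """Attach up/down/none calls and summarize.

    A gene is *up* iff ``fdr <= fdr_cut`` and ``log2_ratio >= lfc_cut``,
    *down* with ``log2_ratio <= -lfc_cut``, else *none*. The summary also
    reports the share of tested genes whose expression difference lies
    within / beyond five-fold.
    """
    frame = frame.copy()
    sig = frame["fdr"] <= fdr_cut
    call = np.where(
        sig & (frame["log2_ratio"] >= lfc_cut),
        "up",
        np.where(sig & (frame["log2_ratio"] <= -lfc_cut), "down", "none"),
    )
    frame["call"] = call
    n_tested = len(frame)
    log2_5 = math.log2(5.0)
    abs_lfc = frame["log2_ratio"].abs()
    summary = {
        "n_tested": n_tested,
        "n_up": int((call == "up").sum()),
        "n_down": int((call == "down").sum()),
        "frac_within_5fold": float((abs_lfc < log2_5).mean()) if n_tested else float("nan"),
        "frac_up_gt_5fold": (
            float(((frame["log2_ratio"] >= log2_5)).mean()) if n_tested else float("nan")
        ),
        "frac_down_gt_5fold": (
            float(((frame["log2_ratio"] <= -log2_5)).mean()) if n_tested else float("nan")
        ),
    }
    return frame, summary


def de_table(
    counts: pd.DataFrame,
    n1: float,
    n2: float,
    *,
    floor: float = 0.001,
    fdr_cut: float = 0.001,
    lfc_cut: float = 1.0,
    method: str = "bh",
) -> tuple[pd.DataFrame, dict]:
    """Full differential-expression table for a two-library count frame.

    *counts* must carry columns ``gene_id``, ``x`` (first library) and
    ``y`` (second library). Genes with ``x == y == 0`` are excluded from
    testing. Returns the result frame (gene_id, x, y, tpm_co, tpm_ds,
    log2_ratio, p, fdr, call) and the classification summary.
    """
    required = {"gene_id", "x", "y"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts frame must have columns {sorted(required)}")
    df = counts.loc[(counts["x"] > 0) | (counts["y"] > 0)].reset_index(drop=True).copy()
    xs = df["x"].to_numpy()
    ys = df["y"].to_numpy()
    df["tpm_co"] = xs / n1 * 1e6
    df["tpm_ds"] = ys / n2 * 1e6
    df["log2_ratio"] = [log2_ratio(x, y, n1, n2, floor) for x, y in zip(xs, ys)]
    df["p"] = [two_sided_pvalue(int(x), int(y), n1, n2) for x, y in zip(xs, ys)]
    df["fdr"] = fdr_adjust(df["p"].to_numpy(), method=method) if len(df) else []
    return classify_degs(df, fdr_cut=fdr_cut, lfc_cut=lfc_cut)
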