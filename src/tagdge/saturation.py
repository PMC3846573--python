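"""Sequencing-depth saturation: detected genes vs. subsampled tag number."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tagdge.annotate import ReferenceTagIndex, map_tags
from tagdge.tagproc import TagCountTable


@dataclass
class SaturationCurve:
    depths: np.ndarray
    genes_detected: np.ndarray  # replicate mean per depth
    replicates: np.ndarray  # (n_replicates, n_depths) integer counts
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tags_sampled": self.depths, "genes_detected": self.genes_detected}
        )


def default_depth_grid(library_size: int, n_points: int = 10) -> np.ndarray:
    """Evenly spaced depths ending exactly at the full library size."""
    grid = np.unique(
        np.round(np.linspace(library_size / n_points, library_size, n_points)).astype(int)
    )
    return grid[grid > 0]


def saturation_curve(
    table: TagCountTable,
    index: ReferenceTagIndex | None = None,
    depths=None,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    assignment: dict[str, str] | None = None,
    max_mismatch: int = 1,
) -> SaturationCurve:
    """Detected-gene count at each subsampled depth, averaged over replicates.

    Retained tags are expanded by copy number into a read pool; each
    replicate draws reads without replacement (a shuffled prefix per
    depth), maps them through the tag->gene assignment, and counts genes
    hit by at least one assigned read. Deterministic under *seed*.
    """
    if assignment is None:
        if index is None:
            raise ValueError("either a ReferenceTagIndex or an assignment is required")
        _, report = map_tags(table, index, max_mismatch=max_mismatch)
        assignment = report.assignment

    genes = sorted(set(assignment.values()))
    gene_code = {g: i for i, g in enumerate(genes)}
    tag_codes = np.array(
        [gene_code.get(assignment.get(tag, ""), -1) for tag in table.entries],
        dtype=np.int64,
    )
    counts = np.fromiter(table.entries.values(), dtype=np.int64, count=len(table.entries))
    pool = np.repeat(tag_codes, counts)
    n = pool.size

    if depths is None:
        depths = default_depth_grid(n)
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    if np.any(np.diff(depths) < 0):
        raise ValueError("depths must be sorted ascending")
    if depths.size and depths[-1] > n:
        raise ValueError(f"depth {int(depths[-1])} exceeds library size {n}")

    reps = np.empty((n_replicates, depths.size), dtype=np.int64)
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        perm = rng.permutation(pool)
        uniq, first = np.unique(perm, return_index=True)
        first = np.sort(first[uniq >= 0])
        reps[r] = np.searchsorted(first, depths, side="left")
    return SaturationCurve(
        depths=depths,
        genes_detected=reps.mean(axis=0),
        replicates=reps,
        n_replicates=n_replicates,
        seed=seed,
    )


def is_saturated(curve: SaturationCurve, window: int = 2, epsilon: float = 0.001) -> bool:
    """True iff the relative gain over the final *window* grid steps < epsilon."""
    g = np.asarray(curve.genes_detected, dtype=float)
    if g.size < window + 1:
        raise ValueError("curve must have more points than the window")
    final = g[-1]
    if final <= 0:
        return True
    return (final - g[-1 - window]) / final < epsilon
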