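"""Tag QC: the raw -> clean -> multi-copy filtering ladder and its ledger.

Cleaning removes reads containing ambiguous bases (N), adapter-matching
reads, and (optionally) reads lacking the CATG anchor; tags observed fewer
than ``min_copy`` times are then excluded for robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from tagdge.digest import ANCHOR, TAG_LENGTH
from tagdge.simulate import DEFAULT_ADAPTER
from tagdge.util import pct

_ANCHOR_BYTES = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)


@dataclass
class TagLedger:
    """Read-accounting totals of the filtering ladder."""

    total_tags: int = 0
    clean_tags: int = 0
    singleton_tags: int = 0
    retained_tags: int = 0
    unique_tags: int = 0

    @classmethod
    def from_counts(
        cls, total: int, clean: int, singletons: int, unique: int = 0
    ) -> "TagLedger":
        """Build a ledger from (possibly externally reported) totals."""
        return cls(
            total_tags=total,
            clean_tags=clean,
            singleton_tags=singletons,
            retained_tags=clean - singletons,
            unique_tags=unique,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "total_tags": self.total_tags,
            "clean_tags": self.clean_tags,
            "singleton_tags": self.singleton_tags,
            "retained_tags": self.retained_tags,
            "unique_tags": self.unique_tags,
        }


@dataclass
class TagCountTable:
    """Per-library unique-tag copy numbers plus the filtering ledger."""

    library_id: str = ""
    entries: dict[str, int] = field(default_factory=dict)
    ledger: TagLedger = field(default_factory=TagLedger)

    def expand_reads(self) -> np.ndarray:
        """Replicate each retained tag by its copy number (S21 array)."""
        if not self.entries:
            return np.empty(0, dtype="S21")
        tags = np.array([t.encode() for t in self.entries], dtype="S21")
        counts = np.fromiter(self.entries.values(), dtype=np.int64, count=len(self.entries))
        return np.repeat(tags, counts)


def _reads_matrix(reads) -> np.ndarray:
    arr = np.asarray(reads)
    if arr.size == 0:
        return np.empty((0, TAG_LENGTH), dtype=np.uint8)
    if arr.dtype.kind == "U":
        arr = np.char.encode(arr, "ascii")
    if arr.dtype != np.dtype("S%d" % TAG_LENGTH):
        arr = arr.astype("S%d" % TAG_LENGTH)
    mat = arr.view(np.uint8).reshape(arr.size, TAG_LENGTH)
    if (mat == 0).any():
        raise ValueError(f"all reads must be exactly {TAG_LENGTH} nt")
    return mat


def filter_tags(
    reads,
    adapter: str = DEFAULT_ADAPTER,
    *,
    min_adapter_prefix: int = 8,
    require_anchor: bool = True,
    min_copy: int = 2,
    library_id: str = "",
) -> TagCountTable:
    """Run the filtering ladder over raw 21-nt reads.

    A read is *clean* when it contains no N, does not begin with the first
    ``min_adapter_prefix`` nt of *adapter*, and (when ``require_anchor``)
    begins with the CATG anchor. Tags with copy number below ``min_copy``
    (default 2, i.e. single-copy tags) are then dropped. Empty input yields
    an empty table with a zeroed ledger.
    """
    mat = _reads_matrix(reads)
    n = mat.shape[0]
    if n == 0:
        return TagCountTable(library_id=library_id)

    has_n = (mat == ord("N")).any(axis=1)
    k = min(min_adapter_prefix, len(adapter), TAG_LENGTH)
    prefix = np.frombuffer(adapter[:k].encode(), dtype=np.uint8)
    is_adapter = (mat[:, :k] == prefix).all(axis=1) if k > 0 else np.zeros(n, bool)
    clean_mask = ~has_n & ~is_adapter
    if require_anchor:
        clean_mask &= (mat[:, : len(ANCHOR)] == _ANCHOR_BYTES).all(axis=1)

    clean_reads = mat[clean_mask].reshape(-1).view("S%d" % TAG_LENGTH)
    uniq, counts = np.unique(clean_reads, return_counts=True)
    below = counts < min_copy
    singleton_tags = int(counts[below].sum())
    keep = ~below
    entries = {
        tag.decode(): int(c) for tag, c in zip(uniq[keep], counts[keep])
    }
    clean = int(clean_mask.sum())
    ledger = TagLedger(
        total_tags=n,
        clean_tags=clean,
        singleton_tags=singleton_tags,
        retained_tags=clean - singleton_tags,
        unique_tags=len(entries),
    )
    return TagCountTable(library_id=library_id, entries=entries, ledger=ledger)


def copy_number_strata(
    table: TagCountTable, thresholds: Sequence[int] = (5, 10, 20, 50, 100)
) -> dict[int, int]:
    """Count unique tags with copy number strictly above each threshold."""
    thresholds = list(thresholds)
    if any(t < 0 for t in thresholds):
        raise ValueError("thresholds must be non-negative")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    counts = np.fromiter(table.entries.values(), dtype=np.int64, count=len(table.entries))
    return {t: int((counts > t).sum()) for t in thresholds}


def library_summary(table: TagCountTable | TagLedger) -> dict[str, float]:
    """Retained and useless percentages of the total sequenced tags.

    Both percentages are computed from raw counts and rounded half-up to
    two decimals independently (not by subtracting rounded values).
    """
    ledger = table.ledger if isinstance(table, TagCountTable) else table
    if ledger.total_tags == 0:
        raise ZeroDivisionError("library summary undefined for an empty library")
    retained_pct = pct(ledger.retained_tags, ledger.total_tags)
    useless_pct = pct(ledger.total_tags - ledger.retained_tags, ledger.total_tags)
    return {"retained_pct": retained_pct, "useless_pct": useless_pct}
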