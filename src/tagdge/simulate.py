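"""Synthetic two-library tag data with planted differential expression.

The generator emulates a restriction-tag expression library: transcripts
carry CATG-anchored tag sites, each sequenced read is a single 21-nt tag
drawn from one transcript, site choice within a transcript decays
geometrically with distance from the 3' end (incomplete digestion), and
reads are corrupted by adapter-only artifacts, ambiguous bases and
per-base substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from tagdge.digest import TAG_LENGTH, tag_sites

# Default adapter ligated 5' of the tag; adapter-only artifact reads are
# its first 21 nt (padded with A if the configured adapter is shorter).
DEFAULT_ADAPTER = "ACAGGTTCAGAGTTCTACAGTCCGAC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def adapter_read(adapter: str = DEFAULT_ADAPTER) -> str:
    """Adapter-only artifact read: adapter prefix padded/truncated to 21 nt."""
    return (adapter + "A" * TAG_LENGTH)[:TAG_LENGTH]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-library tag simulation.

    ``baseline_mean``/``baseline_sigma`` parameterise a log-normal law for
    relative transcript abundance; ``digestion_decay`` is the relative
    sampling weight ``decay**rank`` of tag-site rank counted from the 3'
    end; all rates are per-read or per-base probabilities in [0, 1].
    """

    n_genes: int = 2000
    length_range: tuple[int, int] = (300, 1500)
    n_tags_per_library: int = 1_000_000
    frac_de: float = 0.15
    fold_change_set: tuple[float, ...] = (2.0, 4.0, 8.0, 0.5, 0.25, 0.125)
    baseline_mean: float = 0.0
    baseline_sigma: float = 1.0
    digestion_decay: float = 0.2
    error_rate: float = 0.001
    n_rate: float = 0.001
    adapter_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 25:
            raise ValueError(
                "length_range minimum must be >= 25 nt to host a CATG site "
                "with 17 nt downstream"
            )
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_tags_per_library <= 0:
            raise ValueError("n_tags_per_library must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0.0 < self.digestion_decay <= 1.0:
            if self.digestion_decay != 0.0:
                raise ValueError("digestion_decay must be in (0, 1] or exactly 0")
        for name in ("error_rate", "n_rate", "adapter_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(f <= 0 for f in self.fold_change_set):
            raise ValueError("fold changes must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted per-gene ground truth (DS-vs-CO fold change)."""

    gene_id: str
    baseline_expr: float
    fold_change: float

    @property
    def is_de(self) -> bool:
        return self.fold_change != 1.0

    def __post_init__(self) -> None:
        if self.baseline_expr <= 0:
            raise ValueError("baseline_expr must be positive")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


@dataclass
class SimulationResult:
    transcripts: list[tuple[str, str]]
    truth: list[SimulationTruth]
    reads_co: np.ndarray
    reads_ds: np.ndarray
    gene_draws_co: np.ndarray | None = field(default=None, repr=False)
    gene_draws_ds: np.ndarray | None = field(default=None, repr=False)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_transcriptome(config: SimulationConfig) -> list[tuple[str, str]]:
    """Generate ``n_genes`` random transcripts, each with >=1 valid tag site.

    Sequences are uniform over ACGT; if a draw happens to contain no CATG
    with 17 nt downstream, an anchor is planted at a random valid position.
    Deterministic under ``config.seed``.
    """
    rng = _rng(config, 0)
    lo, hi = config.length_range
    width = len(str(config.n_genes))
    records: list[tuple[str, str]] = []
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        codes = rng.integers(0, 4, size=length)
        seq = bytearray(_BASES[codes].tobytes())
        if not tag_sites(seq.decode()):
            pos = int(rng.integers(0, length - TAG_LENGTH + 1))
            seq[pos : pos + 4] = b"CATG"
        records.append((f"gene{i + 1:0{width}d}", seq.decode()))
    return records


def make_truth(config: SimulationConfig) -> list[SimulationTruth]:
    """Draw per-gene baselines and plant fold changes on ``frac_de`` genes."""
    rng = _rng(config, 1)
    baselines = rng.lognormal(config.baseline_mean, config.baseline_sigma, config.n_genes)
    folds = np.ones(config.n_genes)
    n_de = int(round(config.frac_de * config.n_genes))
    if n_de and config.fold_change_set:
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
        folds[de_idx] = rng.choice(config.fold_change_set, size=n_de)
    width = len(str(config.n_genes))
    return [
        SimulationTruth(f"gene{i + 1:0{width}d}", float(baselines[i]), float(folds[i]))
        for i in range(config.n_genes)
    ]


def _site_catalog(
    transcripts: Sequence[tuple[str, str]], decay: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten (gene, site) pairs into parallel arrays.

    Returns ``(tags, gene_index, site_weight)`` where ``site_weight`` is the
    within-gene site probability (decay**rank normalized over the gene's
    sites; decay 0 puts all mass on the 3'-most site).
    """
    tags: list[bytes] = []
    gene_idx: list[int] = []
    weights: list[float] = []
    for gi, (_gid, seq) in enumerate(transcripts):
        sites = tag_sites(seq)
        if not sites:
            continue
        if decay == 0.0:
            w = [1.0] + [0.0] * (len(sites) - 1)
        else:
            w = [decay**rank for rank, _, _ in sites]
        total = sum(w)
        for (rank, _, tag), wr in zip(sites, w):
            if wr == 0.0:
                continue
            tags.append(tag.encode())
            gene_idx.append(gi)
            weights.append(wr / total)
    return (
        np.array(tags, dtype="S21"),
        np.array(gene_idx, dtype=np.int64),
        np.array(weights, dtype=float),
    )


def _corrupt(
    mat: np.ndarray, rng: np.random.Generator, config: SimulationConfig, adapter: str
) -> None:
    """Apply adapter replacement, substitution errors and N bases in place."""
    n = mat.shape[0]
    is_adapter = rng.random(n) < config.adapter_rate
    rows = np.flatnonzero(~is_adapter)
    if config.error_rate > 0 and rows.size:
        sub = rng.random((rows.size, TAG_LENGTH)) < config.error_rate
        ri, ci = np.nonzero(sub)
        if ri.size:
            old = mat[rows[ri], ci]
            shift = rng.integers(1, 4, size=ri.size)
            mat[rows[ri], ci] = _BASES[(_BASE_CODE[old] + shift) % 4]
    if config.n_rate > 0 and rows.size:
        nmask = rng.random((rows.size, TAG_LENGTH)) < config.n_rate
        ri, ci = np.nonzero(nmask)
        mat[rows[ri], ci] = ord("N")
    if is_adapter.any():
        mat[is_adapter] = np.frombuffer(adapter_read(adapter).encode(), dtype=np.uint8)


def _sample_library(
    rng: np.random.Generator,
    n_reads: int,
    tag_arr: np.ndarray,
    flat_p: np.ndarray,
    config: SimulationConfig,
    gene_of: np.ndarray,
    adapter: str,
) -> tuple[np.ndarray, np.ndarray]:
    draws = rng.choice(flat_p.size, size=n_reads, p=flat_p)
    reads = tag_arr[draws]
    mat = reads.view(np.uint8).reshape(n_reads, TAG_LENGTH).copy()
    _corrupt(mat, rng, config, adapter)
    return mat.reshape(-1).view("S21"), gene_of[draws]


def simulate_libraries(
    transcripts: Sequence[tuple[str, str]],
    truth: Sequence[SimulationTruth],
    config: SimulationConfig,
    adapter: str = DEFAULT_ADAPTER,
    return_gene_draws: bool = False,
):
    """Draw the CO and DS read sets.

    Per read: a gene is chosen proportional to expression (baseline for CO,
    baseline x fold for DS, renormalized over tag-bearing genes), a site
    within the gene by geometric rank weight, then the read is corrupted
    (adapter-only replacement, else substitution errors and N bases).

    Returns ``(reads_co, reads_ds)`` as numpy ``S21`` arrays, or with the
    per-read true gene-index arrays appended when ``return_gene_draws``.
    """
    if not transcripts:
        raise ValueError("empty transcriptome")
    ids = [gid for gid, _ in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript IDs")
    id_to_idx = {gid: i for i, gid in enumerate(ids)}
    missing = [t.gene_id for t in truth if t.gene_id not in id_to_idx]
    if missing:
        raise ValueError(f"truth gene IDs absent from transcriptome: {missing[:5]}")

    baseline = np.zeros(len(transcripts))
    fold = np.ones(len(transcripts))
    for t in truth:
        i = id_to_idx[t.gene_id]
        baseline[i] = t.baseline_expr
        fold[i] = t.fold_change

    tag_arr, gene_of, site_w = _site_catalog(transcripts, config.digestion_decay)
    if tag_arr.size == 0:
        raise ValueError("no transcript carries a valid tag site")

    out = []
    for stream, gene_expr in ((2, baseline), (3, baseline * fold)):
        flat_p = gene_expr[gene_of] * site_w
        total = flat_p.sum()
        if total <= 0:
            raise ValueError("no expression mass on tag-bearing genes")
        flat_p = flat_p / total
        reads, draws = _sample_library(
            _rng(config, stream),
            config.n_tags_per_library,
            tag_arr,
            flat_p,
            config,
            gene_of,
            adapter,
        )
        out.append((reads, draws))
    (reads_co, draws_co), (reads_ds, draws_ds) = out
    if return_gene_draws:
        return reads_co, reads_ds, draws_co, draws_ds
    return reads_co, reads_ds


def simulate_dataset(
    config: SimulationConfig,
    adapter: str = DEFAULT_ADAPTER,
    return_gene_draws: bool = False,
) -> SimulationResult:
    """End-to-end convenience: transcriptome + truth + both libraries."""
    transcripts = generate_transcriptome(config)
    truth = make_truth(config)
    res = simulate_libraries(
        transcripts, truth, config, adapter=adapter, return_gene_draws=return_gene_draws
    )
    if return_gene_draws:
        reads_co, reads_ds, draws_co, draws_ds = res
        return SimulationResult(transcripts, truth, reads_co, reads_ds, draws_co, draws_ds)
    reads_co, reads_ds = res
    return SimulationResult(transcripts, truth, reads_co, reads_ds)
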