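"""End-to-end orchestration: simulate -> filter -> annotate -> saturate ->
differential expression -> enrichment -> truth evaluation."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tagdge import annotate, de, enrichment, io, saturation, simulate, tagproc

log = logging.getLogger("tagdge")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; nothing downstream is hard-coded."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    adapter: str = simulate.DEFAULT_ADAPTER
    min_adapter_prefix: int = 8
    max_mismatch: int = 1
    tpm_floor: float = 0.001
    fdr_cut: float = 0.001
    lfc_cut: float = 1.0
    fdr_method: str = "bh"
    q_cut: float = 0.05
    saturation_grid: int = 10
    saturation_reps: int = 3
    n_pathways: int = 20
    write_reads: bool = False

    @property
    def seed(self) -> int:
        return self.simulation.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("simulation", {})
        for key in ("length_range", "fold_change_set"):
            if key in sim_kwargs and isinstance(sim_kwargs[key], list):
                sim_kwargs[key] = tuple(sim_kwargs[key])
        known = {f.name for f in fields(cls)} - {"simulation"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(simulation=simulate.SimulationConfig(**sim_kwargs), **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def synthetic_pathways(
    genes: list[str], n_pathways: int, seed: int
) -> pd.DataFrame:
    """Random gene -> pathway annotation for the synthetic demo run."""
    rng = np.random.default_rng([seed, 9])
    rows = []
    for g in genes:
        for pid in rng.choice(n_pathways, size=rng.integers(1, 3), replace=False):
            rows.append(
                {"gene_id": g, "pathway_id": f"pw{pid + 1:03d}", "pathway_name": f"pathway {pid + 1}"}
            )
    return pd.DataFrame(rows)


def truth_evaluation(de_frame: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Recall per planted-fold stratum plus the overall false-discovery
    proportion among calls (NA when there are no calls)."""
    unknown = set(de_frame["gene_id"]) - set(truth["gene_id"])
    if unknown:
        raise ValueError(f"DE genes absent from truth: {sorted(unknown)[:5]}")
    merged = truth.merge(
        de_frame[["gene_id", "call"]], on="gene_id", how="left"
    )
    merged["call"] = merged["call"].fillna("none")
    merged["called"] = merged["call"] != "none"
    n_calls = int(merged["called"].sum())
    false_calls = int((merged["called"] & ~merged["is_de"]).sum())
    fdp = false_calls / n_calls if n_calls else float("nan")

    rows = []
    for fold in sorted(set(merged.loc[merged["is_de"], "fold_change"])):
        stratum = merged[merged["fold_change"] == fold]
        planted = len(stratum)
        hit = int(stratum["called"].sum())
        rows.append(
            {
                "stratum": fold,
                "n_planted": planted,
                "n_called": hit,
                "recall": hit / planted if planted else float("nan"),
            }
        )
    planted_all = merged[merged["is_de"]]
    rows.append(
        {
            "stratum": "overall",
            "n_planted": len(planted_all),
            "n_called": n_calls,
            "recall": (
                planted_all["called"].mean() if len(planted_all) else float("nan")
            ),
        }
    )
    out = pd.DataFrame(rows)
    out["fdp"] = fdp
    return out


def _table1_frame(
    tables: dict[str, tagproc.TagCountTable], thresholds=(5, 10, 20, 50, 100)
) -> pd.DataFrame:
    rows = {
        "total tags": lambda t: t.ledger.total_tags,
        "clean tags": lambda t: t.ledger.clean_tags,
        "clean tags copy number = 1": lambda t: t.ledger.singleton_tags,
        "retained tags": lambda t: t.ledger.retained_tags,
        "unique tags": lambda t: t.ledger.unique_tags,
    }
    data = {"row": list(rows)}
    strata = {lib: tagproc.copy_number_strata(t, thresholds) for lib, t in tables.items()}
    for lib, table in tables.items():
        data[lib] = [fn(table) for fn in rows.values()]
    for thr in thresholds:
        data["row"].append(f"unique tags copy number >{thr}")
        for lib in tables:
            data[lib].append(strata[lib][thr])
    return pd.DataFrame(data)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a simulated dataset and write the report bundle.

    Returns a dict with the in-memory results and output paths. All output
    TSVs carry the seed and config hash in '#' header lines, and reruns
    with the same config are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"seed={config.seed}", f"config={config.config_hash()}"]
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s ...", name)
        timings[name] = time.perf_counter()
        return timings[name]

    def done(name, detail=""):
        dt = time.perf_counter() - timings[name]
        log.info("stage %s done in %.2fs %s", name, dt, detail)

    stage("simulate")
    sim = simulate.simulate_dataset(config.simulation, adapter=config.adapter)
    io.write_fasta(sim.transcripts, outdir / "reference.fa")
    io.write_truth(sim.truth, outdir / "truth.tsv")
    if config.write_reads:
        io.write_fastq(sim.reads_co, outdir / "CO.fq")
        io.write_fastq(sim.reads_ds, outdir / "DS.fq")
    done("simulate", f"({len(sim.transcripts)} genes, {sim.reads_co.size} reads/library)")

    stage("filter")
    tables = {}
    for lib, reads in (("CO", sim.reads_co), ("DS", sim.reads_ds)):
        tables[lib] = tagproc.filter_tags(
            reads,
            config.adapter,
            min_adapter_prefix=config.min_adapter_prefix,
            library_id=lib,
        )
        io.write_tag_table(tables[lib], outdir / f"tags_{lib}.tsv", header)
        io.write_ledger_json(tables[lib].ledger, outdir / f"ledger_{lib}.json")
    io.write_frame(_table1_frame(tables), outdir / "table1.tsv", header)
    done("filter", f"(retained CO={tables['CO'].ledger.retained_tags}, DS={tables['DS'].ledger.retained_tags})")

    stage("annotate")
    index = annotate.build_index(sim.transcripts)
    counts, reports = {}, {}
    for lib in ("CO", "DS"):
        counts[lib], reports[lib] = annotate.map_tags(
            tables[lib], index, max_mismatch=config.max_mismatch
        )
    table2 = pd.DataFrame(
        [
            {
                "library": lib,
                "matched_total_tags": reports[lib].matched_tag_copies,
                "matched_unique_tags": reports[lib].matched_unique_tags,
                "matched_genes": reports[lib].matched_genes,
                **annotate.annotation_rates(reports[lib], index.n_genes),
            }
            for lib in ("CO", "DS")
        ]
    )
    io.write_frame(table2, outdir / "table2.tsv", header)
    expr = annotate.expression_frame(
        {lib: (counts[lib], tables[lib].ledger.retained_tags) for lib in ("CO", "DS")}
    )
    io.write_frame(expr, outdir / "expression.tsv", header)
    done("annotate", f"({len(index)} index keys)")

    stage("saturate")
    curves = {}
    for lib in ("CO", "DS"):
        curve = saturation.saturation_curve(
            tables[lib],
            assignment=reports[lib].assignment,
            depths=saturation.default_depth_grid(
                tables[lib].ledger.retained_tags, config.saturation_grid
            ),
            n_replicates=config.saturation_reps,
            seed=config.seed,
        )
        curves[lib] = curve
        io.write_frame(curve.to_frame(), outdir / f"saturation_{lib}.tsv", header)
    done("saturate")

    stage("de")
    counts_frame = expr.rename(columns={"count_CO": "x", "count_DS": "y"})[
        ["gene_id", "x", "y"]
    ]
    de_frame, summary = de.de_table(
        counts_frame,
        tables["CO"].ledger.retained_tags,
        tables["DS"].ledger.retained_tags,
        floor=config.tpm_floor,
        fdr_cut=config.fdr_cut,
        lfc_cut=config.lfc_cut,
        method=config.fdr_method,
    )
    io.write_frame(de_frame, outdir / "de.tsv", header)
    with open(outdir / "de_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    done("de", f"(up={summary['n_up']}, down={summary['n_down']})")

    stage("enrich")
    gene_ids = [gid for gid, _ in sim.transcripts]
    pathways = synthetic_pathways(gene_ids, config.n_pathways, config.seed)
    deg_calls = {
        row.gene_id: row.call for row in de_frame.itertuples() if row.call != "none"
    }
    enrich_frame = enrichment.enrich_all(pathways, gene_ids, deg_calls, q_cut=config.q_cut)
    io.write_frame(enrich_frame, outdir / "enrichment.tsv", header)
    done("enrich")

    stage("evaluate")
    truth_frame = io.read_truth(outdir / "truth.tsv")
    eval_frame = truth_evaluation(de_frame, truth_frame)
    io.write_frame(eval_frame, outdir / "evaluation.tsv", header)
    done("evaluate")

    return {
        "tables": tables,
        "index": index,
        "reports": reports,
        "expression": expr,
        "de": de_frame,
        "de_summary": summary,
        "curves": curves,
        "enrichment": enrich_frame,
        "evaluation": eval_frame,
        "outdir": outdir,
    }
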