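"""End-to-end orchestration: simulate fixtures, run curation + enrichment,
emit a machine-readable run report.

Reports contain nothing that is not re-derivable from the stage outputs
written alongside them, and no timestamps, so rerunning on identical inputs
yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import BaseModel

from . import __version__
from .curation import (
    DEFAULT_MIN_COUNT,
    DEFAULT_NULL_MIN_COUNT,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_THRESHOLD,
    CuratedInteractome,
    curate,
)
from .enrichment import default_universe, enrich, write_enrichment_tsv
from .errors import ConfigurationError
from .io import (
    read_contaminant_list,
    read_design,
    read_gmt,
    read_psm_table,
    write_design,
    write_network_graphml,
    write_network_sif,
    write_psm_table,
)
from .synthetic import (
    SimulationConfig,
    generate_experiment,
    write_contaminant_list,
    write_truth_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one curation + enrichment run needs.

    Paths are checked up front so a bad configuration fails before any
    output is written.
    """

    psm_path: Path
    design_path: Path
    out_dir: Path
    contaminant_path: Path | None = None
    gmt_paths: dict[str, Path] = field(default_factory=dict)  # collection name -> GMT file
    threshold: float = DEFAULT_THRESHOLD
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    min_count: int = DEFAULT_MIN_COUNT
    null_min_count: int = DEFAULT_NULL_MIN_COUNT
    inclusive: bool = False
    require_null: bool = True
    drop_contaminants: bool = False
    min_set: int = 3
    max_set: int = 2000
    universe_path: Path | None = None

    def validate(self) -> None:
        for label, p in [
            ("psm table", self.psm_path),
            ("design", self.design_path),
            ("contaminant list", self.contaminant_path),
            ("universe", self.universe_path),
            *((f"GMT {name}", p) for name, p in self.gmt_paths.items()),
        ]:
            if p is not None and not Path(p).is_file():
                raise ConfigurationError(f"{label} file does not exist: {p}")


class RunReport(BaseModel):
    """Schema of ``report.json`` (also shipped as data/report.schema.json)."""

    tool: str
    version: str
    parameters: dict
    input_checksums: dict[str, str]
    set_sizes: dict[str, int]
    overlap_percent: float
    bait: dict
    enrichment: dict[str, dict]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_simulate(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete simulated fixture directory.

    Emits the PSM table, design YAML, contaminant list, ground-truth table
    and the resolved configuration (seed included), and returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, design, truth = generate_experiment(config)
    paths = {
        "psm": out / "psm.tsv",
        "design": out / "design.yaml",
        "contaminants": out / "contaminants.txt",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.json",
    }
    write_psm_table(table, paths["psm"])
    write_design(design, paths["design"])
    write_contaminant_list(truth, paths["contaminants"])
    write_truth_table(truth, paths["truth"])
    with open(paths["config"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _ratio_str(r) -> str:
    if r is None:
        return ""
    return "inf" if math.isinf(r.ratio) else f"{r.ratio:.4g}"


def write_interactome_tsv(result: CuratedInteractome, symbols: dict[str, str], path: str | Path) -> None:
    """One row per interactome member or null-removed protein."""
    cond_bcs, cond_cu = sorted(result.records)  # "BCS", "CU"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\tgene_symbol\tratio_bcs\tratio_cu\tin_core\tcontaminant_flag\tnull_removed_flag\n")
        for p in sorted(result.interactome | result.null_removed):
            rb = result.records[cond_bcs].get(p)
            rc = result.records[cond_cu].get(p)
            fh.write(
                f"{p}\t{symbols.get(p, '')}\t{_ratio_str(rb)}\t{_ratio_str(rc)}\t"
                f"{int(p in result.core)}\t{int(p in result.contaminant_overlap)}\t"
                f"{int(p in result.null_removed)}\n"
            )


def run_all(config: RunConfig) -> dict:
    """Curation then enrichment; returns the report dict written to disk.

    Stage outputs: ``interactome.tsv``, ``network.sif``/``network.graphml``,
    one ``enrichment_<collection>.tsv`` per GMT, and ``report.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = read_psm_table(config.psm_path)
    design = read_design(config.design_path)
    contaminants = (
        read_contaminant_list(config.contaminant_path) if config.contaminant_path else set()
    )

    result = curate(
        table,
        design,
        contaminants=contaminants,
        threshold=config.threshold,
        pseudocount=config.pseudocount,
        min_count=config.min_count,
        null_min_count=config.null_min_count,
        inclusive=config.inclusive,
        require_null=config.require_null,
        drop_contaminants=config.drop_contaminants,
    )
    symbols = table.gene_symbols()
    write_interactome_tsv(result, symbols, out / "interactome.tsv")
    if result.interactome:
        write_network_sif(result.interactome, design.bait_id, out / "network.sif")
        write_network_graphml(
            result.interactome, design.bait_id, out / "network.graphml",
            core=result.core, contaminants=result.contaminant_overlap,
        )

    hit_symbols = sorted({symbols.get(p, p) for p in result.interactome})
    detected = {symbols.get(p, p) for p in table.proteins} - {design.bait_id}
    explicit_universe = None
    if config.universe_path:
        explicit_universe = [
            line.strip() for line in Path(config.universe_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]

    enrichment_report: dict[str, dict] = {}
    for name, gmt_path in sorted(config.gmt_paths.items()):
        collection = read_gmt(gmt_path)
        universe = explicit_universe if explicit_universe else default_universe(detected, collection)
        results = enrich(
            hit_symbols, universe, collection, min_set=config.min_set, max_set=config.max_set
        )
        write_enrichment_tsv(results, out / f"enrichment_{name}.tsv")
        enrichment_report[name] = {
            "sets_tested": len(results),
            "universe_size": results[0].N if results else len(set(universe)),
            "significant_q_lt_0.05": sum(1 for r in results if r.q < 0.05),
            "top_set": results[0].set_name if results else None,
        }

    checksums = {
        str(Path(p).name): _sha256(p)
        for p in [config.psm_path, config.design_path, config.contaminant_path,
                  *config.gmt_paths.values()]
        if p is not None
    }
    report = RunReport(
        tool="apmscurate",
        version=__version__,
        parameters={
            "threshold": config.threshold,
            "pseudocount": config.pseudocount,
            "min_count": config.min_count,
            "null_min_count": config.null_min_count,
            "inclusive": config.inclusive,
            "drop_contaminants": config.drop_contaminants,
            "min_set": config.min_set,
            "max_set": config.max_set,
        },
        input_checksums=checksums,
        set_sizes={
            "hits_bcs": len(result.hits_bcs),
            "hits_cu": len(result.hits_cu),
            "interactome": len(result.interactome),
            "core": len(result.core),
            "bcs_only": len(result.bcs_only),
            "cu_only": len(result.cu_only),
            "null_removed": len(result.null_removed),
            "contaminant_overlap": len(result.contaminant_overlap),
            "dropped_contaminants": len(result.dropped_contaminants),
        },
        overlap_percent=result.overlap_percent,
        bait={
            "bait_id": result.bait_id,
            "records": {
                cond: {"a": r.a, "b": r.b, "ratio": None if math.isinf(r.ratio) else r.ratio}
                for cond, r in sorted(result.bait_records.items())
            },
        },
        enrichment=enrichment_report,
    )
    doc = report.model_dump()
    with open(out / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc


def validate_report(doc: dict) -> RunReport:
    """Validate a report dict against the shipped schema; raises on failure."""
    return RunReport.model_validate(doc)


def report_schema() -> dict:
    """The JSON schema of ``report.json`` (same content as the shipped file)."""
    return RunReport.model_json_schema()
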