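"""Readers and writers for every external format the pipeline touches.

Formats
-------
PSM table        tab-separated, header ``protein_id  gene_symbol  psm  sample_id``
design file      YAML mapping sample ids to immunoprecipitation arms
contaminant list one identifier per line (first column if tab-separated)
gene sets        GMT (set name, description, then member symbols, tab-separated)
networks         SIF and GraphML bait--prey exports

All text I/O is UTF-8 with LF line endings; the TSV dialect is tab-only
with no quoting, matching the GMT convention.

Identifier policy: ``protein_id`` is an opaque string and never case-folded
(UniProt accessions are case-significant in practice); gene symbols are
case-folded wherever they are matched against gene-set collections, because
HGNC symbol casing is inconsistent across published collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .errors import ConfigurationError, DataFormatError

logger = logging.getLogger(__name__)

PSM_COLUMNS = ("protein_id", "gene_symbol", "psm", "sample_id")

GENOTYPES = ("WT", "NULL")
CONDITIONS = ("BCS", "CU", "NA")
PEPTIDES = ("plus", "minus")


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleArm:
    """Arm assignment of one IP sample.

    genotype : "WT" (bait-expressing) or "NULL" (bait-null control cells)
    condition: "BCS" (copper chelation), "CU" (copper loading) or "NA"
    peptide  : "plus" (antigenic-peptide competition) or "minus"
    """

    genotype: str
    condition: str
    peptide: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ConfigurationError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.peptide not in PEPTIDES:
            raise ConfigurationError(f"peptide must be one of {PEPTIDES}, got {self.peptide!r}")


@dataclass
class ExperimentDesign:
    """Mapping of sample identifiers to IP arms, plus the bait identifier."""

    samples: dict[str, SampleArm]
    bait_id: str

    def __post_init__(self) -> None:
        if not self.bait_id:
            raise ConfigurationError("bait_id must be nonempty")

    def samples_for(
        self,
        genotype: str | None = None,
        condition: str | None = None,
        peptide: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given (non-None) arm attribute, sorted."""
        out = []
        for sid, arm in self.samples.items():
            if genotype is not None and arm.genotype != genotype:
                continue
            if condition is not None and arm.condition != condition:
                continue
            if peptide is not None and arm.peptide != peptide:
                continue
            out.append(sid)
        return sorted(out)

    @property
    def conditions(self) -> list[str]:
        """Experimental conditions with at least one wild-type sample."""
        return sorted({a.condition for a in self.samples.values() if a.genotype == "WT" and a.condition != "NA"})


def read_design(path: str | Path) -> ExperimentDesign:
    """Read an experiment design from YAML.

    Expected layout::

        bait: ATP7A
        samples:
          WT_BCS_minus: {genotype: WT, condition: BCS, peptide: minus}
          ...
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc or "bait" not in doc:
        raise DataFormatError(f"{path}: design file must contain 'bait' and 'samples' keys")
    samples = {}
    for sid, spec in doc["samples"].items():
        try:
            samples[str(sid)] = SampleArm(
                genotype=str(spec["genotype"]),
                condition=str(spec["condition"]),
                peptide=str(spec["peptide"]),
            )
        except KeyError as exc:
            raise DataFormatError(f"{path}: sample {sid!r} missing key {exc}") from exc
    return ExperimentDesign(samples=samples, bait_id=str(doc["bait"]))


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    doc = {
        "bait": design.bait_id,
        "samples": {
            sid: {"genotype": a.genotype, "condition": a.condition, "peptide": a.peptide}
            for sid, a in sorted(design.samples.items())
        },
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

@dataclass
class PSMTable:
    """Long-form table of per-sample spectral counts per protein.

    One row per (protein, sample); duplicates are summed on construction,
    which makes re-ingestion of concatenated search outputs safe.  Rows are
    kept in (protein_id, sample_id) sorted order so that equal tables are
    byte-identical on disk.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PSM_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataFormatError(f"PSM table missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(PSM_COLUMNS)].copy()
        if len(df):
            bad = df["psm"] < 0
            if bad.any():
                raise DataFormatError("PSM table contains negative counts")
        df["psm"] = df["psm"].astype(int)
        df["gene_symbol"] = df["gene_symbol"].fillna("").astype(str)
        # sum duplicate (protein, sample) keys, keeping the first gene symbol
        df = (
            df.groupby(["protein_id", "sample_id"], as_index=False)
            .agg(gene_symbol=("gene_symbol", "first"), psm=("psm", "sum"))
            .loc[:, list(PSM_COLUMNS)]
            .sort_values(["protein_id", "sample_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def proteins(self) -> set[str]:
        return set(self.df["protein_id"])

    @property
    def sample_ids(self) -> set[str]:
        return set(self.df["sample_id"])

    def gene_symbols(self) -> dict[str, str]:
        """First nonempty gene symbol seen for each protein."""
        sub = self.df[self.df["gene_symbol"] != ""]
        return dict(zip(sub["protein_id"], sub["gene_symbol"]))

    def arm_counts(self, sample_ids: Iterable[str]) -> dict[str, int]:
        """Summed PSM per protein across the given samples (absent = no key)."""
        ids = set(sample_ids)
        sub = self.df[self.df["sample_id"].isin(ids)]
        return sub.groupby("protein_id")["psm"].sum().to_dict()


def read_psm_table(path: str | Path) -> PSMTable:
    """Read a PSM TSV, summing duplicate (protein, sample) rows.

    Raises :class:`DataFormatError` naming the missing column, or a value
    error with the offending line number for negative / non-integer counts.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in PSM_COLUMNS if c not in header]
        if missing:
            raise DataFormatError(f"{path}: missing column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in PSM_COLUMNS}
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise DataFormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            raw = fields[idx["psm"]]
            try:
                psm = int(raw)
            except ValueError:
                raise DataFormatError(f"{path}:{lineno}: non-integer psm value {raw!r}") from None
            if psm < 0:
                raise DataFormatError(f"{path}:{lineno}: negative psm value {psm}")
            rows.append((fields[idx["protein_id"]], fields[idx["gene_symbol"]], psm, fields[idx["sample_id"]]))
    if not rows:
        logger.warning("%s: PSM table has a header but no data rows", path)
    df = pd.DataFrame(rows, columns=list(PSM_COLUMNS))
    return PSMTable(df)


def write_psm_table(table: PSMTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for row in table.df.itertuples(index=False):
            fh.write(f"{row.protein_id}\t{row.gene_symbol}\t{row.psm}\t{row.sample_id}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]  # case-folded symbols


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit test universe.

    Member symbols are case-folded at read time; all downstream matching is
    therefore case-insensitive on symbols.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.members
        return frozenset(out)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per nonblank line, members deduplicated."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc = fields[0], fields[1]
            members = frozenset(m.casefold() for m in fields[2:] if m)
            sets[name] = GeneSet(name=name, description=desc, members=members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(collection.sets):
            gs = collection.sets[name]
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# contaminant lists
# ---------------------------------------------------------------------------

def read_contaminant_list(path: str | Path) -> set[str]:
    """Read a contaminant list: one identifier per nonblank line.

    If a line is tab-separated the first column is taken.  An empty file
    yields an empty set with a warning, not an error.
    """
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            out.add(line.split("\t")[0])
    if not out:
        logger.warning("%s: contaminant list is empty", path)
    return out


def write_contaminant_list(identifiers: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ident in sorted(identifiers):
            fh.write(ident + "\n")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network_sif(interactome: Iterable[str], bait_id: str, path: str | Path) -> None:
    """Write a bait-centred star network in SIF, one edge per interactor."""
    preys = sorted(set(interactome))
    if not preys:
        raise ConfigurationError("cannot export an empty interactome")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for prey in preys:
            fh.write(f"{bait_id}\tinteracts\t{prey}\n")


def write_network_graphml(
    interactome: Iterable[str],
    bait_id: str,
    path: str | Path,
    core: Iterable[str] = (),
    contaminants: Iterable[str] = (),
) -> None:
    """GraphML variant of the star network with per-node annotations.

    Nodes carry ``core`` (stable interactor present under both copper
    conditions) and ``contaminant`` (on the supplied bead-background list)
    boolean attributes.
    """
    import networkx as nx

    preys = sorted(set(interactome))
    if not preys:
        raise ConfigurationError("cannot export an empty interactome")
    core_set, contam_set = set(core), set(contaminants)
    g = nx.Graph()
    g.add_node(bait_id, role="bait", core=False, contaminant=False)
    for prey in preys:
        g.add_node(prey, role="prey", core=prey in core_set, contaminant=prey in contam_set)
        g.add_edge(bait_id, prey, interaction="interacts")
    nx.write_graphml(g, path)
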