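"""Specificity filtering and curation of AP-MS spectral counts.

The core computation of the pipeline.  A bait is immunoprecipitated with
and without an excess of its antigenic peptide; the peptide blocks the
antibody's specific binding, so true preys drop out of the +peptide arm
while bead-background binders do not.  Calling is therefore a per-protein
enrichment ratio

    ratio = (a + c) / (b + c)

where ``a`` is the summed PSM count across -peptide samples of one copper
condition, ``b`` the summed PSM count across +peptide samples of that
condition, and ``c`` a small pseudocount guarding against division noise.
A protein is a hit when the ratio strictly exceeds the threshold (default
2-fold).  Hits recovered from bait-null cells are then eliminated, the two
copper conditions (chelation vs loading) are reconciled into a union
("interactome") and an intersection ("core", the stable interactors seen
regardless of copper status), and the result is annotated against a
bead-background contaminant list such as the CRAPome.

Zero-in-control rule: a protein never seen in the +peptide arm but seen at
least ``min_count`` times without competitor is the strongest qualitative
evidence the design offers, and auto-passes with ratio +inf; below
``min_count`` the pseudocount ratio is evaluated normally, which keeps
single-spectrum observations from passing on division noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .errors import ConfigurationError
from .io import ExperimentDesign, PSMTable

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_COUNT = 2
DEFAULT_NULL_MIN_COUNT = 2


@dataclass(frozen=True)
class RatioRecord:
    """Enrichment evidence for one protein in one copper condition."""

    protein_id: str
    a: int  # summed PSM, -peptide samples
    b: int  # summed PSM, +peptide samples
    ratio: float  # may be +inf under the zero-in-control rule
    passed: bool


@dataclass
class CuratedInteractome:
    """Final curated hit sets plus the evidence behind them.

    ``interactome`` is the union of the per-condition hit sets after null
    subtraction, ``core`` their intersection.  Contaminant-list members are
    annotated, not removed (the list is a quality check, not a filter),
    unless curation was run with ``drop_contaminants``.
    """

    hits_bcs: frozenset[str]
    hits_cu: frozenset[str]
    interactome: frozenset[str]
    core: frozenset[str]
    bcs_only: frozenset[str]
    cu_only: frozenset[str]
    null_removed: frozenset[str]
    contaminant_overlap: frozenset[str]
    overlap_percent: float
    records: dict[str, dict[str, RatioRecord]] = field(default_factory=dict)  # condition -> protein -> record
    bait_id: str = ""
    bait_records: dict[str, RatioRecord] = field(default_factory=dict)
    dropped_contaminants: frozenset[str] = frozenset()


def enrichment_ratio(
    a: int,
    b: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_count: int = DEFAULT_MIN_COUNT,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = False,
) -> tuple[float, bool]:
    """Ratio of -peptide to +peptide evidence and its pass/fail call.

    Parameters
    ----------
    a, b
        Summed PSM counts in the -peptide and +peptide arms.
    pseudocount
        Added symmetrically to numerator and denominator.
    min_count
        Minimum ``a`` for the zero-in-control auto-pass when ``b == 0``.
    threshold
        Fold-change cut, strict ``>`` by default.
    inclusive
        Use ``>=`` at the threshold instead of strict ``>``.
    """
    if a < 0 or b < 0:
        raise ValueError(f"PSM counts must be nonnegative, got a={a}, b={b}")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {pseudocount}")
    if min_count < 1:
        raise ValueError(f"min_count must be a positive integer, got {min_count}")
    if b == 0 and a >= min_count:
        return math.inf, True
    ratio = (a + pseudocount) / (b + pseudocount)
    passed = ratio >= threshold if inclusive else ratio > threshold
    return ratio, passed


def call_hits(
    table: PSMTable,
    design: ExperimentDesign,
    condition: str,
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_count: int = DEFAULT_MIN_COUNT,
    inclusive: bool = False,
) -> dict[str, RatioRecord]:
    """Ratio records for every protein observed in the -peptide arm.

    PSMs are summed within each arm across replicate samples before the
    ratio is formed (spectral counts are additive evidence).  Proteins
    absent from the -peptide arm get no record and cannot be hits.  The
    bait is evaluated like any prey.
    """
    minus = design.samples_for(genotype="WT", condition=condition, peptide="minus")
    plus = design.samples_for(genotype="WT", condition=condition, peptide="plus")
    if not minus or not plus:
        raise ConfigurationError(
            f"condition {condition!r} needs at least one WT -peptide and one WT +peptide sample"
        )
    a_counts = table.arm_counts(minus)
    b_counts = table.arm_counts(plus)
    records: dict[str, RatioRecord] = {}
    for protein, a in a_counts.items():
        b = b_counts.get(protein, 0)
        ratio, passed = enrichment_ratio(
            a, b, pseudocount=pseudocount, min_count=min_count, threshold=threshold, inclusive=inclusive
        )
        records[protein] = RatioRecord(protein_id=protein, a=a, b=b, ratio=ratio, passed=passed)
    return records


def hit_set(records: dict[str, RatioRecord]) -> frozenset[str]:
    return frozenset(p for p, r in records.items() if r.passed)


def subtract_null(
    hits: frozenset[str] | set[str],
    table: PSMTable,
    design: ExperimentDesign,
    null_min_count: int = DEFAULT_NULL_MIN_COUNT,
) -> tuple[frozenset[str], frozenset[str]]:
    """Eliminate hits recovered from bait-null cells.

    A hit is removed iff its summed PSM across NULL -peptide samples is at
    least ``null_min_count`` (default 2, so a single stray spectrum in the
    null control does not discard a hit).  Returns (curated, removed),
    disjoint sets whose union is the input.
    """
    null_samples = design.samples_for(genotype="NULL", peptide="minus")
    if not null_samples:
        raise ConfigurationError(
            "design has no NULL-genotype -peptide sample; curation without a "
            "null control must be requested explicitly (require_null=False)"
        )
    null_counts = table.arm_counts(null_samples)
    removed = frozenset(p for p in hits if null_counts.get(p, 0) >= null_min_count)
    curated = frozenset(hits) - removed
    return curated, removed


def reconcile_conditions(
    hits_bcs: frozenset[str] | set[str],
    hits_cu: frozenset[str] | set[str],
) -> dict[str, frozenset[str]]:
    """Union/intersection reconciliation of the two copper conditions.

    The union is the interactome; the intersection ("core") holds preys
    present regardless of cellular copper status, interpreted as stable
    and/or strong interactors.
    """
    bcs, cu = frozenset(hits_bcs), frozenset(hits_cu)
    return {
        "interactome": bcs | cu,
        "core": bcs & cu,
        "bcs_only": bcs - cu,
        "cu_only": cu - bcs,
    }


def contaminant_overlap(
    interactome: frozenset[str] | set[str],
    contaminants: frozenset[str] | set[str],
) -> tuple[frozenset[str], float]:
    """Overlap with a bead-background contaminant list, as a percentage.

    The percentage is relative to the interactome, rounded half-up to one
    decimal; an empty interactome reports 0.0 with a warning.
    """
    overlap = frozenset(interactome) & frozenset(contaminants)
    if not interactome:
        logger.warning("empty interactome; contaminant overlap reported as 0.0%%")
        return overlap, 0.0
    percent = Decimal(100 * len(overlap)) / Decimal(len(interactome))
    return overlap, float(percent.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def curate(
    table: PSMTable,
    design: ExperimentDesign,
    contaminants: frozenset[str] | set[str] = frozenset(),
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_count: int = DEFAULT_MIN_COUNT,
    null_min_count: int = DEFAULT_NULL_MIN_COUNT,
    inclusive: bool = False,
    require_null: bool = True,
    drop_contaminants: bool = False,
    conditions: tuple[str, str] = ("BCS", "CU"),
) -> CuratedInteractome:
    """Full curation: per-condition calling, null subtraction, reconciliation.

    The bait passes the ratio filter like any protein but is excluded from
    the reported interactome (it is the bait, not a prey); its ratio
    records are retained for the run report.
    """
    cond_bcs, cond_cu = conditions
    records_bcs = call_hits(table, design, cond_bcs, threshold, pseudocount, min_count, inclusive)
    records_cu = call_hits(table, design, cond_cu, threshold, pseudocount, min_count, inclusive)
    hits_bcs, hits_cu = hit_set(records_bcs), hit_set(records_cu)

    null_removed: frozenset[str] = frozenset()
    if require_null or design.samples_for(genotype="NULL", peptide="minus"):
        curated_bcs, removed_bcs = subtract_null(hits_bcs, table, design, null_min_count)
        curated_cu, removed_cu = subtract_null(hits_cu, table, design, null_min_count)
        hits_bcs, hits_cu = curated_bcs, curated_cu
        null_removed = removed_bcs | removed_cu

    bait = design.bait_id
    bait_records = {
        cond: recs[bait]
        for cond, recs in ((cond_bcs, records_bcs), (cond_cu, records_cu))
        if bait in recs
    }
    hits_bcs -= {bait}
    hits_cu -= {bait}
    null_removed -= {bait}

    dropped: frozenset[str] = frozenset()
    if drop_contaminants:
        dropped = (hits_bcs | hits_cu) & frozenset(contaminants)
        hits_bcs -= dropped
        hits_cu -= dropped

    parts = reconcile_conditions(hits_bcs, hits_cu)
    overlap, percent = contaminant_overlap(parts["interactome"], contaminants)
    return CuratedInteractome(
        hits_bcs=hits_bcs,
        hits_cu=hits_cu,
        interactome=parts["interactome"],
        core=parts["core"],
        bcs_only=parts["bcs_only"],
        cu_only=parts["cu_only"],
        null_removed=null_removed,
        contaminant_overlap=overlap,
        overlap_percent=percent,
        records={cond_bcs: records_bcs, cond_cu: records_cu},
        bait_id=bait,
        bait_records=bait_records,
        dropped_contaminants=dropped,
    )
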