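"""Ground-truthed synthetic AP-MS experiments.

Emulates the four-arm peptide-competition design plus a bait-null control:

====================  ========================================================
arm                   behaviour
====================  ========================================================
WT / -peptide / BCS   true preys of the chelated condition at mean ``mu_true``
WT / +peptide / BCS   same preys suppressed to ``mu_true * suppression``
WT / -peptide / CU    true preys of the copper-loaded condition
WT / +peptide / CU    suppressed, as above
NULL / -peptide       bait-null cells: background only (plus a small leak)
====================  ========================================================

Bead-background proteins draw counts at mean ``mu_background`` in every arm
including the null; true preys are suppressed by the competing antigenic
peptide in +peptide arms and are essentially absent from null cells.  Counts
are negative binomial parameterized by (mean, dispersion); the Poisson case
is recovered as dispersion grows large.  Overdispersion is the norm for
spectral counts, which is why the generator does not default to Poisson.

True preys in the null arm draw at mean ``null_leak * mu_background``
(default 0.05, i.e. mu_background/20) rather than structurally zero, so
null subtraction is exercised nontrivially; set ``null_leak = 0`` for exact
zeros.  At the default calibration roughly one true prey in fifteen trips
the null filter, mimicking the collateral losses a real genetic-null
control inflicts.

The bait's counts are fixed, not sampled, so bait-detection behaviour is
deterministic.  Randomness uses one top-level seed with per-arm substreams
derived as ``seed + arm offset`` (offsets 1..5 in the table's order), so
adding an arm does not reshuffle draws in existing arms.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .curation import CuratedInteractome
from .errors import ConfigurationError, DataFormatError
from .io import ExperimentDesign, PSMTable, SampleArm
from .io import write_contaminant_list as _write_ids

BAIT_ID = "ATP7A"

# sample ids double as arm names; offsets define the per-arm RNG substreams
ARM_OFFSETS: Mapping[str, int] = {
    "WT_BCS_minus": 1,
    "WT_BCS_plus": 2,
    "WT_CU_minus": 3,
    "WT_CU_plus": 4,
    "NULL_NA_minus": 5,
}

LABELS = ("true_prey", "background", "bait")
MEMBERSHIPS = ("BCS_only", "Cu_only", "both", "n/a")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated four-arm experiment.

    Defaults describe a realistic neuronal-cell bait IP: 150 true preys
    against 800 bead-background proteins, a 25-spectra prey signal over an
    8-spectra background, tenfold suppression by the competing peptide, and
    moderate overdispersion (negative-binomial size 5).
    """

    n_true: int = 150
    n_background: int = 800
    frac_shared: float = 0.5
    mu_true: float = 25.0
    mu_background: float = 8.0
    suppression: float = 0.1
    dispersion: float = 5.0
    frac_contaminant: float = 0.3
    bait_psm: int = 200
    null_leak: float = 0.05  # true-prey null-arm mean, as a fraction of mu_background
    seed: int = 7

    def validate(self) -> None:
        if self.n_true < 0:
            raise ConfigurationError(f"n_true must be nonnegative, got {self.n_true}")
        if self.n_background < 0:
            raise ConfigurationError(f"n_background must be nonnegative, got {self.n_background}")
        if not 0 <= self.frac_shared <= 1:
            raise ConfigurationError(f"frac_shared must be in [0, 1], got {self.frac_shared}")
        if self.mu_true < 0:
            raise ConfigurationError(f"mu_true must be nonnegative, got {self.mu_true}")
        if self.mu_background < 0:
            raise ConfigurationError(f"mu_background must be nonnegative, got {self.mu_background}")
        if not 0 < self.suppression <= 1:
            raise ConfigurationError(f"suppression must be in (0, 1], got {self.suppression}")
        if self.dispersion <= 0:
            raise ConfigurationError(f"dispersion must be positive, got {self.dispersion}")
        if not 0 <= self.frac_contaminant <= 1:
            raise ConfigurationError(f"frac_contaminant must be in [0, 1], got {self.frac_contaminant}")
        if self.bait_psm < 0:
            raise ConfigurationError(f"bait_psm must be nonnegative, got {self.bait_psm}")
        if self.null_leak < 0:
            raise ConfigurationError(f"null_leak must be nonnegative, got {self.null_leak}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class SyntheticTruth:
    """Ground-truth labels for one simulated experiment.

    Labels partition the protein universe into true preys, bead background
    and the bait; condition membership records which copper condition(s)
    each true prey binds under; contaminant-flagged proteins are always
    background (the bead proteome is what contaminant lists catalogue).
    """

    labels: dict[str, str]
    membership: dict[str, str]
    contaminants: frozenset[str]

    def validate(self) -> None:
        for p, lab in self.labels.items():
            if lab not in LABELS:
                raise ConfigurationError(f"unknown label {lab!r} for {p!r}")
            if self.membership.get(p) not in MEMBERSHIPS:
                raise ConfigurationError(f"missing/unknown condition membership for {p!r}")
        if sum(1 for v in self.labels.values() if v == "bait") != 1:
            raise ConfigurationError("truth must contain exactly one bait")
        for c in self.contaminants:
            if self.labels.get(c) != "background":
                raise ConfigurationError(f"contaminant {c!r} is not labelled background")

    @property
    def true_preys(self) -> frozenset[str]:
        return frozenset(p for p, v in self.labels.items() if v == "true_prey")

    @property
    def background(self) -> frozenset[str]:
        return frozenset(p for p, v in self.labels.items() if v == "background")

    @property
    def bait_id(self) -> str:
        return next(p for p, v in self.labels.items() if v == "bait")

    def preys_of(self, condition: str) -> frozenset[str]:
        """True preys binding under one condition ("BCS" or "CU")."""
        want = {"BCS": ("BCS_only", "both"), "CU": ("Cu_only", "both")}[condition]
        return frozenset(p for p in self.true_preys if self.membership[p] in want)


def _nb_draw(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with per-protein means; mean 0 gives count 0."""
    counts = np.zeros(means.shape, dtype=int)
    mask = means > 0
    if mask.any():
        mu = means[mask]
        counts[mask] = rng.negative_binomial(dispersion, dispersion / (dispersion + mu))
    return counts


def generate_experiment(
    config: SimulationConfig,
) -> tuple[PSMTable, ExperimentDesign, SyntheticTruth]:
    """Simulate one four-arm competition IP plus bait-null control.

    Returns a long-form PSM table (zero counts omitted, i.e. undetected
    proteins are simply absent from a sample), the matching design, and the
    ground truth.  Identical configs (including seed) give identical output.
    """
    config.validate()

    # --- protein universe and truth ------------------------------------
    preys = [f"PREY_{i:04d}" for i in range(1, config.n_true + 1)]
    bg = [f"BG_{i:04d}" for i in range(1, config.n_background + 1)]
    n_shared = round(config.frac_shared * config.n_true)
    n_private = config.n_true - n_shared
    n_cu = n_private // 2  # rounding remainder goes to BCS-only
    n_bcs = n_private - n_cu
    membership = {}
    for i, p in enumerate(preys):
        if i < n_shared:
            membership[p] = "both"
        elif i < n_shared + n_bcs:
            membership[p] = "BCS_only"
        else:
            membership[p] = "Cu_only"
    labels = {p: "true_prey" for p in preys}
    labels.update({p: "background" for p in bg})
    labels[BAIT_ID] = "bait"
    membership.update({p: "n/a" for p in bg})
    membership[BAIT_ID] = "n/a"
    n_contam = round(config.frac_contaminant * config.n_background)
    truth = SyntheticTruth(labels=labels, membership=membership, contaminants=frozenset(bg[:n_contam]))
    truth.validate()

    # --- design ---------------------------------------------------------
    samples = {
        "WT_BCS_minus": SampleArm("WT", "BCS", "minus"),
        "WT_BCS_plus": SampleArm("WT", "BCS", "plus"),
        "WT_CU_minus": SampleArm("WT", "CU", "minus"),
        "WT_CU_plus": SampleArm("WT", "CU", "plus"),
        "NULL_NA_minus": SampleArm("NULL", "NA", "minus"),
    }
    design = ExperimentDesign(samples=samples, bait_id=BAIT_ID)

    # --- counts, one RNG substream per arm ------------------------------
    proteins = preys + bg  # fixed draw order within every arm
    prey_mask = np.array([labels[p] == "true_prey" for p in proteins])
    rows: list[tuple[str, str, int, str]] = []
    for sample_id, offset in ARM_OFFSETS.items():
        arm = samples[sample_id]
        rng = np.random.default_rng(config.seed + offset)
        means = np.full(len(proteins), config.mu_background, dtype=float)
        if arm.genotype == "NULL":
            means[prey_mask] = config.null_leak * config.mu_background
        else:
            member = np.array(
                [labels[p] == "true_prey" and p in truth.preys_of(arm.condition) for p in proteins]
            )
            means[prey_mask & ~member] = 0.0
            mu = config.mu_true if arm.peptide == "minus" else config.mu_true * config.suppression
            means[member] = mu
        counts = _nb_draw(rng, means, config.dispersion)
        for p, c in zip(proteins, counts):
            if c > 0:
                rows.append((p, p, int(c), sample_id))
        # bait counts are fixed, not sampled
        if arm.genotype == "WT":
            bait_c = config.bait_psm if arm.peptide == "minus" else round(config.bait_psm * config.suppression)
            if bait_c > 0:
                rows.append((BAIT_ID, BAIT_ID, bait_c, sample_id))
    table = PSMTable(pd.DataFrame(rows, columns=["protein_id", "gene_symbol", "psm", "sample_id"]))
    return table, design, truth


def write_contaminant_list(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the flagged bead-background proteins, one per line, sorted."""
    truth.validate()
    _write_ids(truth.contaminants, path)


TRUTH_COLUMNS = ("protein_id", "label", "condition_membership", "contaminant")


def write_truth_table(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for p in sorted(truth.labels):
            flag = "1" if p in truth.contaminants else "0"
            fh.write(f"{p}\t{truth.labels[p]}\t{truth.membership[p]}\t{flag}\n")


def read_truth_table(path: str | Path) -> SyntheticTruth:
    labels: dict[str, str] = {}
    membership: dict[str, str] = {}
    contaminants: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise DataFormatError(f"{path}: bad truth-table header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            p, lab, mem, flag = line.split("\t")
            labels[p] = lab
            membership[p] = mem
            if flag == "1":
                contaminants.add(p)
    truth = SyntheticTruth(labels=labels, membership=membership, contaminants=frozenset(contaminants))
    truth.validate()
    return truth


@dataclass(frozen=True)
class RecoveryReport:
    """Recall/precision of a curated interactome against ground truth.

    ``precision`` is None (undefined) when the curated set is empty, never
    silently 0.  Per-condition confusion counts use the per-condition hit
    sets against the condition's true preys.
    """

    recall: float | None
    precision: float | None
    tp: int
    fp: int
    fn: int
    per_condition: dict[str, dict[str, int]]


def evaluate_recovery(
    curated: CuratedInteractome | frozenset[str] | set[str],
    truth: SyntheticTruth,
) -> RecoveryReport:
    """Score a curated interactome against the simulation's ground truth."""
    if isinstance(curated, CuratedInteractome):
        called = set(curated.interactome)
        per_cond_sets = {"BCS": set(curated.hits_bcs), "CU": set(curated.hits_cu)}
    else:
        called = set(curated)
        per_cond_sets = {}
    universe = set(truth.labels)
    if called and not (called & universe):
        raise ConfigurationError("curated identifiers share nothing with the truth's namespace")

    true_preys = truth.true_preys
    tp = len(called & true_preys)
    fp = len(called - true_preys)
    fn = len(true_preys - called)
    recall = tp / len(true_preys) if true_preys else None
    precision = tp / len(called) if called else None

    per_condition = {}
    for cond, hits in per_cond_sets.items():
        pos = truth.preys_of(cond)
        per_condition[cond] = {
            "tp": len(hits & pos),
            "fp": len(hits - pos),
            "fn": len(pos - hits),
        }
    return RecoveryReport(recall=recall, precision=precision, tp=tp, fp=fp, fn=fn, per_condition=per_condition)
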