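"""The specificity filter and curation steps, checked against worked
examples and an independent straight-line oracle, plus property tests."""

import dataclasses
import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmscurate.curation import (
    call_hits,
    contaminant_overlap,
    curate,
    enrichment_ratio,
    hit_set,
    reconcile_conditions,
    subtract_null,
)
from apmscurate.errors import ConfigurationError
from apmscurate.io import ExperimentDesign, PSMTable, SampleArm
from apmscurate.pipeline import run_simulate
from apmscurate.synthetic import SimulationConfig, generate_experiment
from oracles import curation_oracle


def make_table(rows):
    return PSMTable(pd.DataFrame(rows, columns=["protein_id", "gene_symbol", "psm", "sample_id"]))


def make_design(with_null=True):
    samples = {
        "m": SampleArm("WT", "BCS", "minus"),
        "p": SampleArm("WT", "BCS", "plus"),
        "mc": SampleArm("WT", "CU", "minus"),
        "pc": SampleArm("WT", "CU", "plus"),
    }
    if with_null:
        samples["n"] = SampleArm("NULL", "NA", "minus")
    return ExperimentDesign(samples=samples, bait_id="BAIT")


class TestEnrichmentRatio:
    @pytest.mark.parametrize("a,b,pseudo,expect_ratio,expect_pass", [
        (10, 4, 0.0, 2.5, True),
        (6, 3, 0.0, 2.0, False),        # strict > at the threshold
        (1, 0, 0.5, 3.0, True),         # below min_count: pseudocount path
        (0, 0, 0.5, 1.0, False),
    ])
    def test_worked_examples(self, a, b, pseudo, expect_ratio, expect_pass):
        ratio, passed = enrichment_ratio(a, b, pseudocount=pseudo, min_count=2)
        assert ratio == pytest.approx(expect_ratio)
        assert passed is expect_pass

    def test_zero_in_control_auto_pass(self):
        ratio, passed = enrichment_ratio(5, 0, min_count=2)
        assert math.isinf(ratio) and passed

    def test_inclusive_mode_passes_at_exactly_twofold(self):
        assert enrichment_ratio(6, 3, pseudocount=0.0, inclusive=True)[1]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(-1, 0)

    @given(
        a=st.integers(0, 500), b=st.integers(0, 500),
        da=st.integers(0, 50), db=st.integers(0, 50),
        pseudo=st.floats(0.1, 2.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_evidence(self, a, b, da, db, pseudo):
        """Ratio never decreases with more -pep evidence, never increases
        with more +pep evidence."""
        r0 = enrichment_ratio(a, b, pseudocount=pseudo)[0]
        assert enrichment_ratio(a + da, b, pseudocount=pseudo)[0] >= r0
        assert enrichment_ratio(a, b + db, pseudocount=pseudo)[0] <= r0


class TestCallHits:
    def test_toy_table(self):
        table = make_table([
            ("X", "X", 20, "m"), ("X", "X", 2, "p"),
            ("Y", "Y", 5, "m"), ("Y", "Y", 5, "p"),
            ("Z", "Z", 9, "p"),  # absent from -pep arm: no record
        ])
        records = call_hits(table, make_design(), "BCS")
        assert hit_set(records) == {"X"}
        assert set(records) == {"X", "Y"}

    def test_replicates_summed_within_arm(self):
        design = ExperimentDesign(
            samples={
                "m1": SampleArm("WT", "BCS", "minus"),
                "m2": SampleArm("WT", "BCS", "minus"),
                "p": SampleArm("WT", "BCS", "plus"),
            },
            bait_id="BAIT",
        )
        table = make_table([("X", "X", 5, "m1"), ("X", "X", 6, "m2"), ("X", "X", 4, "p")])
        rec = call_hits(table, design, "BCS")["X"]
        assert (rec.a, rec.b) == (11, 4)

    def test_missing_condition_is_configuration_error(self):
        table = make_table([("X", "X", 1, "m")])
        with pytest.raises(ConfigurationError):
            call_hits(table, make_design(), "ZN")

    def test_threshold_coherence_on_simulated_data(self, small_config):
        """Raising the fold-change threshold never enlarges a hit set."""
        table, design, _ = generate_experiment(small_config)
        prev = None
        for thr in (1.5, 2.0, 3.0, 5.0):
            hits = hit_set(call_hits(table, design, "BCS", threshold=thr))
            if prev is not None:
                assert hits <= prev
            prev = hits


class TestSubtractNull:
    def test_removal_rule(self):
        table = make_table([("B", "B", 5, "n")])
        curated, removed = subtract_null({"A", "B", "C"}, table, make_design(), 2)
        assert curated == {"A", "C"} and removed == {"B"}

    def test_all_zero_null_keeps_everything(self):
        table = make_table([("A", "A", 3, "m")])
        curated, removed = subtract_null({"A"}, table, make_design(), 2)
        assert curated == {"A"} and removed == set()

    def test_single_spectrum_below_min_count_retained(self):
        table = make_table([("A", "A", 1, "n")])
        curated, removed = subtract_null({"A"}, table, make_design(), 2)
        assert curated == {"A"}

    def test_missing_null_arm_is_configuration_error(self):
        table = make_table([("A", "A", 3, "m")])
        with pytest.raises(ConfigurationError):
            subtract_null({"A"}, table, make_design(with_null=False), 2)


class TestReconcileAndOverlap:
    def test_union_and_core(self):
        parts = reconcile_conditions({"A", "B"}, {"B", "C"})
        assert parts["interactome"] == {"A", "B", "C"}
        assert parts["core"] == {"B"}
        assert len(parts["bcs_only"]) + len(parts["cu_only"]) + len(parts["core"]) == 3

    def test_identical_inputs_core_equals_interactome(self):
        parts = reconcile_conditions({"A", "B"}, {"A", "B"})
        assert parts["core"] == parts["interactome"]

    def test_published_scale_overlap(self):
        """At the published scale (541 interactors, 335 bead-proteome
        entries, 31 shared) the overlap reports 5.7%."""
        interactome = {f"I{i}" for i in range(510)} | {f"S{i}" for i in range(31)}
        crapome = {f"S{i}" for i in range(31)} | {f"C{i}" for i in range(304)}
        overlap, percent = contaminant_overlap(interactome, crapome)
        assert len(interactome) == 541 and len(crapome) == 335
        assert len(overlap) == 31
        assert percent == 5.7

    def test_empty_contaminants(self):
        assert contaminant_overlap({"A"}, set()) == (frozenset(), 0.0)

    def test_full_overlap(self):
        _, percent = contaminant_overlap({"A", "B"}, {"A", "B", "C"})
        assert percent == 100.0

    def test_empty_interactome_reports_zero(self):
        assert contaminant_overlap(set(), {"A"})[1] == 0.0


class TestFullCuration:
    def test_matches_straightline_oracle_small(self, small_config, tmp_path):
        paths = run_simulate(small_config, tmp_path)
        oracle = curation_oracle(paths["psm"], paths["design"])
        table, design, truth = generate_experiment(small_config)
        result = curate(table, design, contaminants=truth.contaminants)
        assert result.hits_bcs == oracle["BCS"]
        assert result.hits_cu == oracle["CU"]
        assert result.interactome == oracle["interactome"]
        assert result.core == oracle["core"]
        assert result.null_removed == oracle["null_removed"]

    def test_set_algebra_invariants(self, default_curation):
        result, _ = default_curation
        assert result.core <= result.interactome
        assert result.hits_bcs | result.hits_cu == result.interactome
        assert result.core <= result.hits_bcs and result.core <= result.hits_cu
        assert not result.interactome & result.null_removed
        assert result.contaminant_overlap <= result.interactome

    def test_bait_excluded_but_reported(self, default_curation):
        result, truth = default_curation
        assert truth.bait_id not in result.interactome
        assert set(result.bait_records) == {"BCS", "CU"}
        assert all(r.passed for r in result.bait_records.values())

    def test_drop_contaminants_flag(self, default_experiment):
        _, table, design, truth = default_experiment
        kept = curate(table, design, contaminants=truth.contaminants)
        dropped = curate(table, design, contaminants=truth.contaminants, drop_contaminants=True)
        assert dropped.interactome == kept.interactome - kept.contaminant_overlap
        assert dropped.dropped_contaminants == kept.contaminant_overlap
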