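import numpy as np
import pytest

from paleodiv import (
    Dataset,
    TaxonRange,
    compare_datasets,
    perturb_dataset,
    summarize,
)
from paleodiv.comparison import records_to_frame
from paleodiv.errors import ConfigError

from conftest import random_resolved_dataset


def _cat(records):
    return {r.taxon: r.category for r in records}


class TestCategories:
    def test_non_overlapping_longer_range_is_extension(self, gts):
        """A wholesale move to a larger stage set still counts as an extension."""
        old = Dataset([TaxonRange("Hanidae", "Artinskian", "Artinskian")])
        new = Dataset([TaxonRange("Hanidae", "Gzhelian", "Sakmarian")])
        records = compare_datasets(new, old, gts, "stage")
        assert _cat(records)["Hanidae"] == "extension"

    def test_identical_ranges_no_change(self, gts):
        d = Dataset([TaxonRange("X", "Aptian", "Albian")])
        assert _cat(compare_datasets(d, d, gts, "stage"))["X"] == "no_change"

    def test_same_count_different_set_is_shift(self, ts20):
        old = Dataset([TaxonRange("X", "S05", "S06")])
        new = Dataset([TaxonRange("X", "S06", "S07")])
        assert _cat(compare_datasets(new, old, ts20, "stage"))["X"] == "shift"

    def test_fewer_stages_is_contraction(self, ts20):
        old = Dataset([TaxonRange("X", "S05", "S09")])
        new = Dataset([TaxonRange("X", "S06", "S08")])
        assert _cat(compare_datasets(new, old, ts20, "stage"))["X"] == "contraction"

    def test_only_in_new_and_only_in_old(self, ts20):
        old = Dataset([TaxonRange("Gone", "S02", "S03")])
        new = Dataset([TaxonRange("Fresh", "S05", "S05")])
        cats = _cat(compare_datasets(new, old, ts20, "stage"))
        assert cats == {"Fresh": "new_in_list", "Gone": "removed"}

    def test_synonymy_mapping_joins_old_to_new_name(self, ts20):
        old = Dataset([TaxonRange("Oldidae", "S02", "S04")])
        new = Dataset([TaxonRange("Newidae", "S02", "S04")])
        records = compare_datasets(new, old, ts20, "stage",
                                   synonymy={"Oldidae": "Newidae"})
        assert _cat(records) == {"Newidae": "no_change"}


class TestCoarseOldPolicy:
    def test_confirming_span_is_no_change(self, gts):
        old = Dataset([TaxonRange("X", "Mississippian", "Mississippian")])
        new = Dataset([TaxonRange("X", "Tournaisian", "Serpukhovian")])
        records = compare_datasets(new, old, gts, "confirm")
        assert _cat(records)["X"] == "no_change"

    def test_non_confirming_span_is_unsubtyped_range_change(self, gts):
        old = Dataset([TaxonRange("X", "Mississippian", "Mississippian")])
        new = Dataset([TaxonRange("X", "Visean", "Serpukhovian")])
        records = compare_datasets(new, old, gts, "confirm")
        assert _cat(records)["X"] == "range_change"

    def test_stage_policy_rejects_coarse_old_records(self, gts):
        old = Dataset([TaxonRange("X", "Mississippian", "Mississippian")])
        new = Dataset([TaxonRange("X", "Visean", "Visean")])
        with pytest.raises(ConfigError, match="stage-resolved"):
            compare_datasets(new, old, gts, "stage")


class TestInvariants:
    def test_self_comparison_is_all_no_change(self, ts20):
        d = random_resolved_dataset(np.random.default_rng(5), ts20, 60)
        summary = summarize(compare_datasets(d, d, ts20, "stage"))
        assert summary.proportions["no_change"] == 1.0
        assert summary.removed == 0

    def test_extension_reverses_to_contraction(self, ts20):
        old = Dataset([TaxonRange("X", "S05", "S07")])
        new = Dataset([TaxonRange("X", "S04", "S09")])
        assert _cat(compare_datasets(new, old, ts20, "stage"))["X"] == "extension"
        assert _cat(compare_datasets(old, new, ts20, "stage"))["X"] == "contraction"

    def test_conservation_over_new_taxa(self, ts20):
        rng = np.random.default_rng(8)
        old = random_resolved_dataset(rng, ts20, 50)
        new, _ = perturb_dataset(
            old,
            {"no_change": 0.2, "new_in_list": 0.2, "contraction": 0.2,
             "extension": 0.2, "shift": 0.2},
            ts20,
            seed=88,
        )
        summary = summarize(compare_datasets(new, old, ts20, "stage"))
        assert summary.denominator == len(new)
        assert sum(summary.proportions.values()) == pytest.approx(1.0)


class TestSummarize:
    def test_empty_old_dataset_all_new_in_list(self, ts20):
        new = Dataset([TaxonRange("A", "S02", "S03"), TaxonRange("B", "S04", "S04")])
        summary = summarize(compare_datasets(new, Dataset([]), ts20, "stage"))
        assert summary.counts["new_in_list"] == 2
        assert summary.proportions["new_in_list"] == 1.0

    def test_frame_output_schema(self, ts20):
        d = Dataset([TaxonRange("X", "S02", "S03")])
        frame = records_to_frame(compare_datasets(d, d, ts20, "stage"))
        assert list(frame.columns) == [
            "taxon", "category", "old_first", "old_last", "new_first", "new_last",
        ]


class TestPerturbationRoundTrip:
    TARGET = {"no_change": 0.1, "new_in_list": 0.3, "contraction": 0.25,
              "extension": 0.28, "shift": 0.07}

    def test_ledger_recovered_exactly(self, ts20, sim_dataset):
        d, _ = sim_dataset
        revised, ledger = perturb_dataset(d, self.TARGET, ts20, seed=1234)
        records = compare_datasets(revised, d, ts20, "stage")
        got = _cat(records)
        for _, row in ledger.iterrows():
            assert got[row["taxon"]] == row["category"], row["taxon"]

    def test_counts_match_largest_remainder_target(self, ts20):
        d = random_resolved_dataset(np.random.default_rng(2), ts20, 100)
        revised, ledger = perturb_dataset(d, self.TARGET, ts20, seed=4)
        counts = ledger["category"].value_counts()
        assert counts["no_change"] == 10
        assert counts["new_in_list"] == 30
        assert counts["contraction"] == 25
        assert counts["extension"] == 28
        assert counts["shift"] == 7
        assert len(revised) == 100

    def test_all_no_change_target_is_identity(self, ts20):
        d = random_resolved_dataset(np.random.default_rng(9), ts20, 30)
        revised, ledger = perturb_dataset(
            d, {"no_change": 1.0}, ts20, seed=1
        )
        assert revised.to_frame().equals(d.to_frame())
        assert (ledger["category"] == "no_change").all()

    def test_infeasible_target_raises(self, ts20):
        from paleodiv.errors import ValidationError

        d = Dataset([TaxonRange("X", "S03", "S03")])  # single stage: cannot contract
        with pytest.raises(ValidationError):
            perturb_dataset(d, {"contraction": 1.0}, ts20, seed=0, max_redraws=3)
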