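"""The affected-kindred/cross-cohort filter and clinical rescue."""

import itertools

import pandas as pd
import pytest

from kindredx import (
    CohortDesign,
    ReferencePanel,
    SampleCallSet,
    SampleInfo,
    clinical_rescue,
    kindred_cross_cohort_filter,
)
from kindredx.errors import ConfigurationError
from kindredx.kindred import (
    REASON_CROSS_COHORT,
    REASON_LOWCOV,
    REASON_UNSHARED,
)

from conftest import make_call, make_callset


def tiny_design():
    samples = [SampleInfo(s) for s in ("A1", "A2", "S1", "S2")]
    return CohortDesign(
        samples=samples, pairs=[("A1", "A2", "brothers")], sporadic=["S1", "S2"]
    )


def clinical_panel(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "clin_sig", "maf"]
    )
    return ReferencePanel(df, source="clinical")


class TestKindredRules:
    def test_variant_in_both_brothers_only_retained(self):
        cohort = [
            make_callset("A1", [1000]), make_callset("A2", [1000]),
            make_callset("S1", [9999]), make_callset("S2", [8888]),
        ]
        out, ledger = kindred_cross_cohort_filter(cohort, tiny_design())
        assert ("X", 1000, "A", "G") in out["A1"]
        assert ("X", 1000, "A", "G") in out["A2"]

    def test_variant_in_two_unrelated_rejected_everywhere(self):
        cohort = [
            make_callset("A1", [1000]), make_callset("A2", [7777]),
            make_callset("S1", [1000]), make_callset("S2", [8888]),
        ]
        out, ledger = kindred_cross_cohort_filter(cohort, tiny_design())
        key = ("X", 1000, "A", "G")
        assert key not in out["A1"] and key not in out["S1"]
        reasons = {e.sample_id for e in ledger if e.reason == REASON_CROSS_COHORT}
        assert reasons == {"A1", "S1"}

    def test_pair_sharing_with_unrelated_loses_everywhere(self):
        cohort = [
            make_callset("A1", [1000]), make_callset("A2", [1000]),
            make_callset("S1", [1000]), make_callset("S2", [8888]),
        ]
        out, _ = kindred_cross_cohort_filter(cohort, tiny_design())
        key = ("X", 1000, "A", "G")
        assert all(key not in out[s] for s in ("A1", "A2", "S1"))

    def test_kin_lowcov_accommodation(self):
        cohort = [
            make_callset("A1", [1000]), make_callset("A2", [7777]),
            make_callset("S1", [5555]), make_callset("S2", [8888]),
        ]
        lowcov = {"A2": [(0, 2000)]}  # A2 has no coverage around pos 1000
        out, ledger = kindred_cross_cohort_filter(cohort, tiny_design(), lowcov_tracks=lowcov)
        assert ("X", 1000, "A", "G") in out["A1"]
        assert any(e.reason == REASON_LOWCOV for e in ledger)

    def test_kin_confident_reference_rejects(self):
        cohort = [
            make_callset("A1", [1000]), make_callset("A2", [7777]),
            make_callset("S1", [5555]), make_callset("S2", [8888]),
        ]
        out, ledger = kindred_cross_cohort_filter(cohort, tiny_design())
        assert ("X", 1000, "A", "G") not in out["A1"]
        assert any(e.reason == REASON_UNSHARED for e in ledger)

    def test_kin_call_with_low_depth_accommodates(self):
        a2 = SampleCallSet("A2", [make_call(1000, alt="T", depth=2, alt_fwd=1, alt_rev=1)])
        cohort = [
            make_callset("A1", [1000]), a2,
            make_callset("S1", [5555]), make_callset("S2", [8888]),
        ]
        out, _ = kindred_cross_cohort_filter(cohort, tiny_design(), min_depth=4)
        assert ("X", 1000, "A", "G") in out["A1"]

    def test_truth_table(self):
        """Exhaustive presence x kin-coverage x relatedness outcomes for the
        focal variant at pos 1000 carried by A1."""
        key = ("X", 1000, "A", "G")
        for kin_has, kin_lowcov, unrelated_carrier in itertools.product(
            [True, False], repeat=3
        ):
            a2_pos = [1000, 7777] if kin_has else [7777]
            s1_pos = [1000, 5555] if unrelated_carrier else [5555]
            cohort = [
                make_callset("A1", [1000]),
                make_callset("A2", a2_pos),
                make_callset("S1", s1_pos),
                make_callset("S2", [8888]),
            ]
            lowcov = {"A2": [(0, 2000)]} if kin_lowcov else None
            out, _ = kindred_cross_cohort_filter(
                cohort, tiny_design(), lowcov_tracks=lowcov
            )
            if unrelated_carrier:
                expect = False  # cross-cohort removal wins over everything
            else:
                expect = kin_has or kin_lowcov
            assert (key in out["A1"]) is expect, (kin_has, kin_lowcov, unrelated_carrier)

    def test_sporadic_keep_cross_cohort_survivors(self):
        cohort = [
            make_callset("A1", [1000]), make_callset("A2", [1000]),
            make_callset("S1", [5555]), make_callset("S2", [8888]),
        ]
        out, _ = kindred_cross_cohort_filter(cohort, tiny_design())
        assert len(out["S1"]) == 1 and len(out["S2"]) == 1

    def test_order_independence(self, small_sim):
        _, cohort = small_sim
        fwd, _ = kindred_cross_cohort_filter(cohort.callsets, cohort.design)
        rev, _ = kindred_cross_cohort_filter(cohort.callsets[::-1], cohort.design)
        assert {s: cs.key_set for s, cs in fwd.items()} == {
            s: cs.key_set for s, cs in rev.items()
        }

    def test_never_increases_counts(self, small_sim):
        _, cohort = small_sim
        out, _ = kindred_cross_cohort_filter(cohort.callsets, cohort.design)
        for cs in cohort.callsets:
            assert len(out[cs.sample_id]) <= len(cs)

    def test_missing_design_sample_errors(self):
        cohort = [make_callset("GHOST", [1000])]
        with pytest.raises(ConfigurationError):
            kindred_cross_cohort_filter(cohort, tiny_design())

    def test_batch_systematic_self_neutralized(self, small_sim):
        """Keys injected into >=2 unrelated samples are always rejected."""
        _, cohort = small_sim
        systematic = cohort.truth.error_keys("batch_systematic")
        assert systematic
        out, _ = kindred_cross_cohort_filter(cohort.callsets, cohort.design)
        for sid, key in systematic:
            assert key not in out[sid]


class TestClinicalRescue:
    def _run(self, clin_sig, maf, maf_max=0.01):
        cohort = [
            make_callset("A1", [1000]), make_callset("A2", [1000]),
            make_callset("S1", [1000]), make_callset("S2", [1000]),
        ]
        _, ledger = kindred_cross_cohort_filter(cohort, tiny_design())
        panel = clinical_panel([("X", 1000, "A", "G", clin_sig, maf)])
        return clinical_rescue(ledger, panel, maf_max=maf_max)

    def test_pathogenic_rare_rescued_in_all_carriers(self):
        ledger, rescued = self._run("pathogenic", 0.002)
        assert rescued == {("X", 1000, "A", "G")}
        samples = {e.sample_id for e in ledger if e.decision == "rescue"}
        assert samples == {"A1", "A2", "S1", "S2"}

    def test_unannotated_not_rescued(self):
        _, rescued = self._run("none", 0.002)
        assert rescued == set()

    def test_common_pathogenic_not_rescued(self):
        _, rescued = self._run("pathogenic", 0.05)
        assert rescued == set()

    def test_probable_pathogenic_counts(self):
        _, rescued = self._run("probable-pathogenic", 0.002)
        assert rescued == {("X", 1000, "A", "G")}
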