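"""Call containers, VCF round trips, genotype audit and array concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kindredx import (
    SampleCallSet,
    audit_genotype_ploidy,
    genotype_concordance,
    read_sample_vcf,
    write_outputs,
    write_sample_vcf,
)
from kindredx.cohort import REJECT, RETAIN, FilterLedger
from kindredx.errors import (
    DuplicateVariantError,
    SampleNotFoundError,
    UndefinedStatisticError,
)

from conftest import make_call, make_callset

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=X,length=155000000>
##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Alt fwd">
##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Alt rev">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf_text(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestVariantCall:
    def test_field_invariants(self):
        with pytest.raises(ValueError):
            make_call(0)
        with pytest.raises(ValueError):
            make_call(100, ref="A", alt="A")
        with pytest.raises(ValueError):
            make_call(100, depth=5, alt_fwd=4, alt_rev=4)

    def test_haploid_validity(self):
        assert make_call(10, genotype=1.0).is_valid_haploid
        assert not make_call(10, genotype=2.0).is_valid_haploid
        assert not make_call(10, genotype=0.05).is_valid_haploid

    def test_duplicate_key_rejected(self):
        with pytest.raises(DuplicateVariantError):
            SampleCallSet("s", [make_call(100), make_call(100)])

    def test_calls_sorted(self):
        cs = make_callset("s", [300, 100, 200])
        assert list(cs.positions()) == [100, 200, 300]


class TestReadVcf:
    def test_single_record_field_mapping(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "X\t1000\t.\tA\tG\t.\tPASS\tFUNC=missense\tGT:DP:ADF:ADR\t1:20:9:11\n"
        )
        cs = read_sample_vcf(path, "S1")
        assert len(cs) == 1
        call = cs.calls[0]
        assert call.key == ("X", 1000, "A", "G")
        assert call.genotype == 1.0
        assert (call.depth, call.alt_fwd, call.alt_rev) == (20, 9, 11)
        assert call.func_class == "missense"

    def test_empty_body(self, tmp_path):
        cs = read_sample_vcf(write_vcf_text(tmp_path, ""), "S1")
        assert len(cs) == 0

    def test_duplicate_records_error(self, tmp_path):
        body = (
            "X\t1000\t.\tA\tG\t.\tPASS\t.\tGT:DP:ADF:ADR\t1:20:9:11\n"
            "X\t1000\t.\tA\tG\t.\tPASS\t.\tGT:DP:ADF:ADR\t1:22:10:12\n"
        )
        with pytest.raises(DuplicateVariantError):
            read_sample_vcf(write_vcf_text(tmp_path, body), "S1")

    def test_missing_sample(self, tmp_path):
        with pytest.raises(SampleNotFoundError):
            read_sample_vcf(write_vcf_text(tmp_path, ""), "NOPE")

    def test_multiallelic_split(self, tmp_path):
        body = "X\t5000\t.\tA\tG,T\t.\tPASS\t.\tGT:DP:ADF:ADR\t2:30:14:16\n"
        cs = read_sample_vcf(write_vcf_text(tmp_path, body), "S1")
        assert [c.key for c in cs] == [("X", 5000, "A", "T")]

    def test_missing_func_defaults_other(self, tmp_path):
        body = "X\t1000\t.\tA\tG\t.\tPASS\t.\tGT:DP:ADF:ADR\t1:20:9:11\n"
        cs = read_sample_vcf(write_vcf_text(tmp_path, body), "S1")
        assert cs.calls[0].func_class == "other"

    def test_strand_sidecar_fallback(self, tmp_path):
        path = write_vcf_text(tmp_path, "X\t1000\t.\tA\tG\t.\tPASS\t.\tGT:DP\t1:20\n")
        sidecar = tmp_path / "strand.tsv"
        sidecar.write_text("1000\t8\t12\n")
        cs = read_sample_vcf(path, "S1", strand_sidecar=sidecar)
        assert (cs.calls[0].alt_fwd, cs.calls[0].alt_rev) == (8, 12)


class TestRoundTrip:
    def test_write_read_identity_50_variants(self, tmp_path, rng):
        positions = sorted(rng.choice(np.arange(1000, 10**6), size=50, replace=False))
        calls = []
        for p in positions:
            depth = int(rng.integers(5, 60))
            fwd = int(rng.integers(1, depth))
            calls.append(
                make_call(int(p), depth=depth, alt_fwd=fwd, alt_rev=depth - fwd,
                          func_class=str(rng.choice(["missense", "nonsense", "intronic"])))
            )
        original = SampleCallSet("RT", calls)
        path = tmp_path / "rt.vcf"
        write_sample_vcf(original, path)
        back = read_sample_vcf(path, "RT")
        assert back.calls == original.calls

    def test_write_outputs_retain_all(self, tmp_path):
        cs = make_callset("S9", [100, 5000, 9000])
        ledger = FilterLedger()
        for c in cs:
            ledger.add("S9", c.key, "strand", RETAIN)
        paths = write_outputs(cs, ledger, tmp_path)
        assert len(read_sample_vcf(paths["vcf"], "S9")) == len(cs)

    def test_write_outputs_reject_all(self, tmp_path):
        cs = make_callset("S9", [100, 5000])
        ledger = FilterLedger()
        for c in cs:
            ledger.add("S9", c.key, "strand", REJECT, "strand")
        paths = write_outputs(cs, ledger, tmp_path)
        assert len(read_sample_vcf(paths["vcf"], "S9")) == 0

    def test_write_outputs_requires_full_coverage(self, tmp_path):
        cs = make_callset("S9", [100, 5000])
        ledger = FilterLedger()
        ledger.add("S9", cs.calls[0].key, "strand", RETAIN)
        with pytest.raises(ValueError):
            write_outputs(cs, ledger, tmp_path)


class TestGenotypeAudit:
    @pytest.mark.parametrize(
        "genotypes, expected",
        [
            ([1, 1, 2], (2 / 3, 1 / 3, 0.0)),
            ([1, 0.05, 3.95, 3], (1 / 4, 0.0, 3 / 4)),
            ([2, 2], (0.0, 1.0, 0.0)),
        ],
    )
    def test_classification(self, genotypes, expected):
        a = audit_genotype_ploidy(genotypes, expected_ploidy=1)
        assert (a.frac_one, a.frac_two, a.frac_ambiguous) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            audit_genotype_ploidy([0, 0, 0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.one_of(st.integers(0, 4), st.floats(0.01, 4.0, allow_nan=False)),
            min_size=1,
        ).filter(lambda g: any(v != 0 for v in g))
    )
    def test_fractions_sum_to_one(self, genotypes):
        a = audit_genotype_ploidy(genotypes)
        assert a.frac_one + a.frac_two + a.frac_ambiguous == pytest.approx(1.0, abs=1e-12)


class TestConcordance:
    def test_self_is_one(self):
        cs = make_callset("s", [100, 200, 300])
        assert genotype_concordance(cs, {100: 1, 200: 1, 300: 1}) == 1.0

    def test_three_of_four(self):
        cs = make_callset("s", [100, 200, 300, 400])
        table = {100: 1, 200: 1, 300: 1, 400: 0}
        assert genotype_concordance(cs, table) == 0.75

    def test_no_overlap_undefined(self):
        cs = make_callset("s", [100])
        with pytest.raises(UndefinedStatisticError):
            genotype_concordance(cs, {999: 1})

    def test_flip_rate_recovered(self, rng):
        n, flip = 1000, 0.05
        positions = sorted(rng.choice(np.arange(100, 10**7), size=n, replace=False))
        cs = make_callset("s", [int(p) for p in positions])
        flips = rng.random(n) < flip
        table = {int(p): (0.0 if f else 1.0) for p, f in zip(positions, flips)}
        got = genotype_concordance(cs, table)
        se = np.sqrt(flip * (1 - flip) / n)
        assert got == pytest.approx(1 - flip, abs=4 * se)
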