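"""Summary-statistics parsing, harmonization and proxy substitution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mr2s import (
    ConfigurationError,
    IncompatibleAllelesError,
    SumstatsValidationError,
    VariantAssociation,
    harmonize,
    harmonize_pairs,
    read_sumstats,
    substitute_proxies,
    write_sumstats,
)

HEADER = "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


def va(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, p=1e-10, n=1000):
    return VariantAssociation(vid, ea, oa, eaf, beta, se, p, n)


class TestReadWrite:
    def test_well_formed_table_parses_in_order(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            HEADER
            + "rs1\tA\tG\t0.30\t0.10\t0.01\t1e-10\t1000\n"
            + "rs2\tC\tT\t0.10\t-0.05\t0.02\t1e-9\t1000\n"
            + "rs3\ta\tg\t0.50\t0.00\t0.01\t0.5\t1000\n"
        )
        records = read_sumstats(path)
        assert [r.variant_id for r in records] == ["rs1", "rs2", "rs3"]
        # lower-case alleles are normalized
        assert (records[2].effect_allele, records[2].other_allele) == ("A", "G")

    def test_invalid_eaf_names_the_row(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            HEADER
            + "rs1\tA\tG\t0.30\t0.10\t0.01\t1e-10\t1000\n"
            + "rs2\tA\tG\t1.20\t0.10\t0.01\t1e-10\t1000\n"
        )
        with pytest.raises(SumstatsValidationError, match="row 2"):
            read_sumstats(path)

    def test_unparsable_numeric_names_offender(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(HEADER + "rs1\tA\tG\t0.30\tnot_a_number\t0.01\t1e-10\t1000\n")
        with pytest.raises(SumstatsValidationError, match="beta"):
            read_sumstats(path)

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError, match="missing mandatory"):
            read_sumstats(path)

    def test_column_map_renames_source_headers(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "SNP\tEA\tOA\tFREQ\tB\tSE\tP\tN\n"
            + "rs1\tA\tG\t0.30\t0.10\t0.01\t1e-10\t1000\n"
        )
        records = read_sumstats(
            path,
            column_map={
                "variant_id": "SNP", "effect_allele": "EA", "other_allele": "OA",
                "eaf": "FREQ", "beta": "B", "se": "SE", "pvalue": "P", "n": "N",
            },
        )
        assert records[0].beta == 0.1

    def test_roundtrip_is_lossless(self, tmp_path):
        records = [
            va("rs1", beta=0.123456789012345, eaf=1 / 3),
            va("rs2", "C", "T", beta=-0.05, p=0.5),
        ]
        path = tmp_path / "out.tsv"
        write_sumstats(records, path)
        assert read_sumstats(path) == records
        # a second round-trip is bit-identical at the file level too
        path2 = tmp_path / "out2.tsv"
        write_sumstats(read_sumstats(path), path2)
        assert path.read_text() == path2.read_text()


class TestHarmonize:
    def test_identical_alleles_copy_through(self):
        res = harmonize(va(beta=0.10), va(beta=0.05))
        assert res.instrument.beta_outcome == 0.05
        assert not res.allele_swapped

    def test_swapped_alleles_negate_outcome(self):
        res = harmonize(va(beta=0.10), va(ea="G", oa="A", beta=0.05, eaf=0.7))
        assert res.instrument.beta_outcome == -0.05
        assert res.allele_swapped

    def test_strand_complement_then_swap(self):
        # exposure A/G; outcome on the other strand, swapped: C/T
        res = harmonize(va(beta=0.10), va(ea="C", oa="T", beta=0.05, eaf=0.7))
        assert res.strand_complemented and res.allele_swapped
        assert res.instrument.beta_outcome == -0.05

    def test_irreconcilable_alleles_raise(self):
        with pytest.raises(IncompatibleAllelesError):
            harmonize(va(), va(ea="A", oa="C"))

    @pytest.mark.parametrize(
        "exp_eaf,out_eaf,kept",
        [
            (0.50, 0.50, False),   # dead centre: ambiguous
            (0.30, 0.55, False),   # inside the window
            (0.30, 0.70, False),   # opposite sides of 0.5
            (0.30, 0.30, True),    # same side, both outside the window
        ],
    )
    def test_palindromic_frequency_rule(self, exp_eaf, out_eaf, kept):
        exp = va(ea="A", oa="T", eaf=exp_eaf)
        out = va(ea="A", oa="T", eaf=out_eaf, beta=0.05)
        res = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert res.dropped is (not kept)
        if not kept:
            assert res.reason == "palindromic_ambiguous"

    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
    )
    def test_allele_flip_is_involutive(self, beta, eaf):
        v = va(beta=beta, eaf=eaf)
        w = v.flipped().flipped()
        assert (w.effect_allele, w.other_allele) == (v.effect_allele, v.other_allele)
        assert w.beta == pytest.approx(v.beta)
        assert w.eaf == pytest.approx(v.eaf)

    @given(
        b_exp=st.floats(-1, 1).filter(lambda x: abs(x) > 1e-6),
        b_out=st.floats(-1, 1),
        eaf=st.floats(0.01, 0.99),
        flip_outcome=st.booleans(),
    )
    def test_harmonized_effect_invariant_to_outcome_coding(
        self, b_exp, b_out, eaf, flip_outcome
    ):
        exp = va(beta=b_exp, eaf=eaf)
        out = va(beta=b_out, eaf=eaf)
        if flip_outcome:
            out = out.flipped()
        res = harmonize(exp, out)
        assert res.instrument.beta_outcome == pytest.approx(b_out)
        assert res.instrument.beta_exposure == b_exp

    @given(
        b_a=st.floats(-1, 1).filter(lambda x: abs(x) > 1e-6),
        b_b=st.floats(-1, 1).filter(lambda x: abs(x) > 1e-6),
        flip=st.booleans(),
    )
    def test_role_swap_preserves_signed_effect_pair(self, b_a, b_b, flip):
        a = va(beta=b_a, eaf=0.3)
        b = va(beta=b_b, eaf=0.3)
        if flip:
            b = b.flipped()
        ab = harmonize(a, b).instrument
        ba = harmonize(b, a).instrument
        # same pair of signed effects up to the joint allele-coding sign
        s = -1.0 if flip else 1.0
        assert ba.beta_exposure == pytest.approx(s * ab.beta_outcome)
        assert ba.beta_outcome == pytest.approx(s * ab.beta_exposure)

    def test_pair_table_records_drop_reasons(self):
        exposures = [va("rs1"), va("rs2", ea="A", oa="T", eaf=0.5), va("rs3")]
        outcomes = [va("rs1", beta=0.02), va("rs2", ea="A", oa="T", eaf=0.5)]
        instruments, drops = harmonize_pairs(exposures, outcomes)
        assert [i.variant_id for i in instruments] == ["rs1"]
        assert dict(drops) == {
            "rs2": "palindromic_ambiguous",
            "rs3": "absent_in_outcome",
        }


class TestProxies:
    @staticmethod
    def _outcome(ids, pvalues=None):
        pvalues = pvalues or {}
        return {v: va(v, p=pvalues.get(v, 1e-5)) for v in ids}

    def test_highest_r2_wins(self):
        table = pd.DataFrame(
            {"variant": ["rs1", "rs1"], "proxy": ["p1", "p2"], "r2": [0.75, 0.9]}
        )
        res = substitute_proxies(["rs1"], table, 0.7, self._outcome(["p1", "p2"]))
        assert res.resolved == {"rs1": ("p2", 0.9)}

    def test_below_threshold_is_unresolved(self):
        table = pd.DataFrame({"variant": ["rs1"], "proxy": ["p1"], "r2": [0.65]})
        res = substitute_proxies(["rs1"], table, 0.7, self._outcome(["p1"]))
        assert res.resolved == {} and res.unresolved == ("rs1",)

    def test_threshold_is_strict(self):
        table = pd.DataFrame({"variant": ["rs1"], "proxy": ["p1"], "r2": [0.7]})
        res = substitute_proxies(["rs1"], table, 0.7, self._outcome(["p1"]))
        assert res.unresolved == ("rs1",)

    def test_r2_tie_breaks_on_outcome_pvalue_then_id(self):
        table = pd.DataFrame(
            {"variant": ["rs1"] * 3, "proxy": ["pa", "pb", "pc"], "r2": [0.9] * 3}
        )
        out = self._outcome(["pa", "pb", "pc"], {"pa": 1e-3, "pb": 1e-6, "pc": 1e-6})
        res = substitute_proxies(["rs1"], table, 0.7, out)
        assert res.resolved["rs1"][0] == "pb"  # smallest p, then lexicographic

    def test_proxy_absent_from_outcome_does_not_qualify(self):
        table = pd.DataFrame({"variant": ["rs1"], "proxy": ["p1"], "r2": [0.95]})
        res = substitute_proxies(["rs1"], table, 0.7, self._outcome(["other"]))
        assert res.unresolved == ("rs1",)

    def test_eight_of_sixtynine_absent_instruments_all_substituted(self):
        # 69 instruments, 8 missing from the outcome study, each with an
        # adequate proxy: all 8 substitutions are recorded
        missing = [f"rs{i:02d}" for i in range(8)]
        table = pd.DataFrame(
            {
                "variant": missing,
                "proxy": [f"px{i}" for i in range(8)],
                "r2": np.linspace(0.75, 0.99, 8),
            }
        )
        res = substitute_proxies(
            missing, table, 0.7, self._outcome([f"px{i}" for i in range(8)])
        )
        assert len(res.resolved) == 8 and not res.unresolved
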