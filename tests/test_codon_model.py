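import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonfold as cf
from codonfold.codon_model import GENETIC_CODE, ProteinSequence, translate


class TestProteinSequence:
    def test_valid_with_trailing_stop(self):
        p = ProteinSequence("MKV*")
        assert p.length == 4

    @pytest.mark.parametrize("bad", ["", "MB", "M*K", "*M", "mkv"])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            ProteinSequence(bad)


class TestLoadCodonUsage:
    def test_tsv_line(self):
        t = cf.load_codon_usage(io.StringIO("UUU\t17.6\n"))
        assert t["UUU"] == 17.6

    def test_t_normalized_to_u(self):
        t = cf.load_codon_usage(io.StringIO("TTT 17.6"))
        assert t["UUU"] == 17.6

    def test_kazusa_multi_column_with_counts(self):
        line = "UUU 17.6(714298)  UCU 15.2(618711)  UAU 12.2(495699)\n"
        t = cf.load_codon_usage(io.StringIO(line))
        assert t["UCU"] == 15.2 and t["UAU"] == 12.2

    @pytest.mark.parametrize("bad", ["UUX 5.0", "UUU abc", "UUU"])
    def test_malformed_line_reports_lineno(self, bad):
        with pytest.raises(ValueError, match="line 2"):
            cf.load_codon_usage(io.StringIO("UUU 1.0\n" + bad + "\n"))

    def test_duplicate_codon(self):
        with pytest.raises(ValueError, match="duplicate"):
            cf.load_codon_usage(io.StringIO("UUU 1.0\nUUU 2.0\n"))

    def test_embedded_table_covers_all_codons(self):
        t = cf.embedded_human_usage()
        assert len(t.entries) == 64


class TestRelativeAdaptiveness:
    def test_family_ratio(self):
        t = cf.load_codon_usage(io.StringIO("AAA 60\nAAG 30"))  # Lys
        w = cf.relative_adaptiveness(t)
        assert w["AAA"] == 1.0 and w["AAG"] == 0.5

    def test_single_codon_family(self, human_w):
        assert human_w["AUG"] == 1.0 and human_w["UGG"] == 1.0

    def test_floor_applied_to_zero_frequency(self):
        t = cf.load_codon_usage(io.StringIO("AAA 50\nAAG 0"))
        w = cf.relative_adaptiveness(t, floor=1e-3)
        assert w["AAG"] == pytest.approx(1e-3)

    def test_all_zero_family_rejected(self):
        t = cf.load_codon_usage(io.StringIO("AAA 0\nAAG 0"))
        with pytest.raises(ValueError, match="zero"):
            cf.relative_adaptiveness(t)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        base = {"GAA": 29.0, "GAG": 39.6}
        w1 = cf.relative_adaptiveness(cf.CodonUsageTable(base))
        w2 = cf.relative_adaptiveness(
            cf.CodonUsageTable({c: f * scale for c, f in base.items()})
        )
        for c in base:
            assert w1[c] == pytest.approx(w2[c])


class TestCai:
    def test_all_optimal_codons(self, human_w):
        assert cf.cai("AUGUGG", human_w) == pytest.approx(1.0)

    def test_geometric_mean_of_two(self):
        t = cf.load_codon_usage(io.StringIO("UUU 60\nUUC 15\nAUG 10"))
        w = cf.relative_adaptiveness(t)
        assert w["UUC"] == pytest.approx(0.25)
        assert cf.cai("UUUUUC", w) == pytest.approx(0.5)  # sqrt(1 * 0.25)

    def test_single_codon(self):
        t = cf.load_codon_usage(io.StringIO("AAA 50\nAAG 25"))
        w = cf.relative_adaptiveness(t)
        assert cf.cai("AAG", w) == pytest.approx(0.5)

    @pytest.mark.parametrize("bad", ["AUGU", "AUNUGG"])
    def test_invalid_cds(self, bad, human_w):
        with pytest.raises(ValueError):
            cf.cai(bad, human_w)

    @given(data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_additive_multiplicative_identity(self, data, human_w):
        prot = data.draw(
            st.text(alphabet=sorted(set(GENETIC_CODE) - {"*"}), min_size=1, max_size=8)
        )
        cds = "".join(
            data.draw(st.sampled_from(GENETIC_CODE[aa]), label=aa) for aa in prot
        )
        S = cf.log_adaptiveness_sum(cds, human_w)
        assert cf.cai(cds, human_w) == pytest.approx(math.exp(S / len(prot)))
        assert 0 < cf.cai(cds, human_w) <= 1.0
        assert translate(cds) == prot

    def test_cai_below_one_when_suboptimal_codon_used(self, human_w):
        # UUA is not the most frequent Leu codon
        assert cf.cai("UUA", human_w) < 1.0
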