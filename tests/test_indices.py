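import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit import (
    cai,
    cai_weights,
    enc,
    expected_enc,
    load_reference_weights,
    rscu,
    standard_code,
)
from cubkit.indices import ReferenceWeights
from tests.conftest import counts_from, random_gene_counts


def wright_enc_oracle(counts, code):
    """Direct, self-contained evaluation of Wright's equations."""
    f_class = {2: [], 3: [], 4: [], 6: []}
    for codons in code.degenerate_families.values():
        n = sum(counts[c] for c in codons)
        if n <= 1:
            continue
        f = (n * sum((counts[c] / n) ** 2 for c in codons) - 1) / (n - 1)
        if f > 0:
            f_class[len(codons)].append(f)
    mean = {k: sum(v) / len(v) if v else None for k, v in f_class.items()}
    if any(mean[k] is None for k in (2, 4, 6)):
        return math.nan
    inv3 = 1 / mean[3] if mean[3] else (9 / mean[2] + 5 / mean[4]) / 14
    raw = 2 + 9 / mean[2] + inv3 + 5 / mean[4] + 3 / mean[6]
    return min(61.0, max(20.0, raw))


class TestRscu:
    def test_definition_arithmetic(self):
        vals = rscu(counts_from({"TTT": 3, "TTC": 1}))
        assert vals["TTT"] == pytest.approx(1.5)
        assert vals["TTC"] == pytest.approx(0.5)

    def test_uniform_usage_is_one(self, code):
        counts = {c: 10 for c in code.sense_codons}
        vals = rscu(counts_from(counts), include_stops=False)
        assert np.allclose(vals.dropna(), 1.0)

    def test_matches_seqinr_uco_oracle(self):
        """Frozen independent oracle: seqinr::uco(index='rscu') on one gene."""
        counts = counts_from(
            {"ATG": 3, "TTT": 3, "TTC": 1, "GAA": 2, "GAG": 2, "CTG": 4,
             "CTA": 1, "ATT": 2, "ATC": 1, "GGT": 3, "GGG": 1, "TGG": 1,
             "TAA": 1}
        )
        vals = rscu(counts)
        expected = {"TTT": 1.5, "TTC": 0.5, "GAA": 1.0, "GAG": 1.0,
                    "CTG": 4.8, "CTA": 1.2, "ATT": 2.0, "ATC": 1.0,
                    "GGT": 3.0, "GGG": 1.0, "ATG": 1.0, "TGG": 1.0,
                    "TAA": 3.0}
        for codon, want in expected.items():
            assert vals[codon] == pytest.approx(want), codon

    def test_unobserved_family_missing_not_zero(self):
        vals = rscu(counts_from({"TTT": 2, "TTC": 2}))
        assert math.isnan(vals["GGG"])

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_family_size(self, seed):
        """Within each observed family, RSCU values sum to the family size."""
        code = standard_code()
        cc = random_gene_counts(np.random.default_rng(seed), code)
        vals = rscu(cc, include_stops=True)
        for codons in list(code.degenerate_families.values()) + [
            tuple(sorted(code.stop_codons))
        ]:
            total = sum(cc[c] for c in codons)
            if total > 0:
                assert sum(vals[c] for c in codons) == pytest.approx(len(codons))


class TestCaiWeights:
    def test_definition_arithmetic(self):
        w = cai_weights(counts_from({**_cover_rest(), "TTT": 90, "TTC": 10}))
        assert w["TTT"] == 1.0
        assert w["TTC"] == pytest.approx(0.2 / 1.8)

    def test_uniform_reference_all_one(self, code):
        w = cai_weights(counts_from({c: 50 for c in code.informative_codons}))
        assert all(v == pytest.approx(1.0) for v in w.weights.values())

    def test_pseudocount_keeps_weights_positive(self):
        w = cai_weights(counts_from({**_cover_rest(), "TTT": 100}))  # TTC absent
        assert 0 < w["TTC"] < 1
        # 0.5 pseudocount: RSCU(TTC) = 0.5*2/100.5, max RSCU = 100*2/100.5
        assert w["TTC"] == pytest.approx(0.5 / 100)

    def test_absent_family_raises_with_names(self):
        counts = {c: 5 for c in _cover_rest()}
        for c in ("GGT", "GGC", "GGA", "GGG"):
            counts.pop(c, None)
        with pytest.raises(ValueError, match="G"):
            cai_weights(counts_from(counts))

    def test_packaged_yeast_table_structure(self, code):
        w = load_reference_weights("yeast")
        assert set(w.weights) == set(code.informative_codons)
        for codons in code.degenerate_families.values():
            assert max(w[c] for c in codons) == pytest.approx(1.0)


class TestCai:
    def test_all_max_weight_gene_is_one(self):
        w = ReferenceWeights({"TTT": 1.0, "TTC": 0.5})
        assert cai(counts_from({"TTT": 40}), w) == pytest.approx(1.0)

    def test_geometric_mean_closed_form(self):
        w = ReferenceWeights({"TTT": 1.0, "TTC": math.exp(-1)})
        value = cai(counts_from({"TTT": 50, "TTC": 50}), w)
        assert value == pytest.approx(math.exp(-0.5))

    def test_monotone_in_weight_substitution(self):
        w = ReferenceWeights({"TTT": 1.0, "TTC": 0.3})
        low = cai(counts_from({"TTT": 10, "TTC": 10}), w)
        high = cai(counts_from({"TTT": 11, "TTC": 9}), w)
        assert high > low

    def test_length_invariant_at_fixed_frequencies(self):
        w = ReferenceWeights({"TTT": 1.0, "TTC": 0.4, "GAA": 0.7, "GAG": 1.0})
        base = {"TTT": 3, "TTC": 1, "GAA": 2, "GAG": 2}
        short = cai(counts_from(base), w)
        long = cai(counts_from({c: 25 * n for c, n in base.items()}), w)
        assert short == pytest.approx(long)

    def test_no_weighted_codons_undefined(self):
        w = ReferenceWeights({"TTT": 1.0})
        assert math.isnan(cai(counts_from({"ATG": 5}), w))


class TestEnc:
    def test_single_codon_per_amino_acid_is_20(self, code):
        counts = {codons[0]: 100 for codons in code.families.values()}
        assert enc(counts_from(counts)) == 20.0

    def test_uniform_61_capped_at_61(self, code):
        counts = {c: 100 for c in code.sense_codons}
        assert enc(counts_from(counts)) == 61.0

    def test_twofold_f_value(self):
        """50/50 split at n=100 gives F2 = 49/99 in Wright's formula."""
        n, half = 100, 50
        f2 = (n * 2 * (half / n) ** 2 - 1) / (n - 1)
        assert f2 == pytest.approx(49 / 99)

    def test_matches_brute_force_oracle(self, code, rng):
        for _ in range(300):
            cc = random_gene_counts(rng, code)
            ours = enc(cc)
            oracle = wright_enc_oracle(cc, code)
            if math.isnan(oracle):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, abs=1e-9)

    def test_count_scaling_moves_toward_asymptote(self, code, rng):
        cc = random_gene_counts(rng, code)
        values = []
        for scale in (1, 2, 4, 8, 16):
            scaled = counts_from({c: n * scale for c, n in cc.counts.items()})
            values.append(enc(scaled))
        diffs = np.diff(values)
        # monotone approach: differences all share one sign (or are ~0)
        assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)

    def test_all_singletons_undefined(self):
        assert math.isnan(enc(counts_from({"TTT": 1, "GAA": 1})))


class TestExpectedEnc:
    def test_printed_formula_spot_values(self):
        assert expected_enc(0.5) == pytest.approx(60.5)
        assert expected_enc(0.0) == pytest.approx(31.0)

    def test_symmetry_up_to_linear_term(self):
        for s in (0.1, 0.25, 0.4):
            assert expected_enc(s) - s == pytest.approx(
                expected_enc(1 - s) - (1 - s)
            )


def _cover_rest():
    """One codon per degenerate family, to satisfy coverage preconditions."""
    code = standard_code()
    return {codons[0]: 5 for codons in code.degenerate_families.values()}
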