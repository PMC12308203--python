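"""Codon counting, RSCU, ENC, CBI and the bias-correlation analysis."""

import math
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoprof.codon_usage import (
    DEFAULT_CODE,
    CodonCountTable,
    GeneticCode,
    bias_correlations,
    cbi,
    count_codons,
    enc,
    gc_content,
    optimal_codons,
    rscu,
)
from mitoprof.synthetic_data import simulate_codon_usage_panel


class TestGeneticCode:
    def test_invertebrate_mito_code_family_structure(self):
        code = DEFAULT_CODE
        assert code.translate("TGA") == "W"          # UGA -> Trp
        assert code.translate("AGA") == "S"          # AGA joins Ser
        assert len(code.families["S"]) == 8
        assert len(code.families["L"]) == 6
        assert len(code.sense_codons) == 62
        assert code.stop_codons == frozenset({"TAA", "TAG"})


class TestCountCodons:
    def test_simple_counts(self):
        t = count_codons(["TTATTATTG"])
        assert t.get("TTA") == 2 and t.get("TTG") == 1

    def test_total_is_length_over_three(self, default_simulation):
        sim = default_simulation
        cds = {f.name: f.extract(sim.record.residues, 18830)
               for f in sim.annotation.pcgs}
        t = count_codons(cds)
        assert t.total == sum(len(s) for s in cds.values()) // 3

    def test_internal_stop_warns_with_gene_name(self):
        with pytest.warns(UserWarning, match="geneX"):
            count_codons({"geneX": "ATTTAAATT"})

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            count_codons(["ATTA"])


class TestRscu:
    def test_published_leucine_family(self):
        t = CodonCountTable({"TTA": 406, "TTG": 24, "CTT": 25, "CTC": 4,
                             "CTA": 34, "CTG": 1})
        assert rscu(t, ndigits=2)["TTA"] == 4.93

    def test_published_eightfold_serine_family(self):
        t = CodonCountTable({"TCT": 48, "TCC": 7, "TCA": 85, "TCG": 2,
                             "AGT": 19, "AGC": 1, "AGA": 43, "AGG": 7})
        assert rscu(t, ndigits=2)["TCA"] == 3.21

    def test_uniform_family_gives_ones(self):
        t = CodonCountTable({c: 10 for c in DEFAULT_CODE.families["V"]})
        vals = rscu(t)
        assert all(vals[c] == 1.0 for c in DEFAULT_CODE.families["V"])

    def test_unobserved_family_is_undefined(self):
        t = CodonCountTable({"TTA": 5})
        assert rscu(t)["GGA"] is None

    def test_full_published_table_reproduced(self, reference_codon_frame,
                                             reference_codon_counts):
        vals = rscu(reference_codon_counts, ndigits=2)
        for row in reference_codon_frame.itertuples():
            dna = row.codon.replace("U", "T")
            assert vals[dna] == pytest.approx(row.printed_rscu, abs=0.005), row.codon

    @given(st.integers(1, 50), st.integers(2, 9))
    def test_scale_invariance(self, k, scale):
        counts = {"GTT": 3 * k, "GTC": k, "GTA": 2, "GTG": 0}
        a = rscu(CodonCountTable(counts))
        b = rscu(CodonCountTable({c: n * scale for c, n in counts.items()}))
        for c in counts:
            assert a[c] == pytest.approx(b[c])

    def test_family_sums_equal_family_size(self, reference_codon_counts):
        vals = rscu(reference_codon_counts)
        by_family = defaultdict(float)
        for codon, v in vals.items():
            if v is not None:
                by_family[DEFAULT_CODE.family_of(codon)] += v
        for family, total in by_family.items():
            if sum(reference_codon_counts.get(c) for c in family):
                assert total == pytest.approx(len(family))


def _enc_oracle(table):
    """Direct family-by-family evaluation of the homozygosity formula."""
    sizes = defaultdict(list)
    for aa, family in table.code.families.items():
        counts = [table.get(c) for c in family]
        n = sum(counts)
        f = None
        if n >= 2:
            f = (n * sum((c / n) ** 2 for c in counts) - 1) / (n - 1)
        sizes[len(family)].append(f)
    total = 0.0
    represented = 0
    nfam = sum(len(v) for v in sizes.values())
    for size, fs in sizes.items():
        obs = [f for f in fs if f is not None and f > 0]
        if not obs:
            continue
        total += len(fs) / (sum(obs) / len(obs))
        represented += len(fs)
    return min(total * nfam / represented, 62)


class TestEnc:
    def test_uniform_usage_reaches_sense_codon_count(self):
        t = CodonCountTable({c: 1000 for c in DEFAULT_CODE.sense_codons})
        assert enc(t) == pytest.approx(62, abs=0.2)

    def test_one_codon_per_amino_acid_gives_twenty(self):
        t = CodonCountTable({f[0]: 100 for f in DEFAULT_CODE.families.values()})
        assert enc(t) == pytest.approx(20.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 60)) for c in DEFAULT_CODE.sense_codons}
        if sum(counts.values()) == 0:
            counts["TTA"] = 5
        t = CodonCountTable(counts)
        assert enc(t) == pytest.approx(_enc_oracle(t), abs=1e-9)

    def test_concentrating_usage_decreases_enc(self, reference_codon_counts):
        # move one count from a rare Leu codon onto the family's most
        # common codon: usage concentrates, ENC must not increase
        base = dict(reference_codon_counts.counts)
        t0 = enc(CodonCountTable(base))
        shifted = dict(base)
        shifted["CTC"] -= 1
        shifted["TTA"] += 1
        assert enc(CodonCountTable(shifted)) < t0


def _cbi_oracle(table, optimal):
    n_opt = n_tot = n_rand = 0.0
    for family in table.code.families.values():
        tot = sum(table.get(c) for c in family)
        n_tot += tot
        n_rand += tot / len(family)
        n_opt += sum(table.get(c) for c in family if c in optimal)
    return (n_opt - n_rand) / (n_tot - n_rand)


class TestCbi:
    def test_only_optimal_codons_gives_one(self):
        t = CodonCountTable({f[0]: 50 for f in DEFAULT_CODE.families.values()})
        assert cbi(t) == pytest.approx(1.0)

    def test_uniform_usage_gives_zero(self):
        t = CodonCountTable({c: 7 for c in DEFAULT_CODE.sense_codons})
        assert cbi(t) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(1, 40)) for c in DEFAULT_CODE.sense_codons}
        t = CodonCountTable(counts)
        opt = optimal_codons(t)
        assert cbi(t) == pytest.approx(_cbi_oracle(t, opt), abs=1e-9)


class TestGcContent:
    def test_all_ggg(self):
        assert gc_content(CodonCountTable({"GGG": 10})) == (1.0, 1.0)

    def test_all_gga(self):
        gc, gc3 = gc_content(CodonCountTable({"GGA": 10}))
        assert gc == pytest.approx(2 / 3) and gc3 == 0.0

    def test_simulated_pcgs_have_at_enriched_third_positions(
        self, default_simulation
    ):
        sim = default_simulation
        cds = {f.name: f.extract(sim.record.residues, 18830)
               for f in sim.annotation.pcgs}
        gc, gc3 = gc_content(count_codons(cds))
        gc12 = (3 * gc - gc3) / 2
        assert gc3 < gc12


class TestBiasCorrelations:
    def test_monotone_input_gives_positive_coefficient(self):
        import pandas as pd
        df = pd.DataFrame({
            "enc": [30.0, 40, 50], "gc3": [0.1, 0.2, 0.3],
            "gc": [0.1, 0.2, 0.3], "cbi": [0.9, 0.5, 0.2],
        })
        out = bias_correlations(df).set_index(["x", "y"])
        assert out.loc[("enc", "gc3"), "coefficient"] > 0

    def test_constant_metric_yields_nan_not_crash(self):
        import pandas as pd
        df = pd.DataFrame({
            "enc": [30.0, 30, 30], "gc3": [0.1, 0.2, 0.3],
            "gc": [0.1, 0.2, 0.3], "cbi": [0.9, 0.5, 0.2],
        })
        out = bias_correlations(df).set_index(["x", "y"])
        assert math.isnan(out.loc[("enc", "gc3"), "coefficient"])

    def test_simulated_at_gradient_reproduces_expected_sign_pattern(self):
        panel = simulate_codon_usage_panel(18, (0.75, 0.92), seed=7)
        out = bias_correlations(panel).set_index(["x", "y"])["sign"]
        assert out[("enc", "gc")] == "+"
        assert out[("enc", "gc3")] == "+"
        assert out[("cbi", "gc")] == "-"
        assert out[("cbi", "gc3")] == "-"
        assert out[("enc", "cbi")] == "-"
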