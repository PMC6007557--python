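import random

import numpy as np
import pandas as pd
import pytest

from genorigin.model import Gene, LoadError, OriginCall
from genorigin.summary import (
    breakdowns,
    class_fractions,
    cross_species_average,
    gc_content_track,
    gc_skew_track,
    load_species_counts,
    pct_int,
    pfge_discrepancy,
    round_half_up,
)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.5, 1), (1.5, 2), (2.49, 2), (2.51, 3), (9.47, 9), (11.86, 12), (0.4, 0)],
    )
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected

    def test_pct_int_exact_half(self):
        assert pct_int(1, 200) == 1  # 0.5% rounds up
        assert pct_int(641, 1346) == 48


class TestClassFractions:
    def test_matches_per_gene_accumulation(self):
        rng = random.Random(9)
        classes = ("native", "species_specific", "hgt_low", "hgt_high")
        genes, calls = [], []
        cur = 1
        for i in range(60):
            span = rng.randint(90, 1500)
            span -= span % 3
            genes.append(
                Gene(gene_id=f"g{i}", start=cur, end=cur + span - 1, strand="+",
                     length_aa=span // 3)
            )
            calls.append(OriginCall(gene_id=f"g{i}", origin_class=rng.choice(classes),
                                    donor_clade="d" if rng.random() < 0.5 else None))
            cur += span + rng.randint(0, 300)
        chrom_len = cur + 100
        for c in calls:  # donor required only on hgt_high; normalise
            if c.origin_class != "hgt_high":
                c.donor_clade = None
            elif c.donor_clade is None:
                c.donor_clade = "d"
        s = class_fractions(calls, genes, chrom_len)
        expected_counts = {c: 0 for c in classes}
        expected_spans = {c: 0 for c in classes}
        for call, g in zip(calls, genes):
            expected_counts[call.origin_class] += 1
            expected_spans[call.origin_class] += g.end - g.start + 1
        assert s.class_counts == expected_counts
        assert s.class_span_bp == expected_spans
        assert sum(s.class_counts.values()) == 60
        # exact rational fractions sum to 1; integer percentages to 100 +/- 3
        assert abs(sum(s.class_count_pct.values()) - 100) <= 3

    def test_single_gene_spanning_chromosome(self):
        g = Gene(gene_id="g1", start=1, end=3000, strand="+", length_aa=999)
        c = OriginCall(gene_id="g1", origin_class="native")
        s = class_fractions([c], [g], 3000)
        assert s.class_length_pct["native"] == 100

    def test_short_chromosome_rejected(self):
        g = Gene(gene_id="g1", start=1, end=3000, strand="+", length_aa=999)
        c = OriginCall(gene_id="g1", origin_class="native")
        with pytest.raises(LoadError):
            class_fractions([c], [g], 2000)


class TestGCTracks:
    def test_balanced_window_zero_skew(self):
        (pt,) = gc_skew_track("GGCC", window=4, step=4, circular=False)
        assert pt.value == 0.0

    def test_all_g_extreme(self):
        (pt,) = gc_skew_track("GGGG", window=4, step=4, circular=False)
        assert pt.value == 1.0

    def test_gc_free_window_flagged_zero(self):
        (pt,) = gc_skew_track("ATAT", window=4, step=4, circular=False)
        assert pt.value == 0.0 and pt.degenerate

    def test_reverse_complement_negates_skew(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(4000))
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = gc_skew_track(seq, window=500, step=500, circular=False)
        rev = gc_skew_track(rc, window=500, step=500, circular=False)
        for p, q in zip(fwd, reversed(rev)):
            assert p.value == pytest.approx(-q.value)

    def test_simple_content(self):
        pts, mean = gc_content_track("ATGC", window=4, step=4, circular=False)
        assert pts[0].value == 0.5 and mean == 0.5

    def test_all_n_window_missing(self):
        pts, mean = gc_content_track("NNNNACGT", window=4, step=4, circular=False)
        assert pts[0].value is None and pts[0].degenerate
        assert pts[1].value == 0.5
        assert mean == 0.5  # N bases excluded from the denominator

    def test_tiling_windows_average_to_whole_sequence_gc(self):
        rng = random.Random(2)
        seq = "".join(rng.choice("ACGTACGG") for _ in range(12_000))
        pts, mean = gc_content_track(seq, window=1000, step=1000, circular=False)
        np.testing.assert_allclose(np.mean([p.value for p in pts]), mean, rtol=1e-12)

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_content_track("ACGT", window=10, step=1)

    def test_circular_rotation_invariance(self):
        rng = random.Random(3)
        seq = "".join(rng.choice("ACGT") for _ in range(5000))
        k = 1000  # rotate by a multiple of the step
        rot = seq[k:] + seq[:k]
        a = gc_skew_track(seq, window=500, step=250, circular=True)
        b = gc_skew_track(rot, window=500, step=250, circular=True)
        shift = k // 250
        vals_a = [p.value for p in a]
        vals_b = [p.value for p in b]
        assert vals_b == vals_a[shift:] + vals_a[:shift]


class TestPFGE:
    def test_published_sizes(self):
        assert pfge_discrepancy(1_560_000, 1_770_000) == 12

    def test_equal_sizes(self):
        assert pfge_discrepancy(1_000_000, 1_000_000) == 0

    def test_plain_arithmetic(self):
        assert pfge_discrepancy(900_000, 1_000_000) == 10

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pfge_discrepancy(0, 1)


class TestCrossSpecies:
    def test_packaged_table_means(self):
        table = load_species_counts()
        excl = list(table.index[table["reference_only"] == 1]) + ["Spiroplasma clarkii"]
        counts = table.drop(columns=["reference_only"])
        assert cross_species_average(counts, "species_specific", exclude=excl) == 16
        assert cross_species_average(counts, "hgt_low", exclude=excl) == 10

    def test_single_species(self):
        df = pd.DataFrame(
            {"native": [30], "species_specific": [50], "hgt_low": [10], "hgt_high": [10]},
            index=["sp1"],
        )
        assert cross_species_average(df, "species_specific") == 50

    def test_identical_rows_equal_single_row(self):
        row = {"native": 70, "species_specific": 20, "hgt_low": 7, "hgt_high": 3}
        df = pd.DataFrame([row] * 4, index=list("abcd"))
        assert cross_species_average(df, "hgt_low") == cross_species_average(
            df.iloc[:1], "hgt_low"
        )

    def test_empty_inclusion_rejected(self):
        df = pd.DataFrame(
            {"native": [1], "species_specific": [1], "hgt_low": [1], "hgt_high": [1]},
            index=["only"],
        )
        with pytest.raises(ValueError):
            cross_species_average(df, "native", exclude=["only"])


class TestBreakdowns:
    def test_single_clade_is_total(self, gene_factory):
        genes = [gene_factory(gene_id=f"g{i}") for i in range(3)]
        calls = [
            OriginCall(gene_id=f"g{i}", origin_class="hgt_high", donor_clade="M")
            for i in range(3)
        ]
        donor, _ = breakdowns(calls, genes)
        assert donor == {"M": 1.0}

    def test_planted_cog_fraction_recovered(self, gene_factory):
        genes = [gene_factory(gene_id=f"g{i}", cog="G" if i < 5 else None) for i in range(10)]
        calls = [
            OriginCall(gene_id=f"g{i}", origin_class="hgt_high", donor_clade="M")
            for i in range(10)
        ]
        _, cog = breakdowns(calls, genes)
        assert cog["G"] == 0.5 and cog["unassigned"] == 0.5

    def test_no_acquired_genes_empty(self, gene_factory):
        genes = [gene_factory()]
        calls = [OriginCall(gene_id="g1", origin_class="native")]
        assert breakdowns(calls, genes) == ({}, {})
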