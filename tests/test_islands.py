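"""Island detection against an independent regex-chaining oracle.

Label strings over {A, B, x}: 'A'/'B' are high-confidence acquired genes
from two donor clades, 'x' is anything else.  The oracle finds maximal
donor runs by greedy regular-expression chaining (``D(N{0,g}D)*``) on the
label string, rotated to a break point for the circular case — a mechanism
entirely separate from the detector's index arithmetic.
"""

import itertools
import random
import re

import pytest

from genorigin.islands import check_synteny, detect_islands
from genorigin.model import ContractError, Gene, Island, OriginCall


def _genes(n):
    return [
        Gene(gene_id=f"g{i:04d}", start=10 * i + 1, end=10 * i + 9, strand="+", length_aa=100)
        for i in range(n)
    ]


_GENE_CACHE = {n: _genes(n) for n in range(1, 13)}


def _calls(labels):
    out = []
    for i, lab in enumerate(labels):
        if lab in ("A", "B"):
            out.append(
                OriginCall(
                    gene_id=f"g{i:04d}", origin_class="hgt_high",
                    donor_clade=lab, top_subjects=(f"s{i}",),
                )
            )
        else:
            out.append(OriginCall(gene_id=f"g{i:04d}", origin_class="native"))
    return out


def _detected_sets(labels, min_genes, max_gap, circular):
    n = len(labels)
    genes = _GENE_CACHE.get(n) or _genes(n)
    islands = detect_islands(_calls(labels), genes, min_genes, max_gap, circular)
    return {
        (isl.donor_clade, frozenset(int(g[1:]) for g in isl.gene_ids))
        for isl in islands
    }


def _oracle_sets(labels, min_genes, max_gap, circular):
    n = len(labels)
    result = set()
    for donor in ("A", "B"):
        t = "".join("D" if lab == donor else "N" for lab in labels)
        if "D" not in t:
            continue
        pat = re.compile(rf"D(?:N{{0,{max_gap}}}D)*")
        if not circular:
            runs = [(m.start(), m.end()) for m in pat.finditer(t) if "D" in m.group()]
            members_runs = [
                frozenset(i for i in range(a, b) if t[i] == "D") for a, b in runs
            ]
        else:
            ds = [i for i, ch in enumerate(t) if ch == "D"]
            gaps = [(ds[(k + 1) % len(ds)] - ds[k] - 1) % n for k in range(len(ds))]
            breaks = [k for k, g in enumerate(gaps) if g > max_gap]
            if not breaks:
                members_runs = [frozenset(ds)]  # chains all the way around
            else:
                rot = ds[(breaks[0] + 1) % len(ds)]
                t_rot = t[rot:] + t[:rot]
                members_runs = [
                    frozenset((i + rot) % n for i in range(m.start(), m.end())
                              if t_rot[i] == "D")
                    for m in pat.finditer(t_rot)
                ]
        for members in members_runs:
            if len(members) >= min_genes:
                result.add((donor, members))
    return result


class TestExamples:
    def test_five_adjacent_same_donor_one_island(self):
        labels = "xAAAAAx"
        (isl,) = detect_islands(_calls(labels), _genes(7), min_genes=5, max_gap=2)
        assert isl.n_acquired == 5 and isl.donor_clade == "A"
        assert isl.n_interrupting == 0

    def test_gap_of_three_splits_below_threshold(self):
        # on a linear stretch a gap of 3 splits the run; neither side reaches 5
        labels = "AAxxxAAA"
        assert detect_islands(_calls(labels), _genes(8), min_genes=5, max_gap=2,
                              circular=False) == []
        # circularly the two ends chain across the origin into one island of 5
        (isl,) = detect_islands(_calls(labels), _genes(8), min_genes=5, max_gap=2,
                                circular=True)
        assert isl.n_acquired == 5

    def test_interrupting_genes_bridged_and_counted(self):
        labels = "AAxxAAA"
        (isl,) = detect_islands(_calls(labels), _genes(7), min_genes=5, max_gap=2,
                                circular=False)
        assert isl.n_acquired == 5 and isl.n_interrupting == 2

    def test_donor_heterogeneity_breaks_runs(self):
        labels = "AAABBB"
        found = detect_islands(_calls(labels), _genes(6), min_genes=3, max_gap=0)
        assert {(i.donor_clade, i.n_acquired) for i in found} == {("A", 3), ("B", 3)}

    def test_wrap_around_origin(self):
        labels = "AAxxxxxAAA"
        (isl,) = detect_islands(_calls(labels), _genes(10), min_genes=5, max_gap=2,
                                circular=True)
        assert isl.n_acquired == 5
        assert isl.span_end < isl.span_start  # wrapping span
        assert detect_islands(_calls(labels), _genes(10), min_genes=5, max_gap=2,
                              circular=False) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            detect_islands(_calls("AA"), _genes(3))


class TestOracle:
    def test_degenerate_closed_form(self):
        """max_gap=0, min_genes=1 returns exactly the maximal same-donor runs."""
        rng = random.Random(5)
        for _ in range(100):
            labels = "".join(rng.choice("ABx") for _ in range(20))
            got = _detected_sets(labels, 1, 0, False)
            runs = set()
            for donor in "AB":
                for m in re.finditer(f"{donor}+", labels):
                    runs.add((donor, frozenset(range(m.start(), m.end()))))
            assert got == runs

    @pytest.mark.parametrize("max_gap", [0, 1, 2])
    @pytest.mark.parametrize("circular", [False, True])
    def test_exhaustive_small_grid(self, max_gap, circular):
        for n in range(1, 8):
            for labels in itertools.product("ABx", repeat=n):
                assert _detected_sets(labels, 2, max_gap, circular) == _oracle_sets(
                    labels, 2, max_gap, circular
                ), labels

    def test_random_long_strings(self):
        rng = random.Random(11)
        for _ in range(60):
            labels = "".join(rng.choice("ABxx") for _ in range(200))
            for max_gap in (0, 1, 2):
                for circular in (False, True):
                    assert _detected_sets(labels, 3, max_gap, circular) == _oracle_sets(
                        labels, 3, max_gap, circular
                    )


class TestInvariants:
    def test_rotation_invariance(self):
        rng = random.Random(3)
        for _ in range(50):
            labels = "".join(rng.choice("ABxxx") for _ in range(40))
            base = {m for _, m in _detected_sets(labels, 3, 2, True)}
            k = rng.randint(1, 39)
            rotated = labels[k:] + labels[:k]
            rot = {
                frozenset((i + k) % 40 for i in m)
                for _, m in _detected_sets(rotated, 3, 2, True)
            }
            assert base == rot

    def test_islands_disjoint_and_high_confidence_only(self, flagship_calls,
                                                       flagship_bundle, flagship_islands):
        hgt_high = {c.gene_id for c in flagship_calls if c.origin_class == "hgt_high"}
        seen = set()
        for isl in flagship_islands:
            members = set(isl.gene_ids)
            assert members <= hgt_high
            assert not (members & seen)
            seen |= members


class TestSynteny:
    def _island(self, subjects):
        return Island(
            island_id="island_1", donor_clade="A", gene_ids=tuple(f"g{i}" for i in range(len(subjects))),
            span_start=1, span_end=100, n_acquired=len(subjects), n_interrupting=0,
            best_hit_subjects=tuple(subjects),
        )

    def test_consecutive_in_donor_order_passes(self):
        isl = self._island(["s1", "s2", "s3", "s4", "s5"])
        assert check_synteny(isl, ["s0", "s1", "s2", "s3", "s4", "s5", "s6"]) is True
        assert isl.synteny_checked and isl.synteny_pass

    def test_inverted_order_passes(self):
        isl = self._island(["s5", "s4", "s3", "s2", "s1"])
        assert check_synteny(isl, ["s1", "s2", "s3", "s4", "s5"]) is True

    def test_shuffled_below_threshold_fails(self):
        # longest ordered common subsequence with the donor order is 3 (< 5)
        members = ["s3", "s1", "s4", "s2", "s5"]
        donor = ["s1", "s2", "s3", "s4", "s5"]

        def lcs(a, b):
            import itertools as it
            best = 0
            for r in range(len(a), 0, -1):
                for comb in it.combinations(a, r):
                    def is_subseq(s, seq):
                        pos = 0
                        for x in seq:
                            if pos < len(s) and s[pos] == x:
                                pos += 1
                        return pos == len(s)
                    if is_subseq(list(comb), b) or is_subseq(list(comb), b[::-1]):
                        return r
            return best

        assert lcs(members, donor) == 3
        isl = self._island(members)
        assert check_synteny(isl, donor) is False

    def test_missing_donor_order_leaves_unchecked(self):
        isl = self._island(["s1"] * 5)
        assert check_synteny(isl, None) is None
        assert not isl.synteny_checked and isl.synteny_pass is None
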