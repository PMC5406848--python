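"""Family alignment, amino-acid diversity, site partition, divergence."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from coreflex import simulate as sim
from coreflex.alignment import (
    ProteinAlignment,
    align_family,
    load_prealigned,
    map_residue_to_column,
    pairwise_aa_diversity,
    pairwise_divergence,
    partition_site_diversity,
)


def brute_force_pi(rows: dict[str, str]) -> float:
    """Independent double-loop diversity oracle with the gap conventions."""
    ids = sorted(rows)
    per_pair = []
    for a, b in combinations(ids, 2):
        diffs = comp = 0
        for x, y in zip(rows[a], rows[b]):
            if x == "-" and y == "-":
                continue
            comp += 1
            diffs += x != y
        per_pair.append(diffs / comp)
    return float(np.mean(per_pair))


class TestAlignFamily:
    def test_identical_pair_is_gap_free(self):
        aln = align_family({"a": "MKTAY", "b": "MKTAY"})
        assert aln.n_columns == 5
        assert set("".join(aln.rows.values())) <= set("MKTAY")

    def test_single_gap_and_roundtrip(self):
        aln = align_family({"a": "ACDE", "b": "ACE"})
        assert aln.n_columns == 4
        assert aln.ungapped("a") == "ACDE"
        assert aln.ungapped("b") == "ACE"
        assert aln.rows["b"].count("-") == 1

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_family({"a": "ACDE"})

    def test_non_residue_characters_rejected(self):
        with pytest.raises(ValueError):
            align_family({"a": "AC1E", "b": "ACDE"})

    def test_prealigned_passthrough_validates_lengths(self):
        aln = load_prealigned({"a": "AC-E", "b": "ACDE"})
        assert aln.n_columns == 4
        with pytest.raises(ValueError):
            load_prealigned({"a": "AC-E", "b": "ACD"})

    def test_multi_sequence_roundtrip(self):
        rng = np.random.default_rng(4)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        base = "".join(rng.choice(aas, size=40))
        seqs = {}
        for i in range(5):
            s = list(base)
            for j in rng.choice(len(s), size=3, replace=False):
                s[j] = rng.choice(aas)
            if i % 2:
                del s[10:13]
            seqs[f"s{i}"] = "".join(s)
        aln = align_family(seqs)
        for sid, seq in seqs.items():
            assert aln.ungapped(sid) == seq


class TestDiversity:
    def test_identical_rows_give_zero(self):
        aln = load_prealigned({f"s{i}": "MKTAY" for i in range(4)})
        assert pairwise_aa_diversity(aln).pi_aa == 0.0

    def test_indel_counts_each_site(self):
        """A 10-residue indel over 100 compared columns adds 10 differences."""
        base = "A" * 100
        gapped = "A" * 90 + "-" * 10
        aln = load_prealigned({"a": base, "b": gapped})
        rec = pairwise_aa_diversity(aln)
        assert rec.pi_aa == pytest.approx(10 / 100)

    def test_sixty_sequences_have_1770_pairs(self):
        aln = load_prealigned({f"s{i:02d}": "MKT" for i in range(60)})
        assert pairwise_aa_diversity(aln).n_pairs == 1770

    def test_three_row_toy_matches_hand_enumeration(self):
        rows = {"s1": "AAAA", "s2": "AACA", "s3": "A-CA"}
        rec = pairwise_aa_diversity(load_prealigned(rows))
        # s1-s2: 1/4; s1-s3: 2/4 (gap + mismatch); s2-s3: 1/4
        assert rec.pi_aa == pytest.approx((0.25 + 0.5 + 0.25) / 3)
        assert rec.pi_aa == pytest.approx(brute_force_pi(rows))

    def test_zero_compared_columns_errors(self):
        rows = {"a": "----", "b": "----", "c": "AAAA"}
        with pytest.raises(ValueError, match="a.*b"):
            pairwise_aa_diversity(load_prealigned(rows))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_seqs=hst.integers(2, 5),
        n_cols=hst.integers(1, 20),
        seed=hst.integers(0, 10_000),
    )
    def test_matches_brute_force_on_random_alignments(self, n_seqs, n_cols, seed):
        rng = np.random.default_rng(seed)
        symbols = np.array(list("ACD-"))
        rows = {}
        for i in range(n_seqs):
            rows[f"s{i}"] = "".join(rng.choice(symbols, size=n_cols))
        aln_rows = rows
        try:
            rec = pairwise_aa_diversity(load_prealigned(aln_rows))
        except ValueError:
            return  # a pair with zero compared columns; contract tested above
        assert rec.pi_aa == pytest.approx(brute_force_pi(aln_rows))

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(1)
        symbols = np.array(list("ACDE-"))
        rows = {f"s{i}": "".join(rng.choice(symbols, size=15)) for i in range(4)}
        rec = pairwise_aa_diversity(load_prealigned(rows))
        perm = rng.permutation(15)
        permuted = {k: "".join(v[j] for j in perm) for k, v in rows.items()}
        rec_p = pairwise_aa_diversity(load_prealigned(permuted))
        assert rec.pi_aa == pytest.approx(rec_p.pi_aa)

    def test_monotone_in_substitution_rate(self):
        """Mean diversity rises with the generator's substitution probability."""
        means = []
        for level, p_sub in enumerate([0.005, 0.03, 0.12]):
            vals = []
            for rep in range(100):
                cfg = sim.PangenomeSimConfig(
                    seed=10_000 * level + rep,
                    n_genomes=5,
                    n_core=1,
                    n_flexible=0,
                    per_site_substitution_prob=p_sub,
                    indel_prob=0.0,
                )
                s = sim.simulate_pangenome(cfg)
                rows = {
                    g: ann.genes[f"{g}_fam0001"].aa_seq
                    for g, ann in s.annotations.items()
                }
                vals.append(pairwise_aa_diversity(load_prealigned(rows)).pi_aa)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSitePartition:
    def test_invariant_alignment_gives_zero_everywhere(self):
        aln = load_prealigned({f"s{i}": "MKTAY" for i in range(3)})
        part = partition_site_diversity(aln, [2, 4])
        assert part.pi_target == 0.0
        assert part.pi_rest == 0.0

    def test_variation_confined_to_target_columns(self):
        aln = load_prealigned({"a": "MKTAY", "b": "MQTAY", "c": "MRTAY"})
        part = partition_site_diversity(aln, [2])
        assert part.pi_rest == 0.0
        assert part.pi_target > 0.0

    def test_matches_column_subset_oracle(self):
        rng = np.random.default_rng(3)
        symbols = np.array(list("ACDE-"))
        rows = {f"s{i}": "".join(rng.choice(symbols, size=12)) for i in range(5)}
        targets = [2, 5, 9]
        part = partition_site_diversity(load_prealigned(rows), targets)
        sub = {k: "".join(v[c - 1] for c in targets) for k, v in rows.items()}
        rest_cols = [c for c in range(1, 13) if c not in targets]
        rest = {k: "".join(v[c - 1] for c in rest_cols) for k, v in rows.items()}

        def oracle(sel):
            per_pair = []
            for a, b in combinations(sorted(sel), 2):
                diffs = comp = 0
                for x, y in zip(sel[a], sel[b]):
                    if x == "-" and y == "-":
                        continue
                    comp += 1
                    diffs += x != y
                if comp:
                    per_pair.append(diffs / comp)
            return float(np.mean(per_pair)) if per_pair else 0.0

        assert part.pi_target == pytest.approx(oracle(sub))
        assert part.pi_rest == pytest.approx(oracle(rest))

    def test_all_columns_recovers_pi_aa(self):
        rng = np.random.default_rng(8)
        symbols = np.array(list("ACD-"))
        rows = {f"s{i}": "".join(rng.choice(symbols, size=10)) for i in range(4)}
        aln = load_prealigned(rows)
        part = partition_site_diversity(aln, list(range(1, 11)))
        assert part.pi_target == pytest.approx(pairwise_aa_diversity(aln).pi_aa)

    def test_out_of_range_column_errors(self):
        aln = load_prealigned({"a": "MKT", "b": "MKT"})
        with pytest.raises(ValueError):
            partition_site_diversity(aln, [4])


class TestResidueColumnMapping:
    def test_gap_free_identity(self):
        aln = load_prealigned({"a": "MKTAY", "b": "MKTAY"})
        assert map_residue_to_column(aln, "a", 3) == 3

    def test_leading_gap_offsets(self):
        aln = load_prealigned({"a": "-AC", "b": "WAC"})
        assert map_residue_to_column(aln, "a", 1) == 2

    def test_roundtrip_on_random_gapped_rows(self):
        rng = np.random.default_rng(11)
        symbols = np.array(list("ACDE-"))
        row = "".join(rng.choice(symbols, size=30))
        other = "".join(rng.choice(np.array(list("ACDE")), size=30))
        aln = load_prealigned({"a": row, "b": other})
        residues = [i for i, ch in enumerate(row) if ch != "-"]
        for res_idx, col0 in enumerate(residues, start=1):
            col = map_residue_to_column(aln, "a", res_idx)
            assert col == col0 + 1
            assert row[col - 1] != "-"

    def test_beyond_ungapped_length_errors(self):
        aln = load_prealigned({"a": "A-C", "b": "AAC"})
        with pytest.raises(ValueError):
            map_residue_to_column(aln, "a", 3)


class TestDivergence:
    def test_identical_pair_zero(self):
        aln = load_prealigned({"a": "MKTAY", "b": "MKTAY"})
        assert pairwise_divergence(aln).d == 0.0

    def test_two_mismatches_in_hundred(self):
        a = "A" * 100
        b = "C" * 2 + "A" * 98
        rec = pairwise_divergence(load_prealigned({"a": a, "b": b}))
        assert rec.d == pytest.approx(0.02)

    def test_indel_plus_mismatch_counts_each_column(self):
        """3-column indel + 1 mismatch over 50 columns -> d = 4/50."""
        a = "A" * 50
        b = "C" + "A" * 46 + "-" * 3
        rec = pairwise_divergence(load_prealigned({"a": a, "b": b}))
        assert rec.aligned_length == 50
        assert rec.n_diff == 4
        assert rec.d == pytest.approx(4 / 50)

    def test_requires_exactly_two_rows(self):
        with pytest.raises(ValueError):
            pairwise_divergence(load_prealigned({"a": "MK", "b": "MK", "c": "MK"}))
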