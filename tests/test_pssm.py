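"""Count-table construction and the centred log-frequency score matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import frpssm as fp
from frpssm._seqcodes import AA_INDEX, GAP, encode_aa
from frpssm.pssm import LOG_BASE

from conftest import make_count_table


def aa_matrix_from_strings(seqs):
    return np.stack([encode_aa(s) for s in seqs])


class TestTally:
    def test_identical_copies_concentrate_on_wildtype(self, ref):
        mat = aa_matrix_from_strings([ref.aa_seq] * 10)
        table = fp.tally_counts(mat, ref)
        gl = encode_aa(ref.aa_seq)
        assert np.array_equal(table.totals, np.full(len(table.positions), 10))
        for i, p in enumerate(table.positions):
            assert table.counts[i, gl[p - 1]] == 10
            assert table.counts[i].sum() == 10

    def test_direct_substitution_count(self, ref):
        # position 5 is framework; mutate it to A in 3 of 10 sequences
        assert ref.region_of(5) == "FR1" and ref.aa_seq[4] != "A"
        mut = ref.aa_seq[:4] + "A" + ref.aa_seq[5:]
        table = fp.tally_counts(aa_matrix_from_strings([mut] * 3 + [ref.aa_seq] * 7), ref)
        i = list(table.positions).index(5)
        assert table.counts[i, AA_INDEX["A"]] == 3
        assert table.totals[i] == 10

    def test_gap_excluded_from_totals(self, ref):
        mat = aa_matrix_from_strings([ref.aa_seq] * 10)
        mat[0, 6] = GAP  # position 7 gapped in one sequence
        table = fp.tally_counts(mat, ref)
        i = list(table.positions).index(7)
        assert table.totals[i] == 9
        assert table.counts[i].sum() == 9

    def test_cdr_columns_excluded(self, ref):
        table = fp.tally_counts(aa_matrix_from_strings([ref.aa_seq]), ref)
        assert all(lbl.startswith("FR") for lbl in table.region_labels)
        assert set(table.positions) == set(ref.fr_positions())


class TestMasking:
    def test_single_allele_masks_wildtype_only(self, ref):
        table = fp.tally_counts(aa_matrix_from_strings([ref.aa_seq] * 4), ref)
        masked = fp.mask_wt_and_alleles(table, ref)
        gl = encode_aa(ref.aa_seq)
        for i, p in enumerate(masked.positions):
            assert masked.masked[i, gl[p - 1]]
            assert masked.masked[i].sum() == 1
        assert np.array_equal(masked.totals, table.totals)

    def test_allelic_variant_masks_both_residues(self, ref):
        allele = fp.synthetic_allele(ref, position=85, target_aa="N")
        table = fp.tally_counts(aa_matrix_from_strings([ref.aa_seq] * 4), ref)
        masked = fp.mask_wt_and_alleles(table, ref, [allele])
        i = list(masked.positions).index(85)
        assert masked.masked[i, AA_INDEX[ref.aa_seq[84]]]
        assert masked.masked[i, AA_INDEX["N"]]
        assert masked.masked[i].sum() == 2

    def test_masking_idempotent(self, ref):
        table = fp.tally_counts(aa_matrix_from_strings([ref.aa_seq] * 4), ref)
        once = fp.mask_wt_and_alleles(table, ref)
        twice = fp.mask_wt_and_alleles(once, ref)
        assert np.array_equal(once.masked, twice.masked)
        assert np.array_equal(once.counts, twice.counts)

    def test_length_mismatched_allele_errors(self, ref):
        allele = fp.GermlineReference(ref.gene_name, ref.gene_name + "*bad",
                                      ref.nt_seq[:-3],
                                      {"FR1": (1, 25), "CDR1": (26, 33), "FR2": (34, 50),
                                       "CDR2": (51, 58), "FR3": (59, 95)})
        table = fp.tally_counts(aa_matrix_from_strings([ref.aa_seq]), ref)
        with pytest.raises(ValueError, match="length"):
            fp.mask_wt_and_alleles(table, ref, [allele])


def test_pseudocount_rules(ref):
    table = fp.tally_counts(aa_matrix_from_strings([ref.aa_seq] * 5), ref)
    table = fp.mask_wt_and_alleles(table, ref)
    table.counts[0, (~table.masked[0]).argmax()] = 5  # a non-zero unmasked cell
    out = fp.apply_pseudocounts(table)
    unmasked_zero = (table.counts == 0) & ~table.masked
    assert (out.counts[unmasked_zero] == 1).all()
    assert (out.pseudocounted == unmasked_zero).all()
    assert (out.counts[~unmasked_zero] == table.counts[~unmasked_zero]).all()
    # masked zeros stay outside scoring entirely
    pssm = fp.score_matrix(out, fp.solve_alpha(out))
    assert np.isnan(pssm.scores[table.masked]).all()


class TestAlpha:
    def test_uniform_frequencies(self):
        table = make_count_table([[(0, 0.05)], [(1, 0.05)]], totals=10_000)
        alpha = fp.solve_alpha(table)
        assert alpha == pytest.approx(20.0)
        pssm = fp.score_matrix(table, alpha)
        assert pssm.flat() == pytest.approx([0.0, 0.0], abs=1e-9)

    @pytest.mark.parametrize("f2,expected_alpha,expected_absscore", [
        (0.001, 100.0, np.log(10) / np.log(LOG_BASE)),
        (0.01, np.sqrt(1000.0), np.log(np.sqrt(10)) / np.log(LOG_BASE)),
    ])
    def test_two_entry_closed_form(self, f2, expected_alpha, expected_absscore):
        table = make_count_table([[(0, 0.1)], [(1, f2)]], totals=100_000)
        alpha = fp.solve_alpha(table)
        assert alpha == pytest.approx(expected_alpha)
        scores = fp.score_matrix(table, alpha).flat()
        assert np.sort(np.abs(scores)) == pytest.approx(
            [expected_absscore, expected_absscore])

    def test_closed_form_agrees_with_root_finder(self, ref, sim_matrices):
        _, aa = sim_matrices
        table = fp.apply_pseudocounts(
            fp.mask_wt_and_alleles(fp.tally_counts(aa[:2000], ref), ref))
        alpha = fp.solve_alpha(table)
        f = (table.counts / table.totals[:, None])[~table.masked]

        def mean_score(a):
            return np.mean(np.log(a * f) / np.log(LOG_BASE))

        root = brentq(mean_score, 1e-6, 1e12)
        assert alpha == pytest.approx(root, rel=1e-9)

    def test_empty_entry_set_errors(self):
        table = make_count_table([[(0, 0.1)]])
        table.masked[:] = True
        with pytest.raises(ValueError):
            fp.solve_alpha(table)


class TestScores:
    def test_spot_values(self):
        # N=100, T=1000, alpha=100 -> log_1.26(10); pseudocount N=1, T=10000,
        # alpha=1000 -> log_1.26(0.1); f = 1/alpha -> 0
        table = make_count_table([[(0, 0.1)]], totals=1000)
        assert fp.score_matrix(table, 100.0).flat()[0] == pytest.approx(
            np.log(10) / np.log(LOG_BASE))
        table = make_count_table([[(0, 1e-4)]], totals=10_000)
        assert fp.score_matrix(table, 1000.0).flat()[0] == pytest.approx(
            np.log(0.1) / np.log(LOG_BASE))
        table = make_count_table([[(0, 0.02)]], totals=10_000)
        assert fp.score_matrix(table, 50.0).flat()[0] == pytest.approx(0.0, abs=1e-9)

    def test_mean_zero_on_simulated_repertoire(self, sim_pssm):
        assert abs(np.mean(sim_pssm.flat())) < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mean_zero_property(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.integers(2, 8)
        freqs = []
        for _ in range(P):
            js = rng.choice(20, size=rng.integers(1, 6), replace=False)
            freqs.append([(int(j), float(rng.uniform(1e-4, 0.3))) for j in js])
        table = make_count_table(freqs, totals=100_000)
        table = fp.apply_pseudocounts(table)
        pssm = fp.score_matrix(table, fp.solve_alpha(table))
        assert abs(np.mean(pssm.flat())) < 1e-6

    def test_monotonic_in_counts(self):
        # at fixed T and alpha, the score strictly increases with N
        scores = []
        for f in (0.001, 0.01, 0.1, 0.3):
            table = make_count_table([[(0, f)]], totals=100_000)
            scores.append(fp.score_matrix(table, 123.0).flat()[0])
        assert np.all(np.diff(scores) > 0)

    def test_scale_invariance(self, ref, sim_matrices):
        # multiplying every N and T by k leaves all scores unchanged
        _, aa = sim_matrices
        table = fp.apply_pseudocounts(
            fp.mask_wt_and_alleles(fp.tally_counts(aa[:3000], ref), ref))
        scaled = table.copy()
        scaled.counts *= 7
        scaled.totals *= 7
        a1, a2 = fp.solve_alpha(table), fp.solve_alpha(scaled)
        s1 = fp.score_matrix(table, a1).flat()
        s2 = fp.score_matrix(scaled, a2).flat()
        assert s1 == pytest.approx(s2)

    def test_pseudocount_floor(self, ref, sim_pssm):
        # wherever a pseudocounted cell exists, it attains the position minimum
        for i in range(len(sim_pssm.positions)):
            row_pseudo = sim_pssm.pseudocounted[i]
            if not row_pseudo.any():
                continue
            row = sim_pssm.scores[i]
            valid = ~np.isnan(row)
            assert np.nanmin(row) == pytest.approx(row[row_pseudo].min())
            assert (row[valid] >= row[row_pseudo].min() - 1e-9).all()


def test_build_pssm_warns_below_depth(ref, sim_matrices):
    _, aa = sim_matrices
    with pytest.warns(UserWarning, match="below the recommended depth"):
        fp.build_pssm(aa[:500], ref, min_sequences=100_000)
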