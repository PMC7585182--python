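import math

import numpy as np
import pytest

from rbhkit.align import (
    ScoringScheme,
    all_vs_all,
    align_proteomes,
    build_external_command,
    self_scores,
    smith_waterman,
)
from rbhkit.io import ProteinRecord

from conftest import AA20, random_protein


class TestSmithWaterman:
    def test_self_alignment_spans_whole_sequence(self, scheme):
        seq = "".join(AA20[i % 20] for i in range(100))
        h = smith_waterman(seq, seq, scheme)
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 100, 1, 100)
        assert h.identity_frac == 1.0

    def test_bit_score_formula(self, scheme):
        # bits = (lambda * raw - ln K) / ln 2, evaluated independently
        expected = (0.267 * 100 - math.log(0.041)) / math.log(2)
        assert scheme.bits_from_raw(100) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(43.129, abs=1e-3)

    def test_no_positive_alignment_returns_none(self, scheme, blosum62):
        # every pairing of A with W scores negative; brute force confirms
        assert all(blosum62[x, "W"] < 0 for x in "A")
        assert smith_waterman("AAAA", "WWWW", scheme) is None

    def test_unknown_residue_is_error(self, scheme):
        with pytest.raises(ValueError, match="residue"):
            smith_waterman("ACDU", "ACD", scheme)

    def test_x_scored_via_matrix_row(self, scheme):
        h = smith_waterman("ACXDE", "ACXDE", scheme)
        assert h is not None and h.raw_score > 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_plain_python_dp_oracle(self, scheme, sw_oracle, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b = random_protein(rng, 4, 40), random_protein(rng, 4, 40)
            h = smith_waterman(a, b, scheme)
            assert (h.raw_score if h else 0) == sw_oracle(a, b)

    def test_matches_biotite_aligner(self, scheme):
        import biotite.sequence as bseq
        import biotite.sequence.align as bta

        mat = bta.SubstitutionMatrix.std_protein_matrix()
        rng = np.random.default_rng(42)
        for _ in range(60):
            a, b = random_protein(rng, 5, 80), random_protein(rng, 5, 80)
            h = smith_waterman(a, b, scheme)
            alns = bta.align_optimal(
                bseq.ProteinSequence(a), bseq.ProteinSequence(b), mat,
                gap_penalty=(-12, -1), local=True, max_number=1,
            )
            ref = alns[0].score if alns else 0
            assert (h.raw_score if h else 0) == max(ref, 0)

    def test_score_symmetry(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = random_protein(rng), random_protein(rng)
            ha, hb = smith_waterman(a, b, scheme), smith_waterman(b, a, scheme)
            assert (ha.raw_score if ha else 0) == (hb.raw_score if hb else 0)

    def test_bits_increase_and_evalue_decreases_with_raw_score(self, scheme):
        raws = [10, 50, 100, 200]
        bits = [scheme.bits_from_raw(r) for r in raws]
        evs = [scheme.evalue_from_bits(b, 100, 100) for b in bits]
        assert bits == sorted(bits) and len(set(bits)) == len(bits)
        assert evs == sorted(evs, reverse=True) and len(set(evs)) == len(evs)


class TestSelfScores:
    def test_acd_diagonal_sum(self, scheme, blosum62):
        # S(A,A)+S(C,C)+S(D,D) = 4+9+6 = 19
        expected_raw = blosum62["A", "A"] + blosum62["C", "C"] + blosum62["D", "D"]
        assert expected_raw == 19
        got = self_scores([ProteinRecord("p", "ACD")], scheme)
        assert got == {"p": pytest.approx(scheme.bits_from_raw(19))}

    def test_empty_proteome_gives_empty_map(self, scheme):
        assert self_scores([], scheme) == {}

    def test_agrees_with_full_alignment(self, scheme):
        rng = np.random.default_rng(11)
        recs = [ProteinRecord(f"p{i}", random_protein(rng)) for i in range(50)]
        bits = self_scores(recs, scheme)
        for r in recs:
            h = smith_waterman(r, r, scheme)
            assert bits[r.protein_id] == pytest.approx(h.bits, rel=1e-12)

    def test_cross_bits_bounded_by_self_bits(self, scheme):
        rng = np.random.default_rng(13)
        recs = [ProteinRecord(f"p{i}", random_protein(rng, 20, 80)) for i in range(20)]
        selfs = self_scores(recs, scheme)
        for i in range(0, 20, 2):
            h = smith_waterman(recs[i], recs[i + 1], scheme)
            if h is not None:
                cap = min(selfs[recs[i].protein_id], selfs[recs[i + 1].protein_id])
                assert h.bits <= cap + 1e-9


class TestAllVsAll:
    def test_identical_proteomes_best_hit_is_self(self, scheme):
        rng = np.random.default_rng(5)
        recs = [ProteinRecord(f"p{i}", random_protein(rng, 30, 60)) for i in range(5)]
        table = all_vs_all(recs, recs, scheme, evalue_cap=1e-3, query_genome="A", target_genome="A")
        for r in recs:
            mine = [h for h in table.hits if h.query_id == r.protein_id]
            assert mine, "every protein hits itself"
            assert mine[0].subject_id == r.protein_id  # sorted by descending bits

    def test_empty_targetome_gives_empty_table(self, scheme):
        recs = [ProteinRecord("p0", "MKVACDEFGH")]
        assert len(all_vs_all(recs, [], scheme)) == 0

    def test_equals_per_pair_calls(self, scheme):
        rng = np.random.default_rng(17)
        a = [ProteinRecord(f"a{i}", random_protein(rng, 20, 60)) for i in range(10)]
        b = [ProteinRecord(f"b{i}", random_protein(rng, 20, 60)) for i in range(10)]
        cap = 1.0  # accept everything with positive score
        table = all_vs_all(a, b, scheme, evalue_cap=cap)
        expected = {}
        for x in a:
            for y in b:
                h = smith_waterman(x, y, scheme)
                if h is not None and h.evalue <= cap:
                    expected[x.protein_id, y.protein_id] = h
        got = {(h.query_id, h.subject_id): h for h in table.hits}
        assert got == expected

    def test_mirrored_table_is_consistent(self, scheme):
        rng = np.random.default_rng(19)
        a = [ProteinRecord(f"a{i}", random_protein(rng, 20, 50)) for i in range(6)]
        b = [ProteinRecord(f"b{i}", random_protein(rng, 20, 50)) for i in range(6)]
        tab, tba = align_proteomes(a, b, scheme, evalue_cap=1.0, genome_a="A", genome_b="B")
        fwd = {(h.query_id, h.subject_id): h for h in tab.hits}
        rev = {(h.subject_id, h.query_id): h for h in tba.hits}
        assert set(fwd) == set(rev)
        for key, h in fwd.items():
            assert rev[key].bits == h.bits
            assert (rev[key].s_start, rev[key].s_end) == (h.q_start, h.q_end)


class TestExternalCommands:
    def test_diamond_very_sensitive_without_masking(self):
        spec = build_external_command("diamond", "q.faa", "s.faa", "out.tsv",
                                      sensitivity="very-sensitive")
        assert "--very-sensitive" in spec.search_command
        masking = spec.search_command.index("--masking")
        assert spec.search_command[masking + 1] == "0"
        assert spec.db_command[:2] == ("diamond", "makedb")

    def test_mmseqs_default_sensitivity_is_5_7(self):
        spec = build_external_command("mmseqs", "q.faa", "s.faa", "out.tsv")
        s_flag = spec.search_command.index("-s")
        assert spec.search_command[s_flag + 1] == "5.7"
        assert "easy-search" in spec.search_command
        assert spec.db_command[:2] == ("mmseqs", "createdb")

    def test_blastp_soft_masking_and_sw_traceback(self):
        spec = build_external_command("blastp", "q.faa", "s.faa", "out.tsv")
        assert "-use_sw_tback" in spec.search_command
        sm = spec.search_command.index("-soft_masking")
        assert spec.search_command[sm + 1] == "true"
        assert spec.db_command[0] == "makeblastdb"
        assert "qlen slen" in " ".join(spec.search_command)

    def test_lastal_database_and_softmask_flag(self):
        spec = build_external_command("lastal", "q.faa", "s.faa", "out.tsv")
        assert spec.db_command[0] == "lastdb" and "-c" in spec.db_command

    @pytest.mark.parametrize(
        "program,sensitivity,msg",
        [
            ("blat", None, "unknown program"),
            ("diamond", "turbo", "sensitivity"),
            ("mmseqs", 9.0, "sensitivity"),
        ],
    )
    def test_invalid_inputs_list_valid_options(self, program, sensitivity, msg):
        with pytest.raises(ValueError, match=msg):
            build_external_command(program, "q", "s", "o", sensitivity=sensitivity)
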