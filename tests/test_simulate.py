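import numpy as np
import pytest

from rbhkit.evaluate import conserved_adjacencies, error_rate
from rbhkit.rbh import find_orthologs
from rbhkit.simulate import (
    SimulationConfig,
    divergence_ladder,
    plant_confusable_paralogs,
    simulate_clades,
    simulate_pair,
)


def small_cfg(**kw):
    defaults = dict(n_genes=12, protein_length_range=(30, 60), seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulatePair:
    def test_zero_divergence_is_a_noop_up_to_ids(self):
        b = simulate_pair(small_cfg())
        assert [r.sequence for r in b.proteome_b] == [r.sequence for r in b.proteome_a]
        assert len(b.truth_orthologs) == 12
        for rec_a, rec_b in zip(b.proteome_a, b.proteome_b):
            assert frozenset((rec_a.protein_id, rec_b.protein_id)) in b.truth_orthologs

    def test_total_loss_is_an_error(self):
        with pytest.raises(ValueError, match="survives"):
            simulate_pair(small_cfg(p_loss=1.0))

    def test_seeded_determinism(self):
        b1 = simulate_pair(small_cfg(divergence=0.2, p_dup=0.5, p_loss=0.1, n_inversions=2))
        b2 = simulate_pair(small_cfg(divergence=0.2, p_dup=0.5, p_loss=0.1, n_inversions=2))
        assert b1.proteome_b == b2.proteome_b
        assert b1.loci_b == b2.loci_b
        assert b1.dna_b == b2.dna_b
        assert b1.truth_orthologs == b2.truth_orthologs

    def test_truth_size_is_genes_minus_losses(self):
        b = simulate_pair(small_cfg(n_genes=60, p_loss=0.3, p_dup=0.4, divergence=0.1))
        survivors = {r.gene_id for r in b.proteome_b if "." not in r.gene_id}
        assert len(b.truth_orthologs) == len(survivors)
        lost = {f"anc{i:04d}" for i in range(60)} - survivors
        for pair in b.truth_orthologs:
            for pid in pair:
                assert pid.rsplit("_", 1)[0] not in lost

    def test_duplicates_share_family_and_add_no_orthologs(self):
        b = simulate_pair(small_cfg(n_genes=30, p_dup=0.5, divergence=0.1))
        dups = [r for r in b.proteome_b if ".dup" in r.protein_id]
        assert dups, "expected some duplications at p_dup=0.5"
        truth_members = {pid for pair in b.truth_orthologs for pid in pair}
        for d in dups:
            assert d.protein_id not in truth_members
            assert b.truth_paralogs[d.protein_id] == d.gene_id.split(".")[0]

    def test_loci_are_consecutive_ranks(self):
        b = simulate_pair(small_cfg(n_genes=25, p_dup=0.4, p_loss=0.2, n_inversions=3))
        ranks = [l.index for l in b.loci_b]
        assert ranks == list(range(len(b.proteome_b)))

    def test_dna_back_translates_the_proteins(self):
        b = simulate_pair(small_cfg(n_genes=5, codon_skew=0.0))
        total_aa = sum(r.length for r in b.proteome_a)
        assert len(b.dna_a[0][1]) == 3 * total_aa
        assert set(b.dna_a[0][1]) <= set("ACGT")

    def test_bundle_write_emits_expected_files(self, tmp_path):
        b = simulate_pair(small_cfg())
        paths = b.write(tmp_path)
        names = {p.name for p in paths}
        assert names == {
            "proteome_a.faa", "proteome_b.faa", "loci_a.tsv", "loci_b.tsv",
            "dna_a.fna", "dna_b.fna", "truth.tsv",
        }
        assert all(p.exists() for p in paths)

    def test_indels_change_lengths_deterministically(self):
        cfg = small_cfg(indel_rate=0.05)
        b1, b2 = simulate_pair(cfg), simulate_pair(cfg)
        assert b1.proteome_b == b2.proteome_b
        lengths_a = [r.length for r in b1.proteome_a]
        lengths_b = [r.length for r in b1.proteome_b]
        assert lengths_a != lengths_b


class TestDivergenceLadder:
    def test_single_zero_rung_gives_identical_proteomes(self):
        (b,) = divergence_ladder(small_cfg(), [0.0])
        assert [r.sequence for r in b.proteome_b] == [r.sequence for r in b.proteome_a]

    def test_rungs_share_gene_ids_and_ancestor(self):
        ladder = divergence_ladder(small_cfg(), [0.0, 0.1, 0.3])
        ids = [tuple(r.protein_id for r in b.proteome_b) for b in ladder]
        assert ids[0] == ids[1] == ids[2]
        seqs_a = [tuple(r.sequence for r in b.proteome_a) for b in ladder]
        assert seqs_a[0] == seqs_a[1] == seqs_a[2]

    def test_substitutions_are_nested_along_the_ladder(self):
        ladder = divergence_ladder(small_cfg(n_genes=8), [0.05, 0.25])
        for lo, hi in zip(ladder[0].proteome_b, ladder[1].proteome_b):
            anc = {r.protein_id.replace("_b", "_a"): r for r in ladder[0].proteome_a}
            a = anc[lo.protein_id.replace("_b", "_a")].sequence
            changed_lo = {i for i, (x, y) in enumerate(zip(a, lo.sequence)) if x != y}
            changed_hi = {i for i, (x, y) in enumerate(zip(a, hi.sequence)) if x != y}
            assert changed_lo <= changed_hi

    def test_unsorted_divergences_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            divergence_ladder(small_cfg(), [0.3, 0.1])


class TestPlantConfusableParalogs:
    def base(self):
        return simulate_pair(small_cfg(n_genes=10, p_dup=1.0, divergence=0.15))

    def test_q_zero_is_identity(self):
        b = self.base()
        planted = plant_confusable_paralogs(b, 0.0)
        assert planted.proteome_b == b.proteome_b
        assert planted.confused_genes == set()

    def test_no_paralogs_is_error(self):
        b = simulate_pair(small_cfg())
        with pytest.raises(ValueError, match="paralog"):
            plant_confusable_paralogs(b, 0.5)

    def test_seeded_determinism(self):
        b = self.base()
        p1 = plant_confusable_paralogs(b, 0.4, seed=3)
        p2 = plant_confusable_paralogs(b, 0.4, seed=3)
        assert p1.confused_genes == p2.confused_genes
        assert p1.proteome_b == p2.proteome_b

    def test_paralog_becomes_the_higher_scoring_partner(self):
        b = self.base()
        planted = plant_confusable_paralogs(b, 1.0, seed=1)
        assert planted.confused_genes
        res = find_orthologs(planted.proteome_a, planted.proteome_b)
        rbh_map = {p.id_a: p.id_b for p in res.rbh}
        hits = 0
        for g in sorted(planted.confused_genes):
            partner = rbh_map.get(f"{g}_a")
            if partner is not None:
                assert partner == f"{g}.dup1_b", "paralog should displace the ortholog"
                hits += 1
        assert hits > 0

    def test_hand_traced_classification_on_mixed_confusion(self):
        # every gene duplicated, half the orthologs confused: on quadruples
        # whose both sides are true ortholog pairs, the RBH status of each
        # side is exactly "gene not confused", so each mixed junction counts
        # one paralog and each clean junction one confirmation
        b = simulate_pair(SimulationConfig(
            n_genes=12, protein_length_range=(40, 60), p_dup=1.0,
            divergence=0.15, seed=5,
        ))
        assert sum(".dup" in r.protein_id for r in b.proteome_b) == 12
        planted = plant_confusable_paralogs(b, 0.5, seed=5)
        assert len(planted.confused_genes) == 6
        res = find_orthologs(planted.proteome_a, planted.proteome_b)
        cases = conserved_adjacencies(
            planted.loci_a, planted.loci_b, res.filtered_ab, res.filtered_ba, res.rbh
        )
        ortholog_cases = [
            c for c in cases if ".dup" not in c.a_prime and ".dup" not in c.b_prime
        ]
        assert ortholog_cases, "some ortholog junctions must survive dup insertion"
        mixed = 0
        for c in ortholog_cases:
            gi = c.a.rsplit("_", 1)[0]
            gj = c.b.rsplit("_", 1)[0]
            assert c.a_is_rbh == (gi not in planted.confused_genes)
            assert c.b_is_rbh == (gj not in planted.confused_genes)
            mixed += c.a_is_rbh != c.b_is_rbh
        est = error_rate(cases, res.rbh)
        assert est.defined
        assert est.P >= mixed > 0

class TestSimulateClades:
    def test_counts_and_determinism(self):
        g1 = simulate_clades(n_clades=2, genomes_per_clade=3, n_genes=10, seed=4)
        g2 = simulate_clades(n_clades=2, genomes_per_clade=3, n_genes=10, seed=4)
        assert len(g1) == 6
        assert g1 == g2
        assert len({g.genome_id for g in g1}) == 6

    def test_protein_counts_distinct_within_clade(self):
        genomes = simulate_clades(n_clades=1, genomes_per_clade=4, n_genes=10, seed=4)
        counts = [g.protein_count for g in genomes]
        assert len(set(counts)) == 4
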