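"""Synthetic-data generators: structure, determinism, planted signal."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import cnescreen as cs
from cnescreen.simulate import CONSTRAINED, RELAXED


class TestFixtureTree:
    def test_small_tree_structure(self):
        t = cs.generate_fixture_tree(3, 1, 0.5, seed=7)
        assert len(t.species) == 4
        assert t.loss_species == ("loss1",)
        parsed = dendropy.Tree.get(data=t.newick_text, schema="newick")
        assert len(parsed.leaf_nodes()) == 4

    def test_same_seed_byte_identical(self):
        a = cs.generate_fixture_tree(8, 2, 0.6, seed=41)
        b = cs.generate_fixture_tree(8, 2, 0.6, seed=41)
        assert a.newick_text == b.newick_text

    def test_ultrametric_depth(self):
        t = cs.generate_fixture_tree(6, 2, 0.5, seed=9)
        for d in t.distance_to_root.values():
            assert d == pytest.approx(0.5, abs=1e-6)

    def test_clustered_losses_form_clade(self, fixture_tree):
        tree = fixture_tree.tree
        taxa = [
            l.taxon for l in tree.leaf_node_iter()
            if l.taxon.label in fixture_tree.loss_species
        ]
        mrca = tree.mrca(taxa=taxa)
        under = {l.taxon.label for l in mrca.leaf_iter()}
        assert under == set(fixture_tree.loss_species)

    def test_scattered_losses_not_siblings(self):
        t = cs.generate_fixture_tree(10, 2, 0.5, seed=1, scattered=True)
        tree = t.tree
        taxa = [
            l.taxon for l in tree.leaf_node_iter() if l.taxon.label in t.loss_species
        ]
        mrca = tree.mrca(taxa=taxa)
        under = {l.taxon.label for l in mrca.leaf_iter()}
        # the MRCA of any two loss leaves also spans non-loss species
        assert under - set(t.loss_species)

    @pytest.mark.parametrize(
        "args", [(2, 1, 0.5), (3, 0, 0.5), (3, 1, 0.0), (3, 1, -1.0)]
    )
    def test_invalid_parameters(self, args):
        with pytest.raises(ValueError):
            cs.generate_fixture_tree(*args, seed=0)


class TestEvolveCnes:
    def test_zero_branch_lengths_yield_identical_sequences(self):
        t = cs.PhyloTree("((a:0.0,b:0.0):0.0,(c:0.0,d:0.0):0.0);")
        alns, _ = cs.evolve_cnes(t, 5, seed=1)
        for aln in alns:
            seqs = set(aln.sequences.values())
            assert len(seqs) == 1

    def test_lengths_within_truncation_range(self, fixture_tree):
        alns, _ = cs.evolve_cnes(fixture_tree, 100, length_mean=100, seed=4)
        for a in alns:
            assert 30 <= a.aligned_length <= 1000

    def test_determinism(self, fixture_tree):
        a1, t1 = cs.evolve_cnes(fixture_tree, 10, seed=5, relaxed_fraction=0.2,
                                relaxation_factor=5)
        a2, t2 = cs.evolve_cnes(fixture_tree, 10, seed=5, relaxed_fraction=0.2,
                                relaxation_factor=5)
        assert [a.sequences for a in a1] == [a.sequences for a in a2]
        assert t1 == t2

    def test_relaxed_fraction_without_loss_species_errors(self):
        t = cs.PhyloTree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        with pytest.raises(ValueError):
            cs.evolve_cnes(t, 5, relaxed_fraction=0.5, relaxation_factor=5, seed=0)

    def test_relaxation_lowers_identity_in_loss_species(self):
        """Monte-Carlo: relaxed CNEs drift further from the ancestor in the
        loss lineages than elsewhere (rate 0.1, factor 10, depth 0.5)."""
        tree = cs.generate_fixture_tree(6, 2, 0.5, seed=2)
        alns, truths, roots = cs.evolve_cnes(
            tree, 200, constrained_rate=0.1, relaxed_fraction=1.0,
            relaxation_factor=10.0, seed=6, _return_roots=True,
        )
        loss_pid, other_pid = [], []
        for aln in alns:
            anc = roots[aln.cne_id]
            for sp, seq in aln.sequences.items():
                pid = cs.percent_identity(seq, anc)
                (loss_pid if sp in tree.loss_species else other_pid).append(pid)
        assert np.mean(loss_pid) < np.mean(other_pid) - 0.05

    def test_factor_one_has_no_lineage_effect(self):
        tree = cs.generate_fixture_tree(6, 2, 0.5, seed=2)
        alns, truths, roots = cs.evolve_cnes(
            tree, 150, constrained_rate=0.15, relaxed_fraction=0.5,
            relaxation_factor=1.0, seed=8, _return_roots=True,
        )
        assert all(t.sim_class == CONSTRAINED or t.relaxation_factor == 1.0
                   for t in truths)
        loss_pid, other_pid = [], []
        for aln in alns:
            anc = roots[aln.cne_id]
            for sp, seq in aln.sequences.items():
                (loss_pid if sp in tree.loss_species else other_pid).append(
                    cs.percent_identity(seq, anc)
                )
        assert abs(np.mean(loss_pid) - np.mean(other_pid)) < 0.02


class TestSimTruth:
    def test_constrained_must_have_unit_factor(self):
        with pytest.raises(ValueError):
            cs.SimTruth("x", CONSTRAINED, 2.0)
        with pytest.raises(ValueError):
            cs.SimTruth("x", RELAXED, 0.5)


class TestGeneAnnotation:
    def test_single_gene(self):
        df = cs.generate_gene_annotation(1, 10_000_000, seed=3)
        assert len(df) == 1
        assert 0 <= df.tss.iloc[0] < 10_000_000
        assert df.strand.iloc[0] in "+-"

    def test_fifty_unique_increasing_tss(self):
        df = cs.generate_gene_annotation(50, 10_000_000, seed=3)
        assert df.tss.is_unique and df.tss.is_monotonic_increasing
        assert (df.tss >= 0).all() and (df.tss < 10_000_000).all()

    def test_determinism(self):
        a = cs.generate_gene_annotation(20, 1_000_000, seed=3)
        b = cs.generate_gene_annotation(20, 1_000_000, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_placement_errors(self):
        with pytest.raises(ValueError):
            cs.generate_gene_annotation(11, 10, seed=0)


class TestPeaks:
    @pytest.fixture
    def cne_df(self):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(20) * 5000,
                "end": np.arange(20) * 5000 + 300,
                "name": [f"c{i}" for i in range(20)],
            }
        )

    @staticmethod
    def _n_overlapping(peaks, cnes):
        n = 0
        for p in peaks.itertuples():
            if any(
                c.start < p.end and p.start < c.end
                for c in cnes.itertuples()
            ):
                n += 1
        return n

    def test_zero_overlap_fraction(self, cne_df):
        peaks = cs.generate_peaks(cne_df, 0.0, 10, seed=1, chrom_length=200_000)
        assert self._n_overlapping(peaks, cne_df) == 0

    def test_full_overlap_fraction(self, cne_df):
        peaks = cs.generate_peaks(cne_df, 1.0, 0, seed=1, chrom_length=200_000)
        assert len(peaks) == 20
        # every CNE is intersected by >= 1 bp
        for c in cne_df.itertuples():
            assert any(
                p.start < c.end and c.start < p.end for p in peaks.itertuples()
            )

    def test_output_sorted_nonnegative(self, cne_df):
        peaks = cs.generate_peaks(cne_df, 0.5, 15, seed=2, chrom_length=200_000)
        assert (peaks.start >= 0).all() and (peaks.end > peaks.start).all()
        assert peaks.start.is_monotonic_increasing

    def test_no_space_for_decoys_errors(self, cne_df):
        wall = pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [10_000], "name": ["big"]}
        )
        with pytest.raises(ValueError):
            cs.generate_peaks(wall, 0.0, 5, seed=0, chrom_length=10_000)


class TestMotifLibrary:
    def test_columns_normalized(self, motif_library):
        for p in motif_library:
            assert np.allclose(p.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_determinism(self):
        a = cs.generate_motif_library(5, seed=4)
        b = cs.generate_motif_library(5, seed=4)
        assert all(np.array_equal(x.matrix, y.matrix) for x, y in zip(a, b))

    def test_ic_spans_more_than_one_bit(self, motif_library):
        ics = np.concatenate([p.column_ics for p in motif_library])
        assert ics.max() - ics.min() >= 1.0

    def test_degenerate_length_range_errors(self):
        with pytest.raises(ValueError):
            cs.generate_motif_library(3, length_range=(3, 5), seed=0)
        with pytest.raises(ValueError):
            cs.generate_motif_library(3, length_range=(10, 6), seed=0)
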