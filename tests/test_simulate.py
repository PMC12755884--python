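import numpy as np
import pytest

from hybridtrace.diversity import pi_synonymous
from hybridtrace.io_core import (cells_of_species, pairwise_divergence,
                                 species_map, write_gene_alignments)
from hybridtrace.simulate import (SimConfig, apply_sweep, inject_transfer,
                                  sample_sags, simulate_neutral_ld,
                                  simulate_population)
from hybridtrace.classify import cluster_gene


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_species", 5),
        ("gene_length_bp", 100),
        ("within_div", 1.5),
        ("between_div", 0.02),      # below within_div
        ("completeness_mean", 0.99),  # outside range upper bound 0.95
    ])
    def test_invalid_field_named_in_error(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            cfg.validate()

    def test_hard_sweep_needs_one_founder(self):
        cfg = SimConfig(n_genes=5, sweep_spec=((0, "hard", 3),))
        with pytest.raises(ValueError, match="hard"):
            cfg.validate()


class TestSimulatePopulation:
    def test_deterministic_fasta_output(self, tmp_path):
        cfg = SimConfig(n_genes=5, n_cells_per_species=(10, 10), seed=5)
        for d in ("a", "b"):
            alns, cells, _ = simulate_population(cfg)
            write_gene_alignments(alns, tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_no_hybridization_limit(self, sim_basic):
        cfg, alns, cells, truth = sim_basic
        assert truth.transfers == [] and truth.blocks == []
        sp = species_map(cells)
        for aln in alns.values():
            cs = cluster_gene(aln)
            assert cs.n_clusters == 2
            for cluster in cs.clusters:
                assert len({sp[c] for c in cluster}) == 1

    def test_between_divergence_target(self, sim_basic):
        cfg, alns, cells, truth = sim_basic
        sp = species_map(cells)
        rng = np.random.default_rng(0)
        divs = []
        for aln in alns.values():
            idx = aln.row_index()
            a = [c for c in aln.cell_ids if sp[c] == "alpha"]
            b = [c for c in aln.cell_ids if sp[c] == "beta"]
            for _ in range(10):
                divs.append(pairwise_divergence(
                    aln.matrix[idx[a[rng.integers(len(a))]]],
                    aln.matrix[idx[b[rng.integers(len(b))]]]))
        assert 0.13 <= np.mean(divs) <= 0.17

    def test_within_diversity_target(self, sim_basic):
        cfg, alns, cells, truth = sim_basic
        alpha = cells_of_species(cells, "alpha")
        pis = [pi_synonymous(a.subset(alpha)) for a in alns.values()]
        assert np.nanmean(pis) == pytest.approx(cfg.within_div, rel=0.35)

    def test_truth_segments_tile_every_gene(self, sim_transfers):
        cfg, alns, cells, truth = sim_transfers
        L = cfg.gene_length_bp
        for (cell, gene), segs in truth.segments.items():
            assert segs[0][0] == 0 and segs[-1][1] == L
            for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
                assert e1 == s2 and s1 < e1

    def test_truth_json_roundtrip(self, tmp_path, sim_transfers):
        from hybridtrace.simulate import TruthTable
        cfg, alns, cells, truth = sim_transfers
        truth.to_json(tmp_path / "t.json")
        back = TruthTable.from_json(tmp_path / "t.json")
        assert back.segments == truth.segments
        assert [t.gene_id for t in back.transfers] == \
            [t.gene_id for t in truth.transfers]


class TestSagSampling:
    def _full(self):
        cfg = SimConfig(n_genes=50, n_cells_per_species=(5, 5),
                        completeness_mean=1.0, completeness_range=(1, 1),
                        seed=1)
        return simulate_population(cfg)

    def test_completeness_one_keeps_everything(self):
        alns, cells, _ = self._full()
        comp = {c.cell_id: 1.0 for c in cells}
        obs = sample_sags(alns, comp, seed=0)
        assert all(o.n_seqs == len(cells) for o in obs.values())

    def test_completeness_zero_removes_cell(self):
        alns, cells, _ = self._full()
        comp = {c.cell_id: 1.0 for c in cells}
        comp[cells[0].cell_id] = 0.0
        obs = sample_sags(alns, comp, seed=0)
        assert all(cells[0].cell_id not in o.cell_ids for o in obs.values())

    def test_binomial_occupancy(self):
        # 1000 genes at completeness 0.3: count within central binomial range
        cfg = SimConfig(n_genes=1000, gene_length_bp=3,
                        n_cells_per_species=(2, 2), completeness_mean=1.0,
                        completeness_range=(1, 1), seed=2)
        alns, cells, _ = simulate_population(cfg)
        comp = {c.cell_id: 0.3 for c in cells}
        obs = sample_sags(alns, comp, seed=3)
        for cell in comp:
            n = sum(cell in o.cell_ids for o in obs.values())
            assert 260 <= n <= 340


class TestPlantedEvents:
    @pytest.fixture
    def sim_basic(self):
        # fresh copy per test: planted events mutate alignments in place
        cfg = SimConfig(n_species=2, n_genes=8, gene_length_bp=300,
                        n_cells_per_species=(15, 15),
                        completeness_mean=1.0, completeness_range=(1, 1),
                        seed=404)
        return cfg, *simulate_population(cfg)

    def test_whole_gene_transfer_clusters_with_donor(self, sim_basic):
        cfg, alns, cells, _ = sim_basic
        sp = species_map(cells)
        rng = np.random.default_rng(0)
        aln = alns["0000"].subset(alns["0000"].cell_ids)  # copy
        recipient = cells_of_species(cells, "alpha")[0]
        inject_transfer(aln, "beta", [recipient], (0, aln.length), sp, rng)
        cs = cluster_gene(aln)
        for cluster in cs.clusters:
            if recipient in cluster:
                assert any(sp[c] == "beta" for c in cluster)

    def test_zero_length_interval_is_identity(self, sim_basic):
        cfg, alns, cells, _ = sim_basic
        sp = species_map(cells)
        aln = alns["0001"]
        before = aln.matrix.copy()
        inject_transfer(aln, "beta", [aln.cell_ids[0]], (10, 10), sp,
                        np.random.default_rng(0))
        assert (aln.matrix == before).all()

    def test_empty_recipients_warns(self, sim_basic):
        cfg, alns, cells, _ = sim_basic
        sp = species_map(cells)
        with pytest.warns(UserWarning):
            inject_transfer(alns["0002"], "beta", [], (0, 10), sp,
                            np.random.default_rng(0))

    def test_hard_sweep_zero_diversity(self, sim_basic):
        cfg, alns, cells, _ = sim_basic
        sp = species_map(cells)
        aln = alns["0003"].subset(alns["0003"].cell_ids)
        apply_sweep(aln, "beta", "alpha", "hard", 1, sp,
                    np.random.default_rng(0))
        alpha = cells_of_species(cells, "alpha")
        assert pi_synonymous(aln.subset(alpha)) == 0.0

    def test_soft_sweep_donor_like_diversity(self, sim_basic):
        cfg, alns, cells, _ = sim_basic
        sp = species_map(cells)
        aln = alns["0004"].subset(alns["0004"].cell_ids)
        beta = cells_of_species(cells, "beta")
        donor_pi = pi_synonymous(aln.subset(beta))
        apply_sweep(aln, "beta", "alpha", "soft", 5, sp,
                    np.random.default_rng(1))
        pi = pi_synonymous(aln.subset(cells_of_species(cells, "alpha")))
        assert donor_pi / 2 <= pi <= donor_pi * 2

    def test_sweep_does_not_touch_neighbors(self, sim_basic):
        cfg, alns, cells, _ = sim_basic
        sp = species_map(cells)
        neighbor = alns["0006"].matrix.copy()
        apply_sweep(alns["0005"], "beta", "alpha", "hard", 1, sp,
                    np.random.default_rng(0))
        assert (alns["0006"].matrix == neighbor).all()

    def test_too_many_founders_rejected(self, sim_basic):
        cfg, alns, cells, _ = sim_basic
        sp = species_map(cells)
        with pytest.raises(ValueError, match="n_founders"):
            apply_sweep(alns["0007"], "beta", "alpha", "soft", 100, sp,
                        np.random.default_rng(0))


class TestNeutralLD:
    def test_two_samples_perfect_linkage(self):
        assert simulate_neutral_ld(200, 2, theta=2.0, seed=0) == \
            pytest.approx(1.0)

    def test_cross_locus_baseline_far_below_anchor(self):
        within = simulate_neutral_ld(800, 30, theta=3.0, seed=1)
        between = simulate_neutral_ld(800, 30, theta=3.0, seed=1,
                                      cross_locus=True)
        assert between < 0.2 * within

    def test_zero_pairs_is_error(self):
        with pytest.raises(ValueError, match="n_loci"):
            simulate_neutral_ld(2, 5, theta=1e-6, seed=0)

    def test_matches_msprime_oracle(self):
        """Independent check of the coalescent engine against msprime."""
        msprime = pytest.importorskip("msprime")
        num = den = 0.0
        for i, ts in enumerate(msprime.sim_ancestry(
                samples=15, ploidy=2, sequence_length=1,
                num_replicates=800, random_seed=9)):
            mts = msprime.sim_mutations(
                ts, rate=1.5, random_seed=i + 1,
                model=msprime.BinaryMutationModel(), discrete_genome=False)
            G = mts.genotype_matrix()
            if G.shape[0] < 2:
                continue
            M = (G.T > 0)
            f = M.mean(axis=0)
            fab = (M.astype(float).T @ M) / M.shape[0]
            D = fab - np.outer(f, f)
            iu = np.triu_indices(f.size, k=1)
            num += (D[iu] ** 2).sum()
            pq = f * (1 - f)
            den += np.outer(pq, pq)[iu].sum()
        oracle = num / den
        ours = simulate_neutral_ld(2000, 30, theta=3.0, seed=3)
        assert ours == pytest.approx(oracle, abs=0.05)
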