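import numpy as np
import pytest

from phylorates import (SimulationConfig, brownian_sample, root_to_tip_omega,
                        scan_fixed_changes, simulate_alignment,
                        simulate_dataset, simulate_gene_rates,
                        simulate_lrt_records, simulate_phenotypes,
                        simulate_tree, vcv_matrix, write_dataset)
from phylorates.errors import SimulationError


class TestSimulateTree:
    def test_contract(self):
        tree = simulate_tree(20, seed=1)
        assert len(tree.tips) == 20
        assert tree.is_ultrametric()
        assert tree.height == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self):
        assert simulate_tree(20, seed=4).to_newick() == \
            simulate_tree(20, seed=4).to_newick()

    def test_minimum_size(self):
        assert len(simulate_tree(3, seed=0).tips) == 3
        with pytest.raises(SimulationError):
            simulate_tree(2, seed=0)

    def test_branch_lengths_positive(self):
        tree = simulate_tree(30, seed=9)
        assert all(v > 0 for v in tree.branch_length.values())


class TestBrownianSample:
    def test_degenerate_variance(self, yule20, rng):
        C = vcv_matrix(yule20)
        vals = brownian_sample(C, 3.5, 0.0, rng)
        np.testing.assert_array_equal(vals, 3.5)

    def test_monte_carlo_covariance(self):
        tree = simulate_tree(4, seed=2)
        C = vcv_matrix(tree)
        rng = np.random.default_rng(10)
        draws = np.array([brownian_sample(C, 0.0, 2.0, rng) for _ in range(5000)])
        emp = np.cov(draws.T)
        np.testing.assert_allclose(emp, 2.0 * C.matrix,
                                   atol=0.05 * 2.0 * C.matrix.max() + 0.02)

    def test_seed_reproducibility(self, yule20):
        C = vcv_matrix(yule20)
        a = brownian_sample(C, 0.0, 1.0, np.random.default_rng(3))
        b = brownian_sample(C, 0.0, 1.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestSimulatePhenotypes:
    def test_zero_slope_zero_noise_constant_length(self, yule20, rng):
        cfg = SimulationConfig(length_allometry_slope=0.0, length_bm_sigma2=0.0)
        phen = simulate_phenotypes(yule20, cfg, rng)
        np.testing.assert_allclose(phen["head_body_length_cm"],
                                   10.0 ** cfg.length_allometry_intercept)

    def test_values_strictly_positive(self, yule20, rng):
        phen = simulate_phenotypes(yule20, SimulationConfig(), rng)
        assert (phen["body_mass_g"] > 0).all()
        assert (phen["head_body_length_cm"] > 0).all()

    def test_length_tracks_mass_when_noise_small(self, yule20):
        cfg = SimulationConfig(length_bm_sigma2=0.001)
        rng = np.random.default_rng(8)
        cors = []
        for _ in range(50):
            phen = simulate_phenotypes(yule20, cfg, rng)
            cors.append(np.corrcoef(np.log10(phen["head_body_length_cm"]),
                                    np.log10(phen["body_mass_g"]))[0, 1])
        assert np.mean(cors) > 0.8


class TestSimulateGeneRates:
    def test_achieved_truth_matches_pipeline(self, tiny_dataset):
        """Internal consistency oracle: the stored truth equals what
        root_to_tip_omega recomputes from the emitted table."""
        ds = tiny_dataset
        rtt = root_to_tip_omega(ds.tree, ds.rates,
                                threshold=ds.config.rate_threshold)
        merged = rtt.merge(ds.truth_rtt, on=["gene", "species"],
                           suffixes=("", "_truth"))
        both = merged.dropna(subset=["omega_bar", "omega_bar_truth"])
        assert len(both) > 0
        np.testing.assert_allclose(both["omega_bar"], both["omega_bar_truth"],
                                   atol=1e-8)
        nan_match = merged["omega_bar"].isna() == merged["omega_bar_truth"].isna()
        assert nan_match.all()

    def test_zero_subthreshold_fraction_all_valid(self, yule20, rng):
        cfg = SimulationConfig(subthreshold_fraction=0.0)
        phen = simulate_phenotypes(yule20, cfg, rng)
        rows, truth = simulate_gene_rates(yule20, phen, "g", 0.4, 0.9, 0.3,
                                          cfg, rng)
        assert (rows["dS"] >= cfg.rate_threshold).all()
        # dN = ω·dS can still dip under the threshold only if ω is tiny
        assert (truth["n_valid_branches"] > 0).all()

    def test_branch_omegas_positive_and_clipped(self, yule20, rng):
        cfg = SimulationConfig()
        phen = simulate_phenotypes(yule20, cfg, rng)
        rows, _ = simulate_gene_rates(yule20, phen, "g", 0.4, 0.9, 0.3, cfg, rng)
        assert (rows["omega"] >= 1e-4).all() and (rows["omega"] <= 10).all()


class TestSimulateAlignment:
    def test_planted_site_recovered(self, rng):
        species = [f"s{i}" for i in range(8)]
        focal = species[:3]
        aln, reg = simulate_alignment(species, 100, focal, [(40, "L", "S")],
                                      [10, 60], rng)
        sites = scan_fixed_changes(aln, focal, species[3:])
        cols = {s.column for s in sites}
        assert 40 in cols
        assert reg.loc[0, "column"] == 40

    def test_plant_gap_overlap_rejected(self, rng):
        with pytest.raises(SimulationError, match="gap"):
            simulate_alignment(["a", "b", "c", "d"], 50, ["a", "b"],
                               [(5, "L", "S")], [5], rng)

    def test_zero_planted_rarely_yields_hits(self):
        """Chance fixed-looking columns exist but are rare: at most 5% of
        random instances produce any hit."""
        rng = np.random.default_rng(17)
        species = [f"s{i}" for i in range(8)]
        focal, background = species[:3], species[3:]
        with_hits = 0
        for _ in range(100):
            aln, _ = simulate_alignment(species, 200, focal, [], [], rng)
            if scan_fixed_changes(aln, focal, background):
                with_hits += 1
        assert with_hits <= 5

    def test_gap_columns_land_outside_focal(self, rng):
        species = [f"s{i}" for i in range(6)]
        focal = species[:2]
        aln, _ = simulate_alignment(species, 30, focal, [], list(range(1, 11)),
                                    rng)
        for sp in focal:
            assert "-" not in aln.rows[sp]


class TestSimulateLrtRecords:
    def test_alt_power(self):
        recs = simulate_lrt_records(0, 400, 10.0, np.random.default_rng(4))
        from phylorates import classify_regs
        out = classify_regs(recs)
        assert out["is_reg"].mean() > 0.8

    def test_empty(self):
        recs = simulate_lrt_records(0, 0, 1.0, np.random.default_rng(0))
        assert len(recs) == 0

    def test_negative_noncentrality_rejected(self):
        with pytest.raises(SimulationError):
            simulate_lrt_records(1, 1, -1.0, np.random.default_rng(0))


class TestSimulateDataset:
    def test_byte_reproducible_outputs(self, tmp_path):
        import hashlib
        cfg = SimulationConfig(seed=6, n_species=8, n_effect_genes=2,
                               n_null_genes=2, n_alignments=1,
                               n_null_records=5, n_alt_records=2)
        hashes = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            write_dataset(simulate_dataset(cfg), out)
            digest = {}
            for p in sorted(out.rglob("*")):
                if p.is_file():
                    digest[p.relative_to(out)] = hashlib.sha256(
                        p.read_bytes()).hexdigest()
            hashes.append(digest)
        assert hashes[0] == hashes[1]

    def test_validators_accept_generated_data(self, tiny_dataset):
        ds = tiny_dataset
        ds.rates.check_branches(ds.tree)       # branch resolvability
        assert ds.tree.is_ultrametric()
        for aln in ds.alignments:
            assert aln.length == ds.config.alignment_length
        assert set(ds.phenotypes["species"]) == set(ds.tree.tips)

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            simulate_dataset(SimulationConfig(n_species=2))
        with pytest.raises(SimulationError):
            simulate_dataset(SimulationConfig(subthreshold_fraction=1.5))
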