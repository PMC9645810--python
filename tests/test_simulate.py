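import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evoexpr.quantify import call_degs, compute_tpm
from evoexpr.ribo import CODONS, STOP_CODONS, assign_asite
from evoexpr.simulate import (
    FootprintSimConfig,
    SimConfig,
    default_spikein_design,
    simulate_cds_sequences,
    simulate_cell_geometry,
    simulate_codon_fc_table,
    simulate_counts,
    simulate_fold_change_table,
    simulate_footprints,
    simulate_pathway_map,
    simulate_spikein_counts,
)

SMALL = dict(n_genes=200, n_lines=3, deg_per_line=20, nb_mean=100.0)


class TestFoldChangeGenerator:
    def test_seeded_determinism(self):
        cfg = SimConfig(**SMALL, seed=7)
        a, ta = simulate_fold_change_table(cfg)
        b, tb = simulate_fold_change_table(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_fully_shared_concordant_degs(self):
        cfg = SimConfig(**SMALL, shared_fraction=1.0, direction_concordance=1.0, seed=3)
        fc, truth = simulate_fold_change_table(cfg)
        deg = call_degs(fc)
        up_sets = [deg.up_genes[line] for line in deg.lines]
        down_sets = [deg.down_genes[line] for line in deg.lines]
        # true DEGs identical across lines with identical sign; only
        # sporadic false positives (uniform q-values) may differ
        true_up = set(truth[truth["direction"] == 1]["gene_id"])
        true_down = set(truth[truth["direction"] == -1]["gene_id"])
        for s in up_sets:
            assert true_up <= s
        for s in down_sets:
            assert true_down <= s

    def test_unshared_overlap_matches_hypergeometric(self):
        # two lines drawing DEGs independently: overlap ~ Hypergeometric
        n_genes, k = 400, 25
        overlaps = []
        for seed in range(100):
            cfg = SimConfig(n_genes=n_genes, n_lines=2, deg_per_line=k, shared_fraction=0.0, seed=seed)
            _, truth = simulate_fold_change_table(cfg)
            per_line = truth[truth["is_deg"]].groupby("line")["gene_id"].apply(set)
            overlaps.append(len(per_line.iloc[0] & per_line.iloc[1]))
        mean_expected = k * k / n_genes
        var = (
            k * (k / n_genes) * (1 - k / n_genes) * (n_genes - k) / (n_genes - 1)
        )
        se = np.sqrt(var / len(overlaps))
        assert abs(np.mean(overlaps) - mean_expected) < 3 * se

    def test_deletions_have_no_fold_change(self):
        cfg = SimConfig(**SMALL, deletion_per_line=5, seed=1)
        fc, truth = simulate_fold_change_table(cfg)
        deleted = fc[fc["status"] == "deleted"]
        assert len(deleted) == 5 * cfg.n_lines
        assert deleted["log2_fc"].isna().all() and deleted["q_value"].isna().all()

    def test_overfull_configuration_rejected(self):
        with pytest.raises(ValueError, match="exceeds n_genes"):
            SimConfig(n_genes=20, deg_per_line=15, deletion_per_line=10)


class TestCountGenerator:
    def test_seeded_determinism_and_zero_deleted(self):
        cfg = SimConfig(**SMALL, deletion_per_line=4, seed=5)
        fc, _ = simulate_fold_change_table(cfg)
        rna1, ribo1 = simulate_counts(cfg, fc)
        rna2, _ = simulate_counts(cfg, fc)
        pd.testing.assert_frame_equal(rna1.counts, rna2.counts)
        for line in cfg.line_ids:
            deleted = fc[(fc["line"] == line) & (fc["status"] == "deleted")]["gene_id"]
            samples = [s for s in rna1.sample_ids if s.startswith(line)]
            assert (rna1.counts.loc[deleted, samples] == 0).all().all()
            assert (ribo1.counts.loc[deleted, samples] == 0).all().all()

    def test_fold_change_scales_the_mean(self):
        # one gene with log2FC = 1: evolved mean ~ 2x ancestral mean
        cfg = SimConfig(n_genes=50, n_lines=1, n_replicates=200, n_ancestor_samples=200,
                        deg_per_line=0, nb_mean=200.0, seed=2)
        fc, _ = simulate_fold_change_table(cfg)
        gene = "g00000"
        fc.loc[fc["gene_id"] == gene, ["log2_fc", "q_value"]] = [1.0, 0.001]
        rna, _ = simulate_counts(cfg, fc)
        anc = [s for s in rna.sample_ids if s.startswith("anc")]
        evo = [s for s in rna.sample_ids if s.startswith("L01")]
        evo_counts = rna.counts.loc[gene, evo].to_numpy(dtype=float)
        anc_counts = rna.counts.loc[gene, anc].to_numpy(dtype=float)
        diff = evo_counts.mean() - 2 * anc_counts.mean()
        se = np.sqrt(evo_counts.var(ddof=1) / len(evo_counts) + 4 * anc_counts.var(ddof=1) / len(anc_counts))
        assert abs(diff) < 3 * se

    def test_small_dispersion_approaches_poisson(self):
        cfg = SimConfig(n_genes=5, n_lines=1, n_replicates=500, deg_per_line=0,
                        nb_mean=100.0, nb_dispersion=1e-6, seed=4)
        fc, _ = simulate_fold_change_table(cfg)
        rna, _ = simulate_counts(cfg, fc)
        evo = [s for s in rna.sample_ids if s.startswith("L01")]
        vals = rna.counts.loc["g00002", evo].to_numpy(dtype=float)
        # Poisson limit: variance ~ mean (index of dispersion ~ 1)
        assert vals.var(ddof=1) / vals.mean() == pytest.approx(1.0, rel=0.3)

    def test_tpm_computable_from_output(self):
        cfg = SimConfig(**SMALL, seed=6)
        fc, _ = simulate_fold_change_table(cfg)
        rna, _ = simulate_counts(cfg, fc)
        tpm = compute_tpm(rna)
        assert np.allclose(tpm.tpm.sum(axis=0), 1e6, rtol=1e-6)


class TestSpikeinGenerator:
    def test_noise_free_power_law(self):
        design = pd.DataFrame({"spikein_id": ["e1"], "sample_id": ["s1"], "molecules": [1e6]})
        obs = simulate_spikein_counts(design, slope=1.0, intercept=-3.0, noise_sd=0.0)
        assert obs.loc["e1", "s1"] == pytest.approx(1e3)

    def test_non_positive_molecules_rejected(self):
        design = pd.DataFrame({"spikein_id": ["e1"], "sample_id": ["s1"], "molecules": [0.0]})
        with pytest.raises(ValueError, match="positive"):
            simulate_spikein_counts(design)

    def test_determinism(self):
        design = default_spikein_design(["s1", "s2"], seed=1)
        a = simulate_spikein_counts(design, noise_sd=0.2, seed=9)
        b = simulate_spikein_counts(design, noise_sd=0.2, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestFootprintGenerator:
    def test_determinism(self):
        seqs = simulate_cds_sequences(5, (60, 90), seed=0)
        cfg = FootprintSimConfig(sequences=seqs, reads_per_gene=200, seed=3)
        pd.testing.assert_frame_equal(simulate_footprints(cfg), simulate_footprints(cfg))

    def test_uniform_dwell_recovers_uniform_profile(self):
        seqs = {"g1": simulate_cds_sequences(1, (100, 100), seed=1)["g00000"]}
        cfg = FootprintSimConfig(sequences=seqs, frame0_fraction=1.0, reads_per_gene=100_000, seed=2)
        reads = simulate_footprints(cfg)
        res = assign_asite(reads, {"g1": len(seqs["g1"])})
        counts = res["counts"]["g1"]
        chi2_p = stats.chisquare(counts).pvalue
        assert chi2_p > 0.01

    def test_hot_codon_enrichment_recovered(self):
        seqs = simulate_cds_sequences(20, (120, 240), seed=4)
        weights = pd.Series(1.0, index=pd.Index(CODONS))
        weights["GGG"] = 10.0
        cfg = FootprintSimConfig(sequences=seqs, dwell_weights=weights, reads_per_gene=5000, seed=4)
        reads = simulate_footprints(cfg)
        res = assign_asite(reads, {g: len(s) for g, s in seqs.items()})
        per_codon_count = pd.Series(0.0, index=pd.Index(CODONS))
        per_codon_occ = pd.Series(0.0, index=pd.Index(CODONS))
        for g, vec in res["counts"].items():
            codons = np.array([seqs[g][3 * i : 3 * i + 3] for i in range(len(vec))])
            for c in np.unique(codons):
                per_codon_count[c] += vec[codons == c].sum()
                per_codon_occ[c] += (codons == c).sum()
        rate = (per_codon_count / per_codon_occ).dropna()
        ratio = rate["GGG"] / rate.drop("GGG").median()
        assert ratio == pytest.approx(10.0, rel=0.2)

    def test_read_lengths_within_range(self):
        seqs = simulate_cds_sequences(3, (60, 90), seed=5)
        cfg = FootprintSimConfig(sequences=seqs, read_length_range=(26, 32), reads_per_gene=500, seed=5)
        reads = simulate_footprints(cfg)
        assert reads["read_length"].between(1, 32).all()

    def test_bad_geometry_rejected(self):
        seqs = {"g1": "ATGAAATAA"}
        with pytest.raises(ValueError, match="offset_nt"):
            FootprintSimConfig(sequences=seqs, offset_nt=10, padding_nt=25)
        with pytest.raises(ValueError, match="divisible"):
            FootprintSimConfig(sequences={"g1": "ATGA"})


class TestCodonFcGenerator:
    def test_noise_free_values_exact(self):
        table = simulate_codon_fc_table(0.0, -0.3, 0.0, 0.0, 0.0, n_lines=3, seed=0)
        stop = table["codon"].isin(STOP_CODONS)
        assert (table.loc[~stop, "log2_fc"] == 0.0).all()
        assert (table.loc[stop, "log2_fc"] == -0.3).all()

    def test_shape_and_determinism(self):
        a = simulate_codon_fc_table(n_lines=4, seed=8)
        b = simulate_codon_fc_table(n_lines=4, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 4 * 64
        assert a.groupby("line")["codon"].nunique().eq(64).all()

    def test_single_line_rejected(self):
        with pytest.raises(ValueError, match="2 lines"):
            simulate_codon_fc_table(n_lines=1)


class TestPathwayMapGenerator:
    def test_singleton_map(self):
        pmap = simulate_pathway_map(1, (1, 1), (1, 1), ["gA"], seed=0)
        assert len(pmap.pathways) == 1
        (rxns,) = pmap.pathways.values()
        assert pmap.reactions[rxns[0]] == frozenset({"gA"})

    def test_requested_count_and_invariants(self):
        pmap = simulate_pathway_map(5, (1, 4), (1, 3), [f"g{i}" for i in range(50)], seed=2)
        assert len(pmap.pathways) == 5
        for rxns in pmap.pathways.values():
            assert len(rxns) >= 1
        for enzymes in pmap.reactions.values():
            assert len(enzymes) >= 1

    def test_determinism_and_validation(self):
        args = (4, (1, 3), (1, 2), [f"g{i}" for i in range(20)])
        assert simulate_pathway_map(*args, seed=3).to_dict() == simulate_pathway_map(*args, seed=3).to_dict()
        with pytest.raises(ValueError, match="non-empty"):
            simulate_pathway_map(2, (1, 2), (1, 2), [])
        with pytest.raises(ValueError, match="ranges"):
            simulate_pathway_map(2, (2, 1), (1, 2), ["gA"])


class TestCellGeometryGenerator:
    def test_lengths_never_below_widths(self):
        geo = simulate_cell_geometry(["L1", "L2"], n_cells=200, seed=1)
        assert (geo["length_um"] >= geo["width_um"]).all()

    def test_line_means_respected(self):
        geo = simulate_cell_geometry(["L1", "L2"], mean_lengths={"L1": 2.0, "L2": 4.0}, n_cells=500, seed=2)
        means = geo.groupby("line")["length_um"].mean()
        assert means["L2"] > means["L1"] * 1.5
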