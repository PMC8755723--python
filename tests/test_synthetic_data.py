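"""Generators: determinism, injected ground truth, and self-consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from deepseep import growth, synthetic_data as syn
from deepseep.codons import FAMILIES, OPTIMIZED_CODON


class TestGenerateGenome:
    def test_same_seed_byte_identical(self):
        a = syn.generate_genome(seed=42, bias_strength=0.3, true_ptr=1.4)
        b = syn.generate_genome(seed=42, bias_strength=0.3, true_ptr=1.4)
        assert a.sequence == b.sequence
        assert [(g.gene_id, g.start, g.end, g.strand, g.is_ribosomal)
                for g in a.genes] == \
               [(g.gene_id, g.start, g.end, g.strand, g.is_ribosomal)
                for g in b.genes]

    def test_zero_bias_tables_identical(self):
        g = syn.generate_genome(seed=7, bias_strength=0.0)
        for aa in FAMILIES:
            np.testing.assert_allclose(g.ribosomal_usage[aa], g.background_usage[aa])

    def test_full_bias_ribosomal_usage_is_optimized(self):
        """At bias 1 ribosomal genes can only draw the preferred codons."""
        g = syn.generate_genome(seed=7, n_genes=40, ribosomal_count=35,
                                bias_strength=1.0)
        prof = growth.codon_usage(g.gene_sequences(ribosomal=True))
        assert prof.codon_count >= 10_000
        for codon, count in prof.counts.items():
            if count:
                aa = [a for a, cods in FAMILIES.items() if codon in cods][0]
                assert codon == OPTIMIZED_CODON[aa]

    def test_half_bias_usage_matches_mixture_table(self):
        """Chi-square GOF of empirical ribosomal usage against the generator's
        own interpolated target table (>= 10,000 codons)."""
        g = syn.generate_genome(seed=7, n_genes=40, ribosomal_count=35,
                                bias_strength=0.5)
        prof = growth.codon_usage(g.gene_sequences(ribosomal=True))
        assert prof.codon_count >= 10_000
        chi2 = 0.0
        df = 0
        for aa, codons in FAMILIES.items():
            obs = np.array([prof.counts.get(c, 0) for c in codons], dtype=float)
            if obs.sum() == 0:
                continue
            exp = g.ribosomal_usage[aa] * obs.sum()
            keep = exp >= 1.0
            chi2 += ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            df += keep.sum() - 1
        assert sps.chi2.sf(chi2, df) > 0.01

    def test_gene_intervals_within_genome(self):
        g = syn.generate_genome(seed=3)
        assert all(0 <= gene.start < gene.end <= g.length for gene in g.genes)
        assert g.ter_position == g.length // 2

    @pytest.mark.parametrize("kwargs,field", [
        ({"length": 10_000}, "length"),
        ({"gc": 1.5}, "gc"),
        ({"bias_strength": 1.2}, "bias_strength"),
        ({"true_ptr": 0.8}, "true_ptr"),
        ({"n_genes": 2, "ribosomal_count": 5}, "n_genes"),
        ({"true_ptr": float("nan")}, "true_ptr"),
    ])
    def test_validation_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            syn.generate_genome(seed=1, **kwargs)


class TestSimulateCoverage:
    def test_flat_when_not_replicating(self):
        prof = syn.simulate_coverage(60_000, mean_depth=25.0, true_ptr=1.0, noise="none")
        np.testing.assert_allclose(prof.depth, 25.0)

    def test_ori_ter_ratio_exact(self):
        prof = syn.simulate_coverage(100_000, mean_depth=50.0, true_ptr=2.0, noise="none")
        assert prof.depth[0] / prof.depth[50_000] == pytest.approx(2.0, abs=1e-9)

    def test_mean_conserved(self):
        prof = syn.simulate_coverage(100_000, mean_depth=50.0, true_ptr=2.3, noise="none")
        assert prof.mean() == pytest.approx(50.0, rel=1e-3)

    def test_poisson_dispersion(self):
        prof = syn.simulate_coverage(100_000, mean_depth=50.0, true_ptr=1.0,
                                     seed=5, noise="poisson")
        assert 0.8 < prof.depth.var() / prof.depth.mean() < 1.2

    def test_seeded_reproducible(self):
        a = syn.simulate_coverage(60_000, 30.0, 1.5, seed=9)
        b = syn.simulate_coverage(60_000, 30.0, 1.5, seed=9)
        np.testing.assert_array_equal(a.depth, b.depth)

    def test_sub_unity_ptr_rejected(self):
        with pytest.raises(ValueError, match="true_ptr"):
            syn.simulate_coverage(60_000, 30.0, 0.9)


class TestSitePanel:
    def test_zero_slope_zero_noise_equal_ptr(self):
        panels = syn.generate_site_panel(seed=2, irep_slope=0.0, irep_noise_sd=0.0,
                                         n_high_co2=0, n_sites=4)
        ptrs = {g.true_ptr for p in panels for g in p.genomes}
        assert ptrs == {1.5}

    def test_linear_slope_spans_expected_range(self):
        panels = syn.generate_site_panel(seed=2, irep_slope=-1e-4, irep_noise_sd=0.0,
                                         n_high_co2=0, depth_range=(0, 3000))
        truth = syn.panel_truth(panels)
        assert truth.true_ptr.max() - truth.true_ptr.min() == pytest.approx(0.3)

    def test_metadata_deterministic(self, tmp_path):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            panels = syn.generate_site_panel(seed=13, n_sites=4)
            p = tmp_path / name
            syn.panel_metadata(panels).to_csv(p, sep="\t", index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_high_co2_offset_applied(self):
        panels = syn.generate_site_panel(seed=4, irep_slope=0.0, irep_noise_sd=0.0,
                                         n_high_co2=3, high_co2_offset=0.25, n_sites=6)
        truth = syn.panel_truth(panels)
        assert set(truth.loc[truth.high_co2, "true_ptr"]) == {1.75}
        assert set(truth.loc[~truth.high_co2, "true_ptr"]) == {1.5}

    def test_enzyme_hits_reference_known_pathways(self):
        panels = syn.generate_site_panel(seed=4, n_sites=3)
        hits = pd.concat([p.enzyme_hits for p in panels])
        assert set(hits.pathway) <= set(syn.ENZYME_PATHWAYS.values())


class TestBiogeoPanel:
    def test_zero_decay_identical_genomes(self):
        panel = syn.generate_biogeo_panel(seed=6, n_genomes=4, ani_decay=0.0)
        seqs = {g.sequence for g in panel.genomes}
        assert len(seqs) == 1

    def test_two_sites_1000km_gives_95_percent(self):
        # ~1000 km apart on the equator at 0.005 %/km decay
        panel = syn.generate_biogeo_panel(
            seed=1, coordinates=[(0.0, 0.0), (0.0, 8.9831)], ani_decay=0.005)
        assert panel.true_ani.iloc[0, 1] == pytest.approx(95.0, abs=0.01)
        assert panel.expected_ani.iloc[0, 1] == pytest.approx(95.0, abs=0.05)

    def test_substitution_counts_reproduce_divergence(self):
        """Generator self-check: realized pairwise mismatch fractions match the
        expectation implied by the substitution loads within binomial error."""
        panel = syn.generate_biogeo_panel(seed=8, n_genomes=4, ani_decay=0.001)
        g = panel.genomes
        L = len(g[0].sequence)
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                a = np.frombuffer(g[i].sequence.encode(), dtype="S1")
                b = np.frombuffer(g[j].sequence.encode(), dtype="S1")
                mism = int((a != b).sum())
                div = 1.0 - panel.expected_ani.iloc[i, j] / 100.0
                tol = 5.0 * np.sqrt(max(L * div * (1 - div), 1.0)) + 2.0
                assert abs(mism - div * L) <= tol

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            syn.generate_biogeo_panel(seed=1, coordinates=[(1.0, 2.0), (1.0, 2.0)])


def test_bias_injection_monotone():
    """The empirical codon-bias statistic strictly increases with the injected
    strength on a 0 -> 1 grid at fixed seed."""
    biases = [growth.genome_bias(syn.generate_genome(seed=11, bias_strength=s))
              for s in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert all(b2 > b1 for b1, b2 in zip(biases, biases[1:]))


def test_fasta_and_coverage_writers_roundtrip(tmp_path):
    from Bio import SeqIO
    g = syn.generate_genome(seed=5, length=50_000, n_genes=20, ribosomal_count=4)
    syn.write_fasta([g], tmp_path / "g.fasta")
    rec = next(SeqIO.parse(str(tmp_path / "g.fasta"), "fasta"))
    assert str(rec.seq) == g.sequence

    prof = syn.simulate_coverage(g, mean_depth=10.0, seed=1)
    syn.write_coverage_tsv(prof, tmp_path / "cov.tsv")
    cov = pd.read_csv(tmp_path / "cov.tsv", sep="\t", header=None)
    assert len(cov) == g.length
    assert cov.iloc[0, 1] == 1  # 1-based positions
    np.testing.assert_allclose(cov[2].to_numpy(), prof.depth)
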