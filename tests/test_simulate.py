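"""Synthetic generator: sampling contracts, planted truth, coverage statistics."""

import numpy as np
import pytest

import pointcen as pc
from pointcen.iupac import IUPAC_SETS


class TestSampleCentromere:
    def test_degenerate_free_model_is_forced(self):
        model = pc.CentromereModel(
            window_length=4,
            elements=(pc.ElementSpec("only", 1, 4, "ACGT"),),
            core_start=1,
            core_end=4,
            at_only_columns=(),
            gc_rich_columns=(),
            neutral_columns=(),
        )
        sample = pc.sample_centromere(model, np.random.default_rng(0))
        assert sample.sequence == "ACGT"

    def test_elements_always_match_their_patterns(self, default_model):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = pc.sample_centromere(default_model, rng).sequence
            assert pc.iupac_match("SGGKTAA", seq[19:26])
            assert pc.iupac_match("ACGDDWWT", seq[44:52])

    def test_seed_determines_sequence(self, default_model):
        a = pc.sample_centromere(default_model, np.random.default_rng(1)).sequence
        b = pc.sample_centromere(default_model, np.random.default_rng(1)).sequence
        c = pc.sample_centromere(default_model, np.random.default_rng(2)).sequence
        assert a == b
        assert a != c  # astronomically unlikely to collide

    def test_overlapping_elements_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pc.CentromereModel(
                elements=(
                    pc.ElementSpec("a", 20, 26, "SGGKTAA"),
                    pc.ElementSpec("b", 25, 32, "ACGDDWWT"),
                ),
                at_only_columns=(),
                gc_rich_columns=(),
                neutral_columns=(),
            )


class TestAtContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATAT", 1.0), ("ACGT", 0.5), ("AATACGTTTA", 0.8)],
    )
    def test_known_values(self, seq, expected):
        assert pc.at_content(seq) == pytest.approx(expected)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            pc.at_content("")


class TestConventionalCen:
    def test_cdeii_spacers_always_exceed_at_bound(self):
        model = pc.ConventionalCenModel()
        rng = np.random.default_rng(3)
        for _ in range(1000):
            spacer = pc.sample_cdeii(model, rng)
            lo, hi = model.cdeII_length_range
            assert lo <= len(spacer) <= hi
            assert pc.at_content(spacer) > model.cdeII_min_at

    def test_configured_flanking_patterns_are_realized(self):
        model = pc.ConventionalCenModel(
            cdeI_pattern="RTCACRTG", cdeIII_pattern="TGTTT"
        )
        rng = np.random.default_rng(5)
        seq = pc.sample_conventional_centromere(model, rng)
        head = seq[:8]
        assert all(b in IUPAC_SETS[c] for c, b in zip("RTCACRTG", head))
        assert seq.endswith("TGTTT")


class TestGenerateGenome:
    def test_dimension_contract_single_chromosome(self):
        config = pc.SyntheticGenomeConfig(
            n_chromosomes=1, chrom_length=10_000, seed=0,
            secondary_sites_per_factor={}, secondary_min_cen_distance=0,
        )
        genome, genes, truth = pc.generate_genome(config)
        assert set(genome) == {"chr01"}
        assert len(genome["chr01"]) == 10_000
        assert len(genes) >= 1
        assert len(truth.centromeres) == 1

    def test_one_intergenic_centromere_per_chromosome(self, fixture_genome):
        _, genome, genes, truth = fixture_genome
        assert len(truth.centromeres) == len(genome) == 10
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for cen in truth.centromeres:
            assert genome[cen.chrom][cen.start : cen.end] == cen.sequence
            for g in by_chrom[cen.chrom]:  # strictly intergenic
                assert cen.end <= g.start or g.end <= cen.start
            for truth_el in cen.elements.values():
                s, e = truth_el.genome
                assert genome[cen.chrom][s:e] == truth_el.sequence

    def test_same_seed_reproduces_everything(self):
        config = pc.SyntheticGenomeConfig(
            n_chromosomes=2, chrom_length=50_000, seed=4,
            secondary_sites_per_factor={"Ndc80": 0, "Ndc10": 2},
            secondary_min_cen_distance=10_000,
        )
        a = pc.generate_genome(config)
        b = pc.generate_genome(config)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2].to_dict() == b[2].to_dict()

    def test_intergenic_interval_must_fit_window(self):
        config = pc.SyntheticGenomeConfig(intergenic_length=100)
        with pytest.raises(ValueError, match="window"):
            pc.generate_genome(config)

    def test_per_chromosome_streams_are_stable(self):
        small = pc.SyntheticGenomeConfig(
            n_chromosomes=2, chrom_length=50_000, seed=4,
            secondary_sites_per_factor={}, secondary_min_cen_distance=10_000,
        )
        large = pc.SyntheticGenomeConfig(
            n_chromosomes=3, chrom_length=50_000, seed=4,
            secondary_sites_per_factor={}, secondary_min_cen_distance=10_000,
        )
        ga, *_ = pc.generate_genome(small)
        gb, *_ = pc.generate_genome(large)
        assert ga["chr01"] == gb["chr01"]
        assert ga["chr02"] == gb["chr02"]


class TestSimulateCoverage:
    def test_background_mean_recovered_away_from_sites(self, fixture_genome):
        config, genome, _, truth = fixture_genome
        rng = pc.child_rng(config.seed, "chip", "Ndc80")
        chip, inp = pc.simulate_coverage(genome, truth, "Ndc80", config.chip, rng)
        params = config.chip
        bg = []
        for chrom, counts in chip.data.items():
            centers = np.arange(counts.size) * params.bin_size + params.bin_size / 2
            mask = np.ones(counts.size, dtype=bool)
            for c, pos in truth.sites_for("Ndc80"):
                if c == chrom:
                    mask &= np.abs(centers - pos) > 3 * params.peak_sd
            bg.append(counts[mask])
        bg = np.concatenate(bg)
        assert abs(bg.mean() - params.background_mean) / params.background_mean < 0.05

    def test_secondary_sites_are_elevated(self, fixture_genome):
        config, genome, _, truth = fixture_genome
        params = pc.ChipSimParams(peak_fold=10.0, secondary_rel_amplitude=0.7)
        rng = pc.child_rng(config.seed, "chip", "Ndc10")
        chip, _ = pc.simulate_coverage(genome, truth, "Ndc10", params, rng)
        for chrom, pos in truth.secondary_sites["Ndc10"]:
            b = pos // params.bin_size
            local = chip.data[chrom][max(0, b - 2) : b + 3].mean()
            assert local >= 2 * params.background_mean

    def test_no_enrichment_limit(self, fixture_genome):
        config, genome, _, truth = fixture_genome
        params = pc.ChipSimParams(peak_fold=1.0 + 1e-12)
        rng = np.random.default_rng(0)
        chip, inp = pc.simulate_coverage(genome, truth, "Ndc80", params, rng)
        c = np.concatenate(list(chip.data.values()))
        i = np.concatenate(list(inp.data.values()))
        assert abs(c.mean() / i.mean() - 1.0) < 0.02

    def test_unknown_factor_is_an_error(self, fixture_genome):
        config, genome, _, truth = fixture_genome
        with pytest.raises(KeyError, match="unknown factor"):
            pc.simulate_coverage(
                genome, truth, "Mif2", config.chip, np.random.default_rng(0)
            )


class TestRoundTrip:
    def test_fasta_gff_truth_round_trip(self, fixture_genome, tmp_path):
        from pointcen import io

        _, genome, genes, truth = fixture_genome
        io.write_fasta(genome, tmp_path / "g.fa")
        io.write_gff3(
            genes, tmp_path / "g.gff3",
            centromeres=[(c.chrom, c.start, c.end) for c in truth.centromeres],
        )
        io.write_truth(truth, tmp_path / "t.json")
        assert io.read_fasta(tmp_path / "g.fa") == genome
        assert io.read_gff3_genes(tmp_path / "g.gff3") == sorted(
            genes, key=lambda g: (g.chrom, g.start)
        )
        cens = io.read_gff3_centromeres(tmp_path / "g.gff3")
        assert cens == [(c.chrom, c.start, c.end) for c in truth.centromeres]
        assert io.read_truth(tmp_path / "t.json").to_dict() == truth.to_dict()

    def test_bedgraph_round_trip(self, tmp_path):
        from pointcen import io

        track = pc.CoverageTrack(
            50, {"chr01": np.arange(20.0), "chr02": np.ones(10)}
        )
        io.write_bedgraph(track, tmp_path / "t.bedgraph")
        back = io.read_bedgraph(tmp_path / "t.bedgraph")
        assert back.bin_size == 50
        for chrom in track.data:
            assert np.array_equal(back.data[chrom], track.data[chrom])
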