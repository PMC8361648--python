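"""Simulator behaviour: determinism, EMS spectrum, cross genetics, depths."""

import numpy as np
import pytest

from mutmapkit.simdata import (
    GenePlacementError,
    SimulationConfig,
    simulate_allele_depths,
    simulate_dataset,
    simulate_ems_mutations,
    simulate_f2_bulk,
    simulate_genome,
    write_vcf,
)
from mutmapkit.variants import read_variants


def haldane_linked_freq(distance_morgans: float) -> float:
    """Expected bulk alt frequency at a locus linked to the selected site.

    Brute-force 2-locus enumeration: F1 gamete classes (causal, marker) have
    probabilities {(1,1): (1-r)/2, (1,0): r/2, (0,1): r/2, (0,0): (1-r)/2}
    with r the Haldane recombination fraction.  Selected individuals carry
    two causal-allele gametes, so each transmits the marker alt allele with
    probability (1-r)|causal=1 = ((1-r)/2) / (1/2).
    """
    r = (1.0 - np.exp(-2.0 * distance_morgans)) / 2.0
    gametes = {(1, 1): (1 - r) / 2, (1, 0): r / 2, (0, 1): r / 2, (0, 0): (1 - r) / 2}
    p_causal = gametes[(1, 1)] + gametes[(1, 0)]
    return gametes[(1, 1)] / p_causal


class TestConfig:
    def test_rejects_invalid_probabilities_and_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(ems_spectrum=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(error_rate=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=0)
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=1000, causal_pos=2000)

    def test_config_file_round_trip(self, tmp_path, fast_config):
        path = tmp_path / "sim.cfg"
        fast_config.to_file(path)
        assert SimulationConfig.from_file(path) == fast_config


class TestGenome:
    def test_sequence_lengths_match_config(self, fast_config, shared_genome):
        sequences, _ = shared_genome
        assert set(sequences) == set(fast_config.chromosomes)
        assert all(len(s) == fast_config.chrom_length for s in sequences.values())

    def test_deterministic_given_seed(self, fast_config):
        a = simulate_genome(fast_config)
        b = simulate_genome(fast_config)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_causal_gene_spans_locus_with_multiple_exons(self, fast_config, shared_genome):
        _, models = shared_genome
        spanning = [
            m
            for m in models
            if m.chrom == fast_config.causal_chrom and m.contains(fast_config.causal_pos)
        ]
        assert len(spanning) == 1
        assert len(spanning[0].exons) >= 2

    def test_gene_models_do_not_overlap(self, shared_genome):
        _, models = shared_genome
        by_chrom: dict = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 > e1

    def test_impossible_gene_placement_raises(self):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=300, causal_pos=150)
        with pytest.raises(GenePlacementError):
            simulate_genome(cfg)


class TestEmsMutations:
    def test_pure_spectrum_gives_only_transitions(self, shared_genome):
        cfg = SimulationConfig(
            n_chromosomes=2, chrom_length=600_000, causal_pos=300_000,
            ems_rate=1e-4, ems_spectrum=1.0, seed=11,
        )
        seqs, models = shared_genome
        records, _ = simulate_ems_mutations(cfg, seqs, models)
        assert records
        assert all((r.ref, r.alt) in {("G", "A"), ("C", "T")} for r in records)

    def test_zero_rate_yields_only_forced_causal(self, fast_config, shared_genome):
        cfg = SimulationConfig(
            n_chromosomes=2, chrom_length=600_000, causal_pos=300_000,
            ems_rate=0.0, seed=11,
        )
        seqs, models = shared_genome
        records, causal = simulate_ems_mutations(cfg, seqs, models)
        assert len(records) == 1
        assert (records[0].chrom, records[0].pos) == causal
        assert (records[0].ref, records[0].alt) in {("G", "A"), ("C", "T")}

    def test_mutation_count_follows_documented_rng_path(self):
        """Regenerate the Binomial(L, rate) count draw and the position draws
        with the same generator stream (single chromosome, 5e-5 per bp)."""
        cfg = SimulationConfig(
            n_chromosomes=1, chrom_length=1_000_000, causal_pos=500_000,
            ems_rate=5e-5, seed=7,
        )
        seqs, models = simulate_genome(cfg)
        records, causal = simulate_ems_mutations(cfg, seqs, models)
        rng = cfg.stage_rng(1)  # stage 1 = mutagenesis
        n = int(rng.binomial(cfg.chrom_length, cfg.ems_rate))
        raw = set((rng.choice(cfg.chrom_length, size=n, replace=False) + 1).tolist())
        raw.discard(causal[1])
        assert len(records) == len(raw) + 1  # + the forced causal lesion

    def test_causal_mutation_is_coding_transition(self, dataset):
        cfg = dataset.config
        chrom, pos = dataset.causal
        gene = next(m for m in dataset.models if m.chrom == chrom and m.contains(pos))
        assert gene.genomic_to_cds(pos) is not None
        rec = next(r for r in dataset.records if (r.chrom, r.pos) == dataset.causal)
        assert (rec.ref, rec.alt) in {("G", "A"), ("C", "T")}


class TestF2Bulk:
    def test_all_bulk_individuals_homozygous_causal(self, dataset):
        g = dataset.cross.genotypes
        assert (g[:, dataset.cross.causal_index] == 2).all()
        assert g.shape[0] == dataset.config.bulk_size
        assert set(np.unique(g)) <= {0, 1, 2}

    def test_unlinked_locus_frequency_is_half(self, fast_config, shared_genome):
        """Mean alt frequency on the other chromosome -> 0.5 (F2 expectation,
        unaffected by selection at the causal locus)."""
        seqs, models = shared_genome
        records, causal = simulate_ems_mutations(fast_config, seqs, models)
        unlinked = [i for i, r in enumerate(records) if r.chrom != causal[0]]
        assert unlinked
        rng = np.random.default_rng(5)
        freqs = []
        for _ in range(200):
            cross = simulate_f2_bulk(fast_config, records, causal, rng=rng)
            freqs.append(cross.genotypes[:, unlinked].mean() / 2.0)
        n_obs = 200 * fast_config.bulk_size * 2 * len(unlinked)
        sigma = np.sqrt(0.25 / n_obs)  # gametes are not all independent; bound below
        # conservative 3-sigma band using per-bulk replicate variance
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) < 3 * max(se, sigma)

    def test_linked_locus_matches_two_locus_enumeration(self):
        """Mean bulk alt frequency 10 cM from the causal site equals the
        exhaustive 2-locus F2 gamete-class prediction under Haldane."""
        cfg = SimulationConfig(
            n_chromosomes=1, chrom_length=1_000_000, causal_pos=200_000,
            ems_rate=0.0, recomb_rate=1.0, seed=3,
        )
        seqs, models = simulate_genome(cfg)
        records, causal = simulate_ems_mutations(cfg, seqs, models)
        # add one marker 10 cM away (0.1 Morgan = 100 kb at 1 M/Mb... here
        # recomb_rate 1.0 over 1 Mb -> 1 Morgan per Mb -> 10 cM = 100 kb)
        from mutmapkit.variants import VariantRecord

        marker_pos = causal[1] + 100_000
        marker = VariantRecord(
            chrom="chr1", pos=marker_pos,
            ref=seqs["chr1"][marker_pos - 1],
            alt="A" if seqs["chr1"][marker_pos - 1] != "A" else "T",
            wt_call="hom_ref", mut_call="hom_alt",
        )
        records = sorted(records + [marker], key=lambda r: (r.chrom, r.pos))
        midx = [i for i, r in enumerate(records) if r.pos == marker_pos][0]
        rng = np.random.default_rng(7)
        freqs = []
        for _ in range(500):
            cross = simulate_f2_bulk(cfg, records, causal, rng=rng)
            freqs.append(cross.genotypes[:, midx].mean() / 2.0)
        expected = haldane_linked_freq(0.1)
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - expected) < 3 * se

    def test_linkage_decay_is_monotone(self):
        """Expected bulk alt frequency never increases with map distance."""
        distances = np.linspace(0.01, 1.0, 25)
        freqs = [haldane_linked_freq(d) for d in distances]
        assert all(a >= b for a, b in zip(freqs, freqs[1:]))


class TestAlleleDepths:
    def test_error_free_homozygous_site_has_no_ref_reads(self, fast_config, shared_genome):
        cfg = SimulationConfig(
            n_chromosomes=2, chrom_length=600_000, causal_pos=300_000,
            ems_rate=1e-4, error_rate=0.0, seed=11,
        )
        seqs, models = shared_genome
        muts, causal = simulate_ems_mutations(cfg, seqs, models)
        cross = simulate_f2_bulk(cfg, muts, causal, rng=np.random.default_rng(1))
        recs = simulate_allele_depths(cfg, muts, cross, rng=np.random.default_rng(2))
        causal_rec = next(r for r in recs if (r.chrom, r.pos) == causal)
        assert causal_rec.bulk_ref_depth == 0
        assert causal_rec.bulk_alt_depth > 0

    def test_zero_depth_mean_flags_all_sites(self, fast_config, dataset):
        cfg = SimulationConfig(
            n_chromosomes=2, chrom_length=600_000, causal_pos=300_000,
            ems_rate=1e-4, depth_mean=0.0, seed=11,
        )
        recs = simulate_allele_depths(cfg, dataset.records, dataset.cross)
        assert all(r.bulk_ref_depth == 0 and r.bulk_alt_depth == 0 for r in recs)

    def test_ref_read_fraction_matches_miscall_model(self):
        """At a dosage-2 site with depth 1000 and error 0.01, reference reads
        arise only from miscalls landing on the reference base (rate e/3)."""
        from mutmapkit.variants import VariantRecord

        cfg = SimulationConfig(
            n_chromosomes=1, chrom_length=10_000, causal_pos=5_000,
            ems_rate=0.0, depth_mean=1000.0, error_rate=0.01, bulk_size=15, seed=2,
        )
        rec = VariantRecord(chrom="chr1", pos=5000, ref="C", alt="T",
                            wt_call="hom_ref", mut_call="hom_alt")
        from mutmapkit.simdata import SimulatedCross

        cross = SimulatedCross(
            loci=[("chr1", 5000)],
            genotypes=np.full((15, 1), 2, dtype=np.int8),
            phenotypes=["mutant"] * 15,
            causal_index=0,
        )
        rng = np.random.default_rng(9)
        fractions = []
        for _ in range(50):
            out = simulate_allele_depths(cfg, [rec], cross, rng=rng)[0]
            total = out.bulk_ref_depth + out.bulk_alt_depth
            fractions.append(out.bulk_ref_depth / total)
        p = 0.01 / 3.0
        n = 50 * 1000
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(np.mean(fractions) - p) < 3.5 * sigma

    def test_vcf_round_trip_is_lossless(self, dataset, tmp_path):
        path = tmp_path / "sim.vcf"
        write_vcf(dataset.records, path, dataset.config.chrom_lengths)
        back = read_variants(path, "wt", "mut", "bulk")
        assert len(back) == len(dataset.records)
        for a, b in zip(dataset.records, back):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            assert (a.wt_call, a.mut_call) == (b.wt_call, b.mut_call)
            assert (a.bulk_ref_depth, a.bulk_alt_depth) == (
                b.bulk_ref_depth, b.bulk_alt_depth,
            )


def test_full_dataset_determinism(fast_config):
    a = simulate_dataset(fast_config)
    b = simulate_dataset(fast_config)
    assert a.causal == b.causal
    assert [(r.chrom, r.pos, r.ref, r.alt, r.bulk_ref_depth, r.bulk_alt_depth) for r in a.records] == [
        (r.chrom, r.pos, r.ref, r.alt, r.bulk_ref_depth, r.bulk_alt_depth) for r in b.records
    ]
    assert (a.cross.genotypes == b.cross.genotypes).all()
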