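"""Simulator determinism, composition statistics and error-model
calibration."""

import dataclasses
import math

import numpy as np
import pytest

from splitmap.genome import revcomp
from splitmap.junctions import JunctionParams, classify_junction, Junction
from splitmap.simulate import (
    SimConfig,
    _apply_errors,
    simulate_genome,
    simulate_isoforms,
    simulate_reads,
    truth_junction_catalog,
    write_fastq,
)


def cfg(**kw):
    base = dict(genome_size=100_000, n_chromosomes=2, n_isoforms=20, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        g1 = simulate_genome(cfg())
        g2 = simulate_genome(cfg())
        assert g1.sequences == g2.sequences

    def test_gc_content_near_half(self):
        g = simulate_genome(cfg(decoy_fraction=0.0))
        seq = "".join(g.sequences.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_decoy_polya_tract_present(self):
        g = simulate_genome(cfg(decoy_fraction=0.05))
        assert any("A" * 50 in s for s in g.sequences.values())

    def test_rejects_tiny_genome(self):
        with pytest.raises(ValueError):
            simulate_genome(cfg(genome_size=5_000))


class TestSimulateIsoforms:
    def test_regular_only_when_fraction_zero(self):
        g = simulate_genome(cfg())
        _, truth = simulate_isoforms(g, cfg(irregular_fraction=0.0))
        assert set(truth["class"]) == {"regular"}

    def test_flip_boundaries_are_strand_reversing(self):
        """Every junction between a flipped and an unflipped exon joins
        opposite strands (junctions between two flipped exons stay
        same-strand and are classified by geometry)."""
        config = cfg(genome_size=1_000_000, irregular_fraction=0.4,
                     flip_fraction=1.0, seed=7)
        g = simulate_genome(config)
        isoforms, _ = simulate_isoforms(g, config)
        checked = 0
        for iso in isoforms:
            internal = [j for t, j in iso.junctions][: len(iso.exons) - 1]
            for k, j in enumerate(internal):
                if iso.exons[k].irregular != iso.exons[k + 1].irregular:
                    assert j.cls == "strand-reversing"
                    checked += 1
        assert checked > 20

    def test_irregular_exon_count_within_binomial_bounds(self):
        config = cfg(genome_size=2_000_000, n_isoforms=250,
                     exons_per_isoform=(4, 4), irregular_fraction=0.2, seed=3)
        g = simulate_genome(config)
        isoforms, _ = simulate_isoforms(g, config)
        n = sum(len(i.exons) for i in isoforms)
        irregular = sum(e.irregular for i in isoforms for e in i.exons)
        p = 0.2
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(irregular - n * p) < 3 * sigma

    def test_truth_classes_consistent_with_classifier(self):
        config = cfg(genome_size=1_000_000, irregular_fraction=0.3, seed=5)
        g = simulate_genome(config)
        _, truth = simulate_isoforms(g, config)
        params = JunctionParams()
        for row in truth.itertuples(index=False):
            j = Junction(
                donor=(row.donor_chrom, row.donor_pos, row.donor_strand),
                acceptor=(row.acceptor_chrom, row.acceptor_pos, row.acceptor_strand),
            )
            assert classify_junction(j, params) == getattr(row, "_8")

    def test_circular_flag_adds_wrap_junction(self):
        config = cfg(circular=True, exons_per_isoform=(2, 3),
                     irregular_fraction=0.0)
        g = simulate_genome(config)
        isoforms, truth = simulate_isoforms(g, config)
        for iso in isoforms:
            assert iso.junctions[-1][0] == len(iso.sequence)
        assert (truth["class"] == "circular").sum() == len(isoforms)


class TestSimulateReads:
    def test_zero_error_reads_are_exact_substrings(self):
        config = cfg(substitution_rate=0.0, insertion_rate=0.0,
                     deletion_rate=0.0, antisense_fraction=0.0,
                     coverage=2, read_length=100)
        g = simulate_genome(config)
        isoforms, _ = simulate_isoforms(g, config)
        reads, _ = simulate_reads(isoforms, config)
        by_name = {i.name: i for i in isoforms}
        assert reads
        for r in reads:
            iso = by_name[r.name.rsplit("_", 1)[0]]
            assert r.sequence in iso.sequence

    def test_coverage_arithmetic(self):
        config = cfg(substitution_rate=0.0, insertion_rate=0.0,
                     deletion_rate=0.0, coverage=10, read_length=100,
                     exons_per_isoform=(4, 4), exon_length=(250, 250),
                     n_isoforms=3)
        g = simulate_genome(config)
        isoforms, _ = simulate_isoforms(g, config)
        reads, _ = simulate_reads(isoforms, config)
        assert len(reads) == 3 * math.ceil(10 * 1000 / 100)

    def test_substitution_rate_calibrated_within_3_sigma(self):
        """Observed mismatch fraction over 1e6 simulated bases."""
        rng = np.random.default_rng(99)
        config = cfg(error_model="illumina", substitution_rate=0.01,
                     insertion_rate=0.0, deletion_rate=0.0)
        n = 1_000_000
        template = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, n)
        )
        noisy = _apply_errors(template, np.random.default_rng(7), config)
        assert len(noisy) == n
        mismatches = sum(a != b for a, b in zip(template, noisy))
        p = 0.01
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(mismatches - n * p) < 3 * sigma

    def test_454_model_is_indel_dominated(self):
        rng = np.random.default_rng(4)
        config = cfg(error_model="454")
        template = "".join("ACGT"[i] for i in rng.integers(0, 4, 200_000))
        noisy = _apply_errors(template, np.random.default_rng(8), config)
        assert len(noisy) != len(template)  # indels occurred

    def test_byte_identical_fastq_under_fixed_seed(self, tmp_path):
        config = cfg(coverage=3)
        outputs = []
        for run in range(2):
            g = simulate_genome(config)
            isoforms, _ = simulate_isoforms(g, config)
            reads, truth = simulate_reads(isoforms, config)
            path = tmp_path / f"run{run}.fastq"
            write_fastq(path, reads)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_read_truth_only_lists_anchored_junctions(self):
        config = cfg(substitution_rate=0.0, insertion_rate=0.0,
                     deletion_rate=0.0, coverage=5, read_length=100,
                     antisense_fraction=0.0)
        g = simulate_genome(config)
        isoforms, _ = simulate_isoforms(g, config)
        reads, read_truth = simulate_reads(isoforms, config)
        catalog = truth_junction_catalog(read_truth)
        # each witnessed junction is a real isoform junction
        iso_keys = {
            (j.donor, j.acceptor)
            for iso in isoforms
            for _, j in iso.junctions
        }
        for row in catalog.itertuples(index=False, name=None):
            key = ((row[0], row[1], row[2]), (row[3], row[4], row[5]))
            assert key in iso_keys
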