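import numpy as np
import pytest

from mitosat.cnv_calling import call_str_cnv, snp_scan
from mitosat.pileup_io import read_pileup
from mitosat.str_catalog import find_strs
from mitosat.synthetic_data import (
    GenomeConfig,
    IRElementSpec,
    PlantedSNP,
    SlippageModel,
    generate_genome,
    simulate_pileup,
    simulate_pileup_file,
    simulate_reads,
    slippage_distribution,
    write_truth_tsv,
)


class TestSlippageModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            SlippageModel(p=0.6)
        with pytest.raises(ValueError):
            SlippageModel(e=1.5)
        with pytest.raises(ValueError):
            SlippageModel(g=-1)


class TestSlippageDistribution:
    def test_zero_probability_is_point_mass(self):
        dist = slippage_distribution(8, SlippageModel(p=0.0, g=10))
        assert dist == {8: 1.0}

    def test_one_step_walk(self):
        dist = slippage_distribution(8, SlippageModel(p=0.01, g=1))
        assert dist[8] == pytest.approx(0.98)
        assert dist[7] == pytest.approx(0.01)
        assert dist[9] == pytest.approx(0.01)

    def test_masses_sum_to_one(self):
        for p in (0.0, 0.01, 0.2, 0.5):
            for g in (0, 1, 5, 20):
                for n0 in (2, 8, 17):
                    dist = slippage_distribution(n0, SlippageModel(p=p, g=g))
                    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
                    assert all(c >= 1 for c in dist)

    def test_reflection_at_one_copy(self):
        dist = slippage_distribution(2, SlippageModel(p=0.5, g=5))
        assert min(dist) == 1
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_monte_carlo(self):
        # exact convolution vs a 10^6-sample simulation of the same walk
        model = SlippageModel(p=0.01, g=20)
        n0 = 8
        dist = slippage_distribution(n0, model)
        rng = np.random.default_rng(123)
        n_samples = 1_000_000
        state = np.full(n_samples, n0, dtype=np.int64)
        for _ in range(model.g):
            r = rng.random(n_samples)
            state[r < model.p] += 1
            down = (r >= model.p) & (r < 2 * model.p)
            state[down & (state > 1)] -= 1
        for copies, prob in dist.items():
            if prob < 1e-7:
                continue
            observed = int((state == copies).sum())
            sigma = max((n_samples * prob * (1 - prob)) ** 0.5, 1.0)
            assert abs(observed - n_samples * prob) <= 3 * sigma, (copies, prob)

    def test_invalid_n0(self):
        with pytest.raises(ValueError):
            slippage_distribution(1, SlippageModel())


class TestGenerateGenome:
    def test_planted_features_recorded(self):
        cfg = GenomeConfig(
            length=6000,
            strs=(("G", 8), ("TA", 9)),
            ir_element=IRElementSpec(34, 5, 400),
        )
        genome, truth = generate_genome(cfg, seed=11)
        assert genome.length == 6000
        assert [(l.unit, l.copies) for l in truth.loci] == [("G", 8), ("TA", 9)]
        for locus in truth.loci:
            array = genome.fetch(locus.position, locus.end)
            assert array == locus.unit * locus.copies
        assert truth.element is not None

    def test_deterministic_under_seed(self):
        cfg = GenomeConfig(length=6000)
        g1, t1 = generate_genome(cfg, seed=42)
        g2, t2 = generate_genome(cfg, seed=42)
        assert g1.sequence == g2.sequence
        assert t1.loci == t2.loci
        g3, _ = generate_genome(cfg, seed=43)
        assert g3.sequence != g1.sequence

    def test_at_fraction_realized(self):
        cfg = GenomeConfig(length=15000, strs=(), ir_element=None, at_fraction=0.78)
        genome, _ = generate_genome(cfg, seed=5)
        at = sum(genome.sequence.count(b) for b in "AT") / genome.length
        assert abs(at - 0.78) < 0.02

    def test_infeasible_packing_raises(self):
        cfg = GenomeConfig(length=300, ir_element=IRElementSpec(34, 5, 400))
        with pytest.raises(ValueError, match="fit"):
            generate_genome(cfg, seed=1)

    def test_scanner_recovers_planted_loci(self):
        for seed in range(5):
            cfg = GenomeConfig(length=8000)
            genome, truth = generate_genome(cfg, seed=seed)
            found = {
                (l.position, l.unit, l.copies)
                for l in find_strs(genome.sequence, circular=True)
            }
            planted = {(l.position, l.unit, l.copies) for l in truth.loci}
            assert planted <= found

    def test_truth_frequencies_sum_to_one(self):
        cfg = GenomeConfig(length=8000)
        _, truth = generate_genome(cfg, seed=2, model=SlippageModel(p=0.01, g=5))
        for freqs in truth.allele_frequencies.values():
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_planted_snps(self):
        cfg = GenomeConfig(
            length=6000, snps=(PlantedSNP(position=0, base="", frequency=0.05),)
        )
        genome, truth = generate_genome(cfg, seed=3)
        assert len(truth.snps) == 1
        snp = truth.snps[0]
        assert snp.base != genome.base_at(snp.position)


class TestSimulatePileup:
    def test_depth_one(self):
        cfg = GenomeConfig(length=6000)
        _, truth = generate_genome(cfg, seed=1)
        cols = simulate_pileup(truth, depth=1, model=SlippageModel(), seed=2)
        assert all(col.total() == 1 for col in cols)

    def test_no_noise_no_substitutions(self):
        cfg = GenomeConfig(length=6000)
        genome, truth = generate_genome(cfg, seed=1)
        model = SlippageModel(p=0.0, g=0, e=0.0)
        cols = simulate_pileup(
            truth, depth=500, model=model, seed=2,
            positions=list(range(1, genome.length + 1, 97)),
        )
        for col in cols:
            assert set(col.counts) == {"Ref"}

    def test_planted_frequencies_recovered(self):
        cfg = GenomeConfig(length=6000)
        model = SlippageModel(p=0.01, g=3)
        _, truth = generate_genome(cfg, seed=1, model=model)
        depth = 100_000
        cols = simulate_pileup(truth, depth=depth, model=model, seed=9)
        by_pos = {c.position: c for c in cols}
        for locus in truth.loci:
            freqs = truth.allele_frequencies[locus.position]
            q = 1.0 - freqs[0]
            col = by_pos[locus.position]
            observed_alt = depth - col.counts["Ref"]
            sigma = (depth * q * (1 - q)) ** 0.5
            assert abs(observed_alt - depth * q) <= 3 * sigma

    def test_written_file_reparses(self, tmp_path):
        cfg = GenomeConfig(length=6000)
        model = SlippageModel(p=0.01, g=3, e=0.001)
        _, truth = generate_genome(cfg, seed=1, model=model)
        p = tmp_path / "sim.pileup"
        simulate_pileup_file(truth, 1000, model, seed=4, path=p)
        cols = list(read_pileup(p))
        assert len(cols) == len(truth.loci)
        assert all(c.total() == 1000 for c in cols)

    def test_invalid_depth(self):
        cfg = GenomeConfig(length=6000)
        _, truth = generate_genome(cfg, seed=1)
        with pytest.raises(ValueError):
            simulate_pileup(truth, depth=0, model=SlippageModel(), seed=1)


class TestSimulateReads:
    def test_coverage_close_to_request(self):
        cfg = GenomeConfig(length=5000)
        _, truth = generate_genome(cfg, seed=1)
        reads = list(simulate_reads(truth, read_len=250, depth=100, seed=2))
        total = sum(len(seq) for _, seq in reads)
        assert abs(total / 5000 - 100) / 100 < 0.05

    def test_deterministic(self):
        cfg = GenomeConfig(length=5000)
        _, truth = generate_genome(cfg, seed=1)
        a = list(simulate_reads(truth, 250, 10, seed=7))
        b = list(simulate_reads(truth, 250, 10, seed=7))
        assert a == b

    def test_read_length_bound(self):
        cfg = GenomeConfig(length=1000, strs=(("G", 8),), ir_element=None)
        _, truth = generate_genome(cfg, seed=1)
        with pytest.raises(ValueError):
            next(simulate_reads(truth, read_len=1000, depth=1, seed=1))

    def test_inversion_requires_element(self):
        cfg = GenomeConfig(length=1000, strs=(("G", 8),), ir_element=None)
        _, truth = generate_genome(cfg, seed=1)
        with pytest.raises(ValueError, match="element"):
            next(simulate_reads(truth, 250, 1, inversion_fraction=0.01, seed=1))


class TestPipelineClosure:
    """generate -> simulate -> call recovers the planted truth."""

    def test_frequencies_within_three_sigma_and_no_spurious(self):
        model = SlippageModel(p=0.008, g=4, e=0.0)
        cfg = GenomeConfig(length=8000)
        _, truth = generate_genome(cfg, seed=21, model=model)
        depth = 50_000
        cols = simulate_pileup(truth, depth=depth, model=model, seed=22)
        calls = call_str_cnv(truth.loci, cols, threshold=0.01)
        for call in calls:
            q = 1.0 - truth.allele_frequencies[call.locus.position][0]
            sigma = (q * (1 - q) / depth) ** 0.5
            assert abs(call.alt_ratio - q) <= 3 * sigma

    def test_no_variation_when_slippage_zero(self):
        model = SlippageModel(p=0.0, g=0, e=0.0)
        cfg = GenomeConfig(length=8000)
        _, truth = generate_genome(cfg, seed=31, model=model)
        cols = simulate_pileup(truth, depth=20_000, model=model, seed=32)
        calls = call_str_cnv(truth.loci, cols, threshold=1e-9)
        assert not any(c.selected for c in calls)
        assert snp_scan(calls, per_allele_threshold=1e-9) == []

    def test_planted_snp_appears_in_scan(self):
        model = SlippageModel(p=0.0, g=0, e=0.0)
        cfg = GenomeConfig(
            length=8000, snps=(PlantedSNP(position=0, base="", frequency=0.05),)
        )
        _, truth = generate_genome(cfg, seed=41, model=model)
        cols = simulate_pileup(truth, depth=20_000, model=model, seed=42)
        snp = truth.snps[0]
        col = next(c for c in cols if c.position == snp.position)
        depth = col.total()
        observed = col.counts[snp.base]
        sigma = (depth * 0.05 * 0.95) ** 0.5
        assert abs(observed - depth * 0.05) <= 3 * sigma


class TestTruthOutput:
    def test_truth_tsv(self, tmp_path):
        cfg = GenomeConfig(length=6000)
        _, truth = generate_genome(cfg, seed=1, model=SlippageModel(p=0.01, g=2))
        p = tmp_path / "truth.tsv"
        write_truth_tsv(truth, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("Position")
        assert len(lines) > len(truth.loci)
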