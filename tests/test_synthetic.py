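"""Generator correctness: construction invariants, determinism, noise models."""

import re

import numpy as np
import pytest
from scipy import stats

from spacerlink.sequtils import revcomp
from spacerlink.synthetic import (
    CommunityConfig,
    Replicon,
    TimepointSpec,
    generate_host,
    generate_viruses,
    simulate_reads,
    simulate_timeseries,
)

from conftest import small_config


class TestGenerateHost:
    def test_zero_spacers_yields_single_dr(self):
        cfg = CommunityConfig(seed=1, n_host_spacers=0, host_length=5000, n_viruses=0)
        host, truth = generate_host(cfg)
        assert host.sequence.count(truth["dr"]) == 1
        assert truth["spacers"] == []

    def test_same_seed_reproduces_genome(self):
        cfg = CommunityConfig(seed=5, n_host_spacers=5, host_length=8000)
        g1, _ = generate_host(cfg)
        g2, _ = generate_host(cfg)
        assert g1.sequence == g2.sequence

    def test_regex_scan_recovers_array_structure(self):
        """Regex scan of the emitted genome finds n+1 DR copies and the spacers."""
        cfg = CommunityConfig(seed=9, n_host_spacers=5, host_length=8000)
        host, truth = generate_host(cfg)
        dr = truth["dr"]
        starts = [m.start() for m in re.finditer(re.escape(dr), host.sequence)]
        assert len(starts) == 6
        between = [
            host.sequence[a + len(dr) : b] for a, b in zip(starts, starts[1:])
        ]
        assert between == [d["seq"] for d in truth["spacers"]]

    def test_invalid_dr_rejected(self):
        with pytest.raises(ValueError, match="dr_sequence"):
            CommunityConfig(seed=0, dr_sequence="ACGTX")


class TestGenerateViruses:
    def test_zero_mutation_rate_plants_exact_protospacers(self):
        cfg = CommunityConfig(seed=3, protospacer_mutation_rate=0.0)
        rng = np.random.default_rng(3)
        _, host_truth = generate_host(cfg, rng)
        viruses, protos, _ = generate_viruses(cfg, host_truth, rng)
        by_id = {v.id: v.sequence for v in viruses}
        for p in protos:
            assert p.n_mutations == 0
            assert p.planted_seq == p.source_seq
            embedded = by_id[p.virus_id][p.start : p.end]
            assert embedded in (p.source_seq, revcomp(p.source_seq))

    def test_all_circular_have_terminal_repeat(self):
        cfg = CommunityConfig(seed=4, circular_fraction=1.0)
        rng = np.random.default_rng(4)
        _, host_truth = generate_host(cfg, rng)
        viruses, _, _ = generate_viruses(cfg, host_truth, rng)
        k = cfg.terminal_repeat_len
        assert viruses
        for v in viruses:
            assert v.circular
            assert v.sequence[:k] == v.sequence[-k:]

    def test_mutation_counts_within_binomial_bounds(self):
        """Mean Hamming distance of planted protospacers tracks rate * length."""
        cfg = CommunityConfig(
            seed=6,
            n_viruses=10,
            protospacers_per_virus=12,
            protospacer_mutation_rate=0.1,
            spacer_len_range=(40, 40),
            n_host_spacers=40,
        )
        rng = np.random.default_rng(6)
        _, host_truth = generate_host(cfg, rng)
        _, protos, _ = generate_viruses(cfg, host_truth, rng)
        assert len(protos) >= 100
        hamming = [
            sum(a != b for a, b in zip(p.source_seq, p.planted_seq)) for p in protos
        ]
        assert hamming == [p.n_mutations for p in protos]
        n = len(protos) * 40
        k = sum(hamming)
        lo, hi = stats.binom.interval(0.999, n, 0.1)
        assert lo <= k <= hi

    def test_virus_too_short_raises(self):
        cfg = CommunityConfig(
            seed=1, virus_len_range=(300, 300), protospacers_per_virus=10
        )
        rng = np.random.default_rng(1)
        _, host_truth = generate_host(cfg, rng)
        with pytest.raises(ValueError, match="too short"):
            generate_viruses(cfg, host_truth, rng)


class TestSimulateReads:
    def _replicon(self, rng, length=4000, name="r1"):
        from spacerlink.sequtils import random_dna

        return Replicon(name, random_dna(rng, length))

    def test_error_free_reads_are_exact_substrings(self, rng):
        rep = self._replicon(rng)
        records, counts = simulate_reads([rep], {"r1": 1.0}, 200, 100, 0.0, 11)
        assert counts["r1"] == 200
        for _, seq, _ in records:
            assert seq in rep.sequence or revcomp(seq) in rep.sequence

    def test_read_count_conservation_and_weight_split(self, rng):
        r1, r2 = self._replicon(rng, 4000, "a"), self._replicon(rng, 4000, "b")
        records, counts = simulate_reads(
            [r1, r2], {"a": 3.0, "b": 1.0}, 10_000, 100, 0.0, 5
        )
        assert len(records) == 10_000
        assert counts["a"] + counts["b"] == 10_000
        lo, hi = stats.binom.interval(0.99, 10_000, 0.75)
        assert lo <= counts["a"] <= hi

    def test_same_seed_identical_output(self, rng):
        rep = self._replicon(rng)
        a, _ = simulate_reads([rep], {"r1": 1.0}, 500, 100, 0.01, 42)
        b, _ = simulate_reads([rep], {"r1": 1.0}, 500, 100, 0.01, 42)
        assert a == b

    def test_short_linear_replicon_contributes_nothing(self, rng):
        short = self._replicon(rng, 50, "tiny")
        long_ = self._replicon(rng, 4000, "big")
        with pytest.warns(UserWarning, match="tiny"):
            _, counts = simulate_reads(
                [short, long_], {"tiny": 5.0, "big": 1.0}, 1000, 100, 0.0, 2
            )
        assert counts["tiny"] == 0
        assert counts["big"] == 1000

    def test_circular_reads_wrap_the_junction(self, rng):
        from spacerlink.sequtils import random_dna

        core = random_dna(rng, 500)
        rep = Replicon("c", core + core[:55], circular=True, core_length=500)
        records, _ = simulate_reads([rep], {"c": 1.0}, 400, 150, 0.0, 3)
        doubled = core + core
        wrapped = 0
        for _, seq, _ in records:
            fwd = seq if seq in doubled else revcomp(seq)
            assert fwd in doubled
            if fwd not in core:
                wrapped += 1
        assert wrapped > 0


class TestSimulateTimeseries:
    def test_no_turnover_keeps_repertoire(self):
        cfg = small_config(
            timepoints=[TimepointSpec("t0"), TimepointSpec("t1")]
        )
        com = simulate_timeseries(cfg)
        reps = [[d["seq"] for d in s.truth["spacers"]] for s in com.samples]
        assert reps[0] == reps[1]

    def test_acquisition_and_loss_arithmetic(self):
        cfg = small_config(
            n_host_spacers=5,
            timepoints=[
                TimepointSpec("t0"),
                TimepointSpec("t1", n_new_spacers=3, n_lost_spacers=1),
            ],
        )
        com = simulate_timeseries(cfg)
        assert len(com.samples[0].truth["spacers"]) == 5
        assert len(com.samples[1].truth["spacers"]) == 7
        # new spacers enter at the leader end (array start)
        t1_ids = [d["id"] for d in com.samples[1].truth["spacers"]]
        assert all(i.startswith("sp_t1") for i in t1_ids[:3])

    def test_excess_loss_raises(self):
        cfg = small_config(
            n_host_spacers=2,
            timepoints=[
                TimepointSpec("t0"),
                TimepointSpec("t1", n_lost_spacers=5),
            ],
        )
        with pytest.raises(ValueError, match="lose"):
            simulate_timeseries(cfg)

    def test_full_reproducibility_across_runs(self):
        cfg = small_config(n_reads=2000)
        a = simulate_timeseries(cfg)
        b = simulate_timeseries(cfg)
        assert [s.reads for s in a.samples] == [s.reads for s in b.samples]
        assert [v.sequence for v in a.viruses] == [v.sequence for v in b.viruses]

    def test_expected_coverage_matches_truth_definition(self, small_community):
        s = small_community.samples[0]
        for rep in small_community.reference_replicons:
            expect = (
                s.truth["read_counts"][rep.id]
                * small_community.config.read_length
                / len(rep.sequence)
            )
            assert s.truth["expected_coverage"][rep.id] == pytest.approx(expect)
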