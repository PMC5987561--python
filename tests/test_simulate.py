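"""Synthetic-data generator: determinism, rates, chain law, DE allocation."""

import numpy as np
import pytest
from scipy import stats

from polydam.errors import ConfigError, OrderingError
from polydam.fragments import find_gatc_fragments
from polydam.simulate import (
    SimConfig,
    perturb_states,
    simulate_counts,
    simulate_de_table,
    simulate_emissions,
    simulate_genome,
    simulate_states,
)


def count_motifs(seq):
    return sum(
        1
        for i in range(len(seq) - 3)
        if seq[i : i + 4] == "GATC"
    )


class TestGenome:
    def test_motif_count_near_planted_plus_spontaneous_rate(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=100_000, gatc_rate=4.0)
        seq = simulate_genome(cfg)["chr1"]
        n = count_motifs(seq)
        # planted 4/kb plus spontaneous 4^-4 per base (~3.9/kb); Poisson-ish
        expected = 100_000 * (4.0 / 1000 + 0.25**4)
        assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_zero_rate_short_sequence_single_fragment(self):
        cfg = SimConfig(seed=5, n_chroms=1, chrom_length=40, gatc_rate=0.0)
        genome = simulate_genome(cfg)
        if count_motifs(genome["chr1"]) == 0:  # seed chosen spontaneous-free
            frags = find_gatc_fragments(genome)
            assert len(frags) == 1
        else:
            pytest.skip("seed produced a spontaneous motif")

    def test_determinism(self):
        cfg = SimConfig(seed=9, n_chroms=2, chrom_length=5000)
        assert simulate_genome(cfg) == simulate_genome(cfg)

    def test_invalid_length_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(chrom_length=0)


class TestStates:
    def test_short_decay_approaches_stationary(self):
        # L tiny relative to spacing: successive states ~ i.i.d. stationary
        cfg = SimConfig(
            seed=11,
            n_chroms=1,
            chrom_length=3_000_000,
            decay_length=1.0,
            stationary=(0.2, 0.3, 0.5),
        )
        genome = simulate_genome(cfg)
        frags = find_gatc_fragments(genome)
        assert len(frags) >= 10_000
        states = simulate_states(frags, cfg)
        obs = np.bincount(states, minlength=3)
        chi2 = stats.chisquare(obs, np.array(cfg.stationary) * len(states))
        assert chi2.pvalue > 0.01

    def test_infinite_decay_freezes_chromosome_state(self):
        cfg = SimConfig(seed=12, n_chroms=3, chrom_length=50_000, decay_length=1e18)
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = simulate_states(frags, cfg)
        for chrom in frags["chrom"].unique():
            sel = (frags["chrom"] == chrom).to_numpy()
            assert len(np.unique(states[sel])) == 1

    def test_determinism(self):
        cfg = SimConfig(seed=13, n_chroms=1, chrom_length=20_000)
        frags = find_gatc_fragments(simulate_genome(cfg))
        assert (simulate_states(frags, cfg) == simulate_states(frags, cfg)).all()

    def test_unsorted_fragments_rejected(self):
        cfg = SimConfig(seed=13, n_chroms=1, chrom_length=20_000)
        frags = find_gatc_fragments(simulate_genome(cfg)).iloc[::-1].reset_index(drop=True)
        with pytest.raises(OrderingError):
            simulate_states(frags, cfg)


class TestCounts:
    def test_enriched_state_log_ratio_recovers_state_mean(self):
        cfg = SimConfig(seed=14, n_chroms=1, chrom_length=2_000_000)
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = simulate_states(frags, cfg)
        counts = simulate_counts(frags, states, cfg)
        pc = counts["pc"][0].counts.astype(float)
        dam = counts["dam"][0].counts.astype(float)
        sel = states == 2
        assert sel.sum() >= 3000
        mean_ratio = np.mean(np.log2((pc[sel] + 1) / (dam[sel] + 1)))
        assert abs(mean_ratio - 1.5) < 0.1

    def test_poisson_limit_variance_over_mean_near_one(self):
        cfg = SimConfig(
            seed=15,
            n_chroms=1,
            chrom_length=1_000_000,
            dispersion=np.inf,
            gatc_rate=0.0,
        )
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = np.ones(len(frags), dtype=np.int8)
        # fixed-length stratum: restrict to a narrow length band
        lengths = (frags["end"] - frags["start"]).to_numpy()
        counts = simulate_counts(frags, states, cfg)["dam"][0].counts
        band = (lengths > 200) & (lengths < 260)
        assert band.sum() > 300
        # remove the within-band mean trend by scaling to per-base rate
        c = counts[band]
        ratio = c.var() / c.mean()
        assert 0.8 < ratio < 1.3

    def test_overdispersion_exceeds_poisson(self):
        cfg = SimConfig(seed=16, n_chroms=1, chrom_length=500_000, dispersion=2.0)
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = np.ones(len(frags), dtype=np.int8)
        lengths = (frags["end"] - frags["start"]).to_numpy()
        counts = simulate_counts(frags, states, cfg)["dam"][0].counts
        band = (lengths > 200) & (lengths < 300)
        c = counts[band]
        assert c.var() / c.mean() > 2.0

    def test_empty_fragment_list_gives_empty_tables(self):
        import pandas as pd

        cfg = SimConfig(seed=17)
        empty = pd.DataFrame(columns=["chrom", "start", "end", "id", "end_flank"])
        out = simulate_counts(empty, np.array([], dtype=np.int8), cfg)
        assert out == {"dam": [], "pc": []}

    def test_replicate_count_and_determinism(self):
        cfg = SimConfig(seed=18, n_chroms=1, chrom_length=20_000, n_replicates=3)
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = simulate_states(frags, cfg)
        c1 = simulate_counts(frags, states, cfg)
        c2 = simulate_counts(frags, states, cfg)
        assert len(c1["dam"]) == 3
        for a, b in zip(c1["pc"], c2["pc"]):
            assert (a.counts == b.counts).all()


class TestEmissions:
    def test_values_distributed_around_state_means(self):
        cfg = SimConfig(seed=19, n_chroms=1, chrom_length=1_000_000)
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = simulate_states(frags, cfg)
        prof = simulate_emissions(frags, states, cfg)
        for s, mu in zip(range(3), cfg.state_means):
            sel = states == s
            assert abs(prof.values[sel].mean() - mu) < 0.05
            assert abs(prof.values[sel].std() - cfg.state_sd) < 0.05


class TestDETable:
    def test_exact_up_down_allocation(self):
        cfg = SimConfig(seed=20, frac_up=0.1, frac_down=0.2, n_genes=100)
        table = simulate_de_table(cfg, {"chr1": 100_000})
        sig = table[table["padj"] < 0.05]
        assert (sig["log2fc"] > 0).sum() == 10
        assert (sig["log2fc"] < 0).sum() == 20
        assert len(table) == 100

    def test_no_de_genes_when_fractions_zero(self):
        cfg = SimConfig(seed=21, frac_up=0.0, frac_down=0.0, n_genes=50)
        table = simulate_de_table(cfg, {"chr1": 100_000})
        assert (table["padj"] >= 0.05).all()

    def test_determinism_and_margins(self):
        cfg = SimConfig(seed=22, n_genes=80)
        t1 = simulate_de_table(cfg, {"chr1": 200_000, "chr2": 100_000})
        t2 = simulate_de_table(cfg, {"chr1": 200_000, "chr2": 100_000})
        assert t1.equals(t2)
        assert (t1["tss"] >= cfg.tss_margin).all()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(frac_up=0.7, frac_down=0.5)


class TestPerturb:
    def test_changes_are_segment_wise_and_seeded(self):
        cfg = SimConfig(seed=23, n_chroms=1, chrom_length=200_000, change_rate=0.3)
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = simulate_states(frags, cfg)
        p1 = perturb_states(states, frags, cfg)
        p2 = perturb_states(states, frags, cfg)
        assert (p1 == p2).all()
        assert (p1 != states).any()

    def test_zero_change_rate_is_identity(self):
        cfg = SimConfig(seed=24, n_chroms=1, chrom_length=50_000, change_rate=0.0)
        frags = find_gatc_fragments(simulate_genome(cfg))
        states = simulate_states(frags, cfg)
        assert (perturb_states(states, frags, cfg) == states).all()
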