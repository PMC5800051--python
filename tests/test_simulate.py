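"""Generator ground truth: identity cases, determinism, conservation, noise laws."""

import numpy as np
import pytest
from scipy import stats

from pavpan import simulate as sim
from pavpan.breakpoints import Breakpoint, extract_microhomology


def _empty_config(**kw):
    return sim.SimulationConfig(n_pavs=0, n_ambiguous=0, n_incomplete=0, **kw)


class TestGenomePair:
    def test_no_pavs_yields_identical_genomes(self):
        donor, acceptor, truth = sim.simulate_genome_pair(_empty_config(seed=3))
        assert donor["chr1"] == acceptor["chr1"]
        assert truth.features == []

    def test_same_seed_reproduces_identical_sequences(self):
        cfg = sim.adversarial_config(seed=9)
        d1, a1, t1 = sim.simulate_genome_pair(cfg)
        d2, a2, t2 = sim.simulate_genome_pair(cfg)
        assert d1 == d2 and a1 == a2
        assert [f.__dict__ for f in t1.features] == [f.__dict__ for f in t2.features]

    def test_length_conservation(self, adversarial_bundle):
        donor = adversarial_bundle["donor"]
        acceptor = adversarial_bundle["acceptor"]
        truth = adversarial_bundle["truth"]
        assert len(donor["chr1"]) - len(acceptor["chr1"]) == truth.removed_length

    def test_planted_microhomology_recovered_by_brute_force(self, adversarial_bundle):
        """Brute-force all-k scan of the emitted sequence returns the drawn length."""
        donor = adversarial_bundle["donor"]["chr1"]
        for f in adversarial_bundle["truth"].true_pavs:
            if f.mh_length is None:
                continue
            best = 0
            for k in range(1, f.length + 1):
                if donor[f.start : f.start + k] == donor[f.end : f.end + k]:
                    best = k
                else:
                    break
            left = 0
            for k in range(1, min(f.length, f.start) + 1):
                if donor[f.start - k : f.start] == donor[f.end - k : f.end]:
                    left = k
                else:
                    break
            assert max(best, left) == f.mh_length

    def test_acceptor_is_donor_with_segments_excised(self, adversarial_bundle):
        donor = adversarial_bundle["donor"]["chr1"]
        truth = adversarial_bundle["truth"]
        removed = sorted((f.start, f.end) for f in truth.features if f.removed)
        parts, cursor = [], 0
        for s, e in removed:
            parts.append(donor[cursor:s])
            cursor = e
        parts.append(donor[cursor:])
        assert "".join(parts) == adversarial_bundle["acceptor"]["chr1"]

    def test_ambiguous_junction_planted_twice(self, adversarial_bundle):
        acceptor = adversarial_bundle["acceptor"]["chr1"]
        donor = adversarial_bundle["donor"]["chr1"]
        flank = adversarial_bundle["config"].flank
        amb = [f for f in adversarial_bundle["truth"].features
               if f.category == "anchored_ambiguous"]
        assert amb
        for f in amb:
            junction = donor[f.start - flank : f.start] + donor[f.end : f.end + flank]
            assert acceptor.count(junction) == 2

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="genome_length"):
            sim.simulate_genome_pair(sim.SimulationConfig(genome_length=10_000, n_pavs=20))


class TestMicrohomologyMixture:
    def test_pmf_sums_to_one_and_respects_spike(self):
        mix = sim.MicrohomologyMixture(spike_mass=0.10, no_mh_prob=0.6)
        pmf = mix.pmf()
        assert pmf.sum() == pytest.approx(1.0)
        assert pmf[0] == pytest.approx(0.6)
        # spike sits on top of the geometric decay at 5 bp
        assert pmf[5] > pmf[4]

    def test_empirical_histogram_matches_mixture(self):
        """Chi-square GOF of 2000 planted MH lengths against the mixture law."""
        mix = sim.MicrohomologyMixture()
        rng = np.random.default_rng(2)
        draws = sim.sample_mh_lengths(mix, 2000, rng)
        pmf = mix.pmf()
        support = pmf.index.to_numpy()
        observed = np.array([(draws == k).sum() for k in support])
        expected = pmf.to_numpy() * 2000
        keep = expected >= 1  # pool ultra-rare tail bins out of the test
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01


class TestCoverage:
    def test_zero_leak_means_zero_depth_over_pavs(self):
        cfg = sim.SimulationConfig(seed=17, leak_fraction=0.0, n_pavs=10, n_incomplete=3)
        _, _, truth = sim.simulate_genome_pair(cfg)
        opp, _ = sim.simulate_coverage(truth, cfg)
        for f in truth.features:
            if f.removed or f.category == "incomplete":
                assert np.all(opp[f.contig].slice_depth(f.start, f.end) == 0)

    def test_shared_region_depth_matches_base_depth(self, adversarial_bundle):
        """Poisson oracle: mean over 10 kb of shared sequence within 3 sigma of 40."""
        cfg = adversarial_bundle["config"]
        truth = adversarial_bundle["truth"]
        opp = adversarial_bundle["opposite"]["chr1"]
        last_end = max(f.end for f in truth.features if f.contig == "chr1")
        shared = opp.slice_depth(last_end + 200, last_end + 200 + 10_000)
        se = np.sqrt(cfg.base_depth / len(shared))
        assert abs(shared.mean() - cfg.base_depth) < 3 * se

    def test_duplication_decoy_keeps_full_opposite_depth(self, adversarial_bundle):
        cfg = adversarial_bundle["config"]
        truth = adversarial_bundle["truth"]
        opp = adversarial_bundle["opposite"]["chr1"]
        dups = [f for f in truth.features if f.category == "duplication_decoy"]
        assert dups
        for f in dups:
            depth = opp.slice_depth(f.start, f.end)
            assert abs(depth.mean() - cfg.base_depth) < 3 * np.sqrt(cfg.base_depth / f.length)

    def test_negative_base_depth_rejected(self, adversarial_bundle):
        cfg = sim.SimulationConfig(seed=1, base_depth=-1.0)
        _, _, truth = sim.simulate_genome_pair(sim.SimulationConfig(seed=1))
        with pytest.raises(ValueError, match="base_depth"):
            sim.simulate_coverage(truth, cfg)


class TestDepthMatrix:
    def test_noise_free_identity_limit(self):
        """sigma=0, b1=1, a1=0: a line carrying all PAVs reproduces x exactly."""
        cfg = sim.SimulationConfig(
            seed=7, n_pavs=15, n_incomplete=0,
            depth=sim.DepthModel(a0=0, b0=0, sigma0=0, a1=0, b1=1, sigma1=0),
            groups=(sim.GroupSpec("G", 3, (50.0, 0.5)),),  # ~all carriers
            n_group_private=0)
        _, _, truth = sim.simulate_genome_pair(cfg)
        sim.simulate_panel(truth, cfg)
        dm = sim.simulate_depth_matrix(truth, cfg)
        x = dm.x
        for line in dm.lines:
            z = truth.genotypes[line].to_numpy()
            y = dm.y(line)
            assert np.allclose(y[z == 1], x[z == 1])
            assert np.allclose(y[z == 0], 0.0)  # a0=0, sigma0=0

    def test_cluster_moments_match_model(self):
        """Mean of Y within each true cluster matches a_k + b_k E[x] at n=5000."""
        cfg = sim.SimulationConfig(seed=13)
        model = cfg.depth
        x, y, z = sim.simulate_mixture_xy(model, 5000, seed=13)
        for k, (a, b, s) in enumerate([(model.a0, model.b0, model.sigma0),
                                       (model.a1, model.b1, model.sigma1)]):
            sel = z == k
            expected = a + b * x[sel].mean()
            se = np.sqrt((s**2 + b**2 * np.var(x[sel])) / sel.sum())
            assert abs(y[sel].mean() - expected) < 3 * max(se, 1e-12)

    def test_poisson_mode_yields_integer_counts_near_model_mean(self):
        cfg = sim.SimulationConfig(seed=19, n_pavs=25, n_incomplete=0,
                                   noise_model="poisson")
        _, _, truth = sim.simulate_genome_pair(cfg)
        dm = sim.simulate_depth_matrix(truth, cfg)
        counts = dm.counts.drop(columns=[cfg.donor_line])
        vals = counts.to_numpy()
        assert np.all(vals >= 0) and np.all(vals == np.round(vals))

    def test_sigma_zero_b0_a0_zero_yields_zero_absent_counts(self):
        model = sim.DepthModel(a0=0, b0=0, sigma0=0, a1=0, b1=1, sigma1=0)
        x, y, z = sim.simulate_mixture_xy(model, 500, seed=3)
        assert np.all(y[z == 0] == 0)


class TestPanel:
    def test_donor_row_all_present_reference_all_absent(self, panel_bundle):
        g = panel_bundle["genotypes"]
        cfg = panel_bundle["config"]
        assert (g[cfg.donor_line] == 1).all()
        assert (g[cfg.reference_line] == 0).all()

    def test_group_private_pavs_have_zero_frequency_elsewhere(self, panel_bundle):
        truth = panel_bundle["truth"]
        cfg = panel_bundle["config"]
        groups = panel_bundle["groups"]
        donor_group = groups[cfg.donor_line]
        for pav in truth.group_freqs.index[: cfg.n_group_private]:
            carriers = [l for l in truth.genotypes.columns
                        if truth.genotypes.loc[pav, l] == 1]
            assert carriers  # at least the donor
            assert {groups[l] for l in carriers} == {donor_group}

    def test_empirical_group_frequency_within_binomial_ci(self):
        """At 50 lines per group the realized frequency sits in the 99% CI."""
        cfg = sim.SimulationConfig(
            seed=21, n_pavs=30, n_incomplete=0,
            groups=(sim.GroupSpec("Big", 50, (2.0, 2.0)),), n_group_private=0)
        _, _, truth = sim.simulate_genome_pair(cfg)
        genotypes, groups = sim.simulate_panel(truth, cfg)
        members = [l for l in genotypes.columns
                   if groups[l] == "Big" and l not in (cfg.donor_line, cfg.reference_line)]
        for pav in genotypes.index:
            f = truth.group_freqs.loc[pav, "Big"]
            k = genotypes.loc[pav, members].sum()
            lo, hi = stats.binom.interval(0.99, len(members), f)
            assert lo <= k <= hi

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least one line"):
            sim.GroupSpec("empty", 0, (1.0, 1.0))
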