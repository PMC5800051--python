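import pytest

from pavpan import simulate as sim


@pytest.fixture(scope="session")
def adversarial_bundle():
    """Genome pair + coverage + candidates with one decoy per filter stage."""
    cfg = sim.adversarial_config(seed=11)
    donor, acceptor, truth = sim.simulate_genome_pair(cfg)
    opposite, own = sim.simulate_coverage(truth, cfg)
    candidates = sim.candidates_from_truth(truth)
    return {
        "config": cfg, "donor": donor, "acceptor": acceptor, "truth": truth,
        "opposite": opposite, "own": own, "candidates": candidates,
        "scaffolds": {k: v for k, v in donor.items() if k != "chr1"},
    }


@pytest.fixture(scope="session")
def panel_bundle():
    """Default-scale panel: genotypes, depth matrix, and truth."""
    cfg = sim.SimulationConfig(seed=5, n_pavs=40, n_incomplete=10, genome_length=700_000)
    _, _, truth = sim.simulate_genome_pair(cfg)
    genotypes, groups = sim.simulate_panel(truth, cfg)
    dm = sim.simulate_depth_matrix(truth, cfg)
    return {"config": cfg, "truth": truth, "genotypes": genotypes,
            "groups": groups, "dm": dm}
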