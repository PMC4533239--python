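"""Shared fixtures: one synthetic study-scale dataset reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import pointcen as pc

FIXTURE_SEED = 11
FACTORS = ("Ndc80", "Cse4", "Ndc10", "Cep3")


@pytest.fixture(scope="session")
def default_model() -> pc.CentromereModel:
    return pc.CentromereModel()


@pytest.fixture(scope="session")
def fixture_genome():
    """Ten-chromosome genome with one planted centromere per chromosome."""
    config = pc.SyntheticGenomeConfig(seed=FIXTURE_SEED)
    genome, genes, truth = pc.generate_genome(config)
    return config, genome, genes, truth


@pytest.fixture(scope="session")
def fixture_annotations(fixture_genome):
    _, _, genes, _ = fixture_genome
    ann: dict[str, list] = {}
    for g in genes:
        ann.setdefault(g.chrom, []).append(g)
    return ann


@pytest.fixture(scope="session")
def fixture_peaks(fixture_genome, fixture_annotations):
    """Classified peak calls for all four factors on the shared fixture."""
    config, genome, _, truth = fixture_genome
    out = {}
    for factor in FACTORS:
        rng = pc.child_rng(config.seed, "chip", factor)
        chip, inp = pc.simulate_coverage(genome, truth, factor, config.chip, rng)
        enr = pc.compute_enrichment(chip, inp)
        out[factor] = [
            pc.classify_intergenic(p, fixture_annotations)
            for p in pc.call_peaks(enr)
        ]
    return out


@pytest.fixture(scope="session")
def sampled_windows(default_model):
    """Ten centromere windows from one seeded stream (the consensus input)."""
    rng = np.random.default_rng([FIXTURE_SEED, 7])
    return [
        (f"cen{i + 1}", pc.sample_centromere(default_model, rng).sequence)
        for i in range(10)
    ]
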