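"""Shared fixtures: one default-scale pipeline run and small genome objects."""
import numpy as np
import pytest

from elimrep import pipeline, synthdata


@pytest.fixture(scope="session")
def families():
    return synthdata.default_families(0)


@pytest.fixture(scope="session")
def default_genomes(families):
    """Germline + somatic genomes built from the packaged placement layout."""
    kary = synthdata.KaryotypeConfig()
    placement = synthdata.default_placement(kary, families, seed=11)
    germ = synthdata.build_germline_genome(kary, families, placement, seed=12)
    soma = synthdata.derive_somatic_genome(germ)
    return kary, germ, soma


@pytest.fixture(scope="session")
def default_run():
    """One full default-configuration pipeline run (seeded)."""
    return pipeline.run_all(pipeline.RunConfig(seed=0))


def tandem_scenario(monomer: str, copies: int, coverage: float, seed: int,
                    flank: int = 10_000, soma_len: int = 40_000):
    """Germline genome with one tandem array vs a repeat-free somatic genome."""
    rng = np.random.default_rng(seed)

    def bg(n):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])

    germ_seq = bg(flank) + monomer * copies + bg(flank)
    pm = synthdata.PlacementMap([
        synthdata.Placement("G1", "G1", "fam", flank,
                            flank + len(monomer) * copies, copies)])
    germ = synthdata.Genome(
        [synthdata.Chromosome("G1", germ_seq, True, "G1")], pm)
    soma = synthdata.Genome(
        [synthdata.Chromosome("S1", bg(soma_len), False, "S1")],
        synthdata.PlacementMap())
    germ_reads = synthdata.simulate_reads(germ, coverage, 100, 0.0, seed + 1)
    soma_reads = synthdata.simulate_reads(soma, coverage, 100, 0.0, seed + 2)
    return germ_reads, soma_reads
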