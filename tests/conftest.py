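import numpy as np
import pytest

import pairscreen as ps
from pairscreen.library import CONTROL_GENE, FLUC_SPACER, Guide, GenePair, build_library


def make_guides(gene: str, n: int, start: int = 0) -> list[Guide]:
    """Deterministic distinct 20-nt spacers for a gene's guide set."""
    bases = "ACGT"
    guides = []
    for j in range(n):
        k = start + j
        spacer = "".join(bases[(k >> (2 * i)) & 3] for i in range(20))
        guides.append(Guide(f"{gene}_g{j+1}", gene, spacer))
    return guides


@pytest.fixture
def control_guide() -> Guide:
    return Guide("Fluc", CONTROL_GENE, FLUC_SPACER, is_control=True)


@pytest.fixture
def tiny_library(control_guide):
    """Two gene pairs, 3 and 2 guides per gene respectively."""
    pairs = {
        GenePair("AKT1", "AKT2"): (make_guides("AKT1", 3, 0),
                                   make_guides("AKT2", 3, 16)),
        GenePair("CNOT7", "CNOT8", "synlethdb"): (make_guides("CNOT7", 2, 32),
                                                  make_guides("CNOT8", 2, 48)),
    }
    return build_library(pairs, control_guide)


@pytest.fixture(scope="session")
def small_screen():
    """A 12-pair screen with 3 planted SL pairs, fitted once per session."""
    cfg = ps.SimulationConfig(n_pairs=12, guides_per_gene=3, frac_sl=0.25,
                              frac_lethal_genes=0.15, seed=3)
    lib, eff, counts = ps.simulate_screen(cfg)
    model = ps.PairedScreen(counts, lib)
    res = model.fit(n_perm=500, bin_size=20, seed=1)
    return cfg, lib, eff, counts, res


def run_null_screen(seed: int, n_perm: int = 10_000):
    """One completely null screen (all f=0, eps=0) through the pipeline."""
    cfg = ps.SimulationConfig(frac_sl=0.0, fitness_sd=0.0,
                              frac_lethal_genes=0.0, seed=seed)
    lib, eff, counts = ps.simulate_screen(cfg)
    res = ps.PairedScreen(counts, lib).fit(seed=seed, n_perm=n_perm)
    return eff, res


@pytest.fixture(scope="session")
def null_screen_results():
    """Twenty seeded null screens; shared by calibration tests."""
    out = []
    for seed in range(20):
        eff, res = run_null_screen(1000 + seed)
        out.append(res)
    return out


def run_recovery_screen(seed: int):
    """One screen under the power-analysis conditions: 200 pairs, 10 of
    them synthetic lethal at eps=-1.5, with the external essential-gene
    list emulating an independent essentiality screen (true f < -0.5)."""
    cfg = ps.SimulationConfig(seed=seed)  # defaults are the study conditions
    lib, eff, counts = ps.simulate_screen(cfg)
    external = {g for g, f in eff.gene_fitness.items() if f < -0.5}
    res = ps.PairedScreen(counts, lib).fit(seed=seed,
                                           external_essential=external)
    return eff, res


@pytest.fixture(scope="session")
def recovery_results():
    """Ten seeded recovery screens with their ground truth."""
    return [run_recovery_screen(2000 + seed) for seed in range(10)]
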