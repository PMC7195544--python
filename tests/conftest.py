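import numpy as np
import pandas as pd
import pytest

from gbsphylo.genotype import MISSING, GenotypeMatrix


def make_matrix(
    rng: np.random.Generator,
    n_samples: int = 30,
    n_sites: int = 300,
    p_missing: float = 0.15,
    n_contigs: int = 3,
    positioned: bool = True,
    max_pos_step: int = 400,
) -> GenotypeMatrix:
    """Random genotype matrix with plausible depths, GQs and positions."""
    genos = rng.choice(
        np.array([0, 1, 2], dtype=np.int8),
        size=(n_samples, n_sites),
        p=[0.55, 0.15, 0.30],
    )
    genos[rng.random((n_samples, n_sites)) < p_missing] = MISSING
    depths = rng.integers(1, 30, size=(n_samples, n_sites)).astype(np.int32)
    depths[genos == MISSING] = 0
    gq = rng.uniform(0, 99, size=(n_samples, n_sites))
    gq[genos == MISSING] = np.nan
    contigs = [f"ctg{j % n_contigs}" for j in range(n_sites)]
    positions = np.zeros(n_sites, dtype=int)
    per_contig: dict[str, int] = {}
    for j, c in enumerate(contigs):
        step = int(rng.integers(1, max_pos_step))
        positions[j] = per_contig.get(c, 0) + step
        per_contig[c] = positions[j]
    sites = pd.DataFrame(
        {
            "id": [f"s{j:04d}" for j in range(n_sites)],
            "contig": contigs,
            "pos0": positions,
            "ref": rng.choice(list("ACGT"), size=n_sites),
            "alt": "N",  # fixed below to differ from ref
            "source": "reference" if positioned else "denovo",
            "positioned": positioned,
        }
    )
    alts = []
    for r in sites["ref"]:
        choices = [b for b in "ACGT" if b != r]
        alts.append(choices[int(rng.integers(0, 3))])
    sites["alt"] = alts
    return GenotypeMatrix(
        [f"smp{i:02d}" for i in range(n_samples)], sites, genos, depths, gq
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """Shared small error-free simulation (de novo + reference friendly)."""
    from gbsphylo.simulate import SimulationConfig, simulate

    return simulate(
        SimulationConfig(
            n_species=5,
            n_samples_per_species=2,
            n_loci=60,
            mean_depth=30,
            depth_dispersion=20.0,
            seed=11,
        )
    )
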