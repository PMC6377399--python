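import numpy as np
import pytest

from ltrdyn.model import GenomeSequence
from ltrdyn.simulate import (AgeMixtureComponent, FamilyCounts, SimConfig,
                             simulate_genome)

BASES = np.array(list("ACGT"))


def random_dna(rng, n):
    return "".join(rng.choice(BASES, n))


@pytest.fixture(scope="session")
def small_sim():
    """A 900-kb genome with 2 families of young elements and full truth."""
    cfg = SimConfig(
        genome_len=900_000, n_families=2, counts=FamilyCounts(5, 5, 3, 3),
        age_model=[AgeMixtureComponent(1.0, 0.5, 3.5)], seed=42,
    )
    return cfg, simulate_genome(cfg)


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """Simulate a genome with planted S:I = 2.0 and run the pipeline twice."""
    from ltrdyn.pipeline import run_pipeline

    root = tmp_path_factory.mktemp("e2e")
    cfg = SimConfig(
        genome_len=800_000, n_families=2,
        counts=FamilyCounts(n_intact=5, n_solo_recomb=6, n_solo_fragment=4,
                            n_truncated=2),
        age_model=[AgeMixtureComponent(1.0, 0.2, 1.8)], seed=7,
    )
    sim = root / "sim"
    genome, truth, library, genes = simulate_genome(cfg, out_dir=sim)
    manifests = [
        run_pipeline(str(sim / "genome.fasta"), str(sim / "domains.faa"),
                     str(root / f"run{i}"), genes_path=str(sim / "genes.gff3"))
        for i in (1, 2)
    ]
    return {"config": cfg, "genome": genome, "truth": truth,
            "library": library, "genes": genes, "root": root,
            "sim_dir": sim, "run_dirs": [root / "run1", root / "run2"],
            "manifests": manifests}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def planted_genome(rng):
    """50-kb random background with one exact planted LTR pair and TSD."""
    ltr = random_dna(rng, 500)
    internal = random_dna(rng, 5000)
    tsd = "ACGTA"
    left, right = random_dna(rng, 20000), random_dna(rng, 24000)
    seq = left + tsd + ltr + internal + ltr + tsd + right
    truth = {
        "ltr5": (len(left) + 5, len(left) + 5 + 500),
        "ltr3": (len(left) + 5 + 5500, len(left) + 5 + 6000),
        "ltr": ltr, "internal": internal, "tsd": tsd,
    }
    return GenomeSequence("chr1", seq), truth
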