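import numpy as np
import pytest

from koalamhc.fixtures import load_fixture_tables
from koalamhc.genotype import genotype_individual
from koalamhc.loci import Allele, ReferenceDatabase, default_loci, load_reference
from koalamhc.reads import process_pairs, read_fastq_pairs
from koalamhc.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def loci():
    return default_loci()


@pytest.fixture(scope="session")
def loci_by_name(loci):
    return {s.name: s for s in loci}


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


def random_interior(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def toy_db(loci):
    """Small synthetic reference: three alleles per locus, fixed seed."""
    rng = np.random.default_rng(7)
    db = ReferenceDatabase(loci)
    for spec in loci:
        for i in range(3):
            label = f"{i + 1:02d}:01" if spec.mhc_class == "I" else f"{i + 1:02d}"
            db.add(Allele(spec.name, label, random_interior(rng, spec.interior_length)))
    return db


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory, loci):
    """One small simulated dataset shared across tests (2 trios, 2 pairs)."""
    outdir = tmp_path_factory.mktemp("sim")
    config = SimConfig(seed=11, n_trios=2, n_pairs=2, depth_per_locus=200)
    truth = simulate_dataset(config, outdir)
    return config, truth, outdir


@pytest.fixture(scope="session")
def small_sim_profiles(small_sim):
    """Genotyped profiles for the small simulated dataset."""
    config, truth, outdir = small_sim
    db, _ = load_reference(outdir / "reference.fasta", config.loci)
    profiles = {}
    for ind in truth.visible_individuals():
        merged, _ = process_pairs(
            read_fastq_pairs(
                outdir / f"{ind}_R1.fastq.gz", outdir / f"{ind}_R2.fastq.gz"
            ),
            config.loci,
        )
        profile, _ = genotype_individual(merged, db, ind)
        profiles[ind] = profile
    return profiles
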