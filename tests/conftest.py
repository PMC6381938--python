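import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import novallele as nv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_db() -> nv.GermlineDatabase:
    """Synthetic germline database: 2 families x 3 genes x 2 alleles."""
    return nv.random_germline_database(
        n_families=2, genes_per_family=3, alleles_per_gene=2, seed=1
    )


@pytest.fixture(scope="session")
def het_subject(small_db):
    """A simulated subject heterozygous at one gene with a novel allele.

    Returns (public db, novel allele, repertoire assigned against the
    public db, truth table).
    """
    novel = nv.inject_snps(small_db["SIMV1-1*01"], 3, 7)
    simdb = small_db.copy()
    simdb.add(novel)
    cfg = nv.SimConfig(
        db=simdb,
        genotype={
            "SIMV1-1": {"SIMV1-1*01": 0.5, novel.full_name: 0.5},
            "SIMV1-2": {"SIMV1-2*01": 1.0},
        },
        sequences_per_gene=1000,
        seed=42,
    )
    rep, truth = nv.simulate_repertoire(cfg)
    rep = nv.filter_input(rep)
    rep = nv.reassign_all(rep, small_db)
    return small_db, novel, rep, truth
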