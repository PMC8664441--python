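import numpy as np
import pandas as pd
import pytest

from diplokit.formats import PedigreeTable
from diplokit.simulate import preset, simulate_cross, simulate_reads


@pytest.fixture(scope="session")
def small_clean():
    """Small error-free scenario: truth, sync counts, pipeline inputs."""
    cfg = preset(
        "clean", seed=11, n_loci=4, family_sizes=(20, 20),
        locus_length_mean=300, locus_length_sd=30,
    )
    truth = simulate_cross(cfg)
    sync = simulate_reads(truth)
    return truth, sync


@pytest.fixture(scope="session")
def small_noisy():
    """Small scenario with the full noise stack (error, overmerging, bias)."""
    cfg = preset(
        "study", seed=7, n_loci=5, family_sizes=(25, 25),
        locus_length_mean=350, locus_length_sd=40,
    )
    truth = simulate_cross(cfg)
    sync = simulate_reads(truth)
    return truth, sync


def make_pedigree(n_per_family=(3, 3), sexes=None):
    """Tiny pedigree for unit tests."""
    rows = [
        ("sire", "F0", "grandsire_Bv", pd.NA, "male"),
        ("dam", "F0", "granddam_Bb", pd.NA, "female"),
        ("dad", "F1", "F1_father", pd.NA, "male"),
        ("mum6", "F1", "F1_mother", 6, "female"),
        ("mum7", "F1", "F1_mother", 7, "female"),
    ]
    k = 0
    for fam, n in zip((6, 7), n_per_family):
        for i in range(n):
            sex = sexes[k] if sexes else "unknown"
            rows.append((f"o{k}", "F2", "offspring", fam, sex))
            k += 1
    df = pd.DataFrame(rows, columns=["sample_id", "generation", "role", "family", "sex"])
    df["family"] = df["family"].astype("Int64")
    return PedigreeTable(df)


@pytest.fixture
def tiny_pedigree():
    return make_pedigree()
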