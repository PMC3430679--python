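import numpy as np
import pytest

from lethalscan import synthetic_data as sd


@pytest.fixture(scope="session")
def marker_map():
    return sd.random_marker_map(seed=1)


@pytest.fixture(scope="session")
def planted_genotypes(marker_map):
    """Six cases homozygous for a planted 2.46 Mb haplotype, 100 phased controls."""
    cfg = sd.PopulationConfig(seed=2, carrier_freq=0.0)
    return sd.simulate_genotypes(cfg, marker_map)


@pytest.fixture(scope="session")
def dd_reads():
    """Mate pairs of a homozygous-deletion individual (3,329 bp deletion, 30x)."""
    return sd.simulate_matepairs(sd.ReadSimConfig(seed=3), "D/D")


@pytest.fixture(scope="session")
def wt_reads():
    """Control (+/+) mate pairs over the same window, for insert-model fitting."""
    return sd.simulate_matepairs(sd.ReadSimConfig(seed=4), "+/+")


@pytest.fixture(scope="session")
def fanci_case():
    return sd.fanci_like_case(seed=0)


def tiny_genotype_matrix(case_rows, control_haps=None, positions=None):
    """Hand-built single-chromosome GenotypeMatrix for oracle-scale tests."""
    case_rows = np.asarray(case_rows, dtype=np.int8)
    n_cases, m = case_rows.shape
    pos = np.asarray(positions if positions is not None else np.arange(1, m + 1) * 1000)
    markers = sd.MarkerMap(
        chrom=np.array(["1"] * m, dtype=object),
        pos=pos,
        ids=np.array([f"m{j}" for j in range(m)], dtype=object),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["C"] * m, dtype=object),
    )
    haps = None if control_haps is None else np.asarray(control_haps, dtype=np.int8)
    n_controls = 0 if haps is None else haps.shape[0] // 2
    geno = case_rows
    sample_ids = [f"case_{i}" for i in range(n_cases)]
    if haps is not None:
        ctrl_geno = haps[0::2] + haps[1::2]
        geno = np.vstack([case_rows, ctrl_geno])
        sample_ids += [f"control_{i}" for i in range(n_controls)]
    return sd.GenotypeMatrix(
        markers=markers,
        sample_ids=sample_ids,
        case_ids=[f"case_{i}" for i in range(n_cases)],
        genotypes=geno.astype(np.int8),
        control_haplotypes=haps,
    )
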