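import numpy as np
import pandas as pd
import pytest

from forgen import simulate


def manual_map(positions_cm, chrom="chr1", cm_per_mb=1.0):
    """MarkerMap with markers at explicit cM positions (constant-rate map)."""
    pos_bp = [int(round(c * 1e6 / cm_per_mb)) or 1 for c in positions_cm]
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": pos_bp,
            "pos_cM": positions_cm,
            "allele_A": "A",
            "allele_B": "G",
        }
    )
    return simulate.MarkerMap(
        chromosomes=((chrom, max(pos_bp) + 1),), markers=markers, cm_per_mb=cm_per_mb
    )


@pytest.fixture(scope="session")
def two_chrom_map():
    """Two 100 Mbp chromosomes, 50 markers each, 1 cM/Mb."""
    return simulate.build_marker_map(2, 50, 100_000_000, 1.0, seed=11)


@pytest.fixture(scope="session")
def f2_population(two_chrom_map):
    """Large single-locus F2: recessive causal locus mid-chromosome 1."""
    cross = simulate.CrossSpec(
        causal_loci=(simulate.CausalLocus("chr1", 50_000_000),), n_f2=10_000, seed=5
    )
    return simulate.simulate_f2(two_chrom_map, cross)


@pytest.fixture(scope="session")
def mutant_bulk(two_chrom_map, f2_population):
    return simulate.select_mutant_bulk(f2_population, 54, seed=7)
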