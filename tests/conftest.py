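"""Shared builders for small in-memory fixtures."""

import numpy as np
import pytest

from haplodate.io import (GenotypeDataset, HaplotypePanel, MarkerMap,
                          make_sample_table)


def make_markers(n, chrom="1", bp_step=100_000, cm_step=0.1,
                 alleles=("A", "C"), start_bp=1):
    """Evenly spaced markers on one chromosome."""
    return MarkerMap(
        chrom=[chrom] * n,
        ids=[f"{chrom}_m{j}" for j in range(n)],
        bp=start_bp + bp_step * np.arange(n),
        cm=cm_step * np.arange(n, dtype=float),
        allele1=[alleles[0]] * n,
        allele2=[alleles[1]] * n,
    )


def make_dataset(genotypes, breeds=None, clades=None, markers=None, **marker_kw):
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    markers = markers or make_markers(m, **marker_kw)
    breeds = breeds or ["B"] * n
    ids = [f"{b}_{i}" for i, b in enumerate(breeds)]
    return GenotypeDataset(markers, make_sample_table(ids, breeds, clades), g)


def make_panel(haplotypes, breeds=None, clades=None, markers=None, **marker_kw):
    h = np.asarray(haplotypes, dtype=np.int8)
    n2, m = h.shape
    assert n2 % 2 == 0
    n = n2 // 2
    markers = markers or make_markers(m, **marker_kw)
    breeds = breeds or ["B"] * n
    ids = [f"{b}_{i}" for i, b in enumerate(breeds)]
    return HaplotypePanel(markers, make_sample_table(ids, breeds, clades), h)


@pytest.fixture
def markers4():
    return make_markers(4)
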