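import numpy as np
import pytest

from citrus_snp.genotype_io import GenotypeMatrix, PopulationScheme, TOKEN_TO_CODE
from citrus_snp.synthetic_data import simulate_dataset
from citrus_snp.marker_classification import classify_all, select_valid


def gm_from_tokens(rows: dict[str, list[str]],
                   locus_ids: list[str] | None = None) -> GenotypeMatrix:
    """Build a small genotype matrix from token lists keyed by accession."""
    accs = list(rows)
    n_loc = len(next(iter(rows.values())))
    loci = locus_ids or [f"L{j}" for j in range(n_loc)]
    calls = np.array([[TOKEN_TO_CODE[t] for t in rows[a]] for a in accs],
                     dtype=np.int8)
    return GenotypeMatrix(accs, loci, calls)


@pytest.fixture(scope="session")
def default_ds():
    """The default synthetic scenario (seed 42): 4 divergent taxa,
    hybrid clones, null-prone loci, 52 F1 progeny, haploid control."""
    return simulate_dataset()


@pytest.fixture(scope="session")
def default_classified(default_ds):
    ds = default_ds
    cls = classify_all(ds.genotypes, ds.scheme,
                       ds.config.discovery_accession,
                       haploid_control=ds.config.haploid_control_name)
    markers = select_valid(cls, ds.genotypes, max_missing=0.05)
    return cls, markers


@pytest.fixture(scope="session")
def wona_loci(default_classified):
    _, markers = default_classified
    return [m.locus_id for m in markers if m.valid_set == "WONA"]


@pytest.fixture(scope="session")
def wna_loci(default_classified):
    _, markers = default_classified
    return [m.locus_id for m in markers if m.valid_set == "WNA"]


@pytest.fixture(scope="session")
def germplasm_ids(default_ds):
    sch = default_ds.scheme
    return [a for a in sch.germplasm
            if a != default_ds.config.haploid_control_name]
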