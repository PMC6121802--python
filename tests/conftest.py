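import warnings

import pytest

import evoparallel as ep
from evoparallel.mutation_io import assign_all_contexts
from evoparallel.pipeline import profiles_from_records
from evoparallel.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic experiment at study-default settings."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Curated records, profile matrix, and Bray-Curtis matrix for the default dataset."""
    ds = default_dataset
    records = assign_all_contexts(ds.records, ds.genes)
    retained, report, matrix = profiles_from_records(records, ds.design.populations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = ep.pairwise_matrix(matrix, "bray_curtis")
    return {
        "dataset": ds,
        "records": records,
        "retained": retained,
        "report": report,
        "matrix": matrix,
        "sim": sim,
    }


@pytest.fixture()
def toy_genes():
    """Three well-separated forward/reverse genes on one replicon."""
    return [
        ep.GeneAnnotation("g1", "chr", 1000, 1900, "+"),
        ep.GeneAnnotation("g2", "chr", 3000, 3900, "-"),
        ep.GeneAnnotation("g3", "chr", 6000, 6900, "+", operon_id="op1"),
    ]


def make_record(pop="P1", replicon="chr", position=1500, mtype="snp",
                coding="nonsynonymous", locus="", freq=0.5):
    return ep.MutationRecord(
        pop, replicon, position, ep.MutationType(mtype),
        ep.CodingClass(coding), locus, freq,
    )
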