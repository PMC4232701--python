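import numpy as np
import pytest
from hypothesis import settings

from famscan.seqkit import MsAlignment
from famscan.synthdata import SimConfig

settings.register_profile("deterministic", derandomize=True,
                          database=None, deadline=None)
settings.load_profile("deterministic")

#: 4-tip species tree used by the scaled-down simulation fixtures.
SMALL_TREE = "((spA:0.08,spB:0.10):0.10,(spC:0.12,spD:0.06):0.08);"


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced synthetic-family configuration for fast module tests."""
    return SimConfig(species_tree_newick=SMALL_TREE, root_length=200,
                     tail_len=30, n_motif_cols=8, exons_per_gene=2,
                     min_exon_aa=20, lambda_dup=0.0, lambda_loss=0.0,
                     n_decoy_contigs=1, decoy_contig_len=500)


@pytest.fixture(scope="session")
def labeled_alignment() -> MsAlignment:
    """A small hand-written labeled alignment with gaps and two subfamilies."""
    rows = [
        ("a1", "ACDEFGHIK-"),
        ("a2", "ACDEFGH-KL"),
        ("a3", "ACDDFGHIKL"),
        ("b1", "MNPQRSTVW-"),
        ("b2", "MNPQRS-VWY"),
        ("b3", "MNPQKSTVWY"),
    ]
    labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    return MsAlignment(rows, labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140215)
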