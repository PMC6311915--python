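import numpy as np
import pytest

from csprv import (
    ExpressionMatrix,
    RegulatoryNetwork,
    make_benchmark,
)


@pytest.fixture
def tiny_network() -> RegulatoryNetwork:
    """Five-node network exercising all five edge types.

    g1 <-> g2 (mRNA-mRNA), t1 -> g1 (TF-mRNA), m1 -> g1 (miRNA-mRNA),
    m1 -> t1 (miRNA-TF), t1 -> m2 (TF-miRNA); g3 isolated.
    """
    nodes = {"g1": "mRNA", "g2": "mRNA", "g3": "mRNA",
             "t1": "TF", "m1": "miRNA", "m2": "miRNA"}
    edges = {
        ("g1", "g2", "mRNA-mRNA"), ("g2", "g1", "mRNA-mRNA"),
        ("t1", "g1", "TF-mRNA"),
        ("m1", "g1", "miRNA-mRNA"),
        ("m1", "t1", "miRNA-TF"),
        ("t1", "m2", "TF-miRNA"),
    }
    return RegulatoryNetwork(nodes, edges)


@pytest.fixture
def tiny_expression(tiny_network):
    """Standardized-looking expression aligned with tiny_network (3 samples)."""
    rng = np.random.default_rng(7)
    gene_ids = ["g1", "g2", "g3", "t1"]
    mirna_ids = ["m1", "m2"]
    samples = ["s1", "s2", "s3"]
    gene = ExpressionMatrix(rng.standard_normal((4, 3)), gene_ids, samples,
                            "gene", standardized=True)
    mirna = ExpressionMatrix(rng.standard_normal((2, 3)), mirna_ids, samples,
                             "mirna", standardized=True)
    return gene, mirna


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory):
    """Default synthetic benchmark bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bench")
    truth = make_benchmark(out, seed=0)
    return out, truth
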