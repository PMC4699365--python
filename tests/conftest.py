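import pytest
from hypothesis import settings

from screenminer import (
    ObjectKind,
    PropertyGraph,
    Role,
    SyntheticScreenTruth,
    generate_screen,
    import_label_file,
    import_screen_file,
)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_graph():
    """Two genes, five cells with len/width features, one hit label."""
    g = PropertyGraph()
    g.register_kind(ObjectKind("Gene", Role.GROUPING))
    g.register_kind(ObjectKind("Cell", Role.DESCRIPTIVE))
    g1 = g.add_node("Gene", [("geneID", "g1")])
    g2 = g.add_node("Gene", [("geneID", "g2")])
    cells = [
        ("c1", g1, {"len": 1.0, "width": 4.0}),
        ("c2", g1, {"len": 2.0, "width": 5.0}),
        ("c3", g1, {"len": 3.0, "width": 6.0}),
        ("c4", g2, {"len": 10.0, "width": 1.0}),
        ("c5", g2, {"len": 20.0}),  # width missing
    ]
    for cid, gene, props in cells:
        nid = g.add_node("Cell", [("cellID", cid)], props)
        g.connect(nid, gene, "BELONGS_TO")
    g.register_feature("Cell", "width")
    g.set_labels("Gene", ("g1",), {"hit": 1})
    g.set_labels("Gene", ("g2",), {"hit": 0})
    return g


@pytest.fixture(scope="session")
def screen(tmp_path_factory):
    """A small generated screen with missing values, imported with labels."""
    out = tmp_path_factory.mktemp("screen")
    truth = SyntheticScreenTruth.default(
        n_genes=12, cells_per_gene=25, n_features=4, n_hits=3,
        effect_size=2.0, seed=11, missing_rate=0.05)
    generated = generate_screen(truth, out)
    graph = import_screen_file(generated.data_path, "Gene", "Cell")
    import_label_file(generated.label_path, graph)
    return generated, graph
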