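import numpy as np
import pytest

from photoperiod_expr.io_tables import (
    DEFAULT_DESIGN,
    AnnotationMap,
    ExpressionMatrix,
)


@pytest.fixture
def design():
    return DEFAULT_DESIGN


@pytest.fixture
def design_file(tmp_path):
    rows = ["label\tphase\thour"] + [
        f"{p.label}\t{p.phase}\t{p.hour}" for p in DEFAULT_DESIGN.points
    ]
    path = tmp_path / "design.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def small_matrix(design):
    """Three genes with distinct temporal behavior."""
    values = np.array(
        [
            [1.0, 3.0, 2.0, 5.0, 5.0, 5.0, 4.0],
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            [0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        ]
    )
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"], values=values, design=design
    )


@pytest.fixture
def tiny_annotations():
    return AnnotationMap(
        assignments={
            "g1": frozenset({"GO:A", "GO:B"}),
            "g2": frozenset({"GO:A"}),
            "g3": frozenset({"GO:B"}),
        },
        universe={"g1", "g2", "g3", "g4"},
    )
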