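"""Expression I/O, normalization and marker-panel parsing."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from branchtime import (
    ExpressionMatrix,
    ValidationError,
    normalize,
    parse_marker_panel,
    read_expression,
    write_expression,
)
from branchtime.data import build_marker_panel, write_marker_panel


@pytest.fixture
def csv_matrix(tmp_path):
    df = pd.DataFrame([[0.0, 1.5], [2.0, 0.5], [1.0, 3.0]],
                      index=["c1", "c2", "c3"], columns=["g1", "g2"])
    path = tmp_path / "expr.csv"
    df.to_csv(path)
    return path, df


def test_read_csv_shape_and_names(csv_matrix):
    path, df = csv_matrix
    m = read_expression(path)
    assert (m.n_cells, m.n_genes) == (3, 2)
    assert m.cell_ids == ["c1", "c2", "c3"]
    assert m.gene_ids == ["g1", "g2"]
    assert not m.normalized
    np.testing.assert_allclose(m.values, df.to_numpy())


def test_csv_round_trip(tmp_path, csv_matrix):
    path, _ = csv_matrix
    m = read_expression(path)
    out = tmp_path / "rt.csv"
    write_expression(m, out)
    m2 = read_expression(out)
    np.testing.assert_allclose(m.values, m2.values, atol=1e-12)


def test_mtx_matches_csv(tmp_path, csv_matrix):
    """Cross-format equality: the MTX reader reproduces the CSV content."""
    path, df = csv_matrix
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(tmp_path / "expr.mtx", csr_matrix(df.to_numpy()))
    (tmp_path / "expr.rows").write_text("\n".join(df.index) + "\n")
    (tmp_path / "expr.cols").write_text("\n".join(df.columns) + "\n")
    m_csv = read_expression(path)
    m_mtx = read_expression(tmp_path / "expr.mtx")
    np.testing.assert_allclose(m_csv.values, m_mtx.values)
    assert m_csv.cell_ids == m_mtx.cell_ids
    assert m_csv.gene_ids == m_mtx.gene_ids


def test_h5ad_round_trip(tmp_path, csv_matrix):
    import anndata as ad

    path, df = csv_matrix
    adata = ad.AnnData(df.to_numpy(), obs=pd.DataFrame(index=df.index),
                       var=pd.DataFrame(index=df.columns))
    adata.write_h5ad(tmp_path / "expr.h5ad")
    m = read_expression(tmp_path / "expr.h5ad")
    np.testing.assert_allclose(m.values, df.to_numpy())


def test_negative_entry_rejected(tmp_path):
    pd.DataFrame([[0.2, -1.0]], index=["c1"], columns=["g1", "g2"]).to_csv(
        tmp_path / "neg.csv")
    with pytest.raises(ValidationError, match="g2"):
        read_expression(tmp_path / "neg.csv")


def test_nan_entry_rejected():
    with pytest.raises(ValidationError, match="NaN"):
        ExpressionMatrix(np.array([[np.nan]]), ["c"], ["g"])


def test_missing_file_is_io_error():
    with pytest.raises(IOError, match="nope.csv"):
        read_expression("nope.csv")


def test_duplicate_gene_ids_rejected():
    with pytest.raises(ValidationError, match="duplicate gene"):
        ExpressionMatrix(np.ones((1, 2)), ["c"], ["g", "g"])


def test_duplicate_cell_ids_suffixed():
    with pytest.warns(UserWarning, match="duplicate cell"):
        m = ExpressionMatrix(np.ones((2, 1)), ["c", "c"], ["g"])
    assert m.cell_ids == ["c", "c.1"]


def test_transpose_flag(tmp_path):
    df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=["c1", "c2", "c3"])
    df.to_csv(tmp_path / "t.csv")
    m = read_expression(tmp_path / "t.csv", transpose=True)
    assert m.cell_ids == ["c1", "c2", "c3"]
    assert m.gene_ids == ["g1"]


class TestNormalize:
    def test_hand_computed_column(self):
        # log1p([0, e-1, e^2-1]) = [0, 1, 2] -> min-max -> [0, 1/2, 1]
        m = ExpressionMatrix(np.array([[0.0], [np.e - 1], [np.e**2 - 1]]),
                             ["a", "b", "c"], ["g"])
        out = normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0], atol=1e-12)
        assert out.normalized and not m.normalized

    def test_constant_gene_maps_to_zero_with_warning(self):
        m = ExpressionMatrix(np.full((3, 1), 5.0), list("abc"), ["g"])
        with pytest.warns(UserWarning, match="constant gene"):
            out = normalize(m)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_double_normalize_rejected(self, toy_matrix):
        with pytest.raises(ValidationError, match="already normalized"):
            normalize(toy_matrix)

    def test_original_unmodified(self):
        vals = np.array([[0.0], [1.0], [3.0]])
        m = ExpressionMatrix(vals.copy(), list("abc"), ["g"])
        normalize(m)
        np.testing.assert_array_equal(m.values, vals)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.5, 50.0), shift=st.floats(0.0, 10.0),
           seed=st.integers(0, 1000))
    def test_unit_range_under_affine_rescaling(self, scale, shift, seed):
        """Any increasing affine map of the raw column still lands on [0,1]
        with both endpoints attained."""
        rng = np.random.default_rng(seed)
        col = rng.uniform(0.0, 5.0, 8)
        col[0], col[1] = 0.0, 5.0  # guarantee non-constant
        m = ExpressionMatrix((scale * col + shift)[:, None],
                             [f"c{i}" for i in range(8)], ["g"])
        out = normalize(m).values[:, 0]
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.all((out >= 0) & (out <= 1))


class TestMarkerPanel:
    def test_yaml_parse(self, tmp_path, toy_matrix):
        (tmp_path / "p.yaml").write_text(
            "branches: [A, B]\nmarkers:\n  g1: A\n  g2: B\n")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            panel = parse_marker_panel(tmp_path / "p.yaml", toy_matrix)
        assert panel.K == 2
        assert panel.marker_map["g1"] == frozenset({1})
        assert panel.marker_map["g2"] == frozenset({2})

    def test_multi_branch_marker(self):
        spec = {"branches": ["A", "B", "C"],
                "markers": {"g1": ["A", "B"], "g2": "C", "g3": ["A", "B", "C"]}}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            panel = build_marker_panel(spec)
        assert panel.marker_map["g1"] == frozenset({1, 2})
        mask = panel.switch_mask(["g1", "g2", "g3"])
        assert mask[0].tolist() == [True, True, False]

    def test_unknown_gene_rejected(self, tmp_path, toy_matrix):
        (tmp_path / "p.json").write_text(
            '{"branches": ["A", "B"], "markers": {"gX": "A", "g2": "B"}}')
        with pytest.raises(ValidationError, match="gX"), warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            parse_marker_panel(tmp_path / "p.json", toy_matrix)

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValidationError, match="'Z'"):
            build_marker_panel({"branches": ["A"], "markers": {"g1": "Z"}})

    def test_branch_without_markers_rejected(self):
        with pytest.raises(ValidationError, match="no marker"):
            build_marker_panel({"branches": ["A", "B"], "markers": {"g1": "A"}})

    def test_few_markers_warns(self):
        with pytest.warns(UserWarning, match="at least four"):
            build_marker_panel({"branches": ["A"], "markers": {"g1": "A"}})

    def test_write_round_trip(self, tmp_path):
        spec = {"branches": ["A", "B"],
                "markers": {"g1": ["A"], "g2": ["B"], "g3": ["A", "B"]}}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            panel = build_marker_panel(spec)
            write_marker_panel(panel, tmp_path / "out.yaml")
            panel2 = parse_marker_panel(tmp_path / "out.yaml")
        assert panel2.marker_map == panel.marker_map
        assert panel2.branch_names == panel.branch_names
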