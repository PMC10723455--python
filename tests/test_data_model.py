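import numpy as np
import pytest

from sccycle.data_model import (
    ExpressionDataset,
    TimepointGrouping,
    load_dataset,
    subset,
    write_dataset,
)
from sccycle.errors import (
    EmptySelectionError,
    IdentityMismatchError,
    UnknownLabelError,
    ValidationError,
)
from sccycle.synthetic_data import simulate_flat_dataset


@pytest.mark.parametrize("dialect", ["mtx+tsv", "csv"])
def test_write_load_round_trip_is_identity(tmp_path, dialect, noiseless_ds):
    ds = noiseless_ds
    ds.values[0, 0] = 1.0 / 3.0  # value without a short decimal expansion
    ext = "mtx" if dialect == "mtx+tsv" else "csv"
    matrix = tmp_path / f"m.{ext}"
    meta = tmp_path / "meta.tsv"
    write_dataset(ds, matrix, meta, dialect=dialect)
    back = load_dataset(matrix, meta, dialect=dialect)
    assert np.array_equal(back.values, ds.values)
    assert back.gene_ids == ds.gene_ids
    assert back.cell_ids == ds.cell_ids
    assert np.array_equal(back.timepoints, ds.timepoints)
    assert back.clusters.tolist() == ds.clusters.tolist()


def test_load_small_csv_fixture(tmp_path):
    matrix = tmp_path / "m.csv"
    matrix.write_text(",c1,c2,c3,c4\ng1,1,2,3,4\ng2,0,0,1,1\ng3,5,5,5,5\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "cell_id\ttimepoint\tcluster\tcondition\n"
        "c1\t0\tx\tLD\nc2\t0\tx\tLD\nc3\t12\tx\tLD\nc4\t12\tx\tLD\n"
    )
    ds = load_dataset(matrix, meta, dialect="csv")
    assert ds.values.shape == (3, 4)
    assert len(ds.distinct_timepoints()) == 2


def test_metadata_cell_absent_from_matrix_is_identity_mismatch(tmp_path):
    matrix = tmp_path / "m.csv"
    matrix.write_text(",c1,c2\ng1,1,2\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "cell_id\ttimepoint\tcluster\tcondition\n"
        "c1\t0\tx\tLD\nmissing\t12\tx\tLD\n"
    )
    with pytest.raises(IdentityMismatchError):
        load_dataset(matrix, meta, dialect="csv")


def test_metadata_order_defines_cell_order(tmp_path):
    matrix = tmp_path / "m.csv"
    matrix.write_text(",c1,c2\ng1,1.0,2.0\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "cell_id\ttimepoint\tcluster\tcondition\nc2\t12\tx\tLD\nc1\t0\tx\tLD\n"
    )
    ds = load_dataset(matrix, meta, dialect="csv")
    assert ds.cell_ids == ["c2", "c1"]
    assert ds.values[0].tolist() == [2.0, 1.0]


@pytest.mark.parametrize(
    "mutate",
    [
        lambda d: d["values"].__setitem__((0, 0), -1.0),
        lambda d: d["values"].__setitem__((0, 0), np.nan),
        lambda d: d.update(gene_ids=["a", "a", "c"]),
        lambda d: d.update(timepoints=np.array([0.0, -1.0, 12.0, 12.0])),
    ],
)
def test_invalid_datasets_are_rejected(mutate):
    kwargs = dict(
        values=np.ones((3, 4)),
        gene_ids=["a", "b", "c"],
        cell_ids=["c1", "c2", "c3", "c4"],
        timepoints=np.array([0.0, 0.0, 12.0, 12.0]),
        clusters=np.array(["x"] * 4, dtype=object),
        condition=np.array(["LD"] * 4, dtype=object),
    )
    mutate(kwargs)
    with pytest.raises(ValidationError):
        ExpressionDataset(**kwargs)


def test_unknown_dialect_is_usage_error(tmp_path):
    with pytest.raises(ValidationError):
        load_dataset(tmp_path / "x", tmp_path / "y", dialect="loom")


class TestSubset:
    def test_identity_filter_keeps_everything(self, noiseless_ds):
        res = subset(noiseless_ds)
        assert res.dataset.n_cells == noiseless_ds.n_cells
        assert res.flagged_timepoints == []

    def test_cluster_filter_counts(self):
        ds = simulate_flat_dataset(5, 1, 4, n_timepoints=4, reps=5, seed=0)
        ds.clusters[:10] = "A"
        ds.clusters[10:] = "B"
        res = subset(ds, cluster="A")
        assert res.dataset.n_cells == 10
        assert res.dataset.gene_ids == ds.gene_ids

    def test_underpopulated_timepoint_is_flagged(self, tiny_ds):
        res = subset(tiny_ds, cluster="x", min_cells_per_timepoint=2)
        assert res.flagged_timepoints == [12.0]

    def test_idempotence(self, noiseless_ds):
        once = subset(noiseless_ds, cluster="neurons").dataset
        twice = subset(once, cluster="neurons").dataset
        assert np.array_equal(once.values, twice.values)
        assert once.cell_ids == twice.cell_ids

    def test_unknown_label(self, noiseless_ds):
        with pytest.raises(UnknownLabelError):
            subset(noiseless_ds, cluster="nope")

    def test_empty_selection(self, tiny_ds):
        with pytest.raises(EmptySelectionError):
            subset(tiny_ds, cluster="x", condition="DD")


def test_timepoint_grouping_partitions_cells(noiseless_ds):
    grouping = TimepointGrouping.from_dataset(noiseless_ds)
    assert np.all(np.diff(grouping.timepoints) > 0)
    joined = np.sort(np.concatenate(grouping.groups))
    assert np.array_equal(joined, np.arange(noiseless_ds.n_cells))
    assert (grouping.sizes >= 1).all()
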