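import numpy as np
import pytest

from sccycle.data_model import ExpressionDataset


def make_noiseless_dataset(
    n_cycling=5,
    n_flat=5,
    n_timepoints=6,
    reps=4,
    spacing=4.0,
    period=24.0,
    cluster="neurons",
):
    """Deterministic fixture: every cell at a timepoint carries the exact
    same value, so subsampling cannot change any detector's answer.

    Cycling genes are cosines with staggered phases and mesor 10;
    flat genes are nonzero constants.
    """
    t_grid = spacing * np.arange(n_timepoints)
    times = np.repeat(t_grid, reps)
    rows = []
    gene_ids = []
    for i in range(n_cycling):
        phase = period * i / max(n_cycling, 1)
        rows.append(10.0 + 5.0 * np.cos(2 * np.pi * (times - phase) / period))
        gene_ids.append(f"cyc{i}")
    for i in range(n_flat):
        rows.append(np.full(times.size, 3.0 + i))
        gene_ids.append(f"flat{i}")
    n_cells = times.size
    return ExpressionDataset(
        values=np.array(rows),
        gene_ids=gene_ids,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        timepoints=times,
        clusters=np.array([cluster] * n_cells, dtype=object),
        condition=np.array(["LD"] * n_cells, dtype=object),
    )


@pytest.fixture
def noiseless_ds():
    return make_noiseless_dataset()


@pytest.fixture
def tiny_ds():
    """3 genes x 4 cells, 2 timepoints, 2 clusters."""
    return ExpressionDataset(
        values=np.array(
            [[1.0, 3.0, 0.0, 2.0], [0.5, 0.5, 0.5, 0.5], [0.0, 1.0, 2.0, 3.0]]
        ),
        gene_ids=["a", "b", "c"],
        cell_ids=["c1", "c2", "c3", "c4"],
        timepoints=np.array([0.0, 0.0, 12.0, 12.0]),
        clusters=np.array(["x", "x", "x", "y"], dtype=object),
        condition=np.array(["LD", "LD", "LD", "DD"], dtype=object),
    )
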