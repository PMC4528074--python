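"""Reading and writing time-course matrices and edge tables.

Matrices travel as delimited text (CSV or TSV, one header row of node
labels, rows are time samples); an HDF5 container is available for large
recordings (datasets ``values`` plus attributes ``node_labels`` and
``sampling_rate``).  The format is inferred from the file extension.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["read_timecourses", "write_timecourses", "write_edge_table", "read_edge_list"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_timecourses(path):
    """Load a samples × nodes matrix.  Returns ``(values, node_labels)``."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            values = fh["values"][...]
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in fh["values"].attrs.get("node_labels", [])
            ]
        if not labels:
            labels = [f"node_{i}" for i in range(values.shape[1])]
        return np.asarray(values, dtype=float), labels
    df = pd.read_csv(path, sep=_sep_for(path))
    return df.to_numpy(dtype=float), list(df.columns)


def write_timecourses(path, values, node_labels=None, sampling_rate=None):
    """Write a samples × nodes matrix in the format implied by the extension."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ParameterError("expected a 2-D samples × nodes matrix")
    if node_labels is None:
        node_labels = [f"node_{i}" for i in range(values.shape[1])]
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("values", data=values)
            ds.attrs["node_labels"] = [str(s) for s in node_labels]
            if sampling_rate is not None:
                ds.attrs["sampling_rate"] = float(sampling_rate)
        return
    pd.DataFrame(values, columns=[str(s) for s in node_labels]).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_edge_table(path, edge_df: pd.DataFrame):
    """Write a (node_i, node_j, r, z, survives_fdr) edge table as text."""
    path = Path(path)
    edge_df.to_csv(path, sep=_sep_for(path), index=False)


def read_edge_list(path):
    """Read a two-column whitespace-delimited edge list into a set of pairs."""
    pairs = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()[:2]
        pairs.add((int(a), int(b)))
    return pairs
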