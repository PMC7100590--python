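"""Minimal BIOM 2.1 (HDF5) feature-table reader/writer built on h5py.

Implements the subset of the BIOM 2.1 layout needed to exchange count
tables: observation/sample id datasets plus the CSR/CSC ``matrix`` groups.
Metadata groups are written empty.
"""

from __future__ import annotations

from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import MetatrackerError

_FORMAT_URL = "http://biom-format.org"


def write_biom(table, path: str | Path) -> None:
    from .tables_io import FeatureTable  # local import to avoid cycle

    assert isinstance(table, FeatureTable)
    mat = sparse.csr_matrix(table.counts.astype(np.float64))
    csc = mat.tocsc()
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = _FORMAT_URL
        h5.attrs["format-version"] = (2, 1)
        h5.attrs["generated-by"] = "metatracker"
        h5.attrs["creation-date"] = datetime.now(timezone.utc).isoformat()
        h5.attrs["shape"] = table.counts.shape
        h5.attrs["nnz"] = mat.nnz
        obs = h5.create_group("observation")
        obs.create_dataset(
            "ids", data=np.array(table.taxon_ids, dtype=h5py.string_dtype())
        )
        om = obs.create_group("matrix")
        om.create_dataset("data", data=mat.data)
        om.create_dataset("indices", data=mat.indices.astype(np.int64))
        om.create_dataset("indptr", data=mat.indptr.astype(np.int64))
        obs.create_group("metadata")
        obs.create_group("group-metadata")
        smp = h5.create_group("sample")
        smp.create_dataset(
            "ids", data=np.array(table.sample_ids, dtype=h5py.string_dtype())
        )
        sm = smp.create_group("matrix")
        sm.create_dataset("data", data=csc.data)
        sm.create_dataset("indices", data=csc.indices.astype(np.int64))
        sm.create_dataset("indptr", data=csc.indptr.astype(np.int64))
        smp.create_group("metadata")
        smp.create_group("group-metadata")


def read_biom(path: str | Path):
    from .tables_io import FeatureTable

    with h5py.File(path, "r") as h5:
        if "observation" not in h5 or "sample" not in h5:
            raise MetatrackerError(f"{path}: not a BIOM 2.x HDF5 file")
        taxa = [_as_str(x) for x in h5["observation/ids"][()]]
        samples = [_as_str(x) for x in h5["sample/ids"][()]]
        om = h5["observation/matrix"]
        mat = sparse.csr_matrix(
            (om["data"][()], om["indices"][()], om["indptr"][()]),
            shape=(len(taxa), len(samples)),
        )
    dense = np.asarray(mat.todense())
    if not np.allclose(dense, np.round(dense)):
        raise MetatrackerError(f"{path}: BIOM table holds non-integer counts")
    return FeatureTable(
        pd.DataFrame(np.round(dense).astype(np.int64), index=taxa, columns=samples)
    )


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)
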