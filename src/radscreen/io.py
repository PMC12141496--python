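"""Reading and writing the pipeline's tabular formats.

Counts travel as TSV (first column gene id, header = sample ids) or as
a MatrixMarket coordinate-integer triplet with sidecar gene/sample
index files; metadata as TSV with columns ``sample_id, donor_id, sex,
dose_gy, time_h``.  Files may carry leading ``#`` provenance comment
lines; identifiers are opaque strings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "write_table_tsv",
]

METADATA_COLUMNS = ["sample_id", "donor_id", "sex", "dose_gy", "time_h"]


def _check_unique(values, what: str, where: str) -> None:
    dupes = pd.Index(values)[pd.Index(values).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{where}: duplicate {what}(s): {dupes[:5]}")


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a gene x sample integer count TSV; '#' lines are comments."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"{path}: ragged/missing value at gene {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    _check_unique(df.index, "gene id", str(path))
    _check_unique(df.columns, "sample id", str(path))
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric count {df.iloc[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    frac = numeric.to_numpy() % 1
    if (frac != 0).any():
        r, c = np.argwhere(frac != 0)[0]
        raise ValueError(
            f"{path}: non-integer count {numeric.iloc[r, c]} at gene "
            f"{numeric.index[r]!r}, sample {numeric.columns[c]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    out = numeric.astype(np.int64)
    out.index.name = "gene"
    return out


def write_counts_tsv(counts: pd.DataFrame, path, provenance: str | None = None) -> None:
    """Write counts as TSV, optionally with a leading '#' provenance line."""
    write_table_tsv(counts, path, provenance=provenance, index_label="gene")


def write_table_tsv(
    table: pd.DataFrame, path, provenance: str | None = None, index_label=None
) -> None:
    """TSV writer used for every pipeline output (UTF-8, NA for missing)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.to_csv(fh, sep="\t", na_rep="NA", index_label=index_label)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read a sample sheet; validates columns, uniqueness, and dtypes."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing column(s) {missing}")
    _check_unique(df["sample_id"], "sample id", str(path))
    df["dose_gy"] = pd.to_numeric(df["dose_gy"], errors="raise")
    df["time_h"] = pd.to_numeric(df["time_h"], errors="raise")
    if (df["dose_gy"] < 0).any() or (df["time_h"] <= 0).any():
        raise ValueError(f"{path}: doses must be >= 0 and times > 0")
    return df[METADATA_COLUMNS]


def write_metadata_tsv(design: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        design[METADATA_COLUMNS].to_csv(fh, sep="\t", index=False)


def write_mtx_triplet(counts: pd.DataFrame, prefix) -> None:
    """Write counts as <prefix>.mtx plus <prefix>.genes.txt / .samples.txt."""
    prefix = str(prefix)
    mat = scipy.sparse.csr_matrix(counts.to_numpy(dtype=np.int64))
    scipy.io.mmwrite(prefix + ".mtx", mat, field="integer")
    Path(prefix + ".genes.txt").write_text(
        "\n".join(map(str, counts.index)) + "\n", encoding="utf-8"
    )
    Path(prefix + ".samples.txt").write_text(
        "\n".join(map(str, counts.columns)) + "\n", encoding="utf-8"
    )


def read_mtx_triplet(prefix) -> pd.DataFrame:
    """Inverse of :func:`write_mtx_triplet`."""
    prefix = str(prefix)
    mat = scipy.io.mmread(prefix + ".mtx")
    genes = Path(prefix + ".genes.txt").read_text(encoding="utf-8").splitlines()
    samples = Path(prefix + ".samples.txt").read_text(encoding="utf-8").splitlines()
    arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if arr.shape != (len(genes), len(samples)):
        raise ValueError(
            f"{prefix}.mtx shape {arr.shape} does not match index files "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    if not np.issubdtype(arr.dtype, np.integer) and (arr % 1 != 0).any():
        raise ValueError(f"{prefix}.mtx contains non-integer entries")
    _check_unique(genes, "gene id", prefix)
    _check_unique(samples, "sample id", prefix)
    return pd.DataFrame(
        arr.astype(np.int64), index=pd.Index(genes, name="gene"), columns=samples
    )
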