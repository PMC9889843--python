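"""Input/output: expression + metadata tables, preprocessing, result tables.

Expression tables follow the transcriptomics convention of genes as rows and
samples as columns (a flag transposes on read).  Metadata carries one row per
sample with columns ``sample``, ``time`` (Zeitgeber Time, hours) and
``group`` (``I`` = reference, ``II`` = comparison; the synonyms
``reference``/``comparison`` are accepted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RhythmDataset", "read_dataset", "preprocess", "write_results"]

MIN_GROUP_SIZE = 5

GROUP_ALIASES = {
    "i": "I",
    "ii": "II",
    "1": "I",
    "2": "II",
    "reference": "I",
    "comparison": "II",
}


@dataclass
class RhythmDataset:
    """A two-group rhythmic expression dataset.

    Attributes
    ----------
    values : (G, N) ndarray
        Log-scale expression, genes by samples, no missing entries.
    gene_ids : list of str
    sample_ids : list of str
    time : (N,) ndarray
        Sampling time in hours (any real scale; interpreted mod ``period``).
    group : (N,) ndarray of {"I", "II"}
        Group I is the reference, group II the comparison.
    period : float
        Rhythm period in hours (default 24).
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    time: np.ndarray = None
    group: np.ndarray = None
    period: float = 24.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes-by-samples matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.group = np.asarray(self.group, dtype=object).ravel()
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix rows")
        if not (len(self.sample_ids) == self.time.size == self.group.size == n):
            raise ValueError("sample_ids, time and group must all have length N")
        if not np.all(np.isfinite(self.time)):
            bad = [self.sample_ids[i] for i in np.where(~np.isfinite(self.time))[0]]
            raise ValueError(f"non-finite time for samples {bad}")
        norm = []
        for i, lab in enumerate(self.group):
            key = str(lab).strip().lower()
            if key not in GROUP_ALIASES:
                raise ValueError(
                    f"sample {self.sample_ids[i]!r} has group label {lab!r}; "
                    "expected I/II (or reference/comparison)"
                )
            norm.append(GROUP_ALIASES[key])
        self.group = np.asarray(norm, dtype=object)
        for lab in ("I", "II"):
            n_lab = int(np.sum(self.group == lab))
            if n_lab == 0:
                raise ValueError(f"group {lab} is empty")
            if n_lab < MIN_GROUP_SIZE:
                raise ValueError(
                    f"group {lab} has {n_lab} samples; at least {MIN_GROUP_SIZE} "
                    "are required for a per-group cosinor fit with residual df"
                )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if not self.period > 0:
            raise ValueError(f"period must be positive, got {self.period}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return self.group == group

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(str(gene))
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def gene_data(self, gene: str, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(y, t)`` for one gene restricted to one group."""
        mask = self.group_mask(group)
        return self.values[self.gene_index(gene), mask], self.time[mask]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Expression and metadata as DataFrames (round-trips through CSV)."""
        expr = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        expr.index.name = "gene"
        meta = pd.DataFrame(
            {"sample": self.sample_ids, "time": self.time, "group": self.group}
        )
        return expr, meta


def _read_table(path, sep=None) -> pd.DataFrame:
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    return pd.read_csv(path, sep=sep, index_col=0)


def read_dataset(
    expression_path,
    metadata_path,
    period: float = 24.0,
    sep: str | None = None,
    transpose: bool = False,
) -> RhythmDataset:
    """Read and validate an expression table plus its sample metadata.

    Parameters
    ----------
    expression_path, metadata_path : path-like
        CSV/TSV files (delimiter sniffed unless ``sep`` is given).  The
        expression table is genes x samples with a header row of sample ids
        and gene ids in the first column; metadata has columns ``sample``,
        ``time``, ``group`` (case-insensitive headers).
    period : float
        Rhythm period in hours.
    transpose : bool
        Set when the expression table is samples x genes.

    Returns
    -------
    RhythmDataset
        Samples reordered to match the metadata row order.  Genes with
        missing values are dropped with a logged warning.
    """
    expr = _read_table(expression_path, sep)
    if transpose:
        expr = expr.T

    meta_raw = pd.read_csv(metadata_path, sep=sep if sep is not None else None,
                           engine="python" if sep is None else "c")
    meta_raw.columns = [str(c).strip().lower() for c in meta_raw.columns]
    required = {"sample", "time", "group"}
    missing_cols = required - set(meta_raw.columns)
    if missing_cols:
        raise ValueError(f"metadata is missing columns {sorted(missing_cols)}")
    meta = meta_raw[["sample", "time", "group"]].copy()
    meta["sample"] = meta["sample"].astype(str)

    expr_samples = [str(c) for c in expr.columns]
    meta_samples = list(meta["sample"])
    only_expr = sorted(set(expr_samples) - set(meta_samples))
    only_meta = sorted(set(meta_samples) - set(expr_samples))
    if only_expr or only_meta:
        raise ValueError(
            "sample ids differ between expression and metadata: "
            f"only in expression {only_expr}, only in metadata {only_meta}"
        )

    expr.columns = expr_samples
    expr = expr[meta_samples]  # reorder to metadata order

    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & expr.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {expr.iat[r, c]!r} at "
            f"gene {expr.index[r]!r}, sample {expr.columns[c]!r}"
        )
    has_na = numeric.isna().any(axis=1)
    if has_na.any():
        logger.warning(
            "dropping %d gene(s) with missing values: %s",
            int(has_na.sum()),
            list(numeric.index[has_na][:10]),
        )
        numeric = numeric.loc[~has_na]
    if numeric.shape[0] == 0:
        raise ValueError("no genes left after dropping rows with missing values")

    time = pd.to_numeric(meta["time"], errors="coerce")
    if time.isna().any():
        bad_s = meta.loc[time.isna(), "sample"].tolist()
        raise ValueError(f"non-numeric time for samples {bad_s}")

    return RhythmDataset(
        values=numeric.to_numpy(dtype=float),
        gene_ids=list(numeric.index.astype(str)),
        sample_ids=meta_samples,
        time=time.to_numpy(dtype=float),
        group=meta["group"].to_numpy(),
        period=period,
    )


def preprocess(
    counts,
    min_prop_expressed: float = 0.5,
    normalize: bool = True,
    log_transform: bool = True,
    pseudocount: float = 1.0,
):
    """Conventional count preprocessing: expression filter, CPM, log2.

    Parameters
    ----------
    counts : DataFrame or (G, N) array
        Nonnegative counts, genes by samples.
    min_prop_expressed : float
        A gene is kept when its value is > 0 in at least this fraction of
        samples (default 0.5).
    normalize : bool
        Rescale each sample column to counts per million (column sum 1e6).
    log_transform : bool
        Apply ``log2(x + pseudocount)`` after normalization.

    Returns
    -------
    (matrix, kept_genes)
        Matrix of the same container type as the input and the surviving
        gene identifiers (row indices for plain arrays).  Sample order is
        never changed.
    """
    is_frame = isinstance(counts, pd.DataFrame)
    mat = counts.to_numpy(dtype=float) if is_frame else np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-D genes-by-samples")
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    if not 0.0 <= min_prop_expressed <= 1.0:
        raise ValueError("min_prop_expressed must be a fraction in [0, 1]")

    keep = (mat > 0).mean(axis=1) >= min_prop_expressed
    if not keep.any():
        raise ValueError("all genes removed by the expression filter")
    mat = mat[keep]

    if normalize:
        colsum = mat.sum(axis=0)
        if np.any(colsum <= 0):
            idx = int(np.argmax(colsum <= 0))
            name = counts.columns[idx] if is_frame else idx
            raise ValueError(f"sample {name!r} has zero total count; cannot CPM-normalize")
        mat = mat / colsum * 1e6
    if log_transform:
        mat = np.log2(mat + pseudocount)

    if is_frame:
        kept_genes = list(counts.index[keep])
        out = pd.DataFrame(mat, index=kept_genes, columns=counts.columns)
        return out, kept_genes
    kept_genes = list(np.where(keep)[0])
    return mat, kept_genes


def write_results(results: pd.DataFrame, path) -> None:
    """Write a result table to CSV, one row per gene, full float precision."""
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(results)
    results.to_csv(path, index=False)
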