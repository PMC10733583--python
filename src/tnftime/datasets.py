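"""Containers and plain-text IO for time-course count data.

A dataset couples three tables: an integer gene x sample count matrix, a
sample sheet (condition, time in hours, pool, sex) and per-gene metadata
(symbol, biotype, length in bp). Counts are read/written as TSV with gene
ids as the first column, or as MatrixMarket with side files for row and
column names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CONTROL = "control"
TREATED = "treated"
CONDITIONS = (CONTROL, TREATED)

SAMPLE_COLUMNS = ("condition", "time_h", "pool", "sex")
GENE_COLUMNS = ("symbol", "biotype", "length_bp")


@dataclass
class CountDataset:
    """Gene x sample integer counts with sample and gene annotations.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids,
        columns = sample ids.
    samples
        Sample sheet indexed by sample id with columns ``condition``
        ("control"/"treated"), ``time_h`` (decimal hours), ``pool``
        (replicate-pool label) and ``sex`` ("F"/"M").
    genes
        Gene metadata indexed by gene id with columns ``symbol``,
        ``biotype`` and ``length_bp``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicated gene ids in counts: {list(dups[:5])}")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            arr = self.counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count matrix contains non-integer values")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative values")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        unmatched = [s for s in self.counts.columns if s not in self.samples.index]
        if unmatched:
            raise ValueError(f"samples in counts absent from sample sheet: {unmatched}")
        # align sheet to count columns (extra sheet rows are dropped)
        self.samples = self.samples.loc[list(self.counts.columns)].copy()
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        try:
            self.samples["time_h"] = self.samples["time_h"].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                "time_h must be decimal hours; string labels are rejected"
            ) from exc
        missing_g = [g for g in self.counts.index if g not in self.genes.index]
        if missing_g:
            raise ValueError(f"genes in counts absent from gene metadata: {missing_g[:5]}")
        self.genes = self.genes.loc[list(self.counts.index)].copy()
        self.counts.index.name = "gene_id"
        self.genes.index.name = "gene_id"
        self.samples.index.name = "sample_id"

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def time_grid(self) -> np.ndarray:
        """Sorted unique time points (hours)."""
        return np.sort(self.samples["time_h"].unique())

    @property
    def sexes(self) -> list[str]:
        return sorted(self.samples["sex"].unique())

    def subset_samples(self, mask: pd.Series | Sequence[bool]) -> "CountDataset":
        keep = self.samples.index[np.asarray(mask, dtype=bool)]
        return CountDataset(
            counts=self.counts[keep].copy(),
            samples=self.samples.loc[keep].copy(),
            genes=self.genes.copy(),
        )

    def sex_subset(self, sex: str) -> "CountDataset":
        if sex not in set(self.samples["sex"]):
            raise ValueError(f"sex {sex!r} not present in sample sheet")
        return self.subset_samples((self.samples["sex"] == sex).to_numpy())

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountDataset":
        gene_ids = list(gene_ids)
        return CountDataset(
            counts=self.counts.loc[gene_ids].copy(),
            samples=self.samples.copy(),
            genes=self.genes.loc[gene_ids].copy(),
        )

    # ------------------------------------------------------------------
    def write(self, outdir: str | Path, matrix_market: bool = False) -> None:
        """Write counts.tsv (or counts.mtx + names), samples.tsv, genes.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if matrix_market:
            scipy.io.mmwrite(
                str(outdir / "counts.mtx"),
                scipy.sparse.csr_matrix(self.counts.to_numpy()),
            )
            (outdir / "counts.rownames.txt").write_text(
                "\n".join(self.counts.index) + "\n"
            )
            (outdir / "counts.colnames.txt").write_text(
                "\n".join(self.counts.columns) + "\n"
            )
        else:
            write_counts_tsv(self.counts, outdir / "counts.tsv")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample_id")
        self.genes.to_csv(outdir / "genes.tsv", sep="\t", index_label="gene_id")


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV count matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicated gene id(s) in {path}: {list(dups[:5])}")
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"non-integer count values in {path}")
    return df.round().astype(np.int64)


def read_counts_mtx(path: str | Path) -> pd.DataFrame:
    """Read MatrixMarket counts with .rownames.txt / .colnames.txt side files."""
    path = Path(path)
    mat = scipy.io.mmread(str(path))
    rows = path.with_suffix("").parent / (path.stem + ".rownames.txt")
    cols = path.with_suffix("").parent / (path.stem + ".colnames.txt")
    gene_ids = rows.read_text().split()
    sample_ids = cols.read_text().split()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    df = pd.DataFrame(dense, index=gene_ids, columns=sample_ids)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicated gene id(s) in {path}: {list(dups[:5])}")
    return df.round().astype(np.int64)


def read_dataset(
    counts_path: str | Path,
    samples_path: str | Path,
    genes_path: str | Path,
) -> CountDataset:
    """Assemble a :class:`CountDataset` from TSV/MatrixMarket files on disk."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = read_counts_mtx(counts_path)
    else:
        counts = read_counts_tsv(counts_path)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    return CountDataset(counts=counts, samples=samples, genes=genes)
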