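"""Readers, writers and validated containers for the standard input formats.

The canonical in-memory layout is samples x OTUs. Four files feed a typical
analysis: an OTU count table (TSV or HDF5 BIOM 2.1), a rooted newick tree
whose tips are OTU identifiers, a taxonomy table mapping OTUs to lineage
labels, and a sample-metadata table with the observed time, the event
indicator and optional covariates.
"""

from __future__ import annotations

import datetime
import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
import skbio

from .exceptions import DegenerateDataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

TAXONOMIC_RANKS = ("phylum", "class", "order", "family", "genus")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_ids(ids, what):
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class CountTable:
    """Non-negative integer read counts, samples x OTUs."""

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise ValidationError("count table must be a non-empty 2-D matrix")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.otu_ids = _check_ids(self.otu_ids, "OTU")
        n, p = self.counts.shape
        if len(self.sample_ids) != n or len(self.otu_ids) != p:
            raise ValidationError("identifier lengths do not match matrix shape")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class CommunityMatrix:
    """Relative abundances Z, samples x OTUs.

    ``community_level`` is True when each row sums to one (the entire
    community) and False for a taxon subset normalised by community totals.
    """

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    community_level: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("community matrix must be a non-empty 2-D matrix")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValidationError("relative abundances must lie in [0, 1]")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.otu_ids = _check_ids(self.otu_ids, "OTU")
        if self.community_level:
            sums = self.values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = np.argmax(np.abs(sums - 1.0))
                raise ValidationError(
                    f"community-level rows must sum to 1; sample "
                    f"{self.sample_ids[bad]} sums to {sums[bad]:.12g}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]


@dataclass
class SurvivalData:
    """Observed times, event indicators and an optional covariate matrix."""

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None
    sample_ids: list[str] | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1:
            raise ValidationError("time must be one-dimensional")
        if np.any(self.time <= 0):
            raise ValidationError("observed times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            bad = sorted(set(np.asarray(self.event).ravel()) - {0, 1})
            raise ValidationError(f"event indicators must be 0/1; found {bad}")
        self.event = self.event.astype(int)
        n = len(self.time)
        if len(self.event) != n:
            raise ValidationError("time and event lengths differ")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValidationError("covariate rows do not match number of subjects")
        if self.sample_ids is not None:
            self.sample_ids = _check_ids(self.sample_ids, "sample")
            if len(self.sample_ids) != n:
                raise ValidationError("sample ids do not match number of subjects")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def q(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class TaxonomyTable:
    """OTU -> lineage labels at the ranks phylum..genus (None = unassigned)."""

    lineages: dict[str, dict[str, str | None]]

    def label(self, otu: str, rank: str) -> str | None:
        return self.lineages[otu].get(rank)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.lineages)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path, fmt: str = "tsv", samples_as_rows: bool = True) -> CountTable:
    """Read an OTU count table from TSV or HDF5 BIOM 2.1.

    TSV layout is samples as rows with a header row of OTU ids; pass
    ``samples_as_rows=False`` to transpose on read. BIOM tables are stored
    observations x samples and are transposed to the canonical layout.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not samples_as_rows:
            df = df.T
        mat = df.to_numpy()
        if not np.issubdtype(mat.dtype, np.number):
            for i, row in enumerate(df.itertuples(index=False)):
                for j, v in enumerate(row):
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise FormatError(
                            f"non-numeric count at row {df.index[i]!r}, "
                            f"column {df.columns[j]!r}: {v!r}"
                        ) from None
            raise FormatError("non-numeric values in count table")
        neg = np.argwhere(mat < 0)
        if neg.size:
            i, j = neg[0]
            raise FormatError(
                f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}: "
                f"{mat[i, j]}"
            )
        table = CountTable(mat.astype(np.int64), list(df.index), list(df.columns))
    elif fmt == "biom":
        table = _read_biom(path)
    else:
        raise FormatError(f"unknown count-table format: {fmt!r}")
    n_zero = int(np.sum(table.counts.sum(axis=0) == 0))
    if n_zero:
        logger.info("count table contains %d all-zero OTU columns (retained)", n_zero)
    return table


def write_count_table(table: CountTable, path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        table.to_frame().to_csv(path, sep="\t", index_label="sample")
    elif fmt == "biom":
        _write_biom(table, path)
    else:
        raise FormatError(f"unknown count-table format: {fmt!r}")


def _read_biom(path) -> CountTable:
    """Minimal HDF5 BIOM 2.1 reader (sample-major CSR group)."""
    try:
        with h5py.File(path, "r") as f:
            sample_ids = [s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["sample/ids"][...]]
            otu_ids = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["observation/ids"][...]]
            g = f["sample/matrix"]
            data = g["data"][...]
            indices = g["indices"][...]
            indptr = g["indptr"][...]
    except (OSError, KeyError) as exc:
        raise FormatError(f"not a readable BIOM 2.1 file: {path} ({exc})") from exc
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr),
                     shape=(len(sample_ids), len(otu_ids))).toarray()
    if np.any(mat < 0):
        raise FormatError("BIOM table contains negative counts")
    return CountTable(np.rint(mat).astype(np.int64), sample_ids, otu_ids)


def _write_biom(table: CountTable, path) -> None:
    from scipy.sparse import csr_matrix

    s_csr = csr_matrix(table.counts)
    o_csr = csr_matrix(table.counts.T)
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = [2, 1]
        f.attrs["generated-by"] = "omisurv"
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()
        f.attrs["shape"] = [table.n_otus, table.n_samples]
        f.attrs["nnz"] = int(s_csr.nnz)
        str_dt = h5py.string_dtype()
        for grp, ids, csr in (("sample", table.sample_ids, s_csr),
                              ("observation", table.otu_ids, o_csr)):
            g = f.create_group(grp)
            g.create_dataset("ids", data=np.array(ids, dtype=object), dtype=str_dt)
            m = g.create_group("matrix")
            m.create_dataset("data", data=csr.data.astype(float))
            m.create_dataset("indices", data=csr.indices.astype(np.int64))
            m.create_dataset("indptr", data=csr.indptr.astype(np.int64))
            g.create_group("metadata")
            g.create_group("group-metadata")


def to_composition(counts: CountTable) -> CommunityMatrix:
    """Convert counts to relative abundances: Z_ij = count_ij / row total."""
    totals = counts.counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        names = [counts.sample_ids[i] for i in zero]
        raise DegenerateDataError(f"samples with zero total count: {names}")
    Z = counts.counts / totals[:, None]
    return CommunityMatrix(Z, counts.sample_ids, counts.otu_ids, community_level=True)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    try:
        tree = skbio.TreeNode.read(path, format="newick")
    except Exception as exc:  # skbio raises several parser exception types
        raise FormatError(f"could not parse newick tree: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    if n_missing:
        warnings.warn(f"{n_missing} branches had no length; treated as 0")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValidationError("tree tip labels are not unique")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(path, format="newick")


def tree_from_newick(newick: str) -> skbio.TreeNode:
    return read_tree(io.StringIO(newick))


# ---------------------------------------------------------------------------
# survival metadata and taxonomy
# ---------------------------------------------------------------------------

def read_survival_metadata(path, time_col: str, event_col: str,
                           covariate_cols: list[str] | None = None,
                           sample_col: str | None = None) -> SurvivalData:
    """Read a sample-metadata TSV into a :class:`SurvivalData`.

    The first column is the sample id unless ``sample_col`` names another.
    """
    df = pd.read_csv(path, sep="\t")
    if sample_col is None:
        sample_col = df.columns[0]
    for col in [sample_col, time_col, event_col, *(covariate_cols or [])]:
        if col not in df.columns:
            raise FormatError(f"column {col!r} not found in metadata")
    events = df[event_col].to_numpy()
    if not np.isin(events, [0, 1]).all():
        bad = sorted(set(events) - {0, 1})
        raise ValidationError(f"event column must be coded 0/1; found {bad}")
    cov = df[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
    return SurvivalData(
        time=df[time_col].to_numpy(dtype=float),
        event=events,
        covariates=cov,
        sample_ids=[str(s) for s in df[sample_col]],
        covariate_names=list(covariate_cols or []),
    )


def align_survival(surv: SurvivalData, sample_ids: list[str]) -> SurvivalData:
    """Reorder a SurvivalData to match the sample order of a community matrix."""
    if surv.sample_ids is None:
        raise ValidationError("survival metadata has no sample ids to join on")
    pos = {s: i for i, s in enumerate(surv.sample_ids)}
    missing = [s for s in sample_ids if s not in pos]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    idx = np.array([pos[s] for s in sample_ids])
    return replace(
        surv,
        time=surv.time[idx],
        event=surv.event[idx],
        covariates=None if surv.covariates is None else surv.covariates[idx],
        sample_ids=list(sample_ids),
    )


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV with columns OTU, phylum..genus (empty = unassigned)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "otu" not in cols:
        raise FormatError("taxonomy table must have an 'OTU' column")
    lineages: dict[str, dict[str, str | None]] = {}
    for _, row in df.iterrows():
        otu = str(row["otu"])
        if otu in lineages:
            raise ValidationError(f"duplicate OTU in taxonomy: {otu!r}")
        lineages[otu] = {
            r: (None if r not in cols or pd.isna(row[r]) or row[r] == "" else str(row[r]))
            for r in TAXONOMIC_RANKS
        }
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    rows = [{"OTU": otu, **{r: tax.label(otu, r) or "" for r in TAXONOMIC_RANKS}}
            for otu in tax.otu_ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
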