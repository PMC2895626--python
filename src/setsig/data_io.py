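"""Reading, validation and preprocessing of expression tables and gene-set collections.

Expression data is a probeset/gene × sample matrix with a binary outcome label
per sample (+1 = event, e.g. distant metastasis before the cutoff; -1 =
event-free).  Gene sets come from GMT files and are mapped onto matrix rows,
optionally through a probeset→symbol annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Cell contents treated as missing in expression tables.
DEFAULT_MISSING_TOKENS = ("NA", "", "NaN")

VALID_CATEGORIES = ("C1", "C2", "C3", "C4", "C5", "other")


@dataclass
class ExpressionDataset:
    """A p×N expression matrix with optional ±1 outcome labels.

    Missing values are encoded as NaN in ``values``; preprocessing
    (:func:`filter_probesets` + :func:`impute_missing_median`) removes them.
    """

    name: str
    feature_ids: np.ndarray  # length p, unique
    sample_ids: np.ndarray  # length N, unique
    values: np.ndarray  # p×N float64, NaN = missing
    labels: np.ndarray | None = None  # length N, entries in {+1, -1}

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features × {len(self.sample_ids)} samples"
            )
        for ids, what in ((self.feature_ids, "feature"), (self.sample_ids, "sample")):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
                raise ValueError(f"duplicate {what} ids: {dup[:5]}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels length does not match sample count")
            bad = set(np.unique(self.labels)) - {1, -1}
            if bad:
                raise ValueError(f"labels must be ±1, found {sorted(bad)}")

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pos(self) -> int:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return int(np.sum(self.labels == -1))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            name=self.name,
            feature_ids=self.feature_ids.copy(),
            sample_ids=self.sample_ids.copy(),
            values=self.values.copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def subset_features(self, row_indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(row_indices, dtype=int)
        return ExpressionDataset(
            name=self.name,
            feature_ids=self.feature_ids[idx],
            sample_ids=self.sample_ids.copy(),
            values=self.values[idx],
            labels=None if self.labels is None else self.labels.copy(),
        )


@dataclass
class GeneSet:
    name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        # de-duplicate while preserving order
        self.members = tuple(dict.fromkeys(self.members))


@dataclass
class GeneSetCollection:
    """Ordered gene sets, optionally mapped onto an expression matrix.

    ``mapped_members[j]`` holds the matrix row indices of set j after
    :func:`map_collection`; ``p`` is the number of rows of that matrix, so
    complement sizes are ``p - s(j)``.
    """

    sets: list[GeneSet]
    mapped_members: list[np.ndarray] | None = None
    p: int | None = None  # size of the feature universe the mapping refers to

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = pd.Index(names)[pd.Index(names).duplicated()].tolist()
            raise ValueError(f"duplicate set names: {dup[:5]}")

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def categories(self) -> list[str]:
        return [s.category for s in self.sets]

    def sizes(self) -> np.ndarray:
        """Mapped set sizes s(j); requires a prior :func:`map_collection`."""
        if self.mapped_members is None:
            raise ValueError("collection is not mapped; call map_collection first")
        return np.array([len(m) for m in self.mapped_members], dtype=int)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    labels_path: str | Path | None = None,
    name: str | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> ExpressionDataset:
    """Read a tab-delimited expression table (rows = features, header = samples).

    ``labels_path`` points to a two-column TSV (sample_id, label ∈ {0,1});
    0 maps to −1 (event-free) and 1 to +1 (event).
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(missing_tokens),
        keep_default_na=False,
        float_precision="round_trip",
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature ids: {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dup[:5]}")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric cell in column {col!r}: {bad.iloc[0]!r}"
            )
    labels = None
    if labels_path is not None:
        labels = read_labels(labels_path, df.columns)
    return ExpressionDataset(
        name=name or path.stem,
        feature_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def read_labels(path: str | Path, sample_ids: Sequence[str]) -> np.ndarray:
    """Read a two-column (sample_id, 0/1) TSV, aligned to ``sample_ids``."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype={0: str})
    tab = tab.set_index("sample")
    missing = [s for s in sample_ids if s not in tab.index]
    if missing:
        raise ValueError(f"{path}: no label for samples {missing[:5]}")
    raw = tab.loc[list(sample_ids), "label"].to_numpy()
    bad = set(np.unique(raw)) - {0, 1}
    if bad:
        raise ValueError(f"{path}: labels must be 0/1, found {sorted(bad)}")
    return np.where(raw == 1, 1, -1)


def write_expression_table(
    ds: ExpressionDataset, path: str | Path, labels_path: str | Path | None = None
) -> None:
    df = pd.DataFrame(ds.values, index=ds.feature_ids, columns=ds.sample_ids)
    # %.17g guarantees an exact float64 round trip through text
    df.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id",
              float_format="%.17g")
    if labels_path is not None:
        if ds.labels is None:
            raise ValueError("dataset has no labels to write")
        pd.DataFrame(
            {"sample": ds.sample_ids, "label": (ds.labels == 1).astype(int)}
        ).to_csv(labels_path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path, category: str = "other") -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members.

    The description field is discarded; duplicated member symbols within one
    line are collapsed.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected ≥3 tab-separated fields")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            members = tuple(m for m in fields[2:] if m)
            sets.append(GeneSet(name=name, category=category, members=members))
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.name, s.category, *s.members]) + "\n")


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (probeset_id, gene_symbol) TSV into symbol→probesets.

    Repeated rows are allowed; the mapping may be many-to-many.
    """
    tab = pd.read_csv(path, sep="\t", header=None, names=["probe", "symbol"], dtype=str)
    out: dict[str, list[str]] = {}
    for probe, symbol in zip(tab["probe"], tab["symbol"]):
        out.setdefault(symbol, [])
        if probe not in out[symbol]:
            out[symbol].append(probe)
    return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_probesets(
    ds: ExpressionDataset,
    qc_prefix: str = "AFFX",
    var_eps: float = 1e-8,
    max_missing_frac: float = 0.15,
) -> tuple[ExpressionDataset, dict[str, str]]:
    """Drop QC probesets, near-constant rows and rows with too many missing values.

    A row is removed when its id starts with ``qc_prefix``, when the sample
    variance of its non-missing values is ≤ ``var_eps``, or when its missing
    fraction strictly exceeds ``max_missing_frac``.  Returns the filtered
    dataset and a removal log (feature id → reason).
    """
    removal: dict[str, str] = {}
    keep: list[int] = []
    n = ds.n_samples
    for i, fid in enumerate(ds.feature_ids):
        row = ds.values[i]
        miss = np.isnan(row)
        if qc_prefix and str(fid).startswith(qc_prefix):
            removal[str(fid)] = "qc_prefix"
            continue
        if miss.sum() / n > max_missing_frac:
            removal[str(fid)] = "missing_fraction"
            continue
        obs = row[~miss]
        if obs.size < 2 or np.var(obs, ddof=1) <= var_eps:
            removal[str(fid)] = "low_variance"
            continue
        keep.append(i)
    if not keep:
        raise ValueError("all rows removed by probeset filtering")
    return ds.subset_features(keep), removal


def impute_missing_median(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace each missing cell by the median of its row's non-missing values."""
    out = ds.copy()
    mask = np.isnan(out.values)
    if not mask.any():
        return out
    fully_missing = mask.all(axis=1)
    if fully_missing.any():
        bad = out.feature_ids[fully_missing][:5].tolist()
        raise ValueError(f"rows with all values missing (filter first): {bad}")
    medians = np.nanmedian(out.values, axis=1)
    rows = np.where(mask)[0]
    out.values[mask] = medians[rows]
    return out


def normalize(ds: ExpressionDataset, mode: str = "none") -> ExpressionDataset:
    """Normalise a complete (no-missing) matrix.

    ``sample_median_center`` subtracts each column's median;
    ``gene_standardize`` scales each row to mean 0 and unit sample standard
    deviation (divisor n−1); ``none`` is the identity.
    """
    if np.isnan(ds.values).any():
        raise ValueError("normalize requires a matrix without missing values")
    if mode == "none":
        return ds.copy()
    out = ds.copy()
    if mode == "sample_median_center":
        out.values = out.values - np.median(out.values, axis=0, keepdims=True)
        return out
    if mode == "gene_standardize":
        mu = out.values.mean(axis=1, keepdims=True)
        sd = out.values.std(axis=1, ddof=1, keepdims=True)
        zero = (sd <= 0).ravel()
        if zero.any():
            bad = out.feature_ids[zero][:5].tolist()
            raise ValueError(f"zero-variance rows under gene_standardize: {bad}")
        out.values = (out.values - mu) / sd
        return out
    raise ValueError(f"unknown normalisation mode {mode!r}")


def map_collection(
    coll: GeneSetCollection,
    ds: ExpressionDataset,
    annotation: Mapping[str, Sequence[str]] | None = None,
    min_set_size: int = 1,
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Map set member symbols onto matrix row indices.

    ``annotation`` maps a gene symbol to one or more feature ids (identity
    when None, i.e. matrix rows already carry symbols).  Sets whose mapped
    size falls below ``min_set_size`` are dropped and logged.  Mapping is
    idempotent: re-mapping a mapped collection against the same matrix gives
    the same result.
    """
    row_of = {fid: i for i, fid in enumerate(ds.feature_ids)}
    kept_sets: list[GeneSet] = []
    mapped: list[np.ndarray] = []
    drop_log: dict[str, str] = {}
    for s in coll.sets:
        idx: list[int] = []
        seen: set[int] = set()
        for sym in s.members:
            fids = annotation.get(sym, []) if annotation is not None else [sym]
            for fid in fids:
                i = row_of.get(fid)
                if i is not None and i not in seen:
                    seen.add(i)
                    idx.append(i)
        if len(idx) < min_set_size:
            drop_log[s.name] = f"mapped size {len(idx)} < {min_set_size}"
            continue
        kept_sets.append(s)
        mapped.append(np.array(idx, dtype=int))
    if not kept_sets:
        raise ValueError("no sets survive mapping")
    return GeneSetCollection(sets=kept_sets, mapped_members=mapped, p=ds.p), drop_log


def preprocess(
    ds: ExpressionDataset,
    qc_prefix: str = "AFFX",
    var_eps: float = 1e-8,
    max_missing_frac: float = 0.15,
    normalization: str = "none",
) -> tuple[ExpressionDataset, dict[str, str]]:
    """Filter → impute → normalise, the standard preprocessing chain."""
    out, log = filter_probesets(ds, qc_prefix=qc_prefix, var_eps=var_eps,
                                max_missing_frac=max_missing_frac)
    out = impute_missing_median(out)
    out = normalize(out, normalization)
    return out, log
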