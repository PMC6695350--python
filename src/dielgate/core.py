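"""Shared data model, file I/O, count filtering and normalization.

The central container is :class:`CountMatrix`: a gene-by-sample matrix of
non-negative integer read counts together with a sample sheet that assigns
every sample a time of day (``AM`` or ``PM``), a treatment condition
(``control`` or ``heat``) and a replicate id.  All downstream stages
(differential expression, categorization, clustering, conservation) consume
this container, so its invariants are enforced at construction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

TIMES = ("AM", "PM")
CONDITIONS = ("control", "heat")

#: canonical ordering of the four experimental groups
GROUPS = ("AM_control", "AM_heat", "PM_control", "PM_heat")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with sample annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
        Values must be non-negative integers.
    samples
        DataFrame indexed by sample id with columns ``time`` (AM/PM),
        ``condition`` (control/heat) and ``replicate``.  Column order of
        ``counts`` follows the sample-sheet order.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        counts, samples = self.counts, self.samples
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if samples.index.duplicated().any():
            dup = samples.index[samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        missing = [s for s in counts.columns if s not in samples.index]
        if missing:
            raise ValidationError(
                f"sample(s) not annotated in sample sheet: {missing}"
            )
        extra = [s for s in samples.index if s not in counts.columns]
        if extra:
            raise ValidationError(f"annotated sample(s) missing from counts: {extra}")
        for col in ("time", "condition"):
            if col not in samples.columns:
                raise ValidationError(f"sample sheet lacks required column {col!r}")
        bad_time = set(samples["time"]) - set(TIMES)
        if bad_time:
            raise ValidationError(f"unknown time label(s): {sorted(bad_time)}")
        bad_cond = set(samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition label(s): {sorted(bad_cond)}")
        arr = counts.to_numpy()
        if np.issubdtype(arr.dtype, np.floating):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integral")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        # samples ordered as in the sheet
        self.counts = counts.loc[:, samples.index].astype(np.int64)
        self.samples = samples

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_labels(self) -> pd.Series:
        """Per-sample ``time_condition`` label, e.g. ``AM_heat``."""
        return self.samples["time"] + "_" + self.samples["condition"]

    def subset_samples(self, mask: pd.Series | np.ndarray | list) -> "CountMatrix":
        samples = self.samples.loc[mask]
        return CountMatrix(self.counts.loc[:, samples.index], samples)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.samples)

    def write(self, counts_path, samplesheet_path) -> None:
        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samplesheet_path)


@dataclass
class Thresholds:
    """Significance and bookkeeping cutoffs used across the pipeline.

    ``lfc_cut`` is in log2 units and applied to the absolute log2 fold
    change; ``min_count`` is the per-sample maximum-count filter applied
    before testing; ``r_conserved``/``r_review`` bound the Pearson-r classes
    of the conservation analysis; ``n_clusters`` is the tree-cut count for
    the temporal clustering.
    """

    padj_cut: float = 0.05
    lfc_cut: float = 0.5
    min_count: int = 10
    category_min_size: int = 10
    r_conserved: float = 0.7
    r_review: float = 0.5
    n_clusters: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.padj_cut < 1:
            raise ValidationError("padj_cut must lie in (0, 1)")
        if self.lfc_cut < 0:
            raise ValidationError("lfc_cut must be >= 0")
        if self.r_review > self.r_conserved:
            raise ValidationError("r_review must not exceed r_conserved")

    @classmethod
    def from_json(cls, path) -> "Thresholds":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), used for over-representation tests."""

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# I/O


def read_counts(path, samplesheet_path) -> CountMatrix:
    """Read a count matrix plus sample sheet into a validated CountMatrix.

    ``path`` may be a TSV/CSV table (genes in rows, first column gene ids)
    or a MatrixMarket file ``x.mtx`` with sidecar row/column name files
    ``x.mtx.rows`` and ``x.mtx.cols`` (one id per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(path)
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        counts = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        counts = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    samples = pd.read_csv(samplesheet_path, index_col=0)
    return CountMatrix(counts, samples)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>members...``.

    Duplicate members within a set are collapsed; a duplicate set name or a
    line with fewer than three fields is an error.
    """
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV with an optional ``#``-prefixed metadata preamble."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and normalization


def filter_low_counts(m: CountMatrix, min_count: int = 10) -> CountMatrix:
    """Keep genes whose maximum count across samples is at least ``min_count``.

    The rule is a per-sample maximum, not a row sum: a gene with counts
    ``[0, 0, 0, 10]`` passes at ``min_count=10``.  Gene order is preserved
    and the operation is idempotent.
    """
    keep = m.counts.max(axis=1) >= min_count
    return CountMatrix(m.counts.loc[keep], m.samples)


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    For every gene expressed (count > 0) in *all* samples, compute the ratio
    of each sample's count to the gene's geometric mean across samples; the
    sample's factor is the median of these ratios.  Raises if no gene is
    expressed in every sample.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "size factors undefined: no gene has nonzero counts in all samples"
        )
    ref = counts[all_pos]
    log_gm = np.log(ref).mean(axis=1)  # per-gene log geometric mean
    ratios = ref / np.exp(log_gm)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def normalized_counts(m: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample median-of-ratios size factors."""
    if factors is None:
        factors = size_factors(m)
    return m.counts / factors.loc[m.sample_ids]
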