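"""Gene-family (functional) analysis of sorted fractions.

Consumes HUMAnN-style gene-family tables.  Only community-level rows are
used: taxon-stratified rows (family id containing ``|``) are dropped at read
time.  Columns are named ``<sample>_<fraction>`` with fraction one of
``all``, ``igg_pos``, ``igg_neg``.

Processing order is fixed: per-participant zeroing of families absent from
the 'all' fraction, renormalisation of reads-per-kilobase (RPK) to relative
abundances, detection cutoff, prevalence filter; then either CLR + PCA on
the 'all' fraction or probability-ratio scoring of the sorted fractions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .exceptions import FormatError, ValidationError
from .scoring import GENE_FAMILY_PSEUDOCOUNT, prob_ratio
from .tables import FlowSummary, ProbRatioMatrix, RelAbundanceTable

#: Detection cutoff on gene-family relative abundance.
GENE_FAMILY_THRESHOLD = 1e-6
#: Families below the cutoff in at least this many samples are discarded.
PREVALENCE_MAX_BELOW = 7

_COLUMN_RE = re.compile(r"^(?P<sample>.+)_(?P<fraction>all|igg_pos|igg_neg)$")


@dataclass
class GeneFamilyTable:
    """Gene families x sample_fraction columns; RPK or relative abundance."""

    values: pd.DataFrame
    unit: str = "rpk"  # "rpk" | "relab"
    community_level: bool = True

    def __post_init__(self) -> None:
        if self.unit not in ("rpk", "relab"):
            raise ValidationError(f"unit must be 'rpk' or 'relab', got {self.unit!r}")
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValidationError("gene-family values must be non-negative")

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.index)

    def split_column(self, col: str) -> tuple[str, str]:
        m = _COLUMN_RE.match(col)
        if not m:
            raise FormatError(
                f"column {col!r} does not match '<sample>_<fraction>'"
            )
        return m.group("sample"), m.group("fraction")

    def participants(self) -> list[str]:
        return sorted({self.split_column(c)[0] for c in self.values.columns})

    def column_for(self, sample: str, fraction: str) -> str:
        col = f"{sample}_{fraction}"
        if col not in self.values.columns:
            raise ValidationError(
                f"participant {sample!r} is missing the {fraction!r} fraction"
            )
        return col

    def fraction_frame(self, fraction: str) -> pd.DataFrame:
        """Families x samples frame for one fraction, columns renamed to samples."""
        cols = {
            self.column_for(s, fraction): s for s in self.participants()
        }
        return self.values[list(cols)].rename(columns=cols)


def read_gene_family_table(path: str | Path, unit: str = "rpk") -> GeneFamilyTable:
    """Read a HUMAnN-style TSV, keeping only community-level rows."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    community = df.loc[[i for i in df.index if "|" not in str(i)]]
    return GeneFamilyTable(community.astype(float), unit=unit)


def write_gene_family_table(table: GeneFamilyTable, path: str | Path) -> None:
    out = table.values.copy()
    out.index.name = "gene_family"
    out.to_csv(path, sep="\t", float_format="%.12g")


def zero_families_absent_in_all(table: GeneFamilyTable) -> GeneFamilyTable:
    """Per participant, zero sorted-fraction values of families with no
    signal in that participant's 'all' fraction (absence means value == 0)."""
    values = table.values.copy()
    for sample in table.participants():
        all_col = table.column_for(sample, "all")
        absent = values[all_col] == 0
        for fraction in ("igg_pos", "igg_neg"):
            col = table.column_for(sample, fraction)
            values.loc[absent, col] = 0.0
    return replace(table, values=values)


def renormalise(table: GeneFamilyTable) -> GeneFamilyTable:
    """Total-sum scale every column to 1, converting RPK to relative abundance."""
    totals = table.values.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValidationError(f"all-zero column(s): {list(empty.index)}")
    return replace(table, values=table.values / totals, unit="relab")


def apply_threshold_families(
    table: GeneFamilyTable, threshold: float = GENE_FAMILY_THRESHOLD
) -> GeneFamilyTable:
    """Zero gene-family abundances not strictly above the detection cutoff."""
    if table.unit != "relab":
        raise ValidationError("threshold applies to relative abundances; renormalise first")
    return replace(table, values=table.values.where(table.values > threshold, 0.0))


def prevalence_filter(
    table: GeneFamilyTable,
    threshold: float = GENE_FAMILY_THRESHOLD,
    max_below: int = PREVALENCE_MAX_BELOW,
) -> GeneFamilyTable:
    """Drop families at or below ``threshold`` in ``max_below`` or more columns."""
    below = (table.values <= threshold).sum(axis=1)
    return replace(table, values=table.values.loc[below < max_below])


def clr_transform(
    matrix: pd.DataFrame, pseudocount: float | None = None
) -> pd.DataFrame:
    """Centred log-ratio transform, applied per sample (column).

    ``pseudocount=None`` adds half the smallest non-zero value in the matrix
    to every cell before taking logs; pass 0 to require strictly positive
    input (raises otherwise).
    """
    arr = matrix.to_numpy(dtype=float)
    if pseudocount is None:
        positive = arr[arr > 0]
        if positive.size == 0:
            raise ValidationError("matrix has no positive values")
        pseudocount = positive.min() / 2.0
    arr = arr + pseudocount
    if (arr <= 0).any():
        raise ValidationError(
            "non-positive values: add a pseudocount before the CLR transform"
        )
    logs = np.log(arr)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=matrix.index, columns=matrix.columns)


@dataclass
class PCAResult:
    """Sample scores, feature loadings and explained-variance fractions."""

    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # features x components
    explained_variance_ratio: np.ndarray


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a features-x-samples matrix, treating samples as observations.

    The matrix is centred internally; components are ordered by decreasing
    variance.  The sign of each component is fixed so its largest-magnitude
    loading is positive, making results deterministic across runs.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValidationError("PCA needs at least two samples")
    max_rank = min(n_samples - 1, n_features)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValidationError(
            f"n_components must be <= {max_rank} for this matrix"
        )
    if np.allclose(X.var(axis=0), 0):
        raise ValidationError("matrix has zero variance across samples")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # features x components
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=pcs),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=pcs),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


def gene_family_prob_ratio(
    table: GeneFamilyTable,
    flow: FlowSummary,
    pseudocount: float = GENE_FAMILY_PSEUDOCOUNT,
    scale: bool = True,
) -> ProbRatioMatrix:
    """Probability ratios of gene families residing in the bound fraction.

    Expects a processed (zeroed, renormalised, thresholded) table.  Families
    undetected in both sorted fractions of any sample have no defined ratio
    there and are discarded, so the result is complete across samples.
    """
    if table.unit != "relab":
        raise ValidationError("ratios require relative abundances; renormalise first")
    pos = table.fraction_frame("igg_pos")
    neg = table.fraction_frame("igg_neg")
    defined = ((pos > 0) | (neg > 0)).all(axis=1)
    pos, neg = pos.loc[defined], neg.loc[defined]
    result = prob_ratio(
        RelAbundanceTable(pos, "igg_pos"),
        RelAbundanceTable(neg, "igg_neg"),
        flow,
        pseudocount=pseudocount,
        scale=scale,
    )
    return result
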