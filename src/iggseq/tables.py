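"""Core in-memory containers for sorted-fraction microbiome data.

Tables are thin dataclass wrappers around pandas DataFrames with the
orientation fixed to features (taxa or gene families) as rows and samples as
columns, which is the layout the merged TSV files on disk use.  Wrapping the
frames lets each container enforce its own invariants once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Valid sorted-fraction labels: the SYBR+ total population and the
#: IgG-bound / IgG-unbound subpopulations sorted from it.
FRACTION_LABELS = ("all", "igg_pos", "igg_neg")

#: Required columns of a flow-cytometry summary table.
FLOW_COLUMNS = ("igg_pos_size", "igg_neg_size", "isotype_pct", "microbial_load")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass
class FractionCountTable:
    """Read counts for one sorted fraction; taxa as rows, samples as columns."""

    counts: pd.DataFrame
    fraction_label: str

    def __post_init__(self) -> None:
        if self.fraction_label not in FRACTION_LABELS:
            raise ValidationError(
                f"fraction_label must be one of {FRACTION_LABELS}, "
                f"got {self.fraction_label!r}"
            )
        _check_unique(self.counts.index, "taxon")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class RelAbundanceTable:
    """Relative abundances (proportions) for one fraction.

    Column sums are exactly 1 immediately after total-sum scaling and may fall
    below 1 after threshold zeroing; values always stay within [0, 1].
    """

    values: pd.DataFrame
    fraction_label: str

    def __post_init__(self) -> None:
        if self.fraction_label not in FRACTION_LABELS:
            raise ValidationError(
                f"fraction_label must be one of {FRACTION_LABELS}, "
                f"got {self.fraction_label!r}"
            )
        _check_unique(self.values.index, "taxon")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        # small upward slack: pseudocount-augmented tables may exceed 1 by c
        if arr.size and ((arr < 0).any() or (arr > 1 + 1e-4).any()):
            raise ValidationError("relative abundances must lie in [0, 1]")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FlowSummary:
    """Per-sample flow-cytometry summaries.

    ``data`` is indexed by sample id with columns:

    - ``igg_pos_size``, ``igg_neg_size``: sorted-fraction sizes as proportions
      of SYBR+ events, in [0, 1];
    - ``isotype_pct``: isotype-control background as a percentage in [0, 100];
    - ``microbial_load``: total cell concentration in cells per gram of stool;
    - optional ``water_wet_weight`` / ``water_dry_weight`` in grams.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FLOW_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"flow summary missing columns: {missing}")
        _check_unique(self.data.index, "sample")
        pos = self.data["igg_pos_size"].to_numpy(dtype=float)
        neg = self.data["igg_neg_size"].to_numpy(dtype=float)
        for name, arr in (("igg_pos_size", pos), ("igg_neg_size", neg)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(f"{name} must lie in [0, 1]")
        if (pos + neg > 1 + 1e-9).any():
            raise ValidationError("igg_pos_size + igg_neg_size must be <= 1")
        load = self.data["microbial_load"].to_numpy(dtype=float)
        if (load <= 0).any():
            raise ValidationError("microbial_load must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def fraction_sizes(self, sample_id: str) -> tuple[float, float]:
        row = self.data.loc[sample_id]
        return float(row["igg_pos_size"]), float(row["igg_neg_size"])


@dataclass
class QuantProfile:
    """Absolute abundances in cells per gram (relative abundance x load)."""

    absolute_abundance: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.absolute_abundance.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValidationError("absolute abundances must be non-negative")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.absolute_abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.absolute_abundance.columns)


@dataclass
class ProbRatioMatrix:
    """log2 probability ratios of features residing in the bound fraction.

    Positive entries mean a feature is more likely found antibody-coated.
    ``scaled`` records whether fraction sizes were rescaled by the larger of
    the two before use.
    """

    ratio: pd.DataFrame
    pseudocount_used: float
    scaled: bool = True

    @property
    def feature_ids(self) -> list[str]:
        return list(self.ratio.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratio.columns)


@dataclass
class CohortMetadata:
    """Sample-to-household bookkeeping: pair id and patient/control role."""

    data: pd.DataFrame  # index: sample_id; columns: pair_id, role

    def __post_init__(self) -> None:
        for col in ("pair_id", "role"):
            if col not in self.data.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        _check_unique(self.data.index, "sample")
        bad = set(self.data["role"]) - {"patient", "control"}
        if bad:
            raise ValidationError(f"unknown roles: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_by_role(self, role: str) -> list[str]:
        return list(self.data.index[self.data["role"] == role])

    def paired_samples(self) -> pd.DataFrame:
        """One row per household pair with patient and control sample ids."""
        wide = (
            self.data.reset_index(names="sample_id")
            .pivot(index="pair_id", columns="role", values="sample_id")
            .sort_index()
        )
        if wide.isna().any().any():
            raise ValidationError("every pair needs one patient and one control")
        return wide[["patient", "control"]]
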