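"""Immunoglobulin-binding scores from sorted-fraction abundances.

The central statistic is the log2 probability ratio of a taxon residing in
the antibody-bound versus unbound fraction.  For taxon i in sample j, with
relative abundances ``pos`` and ``neg`` in the two sorted fractions, fraction
sizes S+ and S- (proportions of SYBR+ events sorted into each gate) and a
pseudocount c:

    ratio[i, j] = log2( (pos[i, j] * S+[j] + c) / (neg[i, j] * S-[j] + c) )

The product of a fraction's composition and its size estimates the joint
probability that a cell belongs to taxon i AND carries (or lacks) the
antibody, so as c -> 0 the ratio converges to log2(theta_i / (1 - theta_i)),
where theta_i is the per-cell coating probability — independent of the
taxon's overall relative abundance.

With ``scale=True`` (the default) both fraction sizes are divided by the
larger of the two within each sample before use.  That rescaling cancels in
the c -> 0 limit and makes the score exactly invariant to multiplying both
sizes by a positive constant, while keeping the pseudocount comparable in
magnitude across samples with very different sorted-gate sizes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ValidationError
from .tables import FlowSummary, ProbRatioMatrix, RelAbundanceTable

logger = logging.getLogger(__name__)

#: Default pseudocount for taxon-level scores.
TAXON_PSEUDOCOUNT = 1e-5
#: Default pseudocount for gene-family scores (gene-family relative
#: abundances are orders of magnitude smaller than species abundances).
GENE_FAMILY_PSEUDOCOUNT = 6e-10
#: Detection cutoff (strictly greater-than) used for fraction presence and
#: for the removal of taxa undetected in the 'all' fraction.
IGG_DETECTION_THRESHOLD = 1e-5


def _aligned_frames(
    pos: RelAbundanceTable, neg: RelAbundanceTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not pos.values.index.equals(neg.values.index) or not pos.values.columns.equals(
        neg.values.columns
    ):
        raise AlignmentError("bound and unbound tables are misaligned")
    return pos.values, neg.values


def scaled_fraction_sizes(
    flow: FlowSummary, sample_ids: list[str], scale: bool
) -> tuple[pd.Series, pd.Series]:
    """Per-sample fraction sizes, optionally rescaled by the larger of the two."""
    missing = [s for s in sample_ids if s not in flow.data.index]
    if missing:
        raise ValidationError(f"no fraction sizes for sample(s): {missing}")
    s_pos = flow.data.loc[sample_ids, "igg_pos_size"].astype(float)
    s_neg = flow.data.loc[sample_ids, "igg_neg_size"].astype(float)
    if scale:
        larger = pd.concat([s_pos, s_neg], axis=1).max(axis=1)
        if (larger <= 0).any():
            raise ValidationError("both fraction sizes are zero for some sample")
        s_pos = s_pos / larger
        s_neg = s_neg / larger
    return s_pos, s_neg


def prob_ratio(
    pos: RelAbundanceTable,
    neg: RelAbundanceTable,
    flow: FlowSummary,
    pseudocount: float = TAXON_PSEUDOCOUNT,
    scale: bool = True,
) -> ProbRatioMatrix:
    """log2 probability ratio of each taxon residing bound vs unbound.

    Raises :class:`ValidationError` if ``pseudocount`` is 0 and any cell of
    the numerator or denominator vanishes (the ratio would be infinite).
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    pos_df, neg_df = _aligned_frames(pos, neg)
    s_pos, s_neg = scaled_fraction_sizes(flow, list(pos_df.columns), scale)
    num = pos_df.mul(s_pos, axis=1) + pseudocount
    den = neg_df.mul(s_neg, axis=1) + pseudocount
    if pseudocount == 0 and ((num.to_numpy() == 0) | (den.to_numpy() == 0)).any():
        raise ValidationError(
            "zero numerator or denominator with pseudocount 0 would give an "
            "infinite ratio; use a positive pseudocount"
        )
    # log2(num) - log2(den), not log2(num/den): keeps swapping the two
    # fractions an exact negation in floating point
    ratio = np.log2(num) - np.log2(den)
    return ProbRatioMatrix(ratio, pseudocount_used=pseudocount, scaled=scale)


def proportion_igg_positive(
    n_only_neg: int | np.ndarray, n_only_pos: int | np.ndarray, n_both: int | np.ndarray
) -> float | np.ndarray:
    """Share of detected taxa present in the bound fraction.

    Defined as (only_pos + both) / (only_neg + only_pos + both); NaN when no
    taxon is detected in either fraction.
    """
    n_only_neg = np.asarray(n_only_neg, dtype=float)
    n_only_pos = np.asarray(n_only_pos, dtype=float)
    n_both = np.asarray(n_both, dtype=float)
    total = n_only_neg + n_only_pos + n_both
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (n_only_pos + n_both) / total, np.nan)
    return out if out.ndim else float(out)


def classify_fraction_presence(
    pos: RelAbundanceTable,
    neg: RelAbundanceTable,
    threshold: float = IGG_DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Partition each sample's detected taxa by fraction membership.

    A taxon is "in" a fraction when its relative abundance there is strictly
    above ``threshold``.  Returns one row per sample with columns
    ``n_only_neg``, ``n_only_pos``, ``n_both`` and ``proportion_pos`` (NaN for
    samples with no detected taxa).
    """
    pos_df, neg_df = _aligned_frames(pos, neg)
    in_pos = pos_df > threshold
    in_neg = neg_df > threshold
    n_only_pos = (in_pos & ~in_neg).sum(axis=0)
    n_only_neg = (in_neg & ~in_pos).sum(axis=0)
    n_both = (in_pos & in_neg).sum(axis=0)
    result = pd.DataFrame(
        {
            "n_only_neg": n_only_neg,
            "n_only_pos": n_only_pos,
            "n_both": n_both,
        }
    )
    result["proportion_pos"] = proportion_igg_positive(
        result["n_only_neg"].to_numpy(),
        result["n_only_pos"].to_numpy(),
        result["n_both"].to_numpy(),
    )
    return result


def select_common_features(
    table: ProbRatioMatrix | RelAbundanceTable,
    threshold: float = IGG_DETECTION_THRESHOLD,
) -> pd.Index:
    """Features usable in every sample.

    For an abundance table: detected (strictly above ``threshold``) in every
    sample.  For a ratio matrix: finite and non-missing in every sample.
    Logs a warning when the intersection is empty.
    """
    if isinstance(table, ProbRatioMatrix):
        ok = table.ratio.notna() & np.isfinite(table.ratio)
    else:
        ok = table.values > threshold
    keep = ok.all(axis=1)
    selected = keep.index[keep]
    if len(selected) == 0:
        logger.warning("no feature passes the detection rule in every sample")
    return selected
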