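"""Relative (RMP) and quantitative (QMP) microbiome profiles.

RMP is total-sum-scaled relative abundance of the SYBR+ 'all' fraction with a
detection cutoff and a pseudocount.  QMP converts RMP to absolute abundance
(cells per gram of stool) by multiplying each sample's relative abundances by
its flow-cytometric microbial load:

    absolute_abundance[i, j] = RA[i, j] * microbial_load[j]

Because QMP is computed on the thresholded, pseudocount-augmented relative
abundances, its column sums deviate slightly from the measured load; pass
``renormalise=True`` to rescale each column to sum to 1 first.
"""

from __future__ import annotations

from .exceptions import ValidationError
from .io import apply_threshold, total_sum_scale
from .tables import FlowSummary, FractionCountTable, QuantProfile, RelAbundanceTable

#: Detection cutoff on relative abundance for profiling (strictly greater-than).
RMP_THRESHOLD = 1e-6
#: Pseudocount added to every cell after cutoff zeroing.
RMP_PSEUDOCOUNT = 1e-7


def rmp(
    all_counts: FractionCountTable,
    threshold: float = RMP_THRESHOLD,
    pseudocount: float = RMP_PSEUDOCOUNT,
) -> RelAbundanceTable:
    """Relative microbiome profile of the 'all' fraction."""
    return apply_threshold(total_sum_scale(all_counts), threshold, pseudocount)


def qmp(
    rmp_table: RelAbundanceTable,
    flow: FlowSummary,
    renormalise: bool = False,
) -> QuantProfile:
    """Quantitative microbiome profile: cells/gram per taxon and sample."""
    missing = [s for s in rmp_table.sample_ids if s not in flow.data.index]
    if missing:
        raise ValidationError(f"no microbial load for sample(s): {missing}")
    load = flow.data.loc[rmp_table.sample_ids, "microbial_load"]
    values = rmp_table.values
    if renormalise:
        values = values / values.sum(axis=0)
    return QuantProfile(values * load)


def water_content(wet_weight: float, dry_weight: float) -> float:
    """Stool water content as a percentage of wet weight."""
    if wet_weight <= 0:
        raise ValidationError("wet weight must be positive")
    if dry_weight < 0 or dry_weight > wet_weight:
        raise ValidationError("dry weight must lie in (0, wet weight]")
    return 100.0 * (wet_weight - dry_weight) / wet_weight
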