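"""End-to-end orchestration: simulate inputs, run the analysis, write outputs.

Stage order is fixed — detection thresholds, removal of taxa undetected in
the total population, probability-ratio scoring, diversity, functional
analysis, paired statistics — because the filtering steps change what the
later stages see.

Every run writes a ``manifest.json`` recording the package version, the full
configuration (and its hash), the seed, and every output file produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import FormatError, ValidationError
from .io import (
    apply_threshold,
    read_count_table,
    read_flow_summary,
    read_metadata,
    total_sum_scale,
    write_matrix_tsv,
    zero_absent_in_all,
)
from .diversity import alpha_diversity, bray_curtis, nmds
from .functional import (
    apply_threshold_families,
    clr_transform,
    gene_family_prob_ratio,
    pca,
    prevalence_filter,
    read_gene_family_table,
    renormalise,
    zero_families_absent_in_all,
)
from .profiles import qmp, rmp
from .scoring import (
    classify_fraction_presence,
    prob_ratio,
    select_common_features,
)
from .stats import paired_t_test
from .synthetic import CohortScenario, SortSpec, generate_cohort, write_bundle
from .tables import FlowSummary, FractionCountTable, RelAbundanceTable

logger = logging.getLogger(__name__)

REQUIRED_INPUTS = (
    "counts_all.tsv",
    "counts_igg_pos.tsv",
    "counts_igg_neg.tsv",
    "flow_summary.tsv",
    "metadata.tsv",
)


@dataclass
class RunConfig:
    """One place for every pipeline knob; round-trips through YAML."""

    mode: str = "synthetic"  # "synthetic" | "files"
    input_dir: str = "inputs"
    output_dir: str = "results"
    seed: int = 0
    # profiling
    rmp_threshold: float = 1e-6
    rmp_pseudocount: float = 1e-7
    # antibody-binding analysis
    igg_threshold: float = 1e-5
    igg_pseudocount: float = 1e-5
    scale_ratio: bool = True
    # functional analysis
    gene_threshold: float = 1e-6
    gene_pseudocount: float = 6e-10
    prevalence_max_below: int = 7
    # diversity
    nmds_dims: int = 2
    nmds_starts: int = 20
    # synthetic-mode scenario and sorter settings
    scenario: dict = field(default_factory=dict)
    sort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "rmp_threshold", "rmp_pseudocount", "igg_threshold",
            "igg_pseudocount", "gene_threshold", "gene_pseudocount",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.mode not in ("synthetic", "files"):
            raise ValidationError("mode must be 'synthetic' or 'files'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_scenario(self) -> CohortScenario:
        return CohortScenario(**self.scenario)

    def sort_spec(self) -> SortSpec:
        return SortSpec(**self.sort)


def run_simulate(config: RunConfig) -> list[Path]:
    """Generate a synthetic input bundle on disk (synthetic mode only)."""
    if config.mode != "synthetic":
        raise ValidationError("run_simulate requires mode='synthetic'")
    bundle = generate_cohort(
        config.cohort_scenario(), config.sort_spec(), config.seed
    )
    return write_bundle(bundle, config.input_dir)


def _isotype_normalised_flow(flow: FlowSummary) -> FlowSummary:
    """Subtract the isotype-control background from the bound gate size."""
    data = flow.data.copy()
    corrected = data["igg_pos_size"] - data["isotype_pct"] / 100.0
    data["igg_pos_size"] = corrected.clip(lower=0.0)
    return FlowSummary(data)


def _check_inputs(indir: Path) -> None:
    missing = [n for n in REQUIRED_INPUTS if not (indir / n).exists()]
    if missing:
        raise FormatError(f"missing input file(s) in {indir}: {missing}")


def score_bundle(
    bundle,
    igg_threshold: float = 1e-5,
    pseudocount: float = 1e-5,
    scale: bool = True,
):
    """Score an in-memory cohort bundle: total-sum scale the sorted
    fractions, drop taxa undetected in the total population, isotype-correct
    the gate sizes, and return the probability-ratio matrix restricted to
    taxa detected in every sample."""
    ra_all = total_sum_scale(bundle.counts["all"])
    ra_pos = total_sum_scale(bundle.counts["igg_pos"])
    ra_neg = total_sum_scale(bundle.counts["igg_neg"])
    ra_pos_f, ra_neg_f = zero_absent_in_all(ra_pos, ra_neg, ra_all, igg_threshold)
    flow = _isotype_normalised_flow(bundle.flow)
    ratios = prob_ratio(ra_pos_f, ra_neg_f, flow,
                        pseudocount=pseudocount, scale=scale)
    common = select_common_features(ra_all, igg_threshold)
    return dataclasses.replace(ratios, ratio=ratios.ratio.loc[common])


def run_analyse(config: RunConfig) -> dict:
    """Run the full analysis over an input bundle; returns the manifest."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_inputs(indir)

    counts = {
        label: read_count_table(indir / f"counts_{label}.tsv", label)
        for label in ("all", "igg_pos", "igg_neg")
    }
    flow = read_flow_summary(indir / "flow_summary.tsv")
    metadata = read_metadata(indir / "metadata.tsv")
    gene_path = indir / "gene_families.tsv"
    gene_table = read_gene_family_table(gene_path) if gene_path.exists() else None

    outputs: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, index_name: str = "taxon_id") -> None:
        path = outdir / name
        write_matrix_tsv(df, path, index_name=index_name)
        outputs[name] = path

    # --- profiles -----------------------------------------------------
    rmp_table = rmp(counts["all"], config.rmp_threshold, config.rmp_pseudocount)
    qmp_table = qmp(rmp_table, flow)
    save("rmp.tsv", rmp_table.values)
    save("qmp.tsv", qmp_table.absolute_abundance)

    # --- antibody-binding scores -------------------------------------
    ra_all = total_sum_scale(counts["all"])
    ra_pos = total_sum_scale(counts["igg_pos"])
    ra_neg = total_sum_scale(counts["igg_neg"])
    ra_pos_f, ra_neg_f = zero_absent_in_all(
        ra_pos, ra_neg, ra_all, config.igg_threshold
    )
    flow_corrected = _isotype_normalised_flow(flow)
    ratios = prob_ratio(
        ra_pos_f, ra_neg_f, flow_corrected,
        pseudocount=config.igg_pseudocount, scale=config.scale_ratio,
    )
    common = select_common_features(ra_all, config.igg_threshold)
    ratios_common = ratios.ratio.loc[common]
    save("prob_ratios_taxa.tsv", ratios_common)

    presence = classify_fraction_presence(ra_pos_f, ra_neg_f, config.igg_threshold)
    presence_out = presence.join(metadata.data).reset_index(names="sample_id")
    presence_out = presence_out[
        ["pair_id", "role", "sample_id", "n_only_neg", "n_only_pos", "n_both",
         "proportion_pos"]
    ]
    presence_out["proportion_pos"] = presence_out["proportion_pos"].round(3)
    path = outdir / "fraction_presence.tsv"
    presence_out.to_csv(path, sep="\t", index=False)
    outputs["fraction_presence.tsv"] = path

    # --- diversity ----------------------------------------------------
    alpha = alpha_diversity(counts["all"])
    save("alpha_diversity.tsv", alpha, index_name="sample_id")
    # rarefied richness of the sorted fractions at the cohort-wide minimum
    sorted_depth = int(
        min(counts["igg_pos"].counts.sum(axis=0).min(),
            counts["igg_neg"].counts.sum(axis=0).min())
    )
    frac_alpha = pd.concat(
        {
            label: alpha_diversity(counts[label], rarefaction_depth=sorted_depth)
            for label in ("igg_pos", "igg_neg")
        },
        names=["fraction", "sample_id"],
    )
    save("alpha_diversity_fractions.tsv", frac_alpha.reset_index().set_index("fraction"),
         index_name="fraction")

    def _save_nmds(name: str, dissim: pd.DataFrame) -> None:
        if len(dissim) <= config.nmds_dims:
            logger.warning(
                "skipping %s: %d samples cannot be embedded in %d dimensions",
                name, len(dissim), config.nmds_dims,
            )
            return
        result = nmds(dissim, k=config.nmds_dims, n_starts=config.nmds_starts,
                      seed=config.seed)
        coords = result.coordinates.copy()
        coords["stress"] = result.stress
        save(name, coords, index_name="sample_id")

    bc = bray_curtis(rmp_table)
    save("bray_curtis_rmp.tsv", bc, index_name="sample_id")
    _save_nmds("nmds_rmp.tsv", bc)

    # bound/unbound fractions together, Bray-Curtis + NMDS
    combined = pd.concat(
        [
            ra_pos_f.values.add_suffix("_igg_pos"),
            ra_neg_f.values.add_suffix("_igg_neg"),
        ],
        axis=1,
    )
    bc_frac = bray_curtis(RelAbundanceTable(combined, "all"))
    save("bray_curtis_fractions.tsv", bc_frac, index_name="sample_id")
    _save_nmds("nmds_fractions.tsv", bc_frac)

    # --- functional ---------------------------------------------------
    if gene_table is not None:
        processed = apply_threshold_families(
            renormalise(zero_families_absent_in_all(gene_table)),
            config.gene_threshold,
        )
        # 'all'-fraction comparison: prevalence filter -> CLR -> PCA
        all_frame = processed.fraction_frame("all")
        filtered = prevalence_filter(
            dataclasses.replace(processed, values=all_frame),
            config.gene_threshold,
            config.prevalence_max_below,
        )
        if len(filtered.values) >= 2:
            clr = clr_transform(filtered.values)
            pca_res = pca(clr)
            save("gene_pca_scores.tsv", pca_res.scores, index_name="sample_id")
            ev = pd.DataFrame(
                {"explained_variance_fraction": pca_res.explained_variance_ratio},
                index=pca_res.scores.columns,
            )
            save("gene_pca_variance.tsv", ev, index_name="component")
        gf_ratios = gene_family_prob_ratio(
            processed, flow_corrected,
            pseudocount=config.gene_pseudocount, scale=config.scale_ratio,
        )
        save("prob_ratios_gene_families.tsv", gf_ratios.ratio,
             index_name="gene_family")
        if len(gf_ratios.ratio) >= 2:
            pca_gf = pca(gf_ratios.ratio)
            save("gene_ratio_pca_scores.tsv", pca_gf.scores,
                 index_name="sample_id")

    # --- paired statistics -------------------------------------------
    pairs = metadata.paired_samples()
    measures: dict[str, pd.Series] = {
        "mean_prob_ratio": ratios_common.mean(axis=0),
        "shannon": alpha["shannon"],
        "inv_simpson": alpha["inv_simpson"],
        "observed_richness": alpha["observed_richness"],
        "microbial_load": flow.data["microbial_load"],
        "igg_pos_size": flow_corrected.data["igg_pos_size"],
        "proportion_pos": presence["proportion_pos"],
    }
    rows = []
    for name, series in measures.items():
        pat = series.loc[pairs["patient"]].to_numpy(dtype=float)
        con = series.loc[pairs["control"]].to_numpy(dtype=float)
        try:
            res = paired_t_test(pat, con, auto_log=True, measure=name)
            rows.append(
                {
                    "measure": name,
                    "n_pairs": res.n_pairs,
                    "transform": "log" if res.transform_applied else "none",
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                }
            )
        except Exception as exc:  # degenerate tests are reported, not fatal
            logger.warning("paired test for %s failed: %s", name, exc)
            rows.append(
                {"measure": name, "n_pairs": len(pat), "transform": "none",
                 "t_statistic": np.nan, "p_value": np.nan}
            )
    stats_df = pd.DataFrame(rows)
    path = outdir / "paired_stats.tsv"
    stats_df.to_csv(path, sep="\t", index=False)
    outputs["paired_stats.tsv"] = path

    manifest = {
        "package": "iggseq",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": sorted(outputs),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
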