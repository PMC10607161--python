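"""Synthetic sorted-fraction cohorts with known ground truth.

The generator emulates the measurement chain of an IgG-Seq experiment well
enough to exercise every downstream stage:

1. A ground-truth community per sample: lognormal relative abundances RA_i,
   a per-taxon antibody-coating probability theta_i drawn from a Beta
   distribution, a flow-cytometric microbial load (cells/gram), and a binary
   taxon-to-gene-family incidence map.
2. Cell sorting: coating is per-cell Bernoulli(theta_i), i.i.d. within a
   taxon, so the bound gate receives probability mass RA_i * theta_i and the
   unbound gate RA_i * (1 - theta_i).  Reported gate sizes are shrunk by a
   small ``gating_gap`` (events assigned to neither gate) and the bound gate
   is inflated by an isotype-control background that downstream isotype
   normalisation subtracts again.
3. Sequencing: multinomial read counts at fixed depth per fraction, with no
   taxon-specific genome-size or amplification bias, so the probability
   ratio computed downstream converges to log2(theta_i / (1 - theta_i)).

Cohorts pair each patient with a same-household control: the two share
correlated log-abundances (``household_similarity``) and the patient's
coating odds are multiplied by ``patient_theta_scale`` (< 1 encodes the
hypothesised reduced IgG reactivity of patients).

All randomness flows from explicit integer seeds; a cohort seed
deterministically derives per-sample streams, so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyFractionError, ValidationError
from .functional import GeneFamilyTable, write_gene_family_table
from .io import (
    write_bracken_report,
    write_count_table,
    write_flow_summary,
    write_matrix_tsv,
    write_metadata,
)
from .tables import CohortMetadata, FlowSummary, FractionCountTable


@dataclass
class CohortScenario:
    """Tunable description of the simulated study population.

    Defaults mirror a small household-paired gut-microbiome study: five
    patient-control pairs, strongly right-skewed species abundances
    (lognormal sigma 2), symmetric Beta(2, 2) coating probabilities, and
    microbial loads around 1.5e11 cells/gram.  ``patient_theta_scale``
    multiplies patients' coating odds (1 = null, < 1 = hyporeactive
    patients); ``household_similarity`` is the correlation of patient and
    control log-abundances within a pair.
    """

    n_pairs: int = 5
    patient_theta_scale: float = 1.0
    household_similarity: float = 0.7
    abundance_sigma: float = 2.0
    theta_alpha: float = 2.0
    theta_beta: float = 2.0
    n_taxa: int = 120
    n_gene_families: int = 150
    gene_incidence_prob: float = 0.3
    load_median: float = 1.5e11
    load_sigma: float = 0.35

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.patient_theta_scale <= 0:
            raise ValidationError("patient_theta_scale must be > 0")
        if not 0 <= self.household_similarity <= 1:
            raise ValidationError("household_similarity must lie in [0, 1]")
        if self.abundance_sigma < 0:
            raise ValidationError("abundance_sigma must be >= 0")
        if self.theta_alpha <= 0 or self.theta_beta <= 0:
            raise ValidationError("Beta parameters must be positive")


@dataclass
class SortSpec:
    """Instrument-side knobs: sorted cell counts, depth, non-idealities."""

    n_cells_sorted: int = 1_000_000
    read_depth: int = 200_000
    isotype_background: float = 0.01
    gating_gap: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gating_gap <= 0.2:
            raise ValidationError("gating_gap must lie in [0, 0.2]")
        if self.read_depth < 0:
            raise ValidationError("read_depth must be >= 0")
        if not 0 <= self.isotype_background <= 0.2:
            raise ValidationError("isotype_background must lie in [0, 0.2]")


@dataclass
class GroundTruthCommunity:
    """Latent state of one sample: abundances, coating, load, gene map."""

    taxon_ids: list[str]
    rel_abundance: np.ndarray
    coating_prob: np.ndarray
    microbial_load: float
    gene_incidence: pd.DataFrame  # taxa x gene families, 0/1

    def __post_init__(self) -> None:
        ra = np.asarray(self.rel_abundance, dtype=float)
        theta = np.asarray(self.coating_prob, dtype=float)
        if (ra < 0).any() or abs(ra.sum() - 1.0) > 1e-12:
            raise ValidationError("rel_abundance must be >= 0 and sum to 1")
        if ((theta < 0) | (theta > 1)).any():
            raise ValidationError("coating_prob must lie in [0, 1]")
        if self.microbial_load <= 0:
            raise ValidationError("microbial_load must be positive")
        self.rel_abundance = ra
        self.coating_prob = theta


def generate_community(
    n_taxa: int, scenario: CohortScenario, seed: int
) -> GroundTruthCommunity:
    """Draw one ground-truth community.

    Relative abundances are lognormal(0, ``abundance_sigma``) normalised to
    sum to 1 (sigma 0 gives a uniform community); coating probabilities are
    Beta(``theta_alpha``, ``theta_beta``); the load is lognormal around
    ``load_median``.
    """
    if n_taxa < 2:
        raise ValidationError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, scenario.abundance_sigma, n_taxa))
    ra = raw / raw.sum()
    theta = rng.beta(scenario.theta_alpha, scenario.theta_beta, n_taxa)
    load = float(
        np.exp(rng.normal(np.log(scenario.load_median), scenario.load_sigma))
    )
    taxon_ids = [f"sp{i:04d}" for i in range(n_taxa)]
    gene_ids = [f"GF{i:05d}" for i in range(scenario.n_gene_families)]
    incidence = pd.DataFrame(
        (rng.random((n_taxa, scenario.n_gene_families))
         < scenario.gene_incidence_prob).astype(int),
        index=taxon_ids,
        columns=gene_ids,
    )
    return GroundTruthCommunity(taxon_ids, ra, theta, load, incidence)


def true_fraction_sizes(community: GroundTruthCommunity) -> tuple[float, float]:
    """Expected bound/unbound gate sizes under per-cell Bernoulli coating.

    Before any gating gap is applied the two sizes sum to exactly 1.
    """
    pos = float(np.dot(community.rel_abundance, community.coating_prob))
    return pos, 1.0 - pos


def scale_coating_odds(theta: np.ndarray, scale: float) -> np.ndarray:
    """Multiply coating odds theta/(1-theta) by ``scale``, back to probability."""
    theta = np.asarray(theta, dtype=float)
    return scale * theta / (1.0 - theta + scale * theta)


def simulate_fractions(
    community: GroundTruthCommunity,
    spec: SortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.Series], dict[str, float]]:
    """Sort and sequence one sample.

    Returns per-fraction read-count vectors ('all', 'igg_pos', 'igg_neg')
    drawn multinomially from the composition each gate receives, and a
    flow-summary row with reported gate sizes: true sizes shrunk by the
    gating gap, plus the isotype background added to the bound gate (the
    recorded ``isotype_pct`` lets downstream normalisation remove it again).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ra = community.rel_abundance
    theta = community.coating_prob
    pos_true, neg_true = true_fraction_sizes(community)
    compositions: dict[str, np.ndarray] = {"all": ra}
    for label, weight, mass in (
        ("igg_pos", ra * theta, pos_true),
        ("igg_neg", ra * (1.0 - theta), neg_true),
    ):
        if mass <= 0:
            if spec.read_depth > 0:
                raise EmptyFractionError(
                    f"fraction {label!r} has zero probability mass; the "
                    "scenario is degenerate (all coating probabilities "
                    f"{'0' if label == 'igg_pos' else '1'})"
                )
            compositions[label] = np.zeros_like(ra)
        else:
            compositions[label] = weight / mass
    counts = {
        label: pd.Series(
            rng.multinomial(spec.read_depth, p).astype(float)
            if spec.read_depth > 0
            else np.zeros(len(ra)),
            index=community.taxon_ids,
        )
        for label, p in compositions.items()
    }
    flow_row = {
        "igg_pos_size": pos_true * (1.0 - spec.gating_gap) + spec.isotype_background,
        "igg_neg_size": neg_true * (1.0 - spec.gating_gap),
        "isotype_pct": spec.isotype_background * 100.0,
        "microbial_load": community.microbial_load,
    }
    return counts, flow_row


@dataclass
class CohortBundle:
    """Everything a pipeline run needs, plus the latent ground truth."""

    counts: dict[str, FractionCountTable]
    flow: FlowSummary
    gene_families: GeneFamilyTable
    metadata: CohortMetadata
    ground_truth: dict[str, GroundTruthCommunity]
    scenario: CohortScenario
    spec: SortSpec
    seed: int


def _correlated_log_abundances(
    rng_house: np.random.Generator,
    rng_pat: np.random.Generator,
    rng_con: np.random.Generator,
    n_taxa: int,
    sigma: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two log-abundance vectors with correlation ``rho`` and scale ``sigma``."""
    shared = rng_house.normal(0.0, 1.0, n_taxa)
    own_p = rng_pat.normal(0.0, 1.0, n_taxa)
    own_c = rng_con.normal(0.0, 1.0, n_taxa)
    w_shared, w_own = np.sqrt(rho), np.sqrt(1.0 - rho)
    log_p = sigma * (w_shared * shared + w_own * own_p)
    log_c = sigma * (w_shared * shared + w_own * own_c)
    return log_p, log_c


def generate_cohort(
    scenario: CohortScenario, spec: SortSpec, seed: int
) -> CohortBundle:
    """Simulate a full household-paired cohort.

    Within a pair, patient and control share correlated log-abundances and
    the same baseline coating probabilities; the patient's coating odds are
    multiplied by ``patient_theta_scale``.  The taxon list and the
    taxon-to-gene-family incidence map are shared cohort-wide so that
    common-feature selection downstream behaves as in a real study.
    """
    ss = np.random.SeedSequence(seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    n_taxa = scenario.n_taxa
    taxon_ids = [f"sp{i:04d}" for i in range(n_taxa)]
    gene_ids = [f"GF{i:05d}" for i in range(scenario.n_gene_families)]
    incidence = pd.DataFrame(
        (cohort_rng.random((n_taxa, scenario.n_gene_families))
         < scenario.gene_incidence_prob).astype(int),
        index=taxon_ids,
        columns=gene_ids,
    )

    count_cols: dict[str, dict[str, pd.Series]] = {
        "all": {}, "igg_pos": {}, "igg_neg": {}
    }
    flow_rows: dict[str, dict[str, float]] = {}
    gf_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    truth: dict[str, GroundTruthCommunity] = {}

    inc_arr = incidence.to_numpy(dtype=float)
    for p in range(scenario.n_pairs):
        pair_ss = ss.spawn(1)[0]
        streams = [np.random.default_rng(s) for s in pair_ss.spawn(6)]
        rng_house, rng_pat, rng_con, rng_theta, rng_load, rng_seq = streams
        log_p, log_c = _correlated_log_abundances(
            rng_house, rng_pat, rng_con, n_taxa,
            scenario.abundance_sigma, scenario.household_similarity,
        )
        theta_base = rng_theta.beta(scenario.theta_alpha, scenario.theta_beta, n_taxa)
        theta_patient = scale_coating_odds(theta_base, scenario.patient_theta_scale)
        for role, log_a, theta in (
            ("patient", log_p, theta_patient),
            ("control", log_c, theta_base),
        ):
            sample_id = f"{'P' if role == 'patient' else 'C'}{p + 1}"
            raw = np.exp(log_a)
            ra = raw / raw.sum()
            load = float(np.exp(
                rng_load.normal(np.log(scenario.load_median), scenario.load_sigma)
            ))
            community = GroundTruthCommunity(taxon_ids, ra, theta, load, incidence)
            counts, flow_row = simulate_fractions(community, spec, rng=rng_seq)
            for label in count_cols:
                count_cols[label][sample_id] = counts[label]
            flow_rows[sample_id] = flow_row
            truth[sample_id] = community
            meta_rows.append(
                {"sample_id": sample_id, "pair_id": str(p + 1), "role": role}
            )
            # gene-family signal: incidence weighted by the observed
            # composition of each fraction, on an RPK-like scale
            for label in ("all", "igg_pos", "igg_neg"):
                vec = counts[label].to_numpy(dtype=float)
                total = vec.sum()
                comp = vec / total if total > 0 else np.zeros_like(vec)
                gf_cols[f"{sample_id}_{label}"] = comp @ inc_arr * 1e6

    tables = {
        label: FractionCountTable(pd.DataFrame(cols).fillna(0.0), label)
        for label, cols in count_cols.items()
    }
    flow = FlowSummary(pd.DataFrame(flow_rows).T)
    gene_table = GeneFamilyTable(
        pd.DataFrame(gf_cols, index=gene_ids), unit="rpk"
    )
    metadata = CohortMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id")
    )
    return CohortBundle(
        counts=tables,
        flow=flow,
        gene_families=gene_table,
        metadata=metadata,
        ground_truth=truth,
        scenario=scenario,
        spec=spec,
        seed=seed,
    )


def write_bundle(
    bundle: CohortBundle, outdir: str | Path, bracken_reports: bool = False
) -> list[Path]:
    """Write a cohort bundle as plain TSV files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label, table in bundle.counts.items():
        path = outdir / f"counts_{label}.tsv"
        write_count_table(table, path)
        written.append(path)
    path = outdir / "flow_summary.tsv"
    write_flow_summary(bundle.flow, path)
    written.append(path)
    path = outdir / "metadata.tsv"
    write_metadata(bundle.metadata, path)
    written.append(path)
    path = outdir / "gene_families.tsv"
    write_gene_family_table(bundle.gene_families, path)
    written.append(path)
    # latent ground truth, for estimator-recovery checks
    ra = pd.DataFrame(
        {s: c.rel_abundance for s, c in bundle.ground_truth.items()},
        index=next(iter(bundle.ground_truth.values())).taxon_ids,
    )
    theta = pd.DataFrame(
        {s: c.coating_prob for s, c in bundle.ground_truth.items()},
        index=ra.index,
    )
    for name, df in (("truth_rel_abundance", ra), ("truth_coating_prob", theta)):
        path = outdir / f"{name}.tsv"
        write_matrix_tsv(df, path)
        written.append(path)
    if bracken_reports:
        rep_dir = outdir / "bracken"
        rep_dir.mkdir(exist_ok=True)
        for label, table in bundle.counts.items():
            for sample in table.sample_ids:
                vec = table.counts[sample]
                keyed = pd.Series(
                    vec.to_numpy(),
                    index=[f"{t}|{i}" for i, t in enumerate(vec.index)],
                )
                path = rep_dir / f"{sample}_{label}.bracken.tsv"
                write_bracken_report(keyed, path)
                written.append(path)
    return written
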