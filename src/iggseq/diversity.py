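"""Alpha and beta diversity of sorted-fraction communities.

Alpha diversity: Shannon entropy (natural log by default), inverse Simpson
(effective number of species), and rarefied observed richness.  Richness is
computed as the analytic expectation of the number of species seen when
``depth`` reads are drawn without replacement from a sample with counts N_i
and total N (hypergeometric expectation):

    E[S_depth] = sum_i [ 1 - C(N - N_i, depth) / C(N, depth) ]

which is deterministic and unbiased; a Monte-Carlo mode that repeatedly
subsamples without replacement is available for cross-checking.

Beta diversity: Bray-Curtis dissimilarity on relative abundances and
non-metric multidimensional scaling (NMDS) of the resulting matrix, run from
multiple random starts with Kruskal stress-1 reported for the best one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.manifold import MDS

from .exceptions import ValidationError
from .tables import FractionCountTable, RelAbundanceTable


def _proportions(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValidationError("abundance vector sums to zero")
    return x / total


def shannon(abundances, base: float = np.e) -> float:
    """Shannon diversity index, in units of log ``base`` (nats by default)."""
    p = _proportions(abundances)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def inv_simpson(abundances) -> float:
    """Inverse Simpson index: effective number of equally-abundant species."""
    p = _proportions(abundances)
    return float(1.0 / (p**2).sum())


def rarefied_richness(
    counts,
    depth: int,
    method: str = "analytic",
    n_reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Expected number of species observed in a without-replacement subsample.

    ``method="analytic"`` evaluates the hypergeometric expectation exactly;
    ``method="montecarlo"`` averages over ``n_reps`` seeded subsamples.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("counts must be non-negative")
    n = x.sum()
    if depth < 0 or depth > n:
        raise ValidationError(f"depth must lie in [0, {int(n)}], got {depth}")
    x = x[x > 0]
    if method == "analytic":
        # log C(N - N_i, d) - log C(N, d), via log-gamma for numeric range
        def log_comb(a: np.ndarray, b: float) -> np.ndarray:
            out = np.full_like(a, -np.inf, dtype=float)
            ok = a >= b
            out[ok] = gammaln(a[ok] + 1) - gammaln(b + 1) - gammaln(a[ok] - b + 1)
            return out

        log_p_absent = log_comb(n - x, depth) - log_comb(np.array([n]), depth)
        return float((1.0 - np.exp(log_p_absent)).sum())
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        ints = x.astype(np.int64)
        seen = 0.0
        for _ in range(n_reps):
            draw = rng.multivariate_hypergeometric(ints, depth)
            seen += (draw > 0).sum()
        return float(seen / n_reps)
    raise ValidationError(f"unknown rarefaction method {method!r}")


def alpha_diversity(
    counts: FractionCountTable,
    rarefaction_depth: int | None = None,
    base: float = np.e,
) -> pd.DataFrame:
    """Per-sample alpha diversity table.

    ``rarefaction_depth`` defaults to the cohort-wide minimum sample depth
    (reads are rarefied to the lowest sequencing depth across samples).
    """
    totals = counts.counts.sum(axis=0)
    if rarefaction_depth is None:
        rarefaction_depth = int(totals.min())
    rows = []
    for sample in counts.sample_ids:
        vec = counts.counts[sample].to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": sample,
                "shannon": shannon(vec, base=base),
                "inv_simpson": inv_simpson(vec),
                "observed_richness": rarefied_richness(vec, rarefaction_depth),
                "rarefaction_depth": rarefaction_depth,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: RelAbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(x, y) = 1 - 2 * sum_i min(x_i, y_i) / sum_i (x_i + y_i)
    """
    if len(table.sample_ids) < 2:
        raise ValidationError("need at least two samples")
    mat = table.values.to_numpy(dtype=float).T  # samples x taxa
    dm = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class OrdinationResult:
    """NMDS embedding: sample coordinates, Kruskal stress-1, convergence."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    seed: int | None = None


def nmds(
    dissimilarity: pd.DataFrame,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = 0,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Runs ``n_starts`` random initialisations of SMACOF with monotone
    regression and keeps the lowest-stress configuration.  Stress is
    Kruskal's stress-1; the run is flagged converged when at least two starts
    (or the single start requested) agree with the best stress to 1e-3.
    """
    n = len(dissimilarity)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k must be < number of samples ({n})")
    if not np.allclose(dissimilarity.values, dissimilarity.values.T):
        raise ValidationError("dissimilarity matrix must be symmetric")
    ss = np.random.SeedSequence(seed)
    stresses = []
    best: tuple[float, np.ndarray] | None = None
    for child in ss.spawn(n_starts):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=1,
            random_state=rs,
            max_iter=max_iter,
            normalized_stress=True,
        )
        coords = model.fit_transform(dissimilarity.values)
        stresses.append(model.stress_)
        if best is None or model.stress_ < best[0]:
            best = (float(model.stress_), coords)
    assert best is not None
    stress, coords = best
    n_agree = sum(1 for s in stresses if s - stress < 1e-3)
    converged = n_agree >= min(2, n_starts)
    coord_df = pd.DataFrame(
        coords,
        index=dissimilarity.index,
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return OrdinationResult(coord_df, stress=stress, converged=converged, seed=seed)
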