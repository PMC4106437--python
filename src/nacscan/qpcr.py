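"""qRT-PCR Ct processing, reference-gene stability and profile clustering.

Raw Ct values from technical triplicates are summarized with a simple
outlier rule (replicate range above one cycle triggers removal of values
more than half a cycle from the median).  Candidate reference genes are
ranked by the geNorm stability measure M: for each gene pair the standard
deviation of per-sample log2 expression ratios is taken, and M_j is the
mean of those pairwise SDs over all partners — lower M means the gene
covaries more faithfully with the panel.  Expression is normalized to a
reference gene by delta-Ct (2^(Ct_ref - Ct_gene)), samples are ordered by
decreasing chlorophyll content as a senescence axis, and per-gene
standardized profiles are clustered by k-means with the sqrt(n/2)
rule-of-thumb cluster count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def summarize_replicates(
    values,
    range_threshold: float = 1.0,
    outlier_distance: float = 0.5,
) -> tuple[float, str]:
    """Mean Ct of up to three replicate wells, with outlier screening.

    If the replicate range exceeds ``range_threshold`` cycles, values
    more than ``outlier_distance`` from the median are dropped and the
    result flagged ``outlier_removed``.  Returns (Ct, flag); all-missing
    input yields (nan, "no_data").
    """
    vals = np.asarray([v for v in values if v is not None and np.isfinite(v)],
                      dtype=float)
    if len(vals) == 0:
        return float("nan"), "no_data"
    if len(vals) > 1 and (vals.max() - vals.min()) > range_threshold:
        med = float(np.median(vals))
        kept = vals[np.abs(vals - med) <= outlier_distance]
        if len(kept) == 0:  # pathological spread: keep the median itself
            kept = np.array([med])
        return float(kept.mean()), "outlier_removed"
    return float(vals.mean()), "clean"


def summarize_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long Ct table (gene_id, sample_id, replicate, ct) to one
    row per (gene, sample) with the summarized Ct and its QC flag."""
    required = {"gene_id", "sample_id", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for (gene, sample), sub in ct.groupby(["gene_id", "sample_id"], sort=True):
        if len(sub) > 3:
            raise ValueError(
                f"more than 3 replicates for ({gene}, {sample}): {len(sub)}"
            )
        val, flag = summarize_replicates(sub["ct"].to_numpy())
        rows.append((gene, sample, val, flag))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "ct", "qc_flag"])


@dataclass(frozen=True)
class StabilityResult:
    gene_id: str
    M: float
    rank: int


def reference_stability(quantities: pd.DataFrame) -> list[StabilityResult]:
    """geNorm stability M for candidate reference genes.

    ``quantities`` is genes x samples of strictly positive relative
    quantities.  For each gene pair (j, k) the SD (n-1 denominator) of
    per-sample log2 ratios is V_jk; M_j is the mean of V_jk over k != j.
    Genes are ranked ascending by M (rank 1 = most stable).  M is
    invariant to rescaling any gene by a constant.
    """
    Q = quantities.to_numpy(dtype=float)
    if Q.shape[0] < 2 or Q.shape[1] < 2:
        raise ValueError(
            f"need >= 2 candidate genes and >= 2 samples, got {Q.shape}"
        )
    bad = np.argwhere(~(Q > 0))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-positive quantity at gene {quantities.index[i]!r}, "
            f"sample {quantities.columns[j]!r}"
        )
    logq = np.log2(Q)
    n = Q.shape[0]
    V = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            V[j, k] = V[k, j] = float(np.std(logq[j] - logq[k], ddof=1))
    M = V.sum(axis=1) / (n - 1)
    order = sorted(range(n), key=lambda j: (M[j], str(quantities.index[j])))
    ranks = {j: r + 1 for r, j in enumerate(order)}
    return [
        StabilityResult(str(quantities.index[j]), float(M[j]), ranks[j])
        for j in range(n)
    ]


def normalize_expression(ct_gene, ct_ref):
    """Delta-Ct relative expression 2^(Ct_ref - Ct_gene).

    Assumes doubling per PCR cycle; missing input propagates missing.
    Accepts scalars or arrays.
    """
    ct_gene = np.asarray(ct_gene, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    out = np.power(2.0, ct_ref - ct_gene)
    if out.ndim == 0:
        return float(out)
    return out


def choose_k(n_genes: int) -> int:
    """Rule-of-thumb k-means cluster count: round(sqrt(n/2)), half-up,
    minimum 1.  91 genes (44 senescence markers + 47 NAC genes) -> 7."""
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    return max(1, int(math.floor(math.sqrt(n_genes / 2.0) + 0.5)))


@dataclass
class ExpressionPanel:
    """Relative expression (linear scale) with a chlorophyll covariate.

    ``expression`` is genes x samples; ``chlorophyll`` is indexed by
    sample id.  ``sample_order`` sorts samples by decreasing chlorophyll
    (senescence progression), ties broken by sample id.
    """

    expression: pd.DataFrame
    chlorophyll: pd.Series

    def __post_init__(self) -> None:
        if not set(self.expression.columns) <= set(self.chlorophyll.index):
            raise ValueError("every sample needs a chlorophyll value")
        if (self.chlorophyll < 0).any():
            raise ValueError("chlorophyll content must be non-negative")
        finite = self.expression.to_numpy(dtype=float)
        if np.nanmin(finite) <= 0:
            raise ValueError("relative expression must be positive")

    @property
    def sample_order(self) -> list[str]:
        chl = self.chlorophyll.loc[list(self.expression.columns)]
        return sorted(
            self.expression.columns, key=lambda s: (-chl[s], str(s))
        )

    def ordered(self) -> pd.DataFrame:
        """Expression with columns in decreasing-chlorophyll order."""
        return self.expression[self.sample_order]


def panel_from_ct(
    ct_summary: pd.DataFrame,
    reference_gene: str,
    chlorophyll: pd.Series,
) -> ExpressionPanel:
    """Build a reference-normalized panel from summarized Ct values."""
    wide = ct_summary.pivot(index="gene_id", columns="sample_id", values="ct")
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} not in Ct table")
    ref = wide.loc[reference_gene]
    expr = pd.DataFrame(
        np.power(2.0, ref.to_numpy()[None, :] - wide.to_numpy()),
        index=wide.index,
        columns=wide.columns,
    ).drop(index=reference_gene)
    return ExpressionPanel(expression=expr, chlorophyll=chlorophyll)


@dataclass
class ClusterResult:
    k: int
    assignment: pd.Series  # gene -> cluster label in 1..k
    centroids: np.ndarray  # k x samples, standardized scale
    inertia: float


def standardize_profiles(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scoring across ordered samples (log2 first).

    Constant genes map to all-zero profiles so clustering sees expression
    *patterns*, not levels.
    """
    logx = np.log2(expr.to_numpy(dtype=float))
    mean = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (logx - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def cluster_profiles(
    panel: ExpressionPanel,
    k: int | None = None,
    seed: int = 0,
    restarts: int = 100,
    standardize: bool = True,
) -> ClusterResult:
    """K-means clustering of senescence expression profiles.

    Missing values are imputed per-gene by linear interpolation over the
    chlorophyll-ordered samples; genes are z-scored (unless
    ``standardize=False``) before Lloyd's algorithm with ``restarts``
    random initializations; best-inertia solution kept.  Deterministic
    for a fixed seed.
    """
    expr = panel.ordered()
    n_genes = expr.shape[0]
    if k is None:
        k = choose_k(n_genes)
    if k > n_genes:
        raise ValueError(f"k={k} exceeds number of genes {n_genes}")
    filled = expr.astype(float).interpolate(
        axis=1, limit_direction="both"
    )
    X = (
        standardize_profiles(filled).to_numpy()
        if standardize
        else np.log2(filled.to_numpy())
    )
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    labels = pd.Series(km.labels_ + 1, index=expr.index, name="cluster")
    return ClusterResult(
        k=k,
        assignment=labels,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )
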