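"""Co-expression ranked lists and rank-bias statistics.

For each seed gene (typically a NAC transcription factor), every other
gene is ranked by Pearson correlation with the seed across samples;
rank 1 = most strongly co-expressed.  Whether a gene set (e.g. genes
whose promoters carry a NAC-binding site) sits toward the top of such a
list is quantified by a one-sided Mann-Whitney U test ("set A has
smaller ranks than set B") with the AUC effect size U/(|A||B|); the
binned rank histograms that the test summarizes are kept as first-class
output.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXACT_ENUMERATION_LIMIT = 12  # |A| + |B| above this -> normal approximation


@dataclass
class CoexpressionList:
    """Ranked co-expression list for one seed gene.

    ``ranked`` holds (gene_id, r) sorted by descending correlation with
    ties broken by gene id; the seed itself is excluded.
    """

    seed_gene: str
    ranked: pd.DataFrame  # columns: gene_id, correlation; 1-based rank = row + 1

    def rank_of(self, gene_id: str) -> int | None:
        pos = np.nonzero((self.ranked["gene_id"] == gene_id).to_numpy())[0]
        return int(pos[0]) + 1 if len(pos) else None

    def ranks_of(self, genes) -> tuple[np.ndarray, int]:
        """1-based ranks of member genes; second value = #genes absent."""
        lookup = {g: i + 1 for i, g in enumerate(self.ranked["gene_id"])}
        ranks = [lookup[g] for g in genes if g in lookup]
        return np.asarray(sorted(ranks)), len(list(genes)) - len(ranks)

    @property
    def universe_size(self) -> int:
        return len(self.ranked)


def build_coexpression_lists(
    expr: pd.DataFrame, seeds: list[str]
) -> dict[str, CoexpressionList]:
    """Pearson co-expression lists for each seed gene.

    ``expr`` is genes x samples (>= 3 samples).  Zero-variance genes get
    correlation 0 with a warning.  Ties in correlation break by gene id.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    missing = [s for s in seeds if s not in expr.index]
    if missing:
        raise ValueError(f"seed genes absent from matrix: {missing}")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance genes; correlations set to 0"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    safe_sd = np.where(flat, 1.0, sd)
    out: dict[str, CoexpressionList] = {}
    gene_ids = np.asarray(expr.index.astype(str))
    for seed in seeds:
        i = int(np.nonzero(gene_ids == seed)[0][0])
        if flat[i]:
            r = np.zeros(len(gene_ids))
        else:
            r = (Xc @ Xc[i]) / (X.shape[1] * safe_sd * sd[i])
            r[flat] = 0.0
        r = np.clip(r, -1.0, 1.0)
        keep = gene_ids != seed
        df = pd.DataFrame({"gene_id": gene_ids[keep], "correlation": r[keep]})
        df = df.sort_values(
            ["correlation", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
        out[seed] = CoexpressionList(seed_gene=seed, ranked=df)
    return out


def rank_distribution(
    clist: CoexpressionList,
    genes,
    n_bins: int = 20,
) -> tuple[np.ndarray, int]:
    """Histogram of the set's ranks in ``n_bins`` equal-width bins over
    [1, universe size].  Returns (counts, number of absent genes)."""
    genes = list(genes)
    ranks, n_missing = clist.ranks_of(genes)
    U = clist.universe_size
    edges = np.linspace(1, U + 1, n_bins + 1)
    counts, _ = np.histogram(ranks, bins=edges)
    return counts, n_missing


@dataclass
class RankBiasResult:
    set_a: str
    set_b: str
    U: float
    auc: float
    p_one_sided: float
    method: str
    histogram_a: np.ndarray = field(default_factory=lambda: np.array([]))
    histogram_b: np.ndarray = field(default_factory=lambda: np.array([]))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = #pairs (a < b) + 0.5 * #ties: large when A has smaller ranks."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float((a < b).sum() + 0.5 * (a == b).sum())


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """P(U >= u_obs) by full enumeration of label assignments of the
    pooled values (exact even with ties)."""
    pooled = np.concatenate([a, b])
    na = len(a)
    total = 0
    at_least = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u >= u_obs - 1e-9:
            at_least += 1
    return at_least / total


def _normal_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    na, nb = len(a), len(b)
    n = na + nb
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    mu = na * nb / 2.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0 if u_obs <= mu else 0.0
    z = (u_obs - mu - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def rank_bias_test(
    ranks_a,
    ranks_b,
    name_a: str = "A",
    name_b: str = "B",
    n_bins: int = 20,
    universe_size: int | None = None,
) -> RankBiasResult:
    """One-sided Mann-Whitney test that set A occupies smaller ranks.

    Exact p by enumeration when |A| + |B| <= 12, otherwise a normal
    approximation with tie correction.  ``auc`` = U/(|A||B|) estimates
    P(rank_A < rank_B) (0.5 under the null).
    """
    a = np.asarray(list(ranks_a), dtype=float)
    b = np.asarray(list(ranks_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both rank sets must be non-empty")
    u = _u_statistic(a, b)
    if len(a) + len(b) <= EXACT_ENUMERATION_LIMIT:
        p = _exact_p(a, b, u)
        method = "exact"
    else:
        p = _normal_p(a, b, u)
        method = "normal"
    U_max = universe_size or int(max(a.max(), b.max()))
    edges = np.linspace(1, U_max + 1, n_bins + 1)
    hist_a, _ = np.histogram(a, bins=edges)
    hist_b, _ = np.histogram(b, bins=edges)
    return RankBiasResult(
        set_a=name_a,
        set_b=name_b,
        U=u,
        auc=u / (len(a) * len(b)),
        p_one_sided=float(p),
        method=method,
        histogram_a=hist_a,
        histogram_b=hist_b,
    )


def random_gene_sample(universe, size: int = 500, seed: int = 0) -> set[str]:
    """Uniform sample of gene ids without replacement (deterministic)."""
    ids = sorted(universe)
    if size > len(ids):
        raise ValueError(f"sample size {size} exceeds universe {len(ids)}")
    rng = np.random.default_rng(seed)
    return set(rng.choice(ids, size=size, replace=False))


def load_ranked_lists(path) -> dict[str, CoexpressionList]:
    """Load externally exported ranked lists from TSV
    (seed_gene, gene_id, rank[, correlation])."""
    df = pd.read_csv(path, sep="\t")
    required = {"seed_gene", "gene_id", "rank"}
    if not required <= set(df.columns):
        raise ValueError(f"ranked-list TSV needs columns {sorted(required)}")
    out = {}
    for seed, sub in df.groupby("seed_gene"):
        sub = sub.sort_values("rank")
        corr = sub["correlation"] if "correlation" in sub else np.nan
        ranked = pd.DataFrame(
            {"gene_id": sub["gene_id"].astype(str).to_numpy(),
             "correlation": corr}
        )
        out[str(seed)] = CoexpressionList(seed_gene=str(seed), ranked=ranked)
    return out
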