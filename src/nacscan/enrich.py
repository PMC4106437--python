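"""Hypergeometric over-representation of motif-containing promoters.

For a universe of N promoters of which K contain at least one motif
occurrence, a gene set of size n with k motif-containing promoters is
tested for over-representation with the exact hypergeometric upper tail
P(X >= k), computed by log-space tail summation.

Because the hypergeometric is discrete, the plain upper tail is
conservative; the report therefore also carries the mid-p value
P(X > k) + 0.5 * P(X = k) and assigns its significance stars from the
mid-p by default (``p_mode="mid"``).  Stars follow the usual two-level
annotation: ``**`` for p <= 0.01, ``*`` for p <= 0.05, ``NS`` otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    for cond, msg in [
        (0 <= K <= N, f"require 0 <= K <= N, got K={K}, N={N}"),
        (0 <= n <= N, f"require 0 <= n <= N, got n={n}, N={N}"),
        (0 <= k <= n, f"require 0 <= k <= n, got k={k}, n={n}"),
        (k <= K, f"require k <= K, got k={k}, K={K}"),
    ]:
        if not cond:
            raise ValueError(f"hypergeometric bound violated: {msg}")


def hypergeom_logpmf(N: int, K: int, n: int, k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return _log_comb(float(K), k) + _log_comb(float(N - K), n - k) - _log_comb(
        float(N), float(n)
    )


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n), in log space."""
    _check_bounds(N, K, n, k)
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    ks = np.arange(k, hi + 1)
    if len(ks) == 0:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(hypergeom_logpmf(N, K, n, ks)))))


def hypergeom_mid(N: int, K: int, n: int, k: int) -> float:
    """Mid-p upper tail: P(X > k) + 0.5 * P(X = k)."""
    _check_bounds(N, K, n, k)
    upper = hypergeom_upper(N, K, n, k)
    if k > min(K, n):
        return 0.0
    pmf = math.exp(hypergeom_logpmf(N, K, n, np.array([k]))[0])
    return float(max(0.0, min(1.0, upper - 0.5 * pmf)))


def hypergeom_two_sided(N: int, K: int, n: int, k: int) -> float:
    """Two-sided p: sum of all outcomes with pmf <= pmf(k)."""
    _check_bounds(N, K, n, k)
    ks = np.arange(max(0, n + K - N), min(K, n) + 1)
    logpmf = hypergeom_logpmf(N, K, n, ks)
    obs = hypergeom_logpmf(N, K, n, np.array([k]))[0]
    mask = logpmf <= obs + 1e-12
    return float(min(1.0, math.exp(logsumexp(logpmf[mask]))))


def stars(p: float) -> str:
    """Two-level significance annotation: ** (p<=0.01), * (p<=0.05), NS."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def per_1000(k: int, n: int) -> int:
    """Promoters-with-motif rate per 1000 genes, rounded half-up."""
    if n < 1:
        raise ValueError(f"set size must be >= 1, got n={n}")
    return int(math.floor(1000.0 * k / n + 0.5))


@dataclass(frozen=True)
class EnrichmentRow:
    """One motif x gene-set over-representation record."""

    motif: str
    set_name: str
    N: int
    K: int
    n: int
    k: int
    p_upper: float
    p_mid: float
    star: str
    per_1000: int
    flag: str = ""


_P_FUNCS = {
    "upper": hypergeom_upper,
    "mid": hypergeom_mid,
    "two_sided": hypergeom_two_sided,
}


def enrichment_row(
    motif: str,
    set_name: str,
    N: int,
    K: int,
    n: int,
    k: int,
    p_mode: str = "mid",
) -> EnrichmentRow:
    """Build one report row from a hypergeometric quadruple."""
    if p_mode not in _P_FUNCS:
        raise ValueError(f"p_mode must be one of {sorted(_P_FUNCS)}, got {p_mode!r}")
    p_upper = hypergeom_upper(N, K, n, k)
    p_mid = hypergeom_mid(N, K, n, k)
    p_star = _P_FUNCS[p_mode](N, K, n, k) if p_mode == "two_sided" else (
        p_mid if p_mode == "mid" else p_upper
    )
    flag = ""
    if stars(p_upper) != stars(p_mid):
        flag = "borderline"  # annotation depends on the discrete tail choice
    return EnrichmentRow(
        motif=motif,
        set_name=set_name,
        N=N,
        K=K,
        n=n,
        k=k,
        p_upper=p_upper,
        p_mid=p_mid,
        star=stars(p_star),
        per_1000=per_1000(k, n),
        flag=flag,
    )


def enrichment_report(
    hits,
    universe: set[str],
    sets: dict[str, set[str]],
    p_mode: str = "mid",
) -> pd.DataFrame:
    """Per-motif, per-set over-representation table plus union totals.

    ``hits`` is a :class:`nacscan.scan.HitTable`; ``universe`` the set of
    scanned promoter ids.  For each set a ``Total, non-redundant`` row is
    added using the union of motif-containing promoters.
    """
    universe = set(universe)
    N = len(universe)
    for name, ids in sets.items():
        if len(ids) == 0:
            raise ValueError(f"gene set {name!r} is empty")
        if not set(ids) <= universe:
            raise ValueError(f"gene set {name!r} is not a subset of the universe")
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = set(sets[a]) & set(sets[b])
            if shared:
                warnings.warn(
                    f"gene sets {a!r} and {b!r} overlap in {len(shared)} ids"
                )
    rows: list[EnrichmentRow] = []
    universe_union: set[str] = set()
    for motif in hits.counts.index:
        ids_universe = hits.hit_ids[motif] & universe
        universe_union |= ids_universe
        K = len(ids_universe)
        for set_name in names:
            n = len(sets[set_name])
            k = int(hits.counts.loc[motif, set_name])
            rows.append(enrichment_row(motif, set_name, N, K, n, k, p_mode))
    K_union = len(universe_union)
    for set_name in names:
        rows.append(
            enrichment_row(
                "Total, non-redundant",
                set_name,
                N,
                K_union,
                len(sets[set_name]),
                len(hits.unions[set_name]),
                p_mode,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df


def table4_style(report: pd.DataFrame) -> pd.DataFrame:
    """Pivot a report into the printed layout: one motif per row, one
    column per set with the count + star suffix, and a per-1000 footer."""
    out = {}
    for set_name, sub in report.groupby("set_name", sort=False):
        sub = sub.set_index("motif")
        out[set_name] = sub["k"].astype(str) + sub["star"]
    table = pd.DataFrame(out)
    footer = {}
    for set_name, sub in report.groupby("set_name", sort=False):
        total = sub[sub["motif"] == "Total, non-redundant"].iloc[0]
        footer[set_name] = str(per_1000(int(total["k"]), int(total["n"])))
    table.loc["Per 1000 genes"] = pd.Series(footer)
    return table
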