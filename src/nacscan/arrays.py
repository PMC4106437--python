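"""Single-channel microarray preprocessing and differential ranking.

The stage mirrors a standard Agilent one-colour workflow: "half"
background correction (signal minus background, floored at 0.5),
quantile normalization across arrays, low-signal filtering, reduction of
redundant probes to one representative per target (the probe with the
highest or second-highest mean signal that lies closest to the 3' end of
the target, where chip labelling starts), and a moderated two-sample t
ranking with Benjamini-Hochberg adjustment.  The moderated statistic
shrinks per-gene variances toward the median gene variance (prior weight
d0 = 4) — a documented stand-in for a full empirical-Bayes fit, which is
deliberately out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


@dataclass
class ProbeRecord:
    """One microarray probe with its target bookkeeping."""

    probe_id: str
    target_id: str
    probe_seq: str
    dist_to_3prime: int
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.dist_to_3prime < 0:
            raise ValueError(
                f"probe {self.probe_id}: dist_to_3prime must be >= 0, "
                f"got {self.dist_to_3prime}"
            )
        bad = set(self.probe_seq.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"probe {self.probe_id}: invalid bases {sorted(bad)}"
            )

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.signals))


@dataclass
class ArraySet:
    """Raw probe intensities with per-array background and group labels."""

    raw: np.ndarray
    background: np.ndarray
    group_labels: list[str]
    probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.raw.shape != self.background.shape:
            raise ValueError(
                f"raw shape {self.raw.shape} != background shape "
                f"{self.background.shape}"
            )
        if len(self.group_labels) != self.raw.shape[1]:
            raise ValueError(
                f"{len(self.group_labels)} group labels for "
                f"{self.raw.shape[1]} arrays"
            )


def background_correct_half(raw: np.ndarray, background: np.ndarray) -> np.ndarray:
    """'half' background correction: max(raw - background, 0.5)."""
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise ValueError(
            f"shape mismatch: raw {raw.shape} vs background {background.shape}"
        )
    for name, a in (("raw", raw), ("background", background)):
        bad = np.argwhere(~np.isfinite(a))
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"non-finite {name} intensity at probe {i}, array {j}"
            )
    return np.maximum(raw - background, 0.5)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile normalization: every column gets the mean sorted profile.

    Ties within a column are assigned the mean of the reference values
    they would have occupied.  A single-column matrix is returned
    unchanged with a logged warning.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires no missing values")
    if X.ndim != 2:
        raise ValueError(f"expected 2-D matrix, got shape {X.shape}")
    if X.shape[1] < 2:
        logger.warning("quantile_normalize: single column, returned unchanged")
        return X.copy()
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties -> mean of the reference values at their rank positions
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return out


def filter_low_signal(
    matrix: np.ndarray,
    background: np.ndarray,
    min_fold_over_bg: float = 1.1,
    min_fraction_arrays: float = 1.0,
    probe_ids: list[str] | None = None,
    group_labels: list[str] | None = None,
) -> tuple[list, int]:
    """Drop probes with signals close to or below background.

    A probe is kept iff its signal is >= ``min_fold_over_bg`` x background
    in at least ``min_fraction_arrays`` of the arrays of at least one
    condition group (all arrays as one group if no labels given).
    Returns (kept ids, kept count).
    """
    if min_fold_over_bg <= 0 or not (0 < min_fraction_arrays <= 1):
        raise ValueError(
            "min_fold_over_bg must be positive and min_fraction_arrays in (0, 1]"
        )
    X = np.asarray(matrix, dtype=float)
    B = np.asarray(background, dtype=float)
    if X.shape != B.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {B.shape}")
    above = X >= min_fold_over_bg * B
    if group_labels is None:
        groups = [np.arange(X.shape[1])]
    else:
        labels = np.asarray(group_labels)
        groups = [np.nonzero(labels == g)[0] for g in dict.fromkeys(group_labels)]
    keep = np.zeros(X.shape[0], dtype=bool)
    for idx in groups:
        frac = above[:, idx].mean(axis=1)
        keep |= frac >= min_fraction_arrays - 1e-12
    ids = probe_ids if probe_ids is not None else list(range(X.shape[0]))
    kept = [pid for pid, ok in zip(ids, keep) if ok]
    return kept, len(kept)


def select_representative_probe(probes: list[ProbeRecord]) -> str:
    """Pick one representative probe for a redundant target group.

    Among the two probes with the highest mean signal (all probes if the
    group has <= 2), the one closest to the target 3' end wins; distance
    ties go to the higher signal, and remaining ties to the smallest
    probe id.
    """
    if not probes:
        raise ValueError("empty probe group")
    targets = {p.target_id for p in probes}
    if len(targets) > 1:
        raise ValueError(f"probe group spans multiple targets: {sorted(targets)}")
    top2 = sorted(
        probes, key=lambda p: (-p.mean_signal, p.dist_to_3prime, p.probe_id)
    )[:2]
    best = min(
        top2, key=lambda p: (p.dist_to_3prime, -p.mean_signal, p.probe_id)
    )
    return best.probe_id


def deduplicate_probes(probes: list[ProbeRecord]) -> dict[str, str]:
    """Map every target id to its representative probe id."""
    by_target: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_target.setdefault(p.target_id, []).append(p)
    return {
        t: select_representative_probe(group) for t, group in by_target.items()
    }


def match_probe_to_gene(
    probe_seq: str,
    gene_seqs: dict[str, str],
    max_mismatch: int = 3,
) -> str | None:
    """Assign a probe to the gene containing the closest sequence window.

    Forward orientation only; a window matches if its Hamming distance to
    the probe is <= ``max_mismatch``.  Ambiguous bases in the probe count
    as mismatches against everything.  Among qualifying genes the
    smallest distance wins, then the lexicographically smallest id.
    """
    if len(probe_seq) < 1:
        raise ValueError("probe sequence must be non-empty")
    if max_mismatch < 0:
        raise ValueError(f"max_mismatch must be >= 0, got {max_mismatch}")
    probe = probe_seq.upper()
    L = len(probe)
    probe_arr = np.frombuffer(probe.encode(), dtype=np.uint8)
    ambiguous = ~np.isin(probe_arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    best: tuple[int, str] | None = None
    for gene_id in sorted(gene_seqs):
        seq = str(gene_seqs[gene_id]).upper()
        if len(seq) < L:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mism = (windows != probe_arr).sum(axis=1) + 0  # ambiguity handled below
        if ambiguous.any():
            # an ambiguous probe base mismatches even an equal character
            eq_amb = (windows == probe_arr) & ambiguous
            mism = mism + eq_amb.sum(axis=1)
        d = int(mism.min())
        if d <= max_mismatch and (best is None or d < best[0]):
            best = (d, gene_id)
    return best[1] if best else None


@dataclass(frozen=True)
class DERow:
    """Differential-expression record for one gene."""

    gene_id: str
    log2fc: float
    stat: float
    p: float
    p_adj: float
    rank: int


def rank_differential(
    expr: np.ndarray,
    groups: list[str],
    contrast: tuple[str, str],
    gene_ids: list[str] | None = None,
    d0: float = 4.0,
) -> list[DERow]:
    """Moderated-t differential ranking between two condition groups.

    ``expr`` is genes x arrays on the log2 scale.  Per-gene pooled
    variances are shrunk toward the median gene variance with prior
    weight ``d0``; two-sided p-values use a t distribution with
    (residual + d0) degrees of freedom and are BH-adjusted.  log2fc is
    mean(group2) - mean(group1).  If one group has a single array, genes
    are ranked by |fold change| with missing p-values (logged warning).
    """
    X = np.asarray(expr, dtype=float)
    labels = np.asarray(groups)
    g1, g2 = contrast
    i1 = np.nonzero(labels == g1)[0]
    i2 = np.nonzero(labels == g2)[0]
    if len(i1) == 0 or len(i2) == 0:
        raise ValueError(f"contrast groups {contrast} not found in labels")
    n1, n2 = len(i1), len(i2)
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(X.shape[0])]
    lfc = X[:, i2].mean(axis=1) - X[:, i1].mean(axis=1)
    if min(n1, n2) < 2 and max(n1, n2) < 2:
        raise ValueError("need >= 2 arrays in at least one group")
    if min(n1, n2) < 2:
        logger.warning(
            "rank_differential: a contrast group has a single array; "
            "falling back to fold-change ranking, p set to missing"
        )
        idx = sorted(
            range(len(lfc)), key=lambda i: (-abs(lfc[i]), gene_ids[i])
        )
        return [
            DERow(gene_ids[i], float(lfc[i]), float("nan"), float("nan"),
                  float("nan"), r + 1)
            for r, i in enumerate(idx)
        ]
    df_resid = n1 + n2 - 2
    ss = X[:, i1].var(axis=1, ddof=1) * (n1 - 1) + X[:, i2].var(
        axis=1, ddof=1
    ) * (n2 - 1)
    s2 = ss / df_resid
    s2_prior = float(np.median(s2))
    s2_mod = (d0 * s2_prior + df_resid * s2) / (d0 + df_resid)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_resid + d0)
    p_adj = stats.false_discovery_control(p, method="bh")
    idx = sorted(
        range(len(p)),
        key=lambda i: (p_adj[i], p[i], -abs(lfc[i]), gene_ids[i]),
    )
    return [
        DERow(
            gene_id=gene_ids[i],
            log2fc=float(lfc[i]),
            stat=float(t[i]),
            p=float(p[i]),
            p_adj=float(p_adj[i]),
            rank=r + 1,
        )
        for r, i in enumerate(idx)
    ]


def select_top(de: list[DERow], count: int) -> tuple[set[str], int]:
    """Top-``count`` gene ids by rank plus the selected percentage.

    Returns (id set, percentage of the list rounded to nearest integer).
    """
    if count <= 0:
        raise ValueError(f"count must be positive, got {count}")
    if count > len(de):
        raise ValueError(f"count {count} exceeds list length {len(de)}")
    chosen = {row.gene_id for row in sorted(de, key=lambda r: r.rank)[:count]}
    percent = int(round(100.0 * count / len(de)))
    return chosen, percent


def flag_outlier_arrays(expr: np.ndarray, n_mad: float = 3.0) -> list[int]:
    """Flag arrays whose median inter-array Spearman correlation falls
    more than ``n_mad`` MADs below the cohort median (screening only;
    exclusion is the caller's reversible choice)."""
    X = np.asarray(expr, dtype=float)
    if X.shape[1] < 3:
        return []
    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, np.nan)
    med = np.nanmedian(rho, axis=0)
    center = np.median(med)
    mad = np.median(np.abs(med - center))
    if mad == 0:
        return []
    return [int(j) for j in np.nonzero(med < center - n_mad * mad)[0]]


def de_to_frame(de: list[DERow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.stat, r.p, r.p_adj, r.rank) for r in de],
        columns=["gene_id", "log2fc", "stat", "p", "p_adj", "rank"],
    )
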