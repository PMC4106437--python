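"""FIMO-style motif scanning with exact p-values.

Every window of a promoter is scored against a letter-probability model
with the usual log-odds score sum_i log2(p_i(b) / bg(b)).  The null
distribution of the window score under a 0-order background is computed
exactly by dynamic programming over a discretized score grid (the same
machinery FIMO uses), which turns a score threshold into an exact
p-value threshold.  Hits are windows whose p-value is at or below the
threshold (default 1e-4), scanned on both strands by default.

Coordinates are 0-based half-open and promoter-relative; for 1000 bp
promoters, position 0 is 1000 bp upstream of the ATG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import ALPHABET, MotifModel, reverse_complement_model

_MAX_GRID_CELLS = 10_000_000

# sequence encoding: A=0 C=1 G=2 T=3, anything else (incl. N) = -1
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes (N and unknowns -> -1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Background:
    """0-order background distribution over A, C, G, T."""

    probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,) or not np.all(p > 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"background must be 4 positive probs summing to 1, got {self.probs}")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @classmethod
    def from_sequences(cls, seqs) -> "Background":
        """Estimate a 0-order background from sequences (N's ignored)."""
        counts = np.zeros(4)
        for s in seqs:
            enc = encode_sequence(str(s))
            counts += np.bincount(enc[enc >= 0], minlength=4)
        if counts.sum() == 0:
            raise ValueError("no A/C/G/T bases found to estimate background")
        # add-one smoothing keeps all probabilities positive
        counts += 1.0
        return cls(tuple(counts / counts.sum()))


UNIFORM_BACKGROUND = Background()


def log_odds(m: MotifModel, bg: Background | None = None) -> np.ndarray:
    """L x 4 log2(prob / background) score matrix (finite, probs floored)."""
    bg = bg or UNIFORM_BACKGROUND
    return np.log2(m.probs / bg.array)


@dataclass
class ScoreDistribution:
    """Exact null distribution of the window log-odds score.

    Scores are discretized to an integer grid with step ``granularity``;
    ``pmf[i]`` is the background probability that the sum of per-position
    integer scores equals ``offset + i``.  ``tail`` gives P(score' >= s).
    """

    granularity: float
    offset: int  # integer grid value of pmf[0]
    pmf: np.ndarray
    int_scores: np.ndarray  # L x 4 integer per-position scores
    tail_: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ValueError(f"pmf sums to {self.pmf.sum()}, not 1")
        tail = np.cumsum(self.pmf[::-1])[::-1]
        self.tail_ = np.minimum(tail, 1.0)

    def pvalue(self, int_score: int | np.ndarray) -> np.ndarray:
        """Exact p-value P(score >= int_score) on the integer grid."""
        idx = np.asarray(int_score) - self.offset
        idx = np.clip(idx, 0, len(self.tail_))
        padded = np.append(self.tail_, 0.0)
        return padded[idx]

    def min_int_score_at(self, p_threshold: float) -> int:
        """Smallest integer score whose tail p-value is <= p_threshold."""
        ok = np.nonzero(self.tail_ <= p_threshold)[0]
        if len(ok) == 0:
            return self.offset + len(self.pmf)  # unreachable: no score passes
        return self.offset + int(ok[0])


def score_pvalue_table(
    scores: np.ndarray,
    bg: Background | None = None,
    granularity: float = 0.01,
) -> ScoreDistribution:
    """Exact null distribution of the L-position score sum by DP.

    Per-position scores are rounded to the nearest multiple of
    ``granularity``; the distribution of their sum over a random word
    drawn from ``bg`` is then computed by exact convolution.
    """
    if granularity <= 0:
        raise ValueError(f"granularity must be positive, got {granularity}")
    bg = bg or UNIFORM_BACKGROUND
    scores = np.asarray(scores, dtype=float)
    int_scores = np.rint(scores / granularity).astype(np.int64)
    lo = int(int_scores.min(axis=1).sum())
    hi = int(int_scores.max(axis=1).sum())
    n_cells = hi - lo + 1
    if n_cells > _MAX_GRID_CELLS:
        raise ValueError(
            f"score grid needs {n_cells} cells (> {_MAX_GRID_CELLS}); "
            "use a coarser granularity"
        )
    bgp = bg.array
    # DP over positions: dist[s] = P(partial sum == s + cur_offset)
    dist = np.array([1.0])
    cur_offset = 0
    for pos in range(int_scores.shape[0]):
        row = int_scores[pos]
        rlo, rhi = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + (rhi - rlo), dtype=float)
        for a in range(4):
            shift = int(row[a]) - rlo
            new[shift : shift + len(dist)] += bgp[a] * dist
        dist = new
        cur_offset += rlo
    assert cur_offset == lo and len(dist) == n_cells
    return ScoreDistribution(
        granularity=granularity, offset=lo, pmf=dist, int_scores=int_scores
    )


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 0-based half-open window on a promoter."""

    promoter_id: str
    motif: str
    start: int
    end: int
    strand: str
    score: float
    p: float


class MotifScanner:
    """Scanner for one model against many sequences.

    Precomputes the log-odds matrices and exact score distributions for
    both strands so repeated scans are cheap.
    """

    def __init__(
        self,
        model: MotifModel,
        bg: Background | None = None,
        p_threshold: float = 1e-4,
        strands: str = "both",
        granularity: float = 0.01,
    ):
        if strands not in ("both", "forward"):
            raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
        self.model = model
        self.bg = bg or UNIFORM_BACKGROUND
        self.p_threshold = float(p_threshold)
        self.strands = strands
        self.granularity = granularity
        self._per_strand: list[tuple[str, ScoreDistribution, int]] = []
        strand_models = [("+", model)]
        if strands == "both":
            strand_models.append(("-", reverse_complement_model(model)))
        for strand, m in strand_models:
            dist = score_pvalue_table(log_odds(m, self.bg), self.bg, granularity)
            cut = dist.min_int_score_at(self.p_threshold)
            self._per_strand.append((strand, dist, cut))

    @staticmethod
    def _window_scores(enc: np.ndarray, int_scores: np.ndarray):
        """Integer score of every window; windows containing N are invalid."""
        L = int_scores.shape[0]
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = ~(windows < 0).any(axis=1)
        safe = np.where(windows < 0, 0, windows)
        scores = int_scores[np.arange(L)[None, :], safe].sum(axis=1)
        return scores, valid

    def scan(self, seq: str, promoter_id: str = "") -> list[MotifHit]:
        """All hits with p <= threshold, one per (position, strand)."""
        L = self.model.length
        if len(seq) < L:
            warnings.warn(
                f"sequence {promoter_id or '<anonymous>'} shorter than motif "
                f"({len(seq)} < {L}); no windows scored"
            )
            return []
        enc = encode_sequence(seq)
        hits: list[MotifHit] = []
        for strand, dist, cut in self._per_strand:
            scores, valid = self._window_scores(enc, dist.int_scores)
            passing = np.nonzero(valid & (scores >= cut))[0]
            if len(passing) == 0:
                continue
            pvals = dist.pvalue(scores[passing])
            for start, s, p in zip(passing, scores[passing], pvals):
                hits.append(
                    MotifHit(
                        promoter_id=promoter_id,
                        motif=self.model.name,
                        start=int(start),
                        end=int(start) + L,
                        strand=strand,
                        score=float(s) * self.granularity,
                        p=float(p),
                    )
                )
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits

    def has_hit(self, seq: str) -> bool:
        """Fast predicate: does any window pass the threshold?"""
        L = self.model.length
        if len(seq) < L:
            return False
        enc = encode_sequence(seq)
        for _strand, dist, cut in self._per_strand:
            scores, valid = self._window_scores(enc, dist.int_scores)
            if np.any(valid & (scores >= cut)):
                return True
        return False


def scan_sequence(
    seq: str,
    m: MotifModel,
    bg: Background | None = None,
    p_threshold: float = 1e-4,
    strands: str = "both",
    promoter_id: str = "",
    granularity: float = 0.01,
) -> list[MotifHit]:
    """Scan one sequence with one model (convenience wrapper)."""
    return MotifScanner(m, bg, p_threshold, strands, granularity).scan(
        seq, promoter_id
    )


def count_promoters_with_hit(
    promoters: dict[str, str],
    m: MotifModel,
    bg: Background | None = None,
    p_threshold: float = 1e-4,
    strands: str = "both",
    scanner: MotifScanner | None = None,
) -> tuple[int, set[str]]:
    """Number of promoters with >= 1 hit (each promoter counted once)."""
    ids = list(promoters)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate promoter ids")
    scanner = scanner or MotifScanner(m, bg, p_threshold, strands)
    with_hit = {pid for pid, seq in promoters.items() if scanner.has_hit(str(seq))}
    return len(with_hit), with_hit


@dataclass
class HitTable:
    """Per-motif / per-set promoter hit accounting.

    counts: DataFrame indexed by motif with one column per set (promoter-
    level counts); unions: per-set non-redundant promoter-id union over
    motifs; universe_hits: per-motif promoter-id sets over the universe.
    """

    counts: pd.DataFrame
    unions: dict[str, set[str]]
    hit_ids: dict[str, set[str]]  # motif -> promoter ids with a hit (universe)
    total_hits: dict[str, int]  # set -> sum of per-motif counts

    def union_counts(self) -> dict[str, int]:
        return {s: len(ids) for s, ids in self.unions.items()}


def scan_promoter_sets(
    models: list[MotifModel],
    promoters: dict[str, str],
    sets: dict[str, set[str]],
    bg: Background | None = None,
    p_threshold: float = 1e-4,
    strands: str = "both",
) -> HitTable:
    """Scan all promoters with all models and tabulate per-set hit counts.

    ``sets`` must be subsets of the promoter universe.  A promoter counts
    once per motif no matter how many matches it contains; the per-set
    union row is the non-redundant set of promoters hit by any motif.
    """
    universe = set(promoters)
    for name, ids in sets.items():
        extra = set(ids) - universe
        if extra:
            raise ValueError(
                f"set {name!r} contains {len(extra)} ids outside the "
                f"promoter universe (e.g. {sorted(extra)[:3]})"
            )
    hit_ids: dict[str, set[str]] = {}
    for m in models:
        _, ids = count_promoters_with_hit(
            promoters, m, bg, p_threshold, strands
        )
        hit_ids[m.name] = ids
    set_names = list(sets)
    rows = {
        m.name: [len(hit_ids[m.name] & set(sets[s])) for s in set_names]
        for m in models
    }
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=set_names)
    counts.index.name = "motif"
    unions = {
        s: set().union(*(hit_ids[m.name] & set(sets[s]) for m in models))
        for s in set_names
    }
    total_hits = {s: int(counts[s].sum()) for s in set_names}
    return HitTable(
        counts=counts, unions=unions, hit_ids=hit_ids, total_hits=total_hits
    )


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """Tabulate hits as a DataFrame (promoter_id, motif, start, end, ...)."""
    return pd.DataFrame(
        [
            (h.promoter_id, h.motif, h.start, h.end, h.strand, h.score, h.p)
            for h in hits
        ],
        columns=["promoter_id", "motif", "start", "end", "strand", "score", "p"],
    )
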