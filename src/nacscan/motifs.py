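"""Palindromic NAC-binding-site (NACBS) motif models.

NAC transcription factors bind DNA motifs built around a short CGT core.
Published binding studies suggest the core occurs as an inverted repeat
(CGT ... ACG) separated by a variable 5-10 nt spacer, often preceded by
T at the -2/-3 positions.  This module builds letter-probability models
for seven such motifs: NACBS-5 .. NACBS-10 carry the palindromic core
pair with spacers of 5-10 nt, and NACBS-1 is a single core with strongly
conserved T's upstream and no inverted repeat.

Consensus strings use the usual case convention: upper-case = core
(non-variable) base, lower-case = weakly conserved base with a minor
weight, ``n`` = unconstrained.  Models are serialized in MEME minimal
motif format so they can be used with any MEME-suite style scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Table of default NACBS consensus strings.  NACBS-k (k = 5..10) is
#: tt n CGT (n x k) ACG nnn; NACBS-1 is n tt n CGT g nnn.
DEFAULT_CONSENSUS: dict[str, str] = {
    "NACBS-1": "nttnCGTgnnn",
    **{f"NACBS-{k}": "ttnCGT" + "n" * k + "ACGnnn" for k in range(5, 11)},
}

DEFAULT_NAMES = tuple(DEFAULT_CONSENSUS)

#: Spacer length (inverted-repeat span) per default model; NACBS-1 has none.
DEFAULT_SPACERS: dict[str, int | None] = {
    "NACBS-1": None,
    **{f"NACBS-{k}": k for k in range(5, 11)},
}


@dataclass(frozen=True)
class WeightScheme:
    """Per-position probability weights used to expand a consensus string.

    Parameters
    ----------
    core_prob:
        Probability assigned to the consensus base at an upper-case (core)
        position; the remainder is split equally over the other 3 bases.
    minor_prob:
        Probability of the consensus base at a lower-case (weakly
        conserved) position.
    floor:
        Minimum probability any cell may take; rows are renormalized
        after flooring so log-odds scores stay finite.
    """

    core_prob: float = 0.94
    minor_prob: float = 0.70
    floor: float = 0.001

    def __post_init__(self) -> None:
        if not (self.core_prob > self.minor_prob > 0.25):
            raise ValueError(
                f"require core_prob > minor_prob > 0.25, got "
                f"core_prob={self.core_prob}, minor_prob={self.minor_prob}"
            )
        off_core = (1.0 - self.core_prob) / 3.0
        off_minor = (1.0 - self.minor_prob) / 3.0
        if not (0.25 >= off_core >= 0 and 0.25 >= off_minor >= 0):
            raise ValueError("off-base probabilities must lie in [0, 0.25]")


@dataclass
class MotifModel:
    """A named letter-probability matrix over A/C/G/T.

    ``probs`` has one row per motif position; each row sums to 1.
    ``spacer`` records the inverted-repeat span for palindromic models
    (None for models without an inverted repeat).
    """

    name: str
    consensus: str
    probs: np.ndarray
    spacer: int | None = None
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"probs must be L x 4, got shape {self.probs.shape}")
        if len(self.consensus) != self.probs.shape[0]:
            raise ValueError(
                f"consensus length {len(self.consensus)} != matrix rows "
                f"{self.probs.shape[0]}"
            )
        rowsums = self.probs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1, got {rowsums}")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def __len__(self) -> int:
        return self.length


_COMPLEMENT = str.maketrans("ACGTacgtn", "TGCAtgcan")


def _expand_position(char: str, weights: WeightScheme) -> np.ndarray:
    row = np.full(4, 0.25)
    if char == "n":
        pass
    elif char in "ACGT":
        row = np.full(4, (1.0 - weights.core_prob) / 3.0)
        row[_BASE_INDEX[char]] = weights.core_prob
    elif char in "acgt":
        row = np.full(4, (1.0 - weights.minor_prob) / 3.0)
        row[_BASE_INDEX[char.upper()]] = weights.minor_prob
    else:
        raise ValueError(f"invalid consensus character {char!r}")
    row = np.maximum(row, weights.floor)
    return row / row.sum()


def build_nacbs(
    name: str,
    weights: WeightScheme | None = None,
    consensus: str | None = None,
    spacer: int | None = None,
) -> MotifModel:
    """Build a NACBS letter-probability model from its consensus string.

    ``name`` may be one of the seven default model names, in which case
    the consensus and spacer are looked up; otherwise an explicit
    ``consensus`` must be supplied.
    """
    weights = weights or WeightScheme()
    if consensus is None:
        try:
            consensus = DEFAULT_CONSENSUS[name]
        except KeyError:
            raise ValueError(
                f"unknown motif name {name!r} and no consensus supplied; "
                f"known names: {', '.join(DEFAULT_CONSENSUS)}"
            ) from None
        spacer = DEFAULT_SPACERS[name]
    probs = np.stack([_expand_position(c, weights) for c in consensus])
    return MotifModel(name=name, consensus=consensus, probs=probs, spacer=spacer)


def build_all_default(weights: WeightScheme | None = None) -> list[MotifModel]:
    """Build the seven default NACBS models (NACBS-1, -5 .. -10)."""
    return [build_nacbs(name, weights) for name in DEFAULT_NAMES]


def reverse_complement_model(m: MotifModel) -> MotifModel:
    """Reverse-complement a model: rows reversed, A<->T and C<->G swapped.

    Because the alphabet is ordered ACGT, complementation is a column
    reversal, so the transform is ``probs[::-1, ::-1]``.
    """
    rc_probs = m.probs[::-1, ::-1].copy()
    rc_consensus = m.consensus.translate(_COMPLEMENT)[::-1]
    return MotifModel(
        name=m.name,
        consensus=rc_consensus,
        probs=rc_probs,
        spacer=m.spacer,
        background=m.background.copy(),
    )


def information_content(m: MotifModel, background: np.ndarray | None = None) -> np.ndarray:
    """Per-position information content (bits) relative to a background."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return np.sum(m.probs * np.log2(m.probs / bg), axis=1)


# ---------------------------------------------------------------------------
# MEME minimal motif format I/O
# ---------------------------------------------------------------------------

def write_meme(
    models: list[MotifModel],
    path,
    background: np.ndarray | None = None,
) -> None:
    """Write models to a MEME minimal motif file."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, bg)),
        "",
    ]
    for m in models:
        lines.append(f"MOTIF {m.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.length} "
            f"nsites= 20 E= 0"
        )
        for row in m.probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class MemeFormatError(ValueError):
    pass


def read_meme(path) -> list[MotifModel]:
    """Read MEME minimal motif files into MotifModel objects.

    Raises :class:`MemeFormatError` (with a line number) on malformed
    letter-probability blocks or rows that do not sum to 1 within 1e-3.
    """
    with open(path) as fh:
        lines = fh.readlines()
    models: list[MotifModel] = []
    background = np.full(4, 0.25)
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            if i < n:
                parts = lines[i].split()
                if len(parts) == 8:
                    try:
                        background = np.array(
                            [float(parts[j]) for j in (1, 3, 5, 7)]
                        )
                    except ValueError:
                        raise MemeFormatError(
                            f"line {i + 1}: bad background frequency line"
                        ) from None
            i += 1
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MemeFormatError(f"line {i + 1}: MOTIF line without a name")
            name = parts[1]
            i += 1
            while i < n and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise MemeFormatError(
                        f"line {i + 1}: motif {name!r} has no "
                        "letter-probability matrix block"
                    )
                i += 1
            if i == n:
                raise MemeFormatError(
                    f"motif {name!r}: missing letter-probability matrix block"
                )
            header = lines[i].strip()
            fields = dict(
                zip(header.split()[2::2], header.split()[3::2])
            )  # alength=, w=, ...
            try:
                alength = int(fields.get("alength=", "4"))
                width = int(fields["w="])
            except (KeyError, ValueError):
                raise MemeFormatError(
                    f"line {i + 1}: malformed matrix header {header!r}"
                ) from None
            if alength != 4:
                raise MemeFormatError(
                    f"line {i + 1}: alphabet length {alength} != 4"
                )
            i += 1
            rows = []
            for r in range(width):
                if i >= n:
                    raise MemeFormatError(
                        f"line {n}: motif {name!r} matrix truncated at row {r}"
                    )
                parts = lines[i].split()
                if len(parts) != 4:
                    raise MemeFormatError(
                        f"line {i + 1}: expected 4 columns, got {len(parts)}"
                    )
                try:
                    row = [float(x) for x in parts]
                except ValueError:
                    raise MemeFormatError(
                        f"line {i + 1}: non-numeric matrix entry"
                    ) from None
                if abs(sum(row) - 1.0) > 1e-3:
                    raise MemeFormatError(
                        f"line {i + 1}: row sums to {sum(row):.6f}, not 1"
                    )
                rows.append(row)
                i += 1
            probs = np.array(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            consensus = _consensus_from_probs(probs)
            models.append(
                MotifModel(
                    name=name,
                    consensus=consensus,
                    probs=probs,
                    spacer=None,
                    background=background.copy(),
                )
            )
            continue
        i += 1
    return models


def _consensus_from_probs(probs: np.ndarray) -> str:
    """Reconstruct a case-coded consensus string from a probability matrix."""
    out = []
    for row in probs:
        j = int(np.argmax(row))
        p = row[j]
        if p >= 0.85:
            out.append(ALPHABET[j])
        elif p >= 0.40:
            out.append(ALPHABET[j].lower())
        else:
            out.append("n")
    return "".join(out)
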