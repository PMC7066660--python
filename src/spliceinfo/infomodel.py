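"""Individual-information models of splice sites.

Weight matrices are built from alignments of known functional sites, one
fixed-width window per sequence. Each cell holds a weight

    Riw(b, l) = 2 + log2 f(b, l) - e_n(l)   [bits]

and a candidate window scores R_i = sum_l Riw(window[l], l). One bit of
change corresponds to a twofold change in predicted binding affinity, so
the minimum fold change of a variant is 2**|delta R_i|.

Coordinate convention: matrix column offsets are relative to the splice
junction; offset 0 is the first intronic base for donors and the first
exonic base for acceptors. Windows are configurable via ``window_start``.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Sentinel returned when a zero-frequency base is scored at pseudocount 0.
NEG_INF = float("-inf")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SiteKind(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"


#: Default window geometry: (window_start, length).
#: Donor: 9 nt spanning offsets -3..+5 around the exon|intron junction.
#: Acceptor: 28 nt spanning -25..+2 around the intron|exon junction.
DEFAULT_WINDOWS: dict[SiteKind, tuple[int, int]] = {
    SiteKind.DONOR: (-3, 9),
    SiteKind.ACCEPTOR: (-25, 28),
}


class Origin(str, Enum):
    NATURAL = "natural"
    CRYPTIC = "cryptic"


class Direction(str, Enum):
    WEAKENED = "weakened"
    STRENGTHENED = "strengthened"
    UNCHANGED = "unchanged"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class TrainingAlignment:
    """Equal-length splice-site windows over the ACGT alphabet."""

    site_kind: SiteKind
    window_start: int
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValidationError("alignment must contain at least one sequence")
        length = len(self.sequences[0])
        if length < 1:
            raise ValidationError("sequences must have length >= 1")
        for row, seq in enumerate(self.sequences):
            if len(seq) != length:
                raise ValidationError(
                    f"ragged alignment: row {row} has length {len(seq)}, "
                    f"expected {length}"
                )
            bad = set(seq) - set(BASES)
            if bad:
                raise ValidationError(
                    f"invalid character(s) {sorted(bad)} in row {row}: {seq!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def counts(self) -> np.ndarray:
        """(L, 4) integer base counts per column."""
        out = np.zeros((self.length, 4), dtype=np.int64)
        for seq in self.sequences:
            for l, base in enumerate(seq):
                out[l, BASE_INDEX[base]] += 1
        return out

    @classmethod
    def from_lines(
        cls, text: str, site_kind: SiteKind, window_start: int
    ) -> "TrainingAlignment":
        seqs = tuple(
            line.strip().upper()
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        )
        return cls(site_kind=site_kind, window_start=window_start, sequences=seqs)


def small_sample_correction(n: int) -> float:
    """Analytic approximation of the per-column small-sample error, in bits."""
    return 3.0 / (2.0 * math.log(2.0) * n)


@dataclass
class InformationWeightMatrix:
    """Per-position, per-base weights in bits (columns ordered A, C, G, T)."""

    site_kind: SiteKind
    window_start: int
    weights: np.ndarray  # (L, 4) float, -inf marks zero frequency
    n: np.ndarray  # per-column training-set size
    e_n: np.ndarray  # per-column correction, bits
    pseudocount: float
    correction: str = "none"

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=1))

    # --- serialization -------------------------------------------------
    # Self-describing TSV: '#key\tvalue' header lines, then one row per
    # position with the offset and four weight columns at full precision.

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"#site_kind\t{self.site_kind.value}\n")
        buf.write(f"#window_start\t{self.window_start}\n")
        buf.write(f"#length\t{self.length}\n")
        buf.write(f"#n\t{','.join(str(int(v)) for v in self.n)}\n")
        buf.write(f"#pseudocount\t{self.pseudocount!r}\n")
        buf.write(f"#correction\t{self.correction}\n")
        buf.write("offset\tA\tC\tG\tT\n")
        for l in range(self.length):
            cells = "\t".join(repr(float(w)) for w in self.weights[l])
            buf.write(f"{self.window_start + l}\t{cells}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, text: str) -> "InformationWeightMatrix":
        header: dict[str, str] = {}
        rows: list[list[float]] = []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                header[key] = value
            elif line.startswith("offset"):
                continue
            else:
                parts = line.split("\t")
                rows.append([float(x) for x in parts[1:5]])
        weights = np.array(rows, dtype=float)
        n = np.array([int(v) for v in header["n"].split(",")], dtype=np.int64)
        corr = header.get("correction", "none")
        e_n = (
            np.array([small_sample_correction(int(v)) for v in n])
            if corr == "analytic"
            else np.zeros(len(n))
        )
        return cls(
            site_kind=SiteKind(header["site_kind"]),
            window_start=int(header["window_start"]),
            weights=weights,
            n=n,
            e_n=e_n,
            pseudocount=float(header["pseudocount"]),
            correction=corr,
        )

    @classmethod
    def load(cls, path) -> "InformationWeightMatrix":
        with open(path) as fh:
            return cls.from_tsv(fh.read())


@dataclass(frozen=True)
class SiteScore:
    contig: str
    junction_position: int  # 0-based; first intronic base (donor) / first exonic base (acceptor)
    strand: str
    site_kind: SiteKind
    ri: float
    origin: Origin = Origin.NATURAL


@dataclass(frozen=True)
class FoldChange:
    ri_initial: float
    ri_final: float
    delta_ri: float
    fold: float
    direction: Direction

    @property
    def fold_1dp(self) -> float:
        """Fold change rounded to one decimal, the reporting convention."""
        return round(self.fold, 1)


def build_weight_matrix(
    alignment: TrainingAlignment,
    pseudocount: float = 0.0,
    correction: str = "none",
) -> InformationWeightMatrix:
    """Build an information weight matrix from a training alignment.

    ``f(b,l) = (count(b,l) + pseudocount) / (n + 4*pseudocount)`` and
    ``Riw(b,l) = 2 + log2 f(b,l) - e_n(l)``. With ``pseudocount=0`` a
    zero-count base yields the -inf sentinel, never a silent number.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if correction not in ("none", "analytic"):
        raise ValidationError(f"unknown correction {correction!r}")
    counts = alignment.counts()
    n = np.full(alignment.length, alignment.n, dtype=np.int64)
    with np.errstate(divide="ignore"):
        freq = (counts + pseudocount) / (alignment.n + 4.0 * pseudocount)
        weights = 2.0 + np.log2(freq)
    if correction == "analytic":
        e_n = np.array([small_sample_correction(int(v)) for v in n])
    else:
        e_n = np.zeros(alignment.length)
    weights = weights - e_n[:, None]
    return InformationWeightMatrix(
        site_kind=alignment.site_kind,
        window_start=alignment.window_start,
        weights=weights,
        n=n,
        e_n=e_n,
        pseudocount=pseudocount,
        correction=correction,
    )


def score_site(matrix: InformationWeightMatrix, window: str) -> float:
    """R_i of one window: the per-column weight sum, in bits.

    Returns -inf when the window hits a zero-frequency base at
    pseudocount 0 (the documented sentinel).
    """
    window = window.upper()
    if len(window) != matrix.length:
        raise ValidationError(
            f"window length {len(window)} != matrix length {matrix.length}"
        )
    total = 0.0
    for l, base in enumerate(window):
        try:
            idx = BASE_INDEX[base]
        except KeyError:
            raise ValidationError(f"invalid character {base!r} at offset {l}")
        total += matrix.weights[l, idx]
    return total


def rsequence(matrix: InformationWeightMatrix, alignment: TrainingAlignment) -> float:
    """Mean information of the model: sum_l sum_b f(b,l) * Riw(b,l).

    Diagnostic; with pseudocount 0 and no correction it equals the mean of
    :func:`score_site` over the training sequences.
    """
    if alignment.length != matrix.length:
        raise ValidationError(
            f"alignment length {alignment.length} != matrix length {matrix.length}"
        )
    counts = alignment.counts()
    freq = (counts + matrix.pseudocount) / (
        alignment.n + 4.0 * matrix.pseudocount
    )
    total = 0.0
    for l in range(matrix.length):
        for b in range(4):
            if freq[l, b] > 0:
                total += freq[l, b] * matrix.weights[l, b]
    return total


_CODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i


def _window_scores(matrix: InformationWeightMatrix, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-offset window scores and a validity mask (no N)."""
    L = matrix.length
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < L:
        return np.empty(0), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~(win == 4).any(axis=1)
    idx = np.where(win == 4, 0, win)
    scores = matrix.weights[np.arange(L)[None, :], idx].sum(axis=1)
    return scores, valid


def scan_sequence(
    matrix: InformationWeightMatrix,
    sequence: str,
    strand_mode: str = "forward",
    contig: str = ".",
) -> list[SiteScore]:
    """Score every offset of ``sequence``; windows containing N are skipped.

    A sequence shorter than the matrix yields an empty list. Reverse-strand
    scores are computed on the reverse complement with the junction
    coordinate mapped back to the forward strand.
    """
    if strand_mode not in ("forward", "both"):
        raise ValidationError(f"unknown strand_mode {strand_mode!r}")
    sequence = sequence.upper()
    out: list[SiteScore] = []
    skipped = 0

    def scan_one(seq: str, strand: str) -> None:
        nonlocal skipped
        scores, valid = _window_scores(matrix, seq)
        skipped += int((~valid).sum())
        for i in np.nonzero(valid)[0]:
            junction = int(i) - matrix.window_start
            if strand == "-":
                junction = len(seq) - 1 - junction
            out.append(
                SiteScore(
                    contig=contig,
                    junction_position=junction,
                    strand=strand,
                    site_kind=matrix.site_kind,
                    ri=float(scores[i]),
                    origin=Origin.CRYPTIC,
                )
            )

    scan_one(sequence, "+")
    if strand_mode == "both":
        scan_one(reverse_complement(sequence), "-")
    if skipped:
        logger.info("scan_sequence: skipped %d windows containing N", skipped)
    return out


def delta_ri(
    matrix: InformationWeightMatrix, ref_window: str, alt_window: str
) -> float:
    """Information change score_site(alt) - score_site(ref), in bits."""
    return score_site(matrix, alt_window) - score_site(matrix, ref_window)


def fold_change(
    ri_initial: float, ri_final: float, clamp_at_zero: bool = False
) -> FoldChange:
    """Minimum predicted fold change in affinity, 2**|ri_final - ri_initial|.

    ``clamp_at_zero=True`` clamps negative R_i to 0 bits before taking the
    difference (an alternative reporting convention for sites crossing 0).
    """
    if not (math.isfinite(ri_initial) and math.isfinite(ri_final)):
        raise ValidationError("fold_change requires finite R_i values")
    delta = ri_final - ri_initial
    if clamp_at_zero:
        eff = max(ri_final, 0.0) - max(ri_initial, 0.0)
    else:
        eff = delta
    if delta < 0:
        direction = Direction.WEAKENED
    elif delta > 0:
        direction = Direction.STRENGTHENED
    else:
        direction = Direction.UNCHANGED
    return FoldChange(
        ri_initial=ri_initial,
        ri_final=ri_final,
        delta_ri=delta,
        fold=2.0 ** abs(eff),
        direction=direction,
    )
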