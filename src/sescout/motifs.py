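"""PWM scanning with exact log-odds p-values (the FIMO-style step).

A JASPAR-like count matrix is turned into a log2-odds score matrix against a
0-order background; the exact null distribution of window scores is computed
by discretizing the matrix onto an integer grid (default 1000 bins over the
full score range) and convolving column score distributions under the
background.  Both strands are scanned — the minus strand scores the reverse
complement of each window with the same matrix, so one null serves both —
and hits are reported when the p-value P(score >= observed) falls at or
below the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ValidationError

__all__ = [
    "Pwm",
    "MotifHit",
    "ScoreNull",
    "pwm_to_logodds",
    "exact_score_pvalues",
    "scan_sequence",
    "read_jaspar",
    "write_jaspar",
    "reverse_complement",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.intp)  # A<->T, C<->G
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_GRANULARITY = 1000
DEFAULT_P_MAX = 1e-4
MAX_PWM_LENGTH = 25
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class Pwm:
    """A position weight matrix as base counts (rows A, C, G, T)."""

    motif_id: str
    counts: np.ndarray  # shape (4, L)
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValidationError("PWM counts must be a 4 x L matrix with L >= 1")
        if np.any(self.counts < 0):
            raise ValidationError("PWM counts must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
            raise ValidationError("background must be 4 strictly positive probs summing to 1")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif_id: str
    offset: int  # 0-based window start on the forward strand
    strand: str
    score_bits: float
    p_value: float


def pwm_to_logodds(pwm: Pwm) -> np.ndarray:
    """4 x L log2-odds matrix: log2 of (pseudocounted frequency / background).

    entry(b, j) = log2((counts(b,j) + pc*bg(b)) / (col_total(j) + pc) / bg(b)).
    A zero count with zero pseudocount yields -inf (legal here, but scanning
    and p-value construction require a finite matrix).
    """
    totals = pwm.counts.sum(axis=0)
    if pwm.pseudocount == 0 and np.any(totals == 0):
        raise ValidationError("zero column total with zero pseudocount")
    bg = np.asarray(pwm.background, dtype=float)[:, None]
    with np.errstate(divide="ignore"):
        freq = (pwm.counts + pwm.pseudocount * bg) / (totals + pwm.pseudocount)[None, :]
        return np.log2(freq / bg)


@dataclass
class ScoreNull:
    """Exact null distribution of window scores on an integer grid.

    The grid discretizes each column's scores after shifting it to be
    non-negative; the common bin width is (total score range)/granularity.
    ``sf[k]`` is P(integer score >= k) under the background.
    """

    eps: float
    total_offset: float  # sum of per-column minima (raw-score origin of bin 0)
    int_matrix: np.ndarray  # 4 x L integer scores
    sf: np.ndarray  # survival function over integer scores

    @property
    def max_int(self) -> int:
        return len(self.sf) - 1

    def window_int_score(self, base_indices: np.ndarray) -> int:
        cols = np.arange(self.int_matrix.shape[1])
        return int(self.int_matrix[base_indices, cols].sum())

    def pvalue_from_int(self, k: int) -> float:
        return float(self.sf[min(max(k, 0), self.max_int)])

    def pvalue(self, score_bits: float) -> float:
        """P(score >= score_bits) via the grid (FIMO-style discretization)."""
        if self.eps == 0.0:
            return 1.0
        k = int(round((score_bits - self.total_offset) / self.eps))
        return self.pvalue_from_int(k)


def exact_score_pvalues(
    logodds: np.ndarray,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    granularity: int = DEFAULT_GRANULARITY,
) -> ScoreNull:
    """Column-wise convolution of the discretized score null distribution."""
    lo = np.asarray(logodds, dtype=float)
    if lo.ndim != 2 or lo.shape[0] != 4:
        raise ValidationError("log-odds matrix must be 4 x L")
    L = lo.shape[1]
    if L > MAX_PWM_LENGTH:
        raise ValidationError(
            f"refusing exact p-value DP for motif length {L} > {MAX_PWM_LENGTH}"
        )
    if not np.all(np.isfinite(lo)):
        raise ValidationError(
            "log-odds matrix must be finite for exact p-values; use a pseudocount > 0"
        )
    if granularity < 1:
        raise ValidationError("granularity must be >= 1")
    bg = np.asarray(background, dtype=float)
    offsets = lo.min(axis=0)
    total_range = float((lo.max(axis=0) - offsets).sum())
    if total_range == 0.0:
        # every window scores identically: p = 1 everywhere
        return ScoreNull(
            eps=0.0,
            total_offset=float(offsets.sum()),
            int_matrix=np.zeros_like(lo, dtype=np.int64),
            sf=np.array([1.0]),
        )
    eps = total_range / granularity
    int_matrix = np.rint((lo - offsets[None, :]) / eps).astype(np.int64)
    pdf = np.array([1.0])
    for j in range(L):
        col = int_matrix[:, j]
        new = np.zeros(len(pdf) + int(col.max()), dtype=float)
        for b in range(4):
            new[col[b] : col[b] + len(pdf)] += bg[b] * pdf
        pdf = new
    sf = np.cumsum(pdf[::-1])[::-1]
    sf = np.minimum(sf, 1.0)  # guard accumulated rounding above 1
    return ScoreNull(
        eps=eps, total_offset=float(offsets.sum()), int_matrix=int_matrix, sf=sf
    )


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.intp)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def scan_sequence(
    seq: str,
    pwm: Pwm,
    p_max: float = DEFAULT_P_MAX,
    sequence_id: str = "seq",
    granularity: int = DEFAULT_GRANULARITY,
    null: ScoreNull | None = None,
) -> list[MotifHit]:
    """Scan both strands of ``seq``; windows containing N are skipped.

    A hit is emitted when P(score >= observed) <= ``p_max``; hits come back
    sorted by (offset, strand).  The minus strand scores the reverse
    complement of each window against the same matrix and null.
    """
    if not seq:
        return []
    lo = pwm_to_logodds(pwm)
    if null is None:
        null = exact_score_pvalues(lo, pwm.background, granularity=granularity)
    L = pwm.length
    enc = _encode(seq)
    if len(enc) < L:
        return []
    hits: list[MotifHit] = []
    cols = np.arange(L)
    for off in range(len(enc) - L + 1):
        window = enc[off : off + L]
        if np.any(window < 0):
            continue
        for strand in "+-":
            if strand == "+":
                w = window
            else:
                w = COMPLEMENT_INDEX[window[::-1]]
            score = float(lo[w, cols].sum())
            k = int(null.int_matrix[w, cols].sum()) if null.eps else 0
            p = null.pvalue_from_int(k)
            if p <= p_max:
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        motif_id=pwm.motif_id,
                        offset=off,
                        strand=strand,
                        score_bits=score,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# JASPAR-style IO
# ---------------------------------------------------------------------------

def read_jaspar(
    path: str | Path,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
) -> list[Pwm]:
    """Read count matrices in JASPAR dialects.

    Accepts both the bracketed form (``A  [ 10  2  0 ]``) and bare
    whitespace-delimited count rows, in A/C/G/T order.
    """
    pwms: list[Pwm] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is not None:
            if len(rows) != 4:
                raise ValidationError(
                    f"motif {motif_id}: expected 4 count rows, got {len(rows)}"
                )
            pwms.append(
                Pwm(
                    motif_id=motif_id,
                    counts=np.array(rows, dtype=float),
                    pseudocount=pseudocount,
                    background=background,
                )
            )
        rows = []
        motif_id = None

    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            body = line
            if body[0].upper() in "ACGT" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append([float(tok) for tok in body.split()])
    flush()
    return pwms


def write_jaspar(pwms: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for b, row in zip(BASES, pwm.counts):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {cells} ]\n")
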