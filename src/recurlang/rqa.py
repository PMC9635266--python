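"""Categorical recurrence quantification of one coded symbol series.

A recurrence plot for a categorical series marks every ordered index pair
(i, j), i != j, with identical positive symbols; unique negative mask ids can
never match, so masked material generates no points.  The line of identity
(the lag-zero diagonal) is trivially fully recurrent and is excluded from all
metrics.

Metrics:

* recurrence rate RR = 100 * |points| / (N^2 - N) — the percentage of
  admissible plot cells that are recurrent.  For categorical data RR is a
  closed function of symbol frequencies, 100 * sum_c n_c (n_c - 1) / (N (N-1)),
  so it is invariant under any permutation of the series.
* percent determinism %DET = 100 * (points on diagonal runs of >= 2
  consecutive recurrent cells) / |points| — the share of recurrence carried by
  repeated *sequences* rather than isolated repeats.  Undefined (None) when
  the plot is empty; such series are dropped from cohort summaries.
* maxline — length of the longest off-identity diagonal line.

Both triangles of the symmetric plot are counted; mirror lines scale the
%DET numerator and denominator identically, so this equals a one-triangle
computation.

Two computational routes are provided: an explicit point-set route
(`recurrence_points` / `diagonal_lines` / `percent_determinism`) that mirrors
the definitions and is convenient for plots and small series, and a fast
frequency-grouped route (`rqa_metrics`) that never materializes the N x N
matrix and is used for cohorts and permutation ensembles.  Their agreement is
asserted in the test suite.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coding import CodedSequence, encode_all
from .transcript import Transcript

__all__ = [
    "RecurrencePointSet",
    "DiagonalLine",
    "RQAResult",
    "recurrence_points",
    "recurrence_rate",
    "diagonal_lines",
    "percent_determinism",
    "rqa_metrics",
    "rqa_profile",
    "loi_recurrence_fraction",
    "export_recurrence_plot",
    "export_sequence_plot",
]


@dataclass(frozen=True)
class RecurrencePointSet:
    """Off-identity recurrent cells of the plot for one series."""

    N: int
    points: frozenset  # of (i, j) int pairs, i != j

    def __post_init__(self) -> None:
        for (i, j) in self.points:
            if i == j:
                raise ValueError("line of identity must be excluded")


@dataclass(frozen=True)
class DiagonalLine:
    """A maximal run of >= min_len consecutive recurrent cells at one lag."""

    offset: int  # j - i, nonzero
    start: int   # i index of first cell
    length: int


@dataclass(frozen=True)
class RQAResult:
    """RR, %DET and the diagonal-line inventory for one series."""

    child_id: str
    type: str
    level: str
    n: int                      # series length
    rr: float                   # percent, [0, 100]
    det: float | None           # percent or None (no recurrent points)
    n_points: int
    n_line_points: int
    line_lengths: tuple[int, ...] = ()   # both triangles
    maxline: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.type, self.level)


# ---------------------------------------------------------------------------
# point-set route (definition-faithful; fine for small/medium N)

def _positions_by_symbol(symbols: np.ndarray) -> dict[int, np.ndarray]:
    symbols = np.asarray(symbols)
    pos = {}
    for v in np.unique(symbols[symbols > 0]):
        pos[int(v)] = np.flatnonzero(symbols == v)
    return pos


def recurrence_points(s: CodedSequence | np.ndarray) -> RecurrencePointSet:
    """All off-identity equal-symbol pairs; masked symbols yield none."""
    symbols = s.symbols if isinstance(s, CodedSequence) else np.asarray(s)
    pts = set()
    for p in _positions_by_symbol(symbols).values():
        for i in p:
            for j in p:
                if i != j:
                    pts.add((int(i), int(j)))
    return RecurrencePointSet(N=int(len(symbols)), points=frozenset(pts))


def recurrence_rate(p: RecurrencePointSet) -> float:
    """100 * |points| / (N^2 - N).  Requires N >= 2."""
    if p.N < 2:
        raise ValueError("recurrence rate undefined for N < 2")
    return 100.0 * len(p.points) / (p.N * p.N - p.N)


def diagonal_lines(p: RecurrencePointSet, min_len: int = 2
                   ) -> list[DiagonalLine]:
    """Maximal runs of recurrent cells along every nonzero lag.

    Both triangles are scanned, so every line appears with its mirror at the
    opposite offset.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    by_offset: dict[int, list[int]] = {}
    for (i, j) in p.points:
        by_offset.setdefault(j - i, []).append(i)
    lines = []
    for offset, starts in sorted(by_offset.items()):
        starts.sort()
        run_start, prev = starts[0], starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            length = prev - run_start + 1
            if length >= min_len:
                lines.append(DiagonalLine(offset=offset, start=run_start,
                                          length=length))
            if i is not None:
                run_start = prev = i
    return lines


def percent_determinism(p: RecurrencePointSet, min_len: int = 2
                        ) -> float | None:
    """Share (in %) of recurrent points on qualifying diagonal lines.

    None when the point set is empty — "undefined" is a value here, not an
    error, because such series are simply excluded from cohort summaries.
    """
    if not p.points:
        return None
    on_lines = sum(l.length for l in diagonal_lines(p, min_len))
    return 100.0 * on_lines / len(p.points)


def loi_recurrence_fraction(s: CodedSequence | np.ndarray) -> float:
    """Recurrent fraction of the lag-zero diagonal: identically 1.

    Every position trivially matches itself, which is exactly why the line
    of identity carries no information and is excluded from RR and %DET.
    """
    symbols = s.symbols if isinstance(s, CodedSequence) else np.asarray(s)
    n = len(symbols)
    if n == 0:
        raise ValueError("empty series")
    return float(np.mean(symbols == symbols))


# ---------------------------------------------------------------------------
# fast route: frequency-grouped, no N x N matrix

def _line_point_count_fast(symbols: np.ndarray, min_len: int) -> int:
    """Number of recurrent cells lying on diagonal runs >= min_len.

    For min_len == 2 a cell (i, j) is on a line iff one of its diagonal
    neighbours (i-1, j-1) or (i+1, j+1) is also recurrent; this is evaluated
    per symbol group without materializing the matrix.  Larger min_len falls
    back to an explicit run-length scan per lag.
    """
    n = len(symbols)
    if min_len == 2:
        # pad with two distinct, never-matching sentinels
        pad = np.empty(n + 2, dtype=np.int64)
        pad[1:-1] = symbols
        pad[0], pad[-1] = -(10 ** 12), -(10 ** 12) - 1
        total = 0
        for p in _positions_by_symbol(symbols).values():
            k = len(p)
            if k < 2:
                continue
            I = np.repeat(p, k)
            J = np.tile(p, k)
            off = I != J
            prev = (pad[I] == pad[J]) & (pad[I] > 0)        # pad[i] == symbols[i-1]
            nxt = (pad[I + 2] == pad[J + 2]) & (pad[I + 2] > 0)
            total += int(np.count_nonzero(off & (prev | nxt)))
        return total
    # general min_len: run-length scan over lags via the point set
    pts = recurrence_points(symbols)
    return sum(l.length for l in diagonal_lines(pts, min_len))


def rqa_metrics(s: CodedSequence | np.ndarray, min_len: int = 2,
                with_lines: bool = False,
                child_id: str = "", type: str = "", level: str = ""
                ) -> RQAResult:
    """RR, %DET (and optionally the line inventory) for one series."""
    if isinstance(s, CodedSequence):
        child_id, type, level = s.child_id, s.type, s.level
        symbols = s.symbols
    else:
        symbols = np.asarray(s, dtype=np.int64)
    n = len(symbols)
    counts = Counter(int(v) for v in symbols if v > 0)
    n_points = sum(c * (c - 1) for c in counts.values())
    rr = 100.0 * n_points / (n * n - n) if n >= 2 else 0.0
    if n_points == 0:
        return RQAResult(child_id, type, level, n, rr, None, 0, 0, (), None)
    n_line = _line_point_count_fast(symbols, min_len)
    det = 100.0 * n_line / n_points
    lengths: tuple[int, ...] = ()
    maxline = None
    if with_lines:
        lines = diagonal_lines(recurrence_points(symbols), min_len)
        lengths = tuple(sorted((l.length for l in lines), reverse=True))
        maxline = max(lengths) if lengths else 0
    return RQAResult(child_id, type, level, n, rr, det,
                     n_points, n_line, lengths, maxline)


def rqa_profile(t: Transcript, min_len: int = 2, with_lines: bool = True,
                codebooks=None) -> dict[tuple[str, str], RQAResult]:
    """The four per-child results (noun/verb x lexical/grammar)."""
    return {key: rqa_metrics(seq, min_len=min_len, with_lines=with_lines)
            for key, seq in encode_all(t, codebooks).items()}


# ---------------------------------------------------------------------------
# plot exports

def _write_tsv(path: Path, header: str, rows) -> None:
    buf = io.StringIO()
    buf.write(header + "\n")
    for r in rows:
        buf.write("\t".join(str(x) for x in r) + "\n")
    path.write_text(buf.getvalue())


def export_recurrence_plot(p: RecurrencePointSet, path) -> Path:
    """Write the (i, j) coordinate TSV and a square raster plot.

    The line of identity is drawn for orientation but is not part of the
    point set.  Returns the image path; the TSV sits next to it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    pts = sorted(p.points)
    _write_tsv(path.with_suffix(".tsv"), "i\tj", pts)

    fig, ax = plt.subplots(figsize=(5, 5))
    if pts:
        xs, ys = zip(*pts)
        ax.scatter(xs, ys, s=4, c="black", marker="s")
    ax.plot([0, max(p.N - 1, 0)], [0, max(p.N - 1, 0)],
            lw=0.5, c="grey", zorder=0)
    ax.set_xlim(-0.5, max(p.N - 0.5, 0.5))
    ax.set_ylim(-0.5, max(p.N - 0.5, 0.5))
    ax.set_xlabel("position i")
    ax.set_ylabel("position j")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def export_sequence_plot(s: CodedSequence, path) -> Path:
    """Category-versus-time dot plot over positive symbols only.

    Masked positions are left blank: gaps show where the child produced
    material outside the target class.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    order = sorted(s.label_map)  # positive ids, stable category order
    row_of = {sid: r for r, sid in enumerate(order)}
    xs = [i for i, v in enumerate(s.symbols) if v > 0]
    ys = [row_of[int(v)] for v in s.symbols if v > 0]

    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.3 * len(order) + 1)))
    ax.scatter(xs, ys, s=8, c="tab:blue")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([s.label_map[sid] for sid in order], fontsize=7)
    ax.set_xlim(-0.5, max(len(s) - 0.5, 0.5))
    ax.set_xlabel("position in series")
    ax.set_title(f"{s.child_id} {s.type}/{s.level}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
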