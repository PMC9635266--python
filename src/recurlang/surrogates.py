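"""Permutation-surrogate significance testing of percent determinism.

Because categorical RR is a closed function of symbol frequencies, any
frequency-preserving shuffle leaves RR unchanged — so a permutation baseline
is only informative for sequence-sensitive metrics, here %DET.  For each
series we draw P uniform random permutations of the full masked symbol
multiset (negatives stay unique, so surrogate length and frequencies match
the original exactly), compute %DET on each, and compare the observed value
to this child-specific null.

The upper-tail empirical p is the proportion of surrogates whose %DET is at
least the observed value (ties count toward the null — conservative).  The
significance criterion flags a series whose observed %DET exceeds the 95th
percentile of its surrogate distribution; a ``two_sided`` tail instead uses
the 2.5th/97.5th percentile bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import CodedSequence
from .rqa import rqa_metrics

__all__ = [
    "SurrogateEnsemble",
    "PermutationTestResult",
    "CohortPermutationSummary",
    "permute_series",
    "det_permutation_test",
    "summarize_cohort",
]

DEFAULT_PERMUTATIONS = 100


@dataclass(frozen=True)
class SurrogateEnsemble:
    """%DET values of P frequency-preserving shuffles of one series."""

    n_permutations: int
    seed: int
    det_values: tuple  # floats; None entries if a surrogate had no points


@dataclass(frozen=True)
class PermutationTestResult:
    child_id: str
    type: str
    level: str
    observed_det: float | None
    p: float | None                 # upper-tail empirical p; None if untestable
    exceeds_criterion: bool | None  # percentile criterion; None if untestable
    tail: str = "upper"
    seed: int = 0
    n_permutations: int = DEFAULT_PERMUTATIONS

    @property
    def testable(self) -> bool:
        return self.observed_det is not None


@dataclass(frozen=True)
class CohortPermutationSummary:
    """Cohort-level reporting for one (type, level) measure."""

    type: str
    level: str
    n_included: int            # series with defined observed %DET
    prop_above_criterion: float  # percent of included series flagged
    p_median: float
    p_sd: float


def permute_series(s: CodedSequence, seed: int) -> CodedSequence:
    """Uniform random permutation of the symbols; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return s.with_symbols(rng.permutation(s.symbols))


def surrogate_dets(s: CodedSequence, n_permutations: int, seed: int,
                   min_len: int = 2) -> SurrogateEnsemble:
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_permutations):
        shuffled = rng.permutation(s.symbols)
        vals.append(rqa_metrics(shuffled, min_len=min_len).det)
    return SurrogateEnsemble(n_permutations=n_permutations, seed=seed,
                             det_values=tuple(vals))


def det_permutation_test(s: CodedSequence,
                         n_permutations: int = DEFAULT_PERMUTATIONS,
                         seed: int = 0, min_len: int = 2,
                         tail: str = "upper") -> PermutationTestResult:
    """Empirical test of observed %DET against its shuffled baseline.

    A series with no recurrent points has undefined %DET and is returned as
    not testable (all fields None) rather than raising: the cohort summary
    simply excludes it, which is what produces reduced per-measure n.
    """
    if tail not in ("upper", "two_sided"):
        raise ValueError("tail must be 'upper' or 'two_sided'")
    observed = rqa_metrics(s, min_len=min_len).det
    if observed is None:
        return PermutationTestResult(s.child_id, s.type, s.level,
                                     None, None, None, tail, seed,
                                     n_permutations)
    ens = surrogate_dets(s, n_permutations, seed, min_len)
    # frequencies are preserved, so every surrogate has the same point count
    # as the original and %DET is defined for all of them
    dets = np.array([v for v in ens.det_values], dtype=float)
    p = float(np.mean(dets >= observed))
    if tail == "upper":
        exceeds = bool(observed > np.percentile(dets, 95))
    else:
        lo, hi = np.percentile(dets, [2.5, 97.5])
        exceeds = bool(observed > hi or observed < lo)
    return PermutationTestResult(s.child_id, s.type, s.level, observed,
                                 p, exceeds, tail, seed, n_permutations)


def summarize_cohort(results: list[PermutationTestResult]
                     ) -> CohortPermutationSummary:
    """Proportion of testable series above criterion, plus p median and sd."""
    if not results:
        raise ValueError("no results to summarize")
    types = {r.type for r in results}
    levels = {r.level for r in results}
    if len(types) != 1 or len(levels) != 1:
        raise ValueError("summarize one (type, level) measure at a time")
    included = [r for r in results if r.testable]
    if not included:
        raise ValueError("no testable series for this measure")
    ps = np.array([r.p for r in included], dtype=float)
    flagged = np.array([r.exceeds_criterion for r in included], dtype=bool)
    return CohortPermutationSummary(
        type=types.pop(), level=levels.pop(),
        n_included=len(included),
        prop_above_criterion=100.0 * float(np.mean(flagged)),
        p_median=float(np.median(ps)),
        p_sd=float(np.std(ps, ddof=1)) if len(ps) > 1 else 0.0,
    )
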