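"""Recurrence point sets, RR, diagonal lines, %DET, and plot exports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recurlang.coding import encode
from recurlang.rqa import (diagonal_lines, export_recurrence_plot,
                           export_sequence_plot, loi_recurrence_fraction,
                           percent_determinism, recurrence_points,
                           recurrence_rate, rqa_metrics, rqa_profile)
from recurlang.transcript import build_transcript

from _reference import brute_det, brute_rr
from conftest import random_series


def test_point_set_of_abab_series():
    p = recurrence_points(np.array([1, 2, 1, 2, 3]))
    assert p.points == {(0, 2), (2, 0), (1, 3), (3, 1)}
    assert recurrence_rate(p) == pytest.approx(20.0)
    assert percent_determinism(p) == pytest.approx(100.0)


def test_all_distinct_symbols_empty_point_set():
    p = recurrence_points(np.array([1, 2, 3, 4]))
    assert p.points == frozenset()
    assert percent_determinism(p) is None


def test_negative_symbols_generate_no_points():
    p = recurrence_points(np.array([-1, -2, -3, 1, 1]))
    assert p.points == {(3, 4), (4, 3)}


def test_point_set_symmetric_and_excludes_loi():
    rng = np.random.default_rng(0)
    p = recurrence_points(random_series(rng, 40))
    for (i, j) in p.points:
        assert i != j
        assert (j, i) in p.points


def test_isolated_points_carry_no_determinism():
    r = rqa_metrics(np.array([1, 1, 2]), with_lines=True)
    assert r.n_points == 2
    assert r.det == 0.0
    assert r.line_lengths == ()


def test_constant_series_line_inventory():
    r = rqa_metrics(np.array([7, 7, 7, 7]), with_lines=True)
    assert r.rr == pytest.approx(100.0)
    # offsets +-1 give maximal runs of 3, +-2 runs of 2, +-3 isolated corners
    assert sorted(r.line_lengths) == [2, 2, 3, 3]
    assert r.det == pytest.approx(100.0 * 10 / 12)
    assert r.maxline == 3


def test_loi_fraction_is_always_one():
    rng = np.random.default_rng(1)
    for n in (1, 5, 50):
        assert loi_recurrence_fraction(random_series(rng, n)) == 1.0


def test_rr_undefined_below_two():
    with pytest.raises(ValueError):
        recurrence_rate(recurrence_points(np.array([1])))


def test_fast_route_matches_point_set_route():
    rng = np.random.default_rng(2)
    for _ in range(50):
        s = random_series(rng, int(rng.integers(2, 60)),
                          n_symbols=int(rng.integers(2, 8)))
        p = recurrence_points(s)
        r = rqa_metrics(s, with_lines=True)
        assert r.n_points == len(p.points)
        if len(p.points):
            assert r.rr == pytest.approx(recurrence_rate(p))
            assert r.det == pytest.approx(percent_determinism(p))
            lines = diagonal_lines(p)
            assert sorted(r.line_lengths) == sorted(l.length for l in lines)


def test_brute_force_oracle_agreement():
    rng = np.random.default_rng(3)
    for _ in range(200):
        s = random_series(rng, int(rng.integers(2, 31)),
                          n_symbols=int(rng.integers(1, 6)))
        r = rqa_metrics(s)
        assert r.rr == pytest.approx(brute_rr(s.tolist()), abs=1e-12)
        bd = brute_det(s.tolist())
        if bd is None:
            assert r.det is None
        else:
            assert r.det == pytest.approx(bd, abs=1e-12)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=6), min_size=2,
                max_size=200))
def test_closed_form_rr_and_permutation_invariance(symbols):
    s = np.array(symbols, dtype=np.int64)
    n = len(s)
    counts = np.bincount(s)
    closed = 100.0 * float((counts * (counts - 1)).sum()) / (n * n - n)
    r = rqa_metrics(s)
    assert r.rr == pytest.approx(closed, abs=1e-10)
    shuffled = np.random.default_rng(0).permutation(s)
    assert rqa_metrics(shuffled).rr == pytest.approx(r.rr, abs=1e-10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=5), min_size=2,
                max_size=80))
def test_reversal_and_relabeling_invariance(symbols):
    s = np.array(symbols, dtype=np.int64)
    base = rqa_metrics(s, with_lines=True)
    rev = rqa_metrics(s[::-1].copy(), with_lines=True)
    assert rev.rr == pytest.approx(base.rr)
    assert (rev.det is None) == (base.det is None)
    if base.det is not None:
        assert rev.det == pytest.approx(base.det)
    assert sorted(rev.line_lengths) == sorted(base.line_lengths)
    relabeled = rqa_metrics(s + 17, with_lines=True)  # bijection on symbols
    assert relabeled.rr == pytest.approx(base.rr)
    assert sorted(relabeled.line_lengths) == sorted(base.line_lengths)


def test_metric_bounds():
    rng = np.random.default_rng(4)
    for _ in range(50):
        s = random_series(rng, int(rng.integers(2, 60)), n_symbols=3)
        r = rqa_metrics(s, with_lines=True)
        assert 0.0 <= r.rr <= 100.0
        assert r.n_line_points <= r.n_points
        if r.det is not None:
            assert 0.0 <= r.det <= 100.0
        if r.maxline is not None:
            assert r.maxline <= r.n - 1


def test_profile_keys_and_undefined_det():
    t = build_transcript("c", [
        [("red", ["adjective"], []), ("go", [], ["verb"])],
        [("blue", ["adjective"], []), ("go", [], ["verb"])],
    ])
    prof = rqa_profile(t)
    assert set(prof) == {("noun", "lexical"), ("noun", "grammar"),
                        ("verb", "lexical"), ("verb", "grammar")}
    # noun words never repeat: RR 0, DET undefined
    assert prof[("noun", "lexical")].rr == 0.0
    assert prof[("noun", "lexical")].det is None
    # noun grammar repeats (adjective twice, isolated) but not in sequence
    assert prof[("noun", "grammar")].det == 0.0


def test_repeated_template_child_fully_deterministic():
    utt = [("the", ["determiner"], []), ("dog", ["common_noun"], []),
           ("runs", [], ["verb", "third_person_singular"])]
    t = build_transcript("c", [utt] * 5)
    prof = rqa_profile(t)
    assert prof[("noun", "grammar")].det == pytest.approx(100.0)
    assert prof[("verb", "grammar")].det == pytest.approx(100.0)


def test_frog_determiner_pairs_in_point_set(frog):
    s = encode(frog, "noun", "grammar")
    p = recurrence_points(s)
    det_code = {v: k for k, v in s.label_map.items()}["determiner"]
    det_positions = [i for i, v in enumerate(s.symbols) if v == det_code]
    assert len(det_positions) == 5
    pairs = {(i, j) for i in det_positions for j in det_positions if i != j}
    assert pairs <= p.points
    assert len(pairs) == 20


def test_recurrence_plot_export(tmp_path):
    p = recurrence_points(np.array([1, 2, 1, 2, 3]))
    img = export_recurrence_plot(p, tmp_path / "rp.png")
    coords = (tmp_path / "rp.tsv").read_text().strip().splitlines()
    assert img.exists()
    assert len(coords) - 1 == len(p.points)  # header + one row per point
    empty = recurrence_points(np.array([1, 2, 3]))
    export_recurrence_plot(empty, tmp_path / "empty.png")
    assert (tmp_path / "empty.tsv").read_text().strip() == "i\tj"


def test_sequence_plot_export(tmp_path, frog):
    s = encode(frog, "noun", "grammar")
    img = export_sequence_plot(s, tmp_path / "seq.png")
    assert img.exists()
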