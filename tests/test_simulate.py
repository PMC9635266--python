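"""Synthetic-cohort generator: validity, determinism, and tunable signals."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from recurlang.rqa import rqa_profile
from recurlang.simulate import (GeneratorConfig, simulate_child,
                                simulate_cohort, write_simulated_cohort)
from recurlang.transcript import read_transcript, speech_descriptives


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(template_reuse_prob=1.5).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(template_library_size=0).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(n_children=-1).validate()


def test_generated_transcripts_validate_roundtrip(tmp_path, codebooks):
    cohort = simulate_cohort(GeneratorConfig(n_children=4, seed=2))
    paths = write_simulated_cohort(cohort, tmp_path)
    for p in paths["transcripts"]:
        t = read_transcript(p, codebooks)  # validates against codebooks
        assert t.n_utterances >= 1


def test_fixed_seed_byte_identical(tmp_path):
    cfg = GeneratorConfig(n_children=3, seed=9)
    a = write_simulated_cohort(simulate_cohort(cfg), tmp_path / "a")
    b = write_simulated_cohort(simulate_cohort(cfg), tmp_path / "b")
    for pa, pb in zip(a["transcripts"], b["transcripts"]):
        assert open(pa, "rb").read() == open(pb, "rb").read()
    assert (tmp_path / "a/metadata.csv").read_text() == \
           (tmp_path / "b/metadata.csv").read_text()


def test_empty_cohort():
    cohort = simulate_cohort(GeneratorConfig(n_children=0, seed=1))
    assert cohort.children == []
    assert len(cohort.metadata) == 0


def test_verbatim_repetition_yields_full_determinism():
    cfg = GeneratorConfig(template_reuse_prob=1.0, template_library_size=1,
                          word_reuse_prob=1.0, n_utterances_range=(20, 20),
                          low_talker_fraction=0.0)
    child = simulate_child(cfg, 5, "edge")
    prof = rqa_profile(child.transcript)
    for r in prof.values():
        if r.n_points:
            assert r.det == pytest.approx(100.0)


def test_unbounded_vocabulary_kills_lexical_recurrence():
    cfg = GeneratorConfig(template_reuse_prob=0.0, word_reuse_prob=0.0,
                          open_class_vocab=None,
                          n_utterances_range=(40, 40),
                          low_talker_fraction=0.0)
    child = simulate_child(cfg, 7, "fresh")
    prof = rqa_profile(child.transcript)
    assert prof[("noun", "lexical")].rr == 0.0
    assert prof[("verb", "lexical")].rr == 0.0


def test_echolalia_repeats_previous_utterance():
    cfg = GeneratorConfig(echolalia_prob=1.0, n_utterances_range=(10, 10),
                          low_talker_fraction=0.0)
    child = simulate_child(cfg, 3, "echo")
    utts = child.transcript.utterances
    surfaces = [[t.surface for t in u.tokens] for u in utts]
    assert all(s == surfaces[0] for s in surfaces)


def test_template_reuse_raises_grammar_determinism():
    def mean_gdet(rho, seed):
        cfg = GeneratorConfig(n_children=12, seed=seed,
                              template_reuse_prob=rho,
                              low_talker_fraction=0.0)
        dets = []
        for c in simulate_cohort(cfg).children:
            p = rqa_profile(c.transcript, with_lines=False)
            for key in (("noun", "grammar"), ("verb", "grammar")):
                if p[key].det is not None:
                    dets.append(p[key].det)
        return float(np.mean(dets))

    assert mean_gdet(0.8, seed=21) > mean_gdet(0.1, seed=22)


def test_word_reuse_raises_lexical_recurrence():
    def mean_lrr(w, seed):
        cfg = GeneratorConfig(n_children=12, seed=seed, word_reuse_prob=w,
                              low_talker_fraction=0.0)
        rrs = []
        for c in simulate_cohort(cfg).children:
            p = rqa_profile(c.transcript, with_lines=False)
            rrs += [p[("noun", "lexical")].rr, p[("verb", "lexical")].rr]
        return float(np.mean(rrs))

    assert mean_lrr(0.8, seed=31) > mean_lrr(0.1, seed=32)


def test_severity_tracks_repetitiveness():
    cfg = GeneratorConfig(n_children=60, seed=13,
                          template_reuse_range=(0.0, 1.0))
    cohort = simulate_cohort(cfg)
    rho = [c.truth["rho"] for c in cohort.children]
    sev = [c.truth["ados_severity"] for c in cohort.children]
    assert spearmanr(rho, sev).statistic > 0.5


def test_cohort_includes_low_talkers_and_metadata_schema():
    cohort = simulate_cohort(GeneratorConfig(n_children=40, seed=17,
                                             low_talker_fraction=0.2))
    counts = cohort.metadata["total_utterances"]
    assert (counts < 20).any() and (counts >= 20).any()
    assert list(cohort.metadata.columns) == \
        ["child_id", "mlu", "total_utterances", "ados_severity"]
    assert cohort.metadata["ados_severity"].between(2, 10).all()


def test_realized_mlu_in_plausible_band():
    cohort = simulate_cohort(GeneratorConfig(n_children=30, seed=19))
    mlus = [speech_descriptives(t).mlu for t in cohort.transcripts]
    assert 2.0 <= float(np.mean(mlus)) <= 9.0


def test_truth_record_matches_transcript():
    cfg = GeneratorConfig(n_children=2, seed=23)
    cohort = simulate_cohort(cfg)
    for c in cohort.children:
        assert c.truth["n_utterances"] == c.transcript.n_utterances
        d = speech_descriptives(c.transcript)
        assert c.truth["mlu"] == pytest.approx(d.mlu)
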