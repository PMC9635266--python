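"""Synthetic annotated transcripts with tunable repetitiveness.

No raw transcripts from the clinical corpus are public, so every pipeline
stage is exercised on simulated children whose observable signatures match
the published cohort ranges: 20-260 utterances per included child (with a
few low talkers below the 20-utterance threshold), MLU roughly 2-9
morphemes, and an autism severity score on the 2-10 calibrated scale that
co-varies with repetitiveness.

Generative mechanism (an observational stand-in, not a cognitive claim):

* Each child owns a small library of *grammatical templates* — category
  sequences over noun-related, verb-related, and filler slots drawn from a
  miniature phrase grammar (subject NP, verb complex, optional object NP,
  optional fillers).  At each utterance the child reuses a library template
  with probability rho (template reuse), else improvises a fresh one.
  Template reuse creates repeated *category sequences*, i.e. grammar-level
  determinism, independently of word choice.
* Each lexical slot is filled from a per-category vocabulary: with
  probability w (word reuse) a previously used word of that category is
  re-emitted, else a word is drawn Zipf-distributed from the category
  vocabulary.  Closed classes (determiners, pronouns, modals, ...) have
  small vocabularies, open classes large ones, so lexical recurrence is
  nonzero at realistic vocabulary sizes.
* severity = a + b * rho + noise, clipped to [2, 10], so cohorts carry a
  positive severity-repetitiveness linkage by default.
* An optional echolalia knob re-emits the previous utterance verbatim with
  probability e (default 0).

Everything is deterministic given the config seed; per-child streams are
spawned from the cohort seed so cohorts are reproducible file-for-file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codebooks import Codebook, default_codebooks
from .transcript import Transcript, build_transcript, write_cohort

__all__ = ["GeneratorConfig", "SimulatedChild", "SimulatedCohort",
           "simulate_child", "simulate_cohort", "write_simulated_cohort"]


# per-category vocabulary sizes; closed classes are small by construction
OPEN_CLASS_SIZE = 150
VOCAB_SIZES = {
    "common_noun": OPEN_CLASS_SIZE,
    "proper_noun": 25,
    "adjective": 40,
    "verb": OPEN_CLASS_SIZE,
    "pronoun": 12,
    "determiner": 5,
    "noun_adverb": 15,
    "verb_adverb": 12,
    "noun_preposition": 8,
    "verb_preposition": 8,
    "wh_question": 6,
    "number": 10,
    "modal": 6,
    "auxiliary": 4,
    "copula": 3,
    "negative": 1,
    "infinitive": 1,
    "filler": 30,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level simulation settings.

    Per-child repetitiveness parameters rho (template reuse) and w (word
    reuse) are drawn uniformly from their ranges unless pinned with the
    scalar fields.
    """

    n_children: int = 51
    seed: int = 0
    # utterance counts span the published cohort range; a small fraction of
    # children are low talkers below the 20-utterance inclusion threshold
    n_utterances_range: tuple[int, int] = (20, 260)
    low_talker_fraction: float = 0.08
    low_talker_range: tuple[int, int] = (5, 19)
    # utterance length (tokens): per-child mean drawn from this range
    mean_tokens_range: tuple[float, float] = (2.0, 5.5)
    # grammatical repetitiveness
    template_library_size: int = 6
    template_reuse_prob: float | None = None       # rho; None -> draw
    template_reuse_range: tuple[float, float] = (0.05, 0.95)
    # lexical repetitiveness
    word_reuse_prob: float | None = None           # w; None -> draw
    word_reuse_range: tuple[float, float] = (0.2, 0.8)
    zipf_exponent: float = 1.1
    # None = unbounded vocabulary in every category: each non-reused draw is
    # a brand-new word, so with word_reuse_prob 0 lexical recurrence is 0
    open_class_vocab: int | None = OPEN_CLASS_SIZE
    # severity linkage: severity = a + b * rho + N(0, sd), clipped to [2, 10]
    severity_intercept: float = 2.5
    severity_slope: float = 5.0
    severity_noise_sd: float = 1.2
    echolalia_prob: float = 0.0

    def validate(self) -> None:
        probs = [self.low_talker_fraction, self.echolalia_prob,
                 *self.template_reuse_range, *self.word_reuse_range]
        if self.template_reuse_prob is not None:
            probs.append(self.template_reuse_prob)
        if self.word_reuse_prob is not None:
            probs.append(self.word_reuse_prob)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_children < 0:
            raise ValueError("n_children must be >= 0")
        if self.template_library_size < 1:
            raise ValueError("template_library_size must be >= 1")
        if self.n_utterances_range[0] < 1:
            raise ValueError("n_utterances must be >= 1")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")


@dataclass(frozen=True)
class SimulatedChild:
    transcript: Transcript
    truth: dict


@dataclass
class SimulatedCohort:
    children: list[SimulatedChild]
    metadata: pd.DataFrame  # child_id, mlu, total_utterances, ados_severity
    config: GeneratorConfig

    @property
    def transcripts(self) -> list[Transcript]:
        return [c.transcript for c in self.children]


# ---------------------------------------------------------------------------
# template grammar

# slot inventory per class: (lex_category, noun_units, verb_units, weight).
# Weights skew toward pronouns, nouns, determiners and verbs, the way child
# speech does.  A fresh template samples its *class* sequence from a sticky
# Markov chain — noun-phrase and verb-complex material comes in contiguous
# chunks, as in real syntax — and the category within each class slot
# independently.  Different fresh templates therefore share category
# sub-sequences only by chance, so repeated multi-unit sequences come almost
# entirely from template reuse.
_CLASS_SLOTS = {
    "noun": [
        ("pronoun", ("pronoun",), (), 0.28),
        ("common_noun", ("common_noun",), (), 0.28),
        ("determiner", ("determiner",), (), 0.19),
        ("adjective", ("adjective",), (), 0.08),
        ("proper_noun", ("proper_noun",), (), 0.03),
        ("noun_adverb", ("adverb",), (), 0.04),
        ("wh_question", ("wh_question",), (), 0.03),
        ("number", ("number",), (), 0.02),
        ("noun_preposition", ("preposition",), (), 0.05),
    ],
    "verb": [
        ("verb", (), ("verb",), 0.52),
        ("modal", (), ("modal",), 0.11),
        ("auxiliary", (), ("auxiliary",), 0.11),
        ("copula", (), ("copula",), 0.07),
        ("negative", (), ("negative",), 0.04),
        ("verb_adverb", (), ("adverb",), 0.06),
        ("verb_preposition", (), ("preposition",), 0.06),
        ("infinitive", (), ("infinitive",), 0.03),
    ],
    "filler": [("filler", (), (), 1.0)],
}
_CLASS_WEIGHTS = {
    cls: np.array([w for *_, w in slots]) / sum(w for *_, w in slots)
    for cls, slots in _CLASS_SLOTS.items()
}
_CLASS_NAMES = ("noun", "verb", "filler")
_CLASS_STATIONARY = np.array([0.58, 0.34, 0.08])
_CLASS_PERSISTENCE = 0.65  # P(next slot keeps the current class)

_VERB_MORPH = ("third_person_singular", "past_tense", "present_participle",
               "present_tense")


def _sample_template(rng: np.random.Generator, mean_tokens: float) -> list:
    """A fresh (improvised) template: a sticky-class category sequence."""
    n_slots = max(1, int(round(rng.normal(mean_tokens, 1.5))))
    slots: list[tuple[str, tuple, tuple]] = []
    cls = _CLASS_NAMES[rng.choice(3, p=_CLASS_STATIONARY)]
    for _ in range(n_slots):
        options = _CLASS_SLOTS[cls]
        cat, nu, vu, _ = options[rng.choice(len(options),
                                            p=_CLASS_WEIGHTS[cls])]
        if cat == "common_noun" and rng.random() < 0.3:
            nu = ("common_noun", "plural")
        elif cat == "verb" and rng.random() < 0.5:
            vu = ("verb", _VERB_MORPH[rng.integers(len(_VERB_MORPH))])
        slots.append((cat, nu, vu))
        if rng.random() >= _CLASS_PERSISTENCE:
            cls = _CLASS_NAMES[rng.choice(3, p=_CLASS_STATIONARY)]
    return slots


def _sample_frame(rng: np.random.Generator, mean_tokens: float) -> list:
    """A library template: a well-formed phrase frame.

    Stored frames carry guaranteed contiguous noun-phrase and verb-complex
    chunks (determiner-[adjective]-noun, modal/auxiliary-verb, ...), so a
    reused frame reliably produces multi-unit repeated sequences — this is
    what makes grammar-level determinism rise with the reuse probability
    rather than with the luck of template composition.
    """
    slots: list[tuple[str, tuple, tuple]] = []

    def noun_phrase(subject: bool) -> None:
        if subject and rng.random() < 0.45:
            slots.append(("pronoun", ("pronoun",), ()))
            return
        if not subject and rng.random() < 0.3:
            slots.append(("noun_preposition", ("preposition",), ()))
        slots.append(("determiner", ("determiner",), ()))
        if rng.random() < 0.3:
            slots.append(("adjective", ("adjective",), ()))
        if rng.random() < 0.3:
            slots.append(("common_noun", ("common_noun", "plural"), ()))
        else:
            slots.append(("common_noun", ("common_noun",), ()))

    def verb_complex() -> None:
        r = rng.random()
        if r < 0.25:
            slots.append(("modal", (), ("modal",)))
            slots.append(("verb", (), ("verb",)))
        elif r < 0.5:
            slots.append(("auxiliary", (), ("auxiliary",)))
            slots.append(("verb", (), ("verb", "present_participle")))
        else:
            morph = _VERB_MORPH[rng.integers(len(_VERB_MORPH))]
            slots.append(("verb", (), ("verb", morph)))
            if rng.random() < 0.3:
                slots.append(("verb_adverb", (), ("adverb",)))

    noun_phrase(subject=True)
    verb_complex()
    if rng.random() < 0.75:
        noun_phrase(subject=False)
    if rng.random() < 0.2:
        slots.append(("filler", (), ()))
    return slots


def _zipf_probs(size: int, s: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    w = ranks ** (-s) if s > 0 else np.ones_like(ranks)
    return w / w.sum()


class _Lexicon:
    """Per-child word store: Zipf draws plus reuse of previously used words."""

    def __init__(self, rng: np.random.Generator, w: float, s: float,
                 open_class_vocab: int):
        self.rng = rng
        self.w = w
        self.s = s
        self.open_class_vocab = open_class_vocab
        self.used: dict[str, list[str]] = {}
        self.probs: dict[str, np.ndarray] = {}

    def draw(self, category: str) -> str:
        used = self.used.setdefault(category, [])
        if used and self.rng.random() < self.w:
            return used[self.rng.integers(len(used))]
        if self.open_class_vocab is None:  # unbounded: always a new word
            word = f"{category}_u{sum(len(v) for v in self.used.values())}"
            used.append(word)
            return word
        size = VOCAB_SIZES.get(category, self.open_class_vocab)
        if size == OPEN_CLASS_SIZE:
            size = self.open_class_vocab
        if category not in self.probs:
            self.probs[category] = _zipf_probs(size, self.s)
        idx = int(self.rng.choice(size, p=self.probs[category]))
        word = f"{category}{idx:03d}"
        used.append(word)
        return word


def simulate_child(cfg: GeneratorConfig, child_seed: int,
                   child_id: str = "sim",
                   codebooks: dict[str, Codebook] | None = None
                   ) -> SimulatedChild:
    """Generate one annotated transcript plus its ground-truth parameters."""
    cfg.validate()
    codebooks = codebooks or default_codebooks()
    rng = np.random.default_rng(child_seed)

    rho = (cfg.template_reuse_prob if cfg.template_reuse_prob is not None
           else rng.uniform(*cfg.template_reuse_range))
    w = (cfg.word_reuse_prob if cfg.word_reuse_prob is not None
         else rng.uniform(*cfg.word_reuse_range))
    if rng.random() < cfg.low_talker_fraction:
        n_utts = int(rng.integers(cfg.low_talker_range[0],
                                  cfg.low_talker_range[1] + 1))
    else:
        n_utts = int(rng.integers(cfg.n_utterances_range[0],
                                  cfg.n_utterances_range[1] + 1))
    mean_tokens = rng.uniform(*cfg.mean_tokens_range)

    library = [_sample_frame(rng, mean_tokens)
               for _ in range(cfg.template_library_size)]
    lexicon = _Lexicon(rng, w, cfg.zipf_exponent, cfg.open_class_vocab)

    utterances: list[list[tuple]] = []
    for _ in range(n_utts):
        if utterances and rng.random() < cfg.echolalia_prob:
            utterances.append(list(utterances[-1]))
            continue
        if rng.random() < rho:
            template = library[rng.integers(len(library))]
        else:
            template = _sample_template(rng, mean_tokens)
        utterances.append([(lexicon.draw(cat), nu, vu)
                           for cat, nu, vu in template])

    severity = float(np.clip(
        cfg.severity_intercept + cfg.severity_slope * rho
        + rng.normal(0.0, cfg.severity_noise_sd), 2.0, 10.0))

    transcript = build_transcript(child_id, utterances, codebooks,
                                  metadata={"ados_severity": severity})
    from .transcript import speech_descriptives
    desc = speech_descriptives(transcript, codebooks)
    truth = {
        "child_id": child_id,
        "rho": float(rho),
        "w": float(w),
        "zipf_exponent": cfg.zipf_exponent,
        "template_library_size": cfg.template_library_size,
        "n_utterances": n_utts,
        "mlu": desc.mlu,
        "ados_severity": severity,
    }
    return SimulatedChild(transcript=transcript, truth=truth)


def simulate_cohort(cfg: GeneratorConfig) -> SimulatedCohort:
    """Independent simulated children plus a model-ready metadata table."""
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    child_seeds = root.integers(0, 2 ** 31 - 1, size=cfg.n_children)
    children = [
        simulate_child(cfg, int(child_seeds[i]), child_id=f"sim{i:03d}")
        for i in range(cfg.n_children)
    ]
    meta = pd.DataFrame([{
        "child_id": c.transcript.child_id,
        "mlu": c.truth["mlu"],
        "total_utterances": c.truth["n_utterances"],
        "ados_severity": c.truth["ados_severity"],
    } for c in children])
    return SimulatedCohort(children=children, metadata=meta, config=cfg)


def write_simulated_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write per-child transcript CSVs, metadata CSV, and truth JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tdir = outdir / "transcripts"
    paths = write_cohort(cohort.transcripts, tdir)
    meta_path = outdir / "metadata.csv"
    cohort.metadata.to_csv(meta_path, index=False, lineterminator="\n")
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(
        [c.truth for c in cohort.children], indent=1, sort_keys=True) + "\n")
    return {"transcripts": [str(p) for p in paths],
            "metadata": str(meta_path), "truth": str(truth_path)}
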