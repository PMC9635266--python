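"""Hand-annotated worked-example excerpts.

Four short excerpts of child speech, annotated token-by-token with
noun-related and verb-related grammatical units, used throughout the test
suite and documentation as ground truth for the coding and counting
operations: e.g. the frog excerpt repeats determiners five times and
verb-related verbs seven times; the ball excerpt repeats the bigram
"the ball" twice and "the balls" three times; the ice-cream excerpt repeats
the exact form "ice_cream" twice (the plural is a different word) and "big"
once.
"""

from __future__ import annotations

from .transcript import Transcript, build_transcript

__all__ = ["jump_excerpt", "frog_excerpt", "ice_cream_excerpt",
           "ball_excerpt"]


def jump_excerpt() -> Transcript:
    """Make-believe play excerpt ("He can jump super high...")."""
    utts = [
        # He can jump super high.
        [("he", ["pronoun"], []),
         ("can", [], ["modal"]),
         ("jump", [], ["verb"]),
         ("super", [], []),
         ("high", [], [])],
        # Higher than you can fly.
        [("higher", [], []),
         ("than", ["preposition"], []),
         ("you", ["pronoun"], []),
         ("can", [], ["modal"]),
         ("fly", [], ["verb"])],
        # Pretend that's just a baseball and you can find it to get more power.
        [("pretend", [], ["verb"]),
         ("that's", ["pronoun"], ["third_person_singular"]),
         ("just", ["adverb"], []),
         ("a", ["determiner"], []),
         ("baseball", ["common_noun"], []),
         ("and", [], []),
         ("you", ["pronoun"], []),
         ("can", [], ["modal"]),
         ("find", [], ["verb"]),
         ("it", ["pronoun"], []),
         ("to", [], ["infinitive"]),
         ("get", [], ["verb"]),
         ("more", ["common_noun"], []),
         ("power", ["common_noun"], [])],
        # Watch you can hold this up and how long you knock it you get more
        # power that way.
        [("watch", [], ["verb"]),
         ("you", ["pronoun"], []),
         ("can", [], ["modal"]),
         ("hold", [], ["verb"]),
         ("this", ["pronoun"], []),
         ("up", [], ["adverb"]),
         ("and", [], []),
         ("how", ["wh_question"], []),
         ("long", [], []),
         ("you", ["pronoun"], []),
         ("knock", [], ["verb"]),
         ("it", ["pronoun"], []),
         ("you", ["pronoun"], []),
         ("get", [], ["verb"]),
         ("more", [], ["adverb"]),
         ("power", ["common_noun"], []),
         ("that", ["determiner"], []),
         ("way", ["common_noun"], [])],
    ]
    return build_transcript("example_jump", utts)


def frog_excerpt() -> Transcript:
    """Three frog utterances rich in determiner-noun repetition."""
    utts = [
        # The frog starts going like xxx.
        [("the", ["determiner"], []),
         ("frog", ["common_noun"], []),
         ("starts", [], ["verb", "third_person_singular"]),
         ("going", [], ["verb", "present_participle"]),
         ("like", [], ["preposition"]),
         ("xxx", [], [])],
        # The frogs are gonna invade the city.
        [("the", ["determiner"], []),
         ("frogs", ["common_noun", "plural"], []),
         ("are", [], ["auxiliary", "present_tense"]),
         ("gonna", [], ["verb", "present_participle"]),
         ("invade", [], ["verb"]),
         ("the", ["determiner"], []),
         ("city", ["common_noun"], [])],
        # The frogs are leaving trying to invade the city.
        [("the", ["determiner"], []),
         ("frogs", ["common_noun", "plural"], []),
         ("are", [], ["auxiliary", "present_tense"]),
         ("leaving", [], ["verb", "present_participle"]),
         ("trying", [], ["verb", "present_participle"]),
         ("to", [], []),
         ("invade", [], ["verb"]),
         ("the", ["determiner"], []),
         ("city", ["common_noun"], [])],
    ]
    return build_transcript("example_frog", utts)


def ice_cream_excerpt() -> Transcript:
    """Exact-repetition identity: ice_cream twice, ice_creams once, big once."""
    utts = [
        # You got me ice_cream.
        [("you", ["pronoun"], []),
         ("got", [], ["verb", "past_tense"]),
         ("me", ["pronoun"], []),
         ("ice_cream", ["common_noun"], [])],
        # Big ice_creams.
        [("big", ["adjective"], []),
         ("ice_creams", ["common_noun", "plural"], [])],
        # You'll have vanilla and I'll have white ice_cream.
        [("you", ["pronoun"], []),
         ("will", [], ["modal"]),
         ("have", [], ["verb"]),
         ("vanilla", ["common_noun"], []),
         ("and", [], []),
         ("i", ["pronoun"], []),
         ("will", [], ["modal"]),
         ("have", [], ["verb"]),
         ("white", ["adjective"], []),
         ("ice_cream", ["common_noun"], [])],
    ]
    return build_transcript("example_ice_cream", utts)


def ball_excerpt() -> Transcript:
    """Seven ball utterances: "the ball" x2 and "the balls" x3 at the
    noun-lexical level; "do not let" repeats at the verb-lexical level."""
    utts = [
        # Can I play with the ball?
        [("can", [], ["modal"]),
         ("i", ["pronoun"], []),
         ("play", [], ["verb"]),
         ("with", [], ["preposition"]),
         ("the", ["determiner"], []),
         ("ball", ["common_noun"], [])],
        # Where's the ball?
        [("where's", ["pronoun"], ["third_person_singular"]),
         ("the", ["determiner"], []),
         ("ball", ["common_noun"], [])],
        # He likes balls.
        [("he", ["pronoun"], []),
         ("likes", [], ["verb", "third_person_singular"]),
         ("balls", ["common_noun", "plural"], [])],
        # Of dogs that like to play ball.
        [("of", ["preposition"], []),
         ("dogs", ["common_noun", "plural"], []),
         ("that", ["pronoun"], []),
         ("like", [], ["verb"]),
         ("to", [], []),
         ("play", [], ["verb"]),
         ("ball", ["common_noun"], [])],
        # He likes to play with all the balls.
        [("he", ["pronoun"], []),
         ("likes", [], ["verb", "third_person_singular"]),
         ("to", [], []),
         ("play", [], ["verb"]),
         ("with", [], ["preposition"]),
         ("all", ["common_noun"], []),
         ("the", ["determiner"], []),
         ("balls", ["common_noun", "plural"], [])],
        # And mine too but I do not let him have the balls but I do not let
        # him have the balls because.
        [("and", [], []),
         ("mine", ["pronoun"], []),
         ("too", ["adverb"], []),
         ("but", [], []),
         ("i", ["pronoun"], []),
         ("do", [], ["auxiliary"]),
         ("not", [], ["negative"]),
         ("let", [], ["verb"]),
         ("him", ["pronoun"], []),
         ("have", [], ["verb"]),
         ("the", ["determiner"], []),
         ("balls", ["common_noun", "plural"], []),
         ("but", [], []),
         ("i", ["pronoun"], []),
         ("do", [], ["auxiliary"]),
         ("not", [], ["negative"]),
         ("let", [], ["verb"]),
         ("him", ["pronoun"], []),
         ("have", [], ["verb"]),
         ("the", ["determiner"], []),
         ("balls", ["common_noun", "plural"], []),
         ("because", [], [])],
        # There's some balls that can that he can choke on it.
        [("there's", ["pronoun"], ["third_person_singular"]),
         ("some", ["common_noun"], []),
         ("balls", ["common_noun", "plural"], []),
         ("that", ["pronoun"], []),
         ("can", [], ["modal"]),
         ("that", ["pronoun"], []),
         ("he", ["pronoun"], []),
         ("can", [], ["modal"]),
         ("choke", [], ["verb"]),
         ("on", [], ["preposition"]),
         ("it", ["pronoun"], [])],
    ]
    return build_transcript("example_ball", utts)
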