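"""Emotional profiling of semantic frames with a sampling null model.

A frame's emotional profile is the fraction of its words that evoke
each of Plutchik's eight basic emotions (a word may evoke several, so
fractions need not sum to one). Because emotions have unequal base
rates in any word–emotion lexicon — there are simply more fear- and
joy-words than sadness-words — raw fractions are compared against a
null: fix m, the number of frame words carrying at least one emotion,
draw m words uniformly at random (without replacement) from the
lexicon's emotion-bearing vocabulary, recompute the profile, and repeat
(1,000 draws by default). The per-emotion z-score

    z_e = (observed_e - null_mean_e) / null_sd_e

is significant at z >= 1.96 ("emotional flower" convention: petals
escaping the rejection disc mark emotions over-represented beyond the
0.05 level).

Concepts linked to a negation node carry their negated meaning as well:
each word adjacent to "not" in the network contributes its listed
antonyms alongside itself before profiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .lexicons import EMOTIONS, EmotionLexicon, PairLexicon
from .network import TFMN, aggregate_graph
from .syntax import NEGATION_WORDS

logger = logging.getLogger(__name__)

__all__ = [
    "Z_CRITICAL",
    "EmotionalProfile",
    "NullDistribution",
    "EmotionalFlower",
    "expand_negated",
    "emotional_profile",
    "sample_null",
    "flower",
    "profile_frame",
]

#: Significance threshold on z (the rejection-region radius).
Z_CRITICAL = 1.96


@dataclass(frozen=True)
class EmotionalProfile:
    """Per-emotion fractions over the m emotion-bearing words of a frame."""

    focus: str
    m: int
    fractions: Mapping[str, float]

    @property
    def defined(self) -> bool:
        return self.m > 0


@dataclass(frozen=True)
class NullDistribution:
    """Null mean/sd of emotion fractions under uniform m-word sampling."""

    m: int
    reps: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    seed: int


@dataclass(frozen=True)
class EmotionalFlower:
    """z-scores and significance flags per emotion.

    ``z[e]`` is NaN (and flagged undefined) when the null sd vanishes.
    Ring metadata for plotting layers: concentric rings mark unit
    z-score steps beyond the rejection radius ``Z_CRITICAL``.
    """

    focus: str
    z: Mapping[str, float]
    significant: Mapping[str, bool]
    rejection_radius: float = Z_CRITICAL


def expand_negated(
    frame_words: Iterable[str],
    tfmn: TFMN,
    antonyms: PairLexicon,
) -> List[str]:
    """Add antonyms of negation-linked words; originals always retained.

    A word is negation-linked when it is adjacent to a negation node
    ("not") in the aggregate network. Negated words with no listed
    antonym pass through unchanged (logged).
    """
    words = list(frame_words)
    g = aggregate_graph(tfmn)
    neg_nodes = [n for n in tfmn.nodes if n in NEGATION_WORDS]
    negated: Set[str] = set()
    for neg in neg_nodes:
        negated.update(g.neighbors(neg))
    out = list(words)
    for w in words:
        if w in negated:
            ants = sorted(antonyms.partners_of(w))
            if not ants:
                logger.warning("negated word %r has no listed antonym", w)
            out.extend(ants)
    return out


def emotional_profile(words: Iterable[str], emolex: EmotionLexicon, focus: str = "") -> EmotionalProfile:
    """Fraction of emotion-bearing frame words evoking each emotion.

    Contributing words are the *distinct* words with at least one
    emotion (m = their count); ``fraction(e) = |{w: e evoked by w}| / m``.
    m = 0 yields an explicitly undefined profile (NaN fractions).
    """
    contributing = {w for w in set(words) if emolex.emotions_of(w)}
    m = len(contributing)
    if m == 0:
        return EmotionalProfile(
            focus=focus, m=0, fractions={e: float("nan") for e in EMOTIONS}
        )
    fractions = {
        e: sum(1 for w in contributing if e in emolex.emotions_of(w)) / m
        for e in EMOTIONS
    }
    return EmotionalProfile(focus=focus, m=m, fractions=fractions)


def _membership_matrix(emolex: EmotionLexicon) -> Tuple[Tuple[str, ...], np.ndarray]:
    vocab = emolex.eligible_words()
    mat = np.zeros((len(vocab), len(EMOTIONS)), dtype=bool)
    for i, w in enumerate(vocab):
        ems = emolex.emotions_of(w)
        for j, e in enumerate(EMOTIONS):
            mat[i, j] = e in ems
    return vocab, mat


def sample_null(
    m: int, emolex: EmotionLexicon, reps: int = 1000, seed: int = 0
) -> NullDistribution:
    """Null emotion-fraction distribution from uniform m-word samples.

    Each repetition draws m distinct words uniformly at random from the
    emotion-bearing vocabulary (a frame is a set of distinct words, so
    sampling is without replacement).
    """
    vocab, mat = _membership_matrix(emolex)
    n = len(vocab)
    if not 1 <= m <= n:
        raise ValueError(f"m={m} outside [1, {n}] (eligible vocabulary size)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if m == n:
        base = mat.mean(axis=0)
        mean = {e: float(base[j]) for j, e in enumerate(EMOTIONS)}
        sd = {e: 0.0 for e in EMOTIONS}
        return NullDistribution(m=m, reps=reps, mean=mean, sd=sd, seed=seed)
    # vectorised sampling without replacement: argpartition of random keys
    keys = rng.random((reps, n))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    fracs = mat[idx].mean(axis=1)  # (reps, 8)
    mean = {e: float(fracs[:, j].mean()) for j, e in enumerate(EMOTIONS)}
    sd = {e: float(fracs[:, j].std(ddof=0)) for j, e in enumerate(EMOTIONS)}
    return NullDistribution(m=m, reps=reps, mean=mean, sd=sd, seed=seed)


def flower(profile: EmotionalProfile, null: NullDistribution) -> EmotionalFlower:
    """z-scores of a profile against its null; significant iff z >= 1.96.

    The threshold is one-sided — petals mark emotions evoked *more*
    than random expectation. A zero null sd leaves z undefined (NaN,
    never significant).
    """
    if null.m != profile.m:
        raise ValueError(f"null m={null.m} does not match profile m={profile.m}")
    z: Dict[str, float] = {}
    sig: Dict[str, bool] = {}
    for e in EMOTIONS:
        s = null.sd[e]
        obs = profile.fractions[e]
        if s == 0 or not np.isfinite(obs):
            z[e] = float("nan")
            sig[e] = False
        else:
            z[e] = (obs - null.mean[e]) / s
            sig[e] = z[e] >= Z_CRITICAL
    return EmotionalFlower(focus=profile.focus, z=z, significant=sig)


def profile_frame(
    frame_words: Iterable[str],
    tfmn: TFMN,
    emolex: EmotionLexicon,
    antonyms: PairLexicon,
    focus: str = "",
    reps: int = 1000,
    seed: int = 0,
) -> Tuple[EmotionalProfile, Optional[NullDistribution], Optional[EmotionalFlower]]:
    """Full pipeline: negation expansion → profile → null → flower."""
    expanded = expand_negated(frame_words, tfmn, antonyms)
    profile = emotional_profile(expanded, emolex, focus=focus)
    if not profile.defined:
        return profile, None, None
    null = sample_null(profile.m, emolex, reps=reps, seed=seed)
    return profile, null, flower(profile, null)
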