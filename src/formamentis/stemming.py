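"""Suffix stemming for network-level concept merging.

Network nodes are word stems so that inflectional variants ("weak",
"weakness") collapse onto a single concept. The stemmer is the classic
Porter (1980) suffix-stripping algorithm, exposed through a small
deterministic, idempotent contract: ``stem(stem(w)) == stem(w)``.
Idempotence is enforced by iterating the underlying algorithm to a
fixed point (Porter is single-pass and not idempotent on every input).
"""

from __future__ import annotations

__all__ = ["PorterStemmer", "stem", "Stemmer"]

from typing import Callable, Protocol

_VOWELS = frozenset("aeiou")


class Stemmer(Protocol):
    """Contract: a deterministic, idempotent word → stem mapping."""

    def __call__(self, word: str) -> str: ...


class PorterStemmer:
    """Porter suffix-stripping stemmer (Porter 1980), lowercase input."""

    def _is_cons(self, w: str, i: int) -> bool:
        c = w[i]
        if c in _VOWELS:
            return False
        if c == "y":
            return i == 0 or not self._is_cons(w, i - 1)
        return True

    def _measure(self, w: str) -> int:
        """Number of VC sequences in the [C](VC)^m[V] decomposition."""
        m = 0
        prev_vowel = False
        for i in range(len(w)):
            v = not self._is_cons(w, i)
            if prev_vowel and not v:
                m += 1
            prev_vowel = v
        return m

    def _has_vowel(self, w: str) -> bool:
        return any(not self._is_cons(w, i) for i in range(len(w)))

    def _ends_double_cons(self, w: str) -> bool:
        return (
            len(w) >= 2
            and w[-1] == w[-2]
            and self._is_cons(w, len(w) - 1)
        )

    def _cvc(self, w: str) -> bool:
        # ends consonant-vowel-consonant, final consonant not w/x/y
        if len(w) < 3:
            return False
        return (
            self._is_cons(w, len(w) - 3)
            and not self._is_cons(w, len(w) - 2)
            and self._is_cons(w, len(w) - 1)
            and w[-1] not in "wxy"
        )

    def _step1ab(self, w: str) -> str:
        if w.endswith("sses"):
            w = w[:-2]
        elif w.endswith("ies"):
            w = w[:-2]
        elif w.endswith("ss"):
            pass
        elif w.endswith("s"):
            w = w[:-1]

        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                w = w[:-1]
        elif w.endswith("ed") and self._has_vowel(w[:-2]):
            w = self._step1b_fix(w[:-2])
        elif w.endswith("ing") and self._has_vowel(w[:-3]):
            w = self._step1b_fix(w[:-3])
        return w

    def _step1b_fix(self, w: str) -> str:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if self._ends_double_cons(w) and w[-1] not in "lsz":
            return w[:-1]
        if self._measure(w) == 1 and self._cvc(w):
            return w + "e"
        return w

    def _step1c(self, w: str) -> str:
        if w.endswith("y") and self._has_vowel(w[:-1]):
            return w[:-1] + "i"
        return w

    _STEP2 = [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
        ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
        ("alli", "al"), ("entli", "ent"), ("eli", "e"), ("ousli", "ous"),
        ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
        ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
        ("biliti", "ble"),
    ]
    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]
    _STEP4 = [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive",
        "ize",
    ]

    def _rule_list(self, w: str, rules, min_measure: int) -> str:
        for suf, rep in rules:
            if w.endswith(suf):
                base = w[: len(w) - len(suf)]
                if self._measure(base) > min_measure - 1:
                    return base + rep
                return w
        return w

    def _step4(self, w: str) -> str:
        for suf in self._STEP4:
            if w.endswith(suf):
                base = w[: len(w) - len(suf)]
                if suf == "ion" and (not base or base[-1] not in "st"):
                    return w
                if self._measure(base) > 1:
                    return base
                return w
        return w

    def _step5(self, w: str) -> str:
        if w.endswith("e"):
            base = w[:-1]
            m = self._measure(base)
            if m > 1 or (m == 1 and not self._cvc(base)):
                w = base
        if self._ends_double_cons(w) and w.endswith("l") and self._measure(w) > 1:
            w = w[:-1]
        return w

    def stem_once(self, word: str) -> str:
        w = word.lower()
        if len(w) <= 2:
            return w
        w = self._step1ab(w)
        w = self._step1c(w)
        w = self._rule_list(w, self._STEP2, 1)
        w = self._rule_list(w, self._STEP3, 1)
        w = self._step4(w)
        w = self._step5(w)
        return w

    def __call__(self, word: str) -> str:
        """Stem to a fixed point so the mapping is idempotent.

        A repeat-guard handles the (pathological) case of a cycle: the
        lexicographically smallest member of the cycle is returned, which
        is again a deterministic, idempotent choice.
        """
        w = word.lower()
        seen = [w]
        for _ in range(8):
            nxt = self.stem_once(w)
            if nxt == w:
                return w
            if nxt in seen:
                return min(seen[seen.index(nxt):])
            seen.append(nxt)
            w = nxt
        return w


_default = PorterStemmer()


def stem(word: str) -> str:
    """Stem a word with the package-default Porter stemmer."""
    return _default(word)
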