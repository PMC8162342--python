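"""Text normalisation for content tagging.

Free-text content descriptions are lowercased, split at Unicode word
boundaries, filtered against a stop-word list and reduced to base forms
with the classic Porter stemming algorithm.  The resulting stems are what
the semantic network's surface-form index resolves to concepts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["StopWordList", "PorterStemmer", "tokenize", "tokenize_and_stem"]

_WORD_RE = re.compile(r"\w+", re.UNICODE)


@dataclass(frozen=True)
class StopWordList:
    """Case-insensitive stop-word lookup."""

    words: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "words", frozenset(w.lower() for w in self.words))

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.words

    @classmethod
    def from_iterable(cls, words: Iterable[str]) -> "StopWordList":
        return cls(frozenset(words))

    @classmethod
    def load(cls, path: str | Path) -> "StopWordList":
        """Read one word per line; blank lines and ``#`` comments ignored."""
        words = set()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip().lower()
            if line and not line.startswith("#"):
                words.add(line)
        return cls(frozenset(words))


class PorterStemmer:
    """The Porter (1980) suffix-stripping stemmer for English.

    Deterministic, dependency-free.  Words of length <= 2 are returned
    unchanged, as in the reference algorithm.
    """

    _VOWELS = "aeiou"

    def _cons(self, word: str, i: int) -> bool:
        c = word[i]
        if c in self._VOWELS:
            return False
        if c == "y":
            return i == 0 or not self._cons(word, i - 1)
        return True

    def _measure(self, stem: str) -> int:
        # number of vowel->consonant transitions ("m" in Porter's notation)
        m = 0
        prev_vowel = False
        for i in range(len(stem)):
            is_v = not self._cons(stem, i)
            if prev_vowel and not is_v:
                m += 1
            prev_vowel = is_v
        return m

    def _has_vowel(self, stem: str) -> bool:
        return any(not self._cons(stem, i) for i in range(len(stem)))

    def _ends_double_cons(self, word: str) -> bool:
        return (
            len(word) >= 2
            and word[-1] == word[-2]
            and self._cons(word, len(word) - 1)
        )

    def _cvc(self, word: str) -> bool:
        # consonant-vowel-consonant ending, last consonant not w, x or y
        if len(word) < 3:
            return False
        return (
            self._cons(word, len(word) - 3)
            and not self._cons(word, len(word) - 2)
            and self._cons(word, len(word) - 1)
            and word[-1] not in "wxy"
        )

    def _replace(self, word: str, suffix: str, repl: str, m_min: int) -> str | None:
        if not word.endswith(suffix):
            return None
        stem = word[: len(word) - len(suffix)]
        if self._measure(stem) > m_min:
            return stem + repl
        return word

    def stem(self, word: str) -> str:
        word = word.lower()
        if len(word) <= 2:
            return word
        word = self._step1a(word)
        word = self._step1b(word)
        word = self._step1c(word)
        word = self._step2(word)
        word = self._step3(word)
        word = self._step4(word)
        word = self._step5(word)
        return word

    def _step1a(self, w: str) -> str:
        if w.endswith("sses"):
            return w[:-2]
        if w.endswith("ies"):
            return w[:-2]
        if w.endswith("ss"):
            return w
        if w.endswith("s"):
            return w[:-1]
        return w

    def _step1b(self, w: str) -> str:
        if w.endswith("eed"):
            stem = w[:-3]
            return w[:-1] if self._measure(stem) > 0 else w
        flag = False
        if w.endswith("ed") and self._has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and self._has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
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
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ]

    def _step2(self, w: str) -> str:
        for suffix, repl in self._STEP2:
            out = self._replace(w, suffix, repl, 0)
            if out is not None:
                return out
        return w

    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]

    def _step3(self, w: str) -> str:
        for suffix, repl in self._STEP3:
            out = self._replace(w, suffix, repl, 0)
            if out is not None:
                return out
        return w

    _STEP4 = [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ]

    def _step4(self, w: str) -> str:
        if w.endswith("ion") and len(w) > 3 and w[-4] in "st":
            stem = w[:-3]
            return stem if self._measure(stem) > 1 else w
        for suffix in self._STEP4:
            if w.endswith(suffix):
                stem = w[: len(w) - len(suffix)]
                if self._measure(stem) > 1:
                    return stem
                return w
        return w

    def _step5(self, w: str) -> str:
        # 5a
        if w.endswith("e"):
            stem = w[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._cvc(stem)):
                w = stem
        # 5b
        if self._measure(w) > 1 and self._ends_double_cons(w) and w.endswith("l"):
            w = w[:-1]
        return w


_DEFAULT_STEMMER = PorterStemmer()


def tokenize(text: str) -> list[str]:
    """Lowercased tokens at Unicode word boundaries; punctuation stripped."""
    return _WORD_RE.findall(text.lower())


def tokenize_and_stem(
    description: str,
    stop_words: StopWordList | None = None,
    stemmer: PorterStemmer | None = None,
) -> list[str]:
    """Tokenize ``description``, drop stop words, stem the remainder.

    Order is preserved and duplicate stems retained; an empty description
    yields an empty sequence.
    """
    stop_words = stop_words or StopWordList()
    stemmer = stemmer or _DEFAULT_STEMMER
    return [stemmer.stem(t) for t in tokenize(description) if t not in stop_words]
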