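"""Stemmers used for lexicon and text normalization.

English uses the classic Porter algorithm, implemented here in full.
French uses a deliberately light suffix stripper (plural and final-e
removal): because the same function is applied to both the dictionary
terms and the text being matched, consistency — not linguistic depth —
is what makes matching work.
"""

from __future__ import annotations


class PorterStemmer:
    """The Porter (1980) suffix-stripping algorithm."""

    def stem(self, word: str) -> str:
        word = word.lower()
        if len(word) <= 2:
            return word
        self.b = word
        self.k = len(word) - 1
        self.j = 0
        self._step1ab()
        self._step1c()
        self._step2()
        self._step3()
        self._step4()
        self._step5()
        return self.b[: self.k + 1]

    # -- character classes ---------------------------------------------------

    def _cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in "aeiou":
            return False
        if ch == "y":
            return True if i == 0 else not self._cons(i - 1)
        return True

    def _m(self) -> int:
        """Number of consonant-vowel sequences in b[0..j]."""
        n = i = 0
        while True:
            if i > self.j:
                return n
            if not self._cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > self.j:
                    return n
                if self._cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > self.j:
                    return n
                if not self._cons(i):
                    break
                i += 1
            i += 1

    def _vowel_in_stem(self) -> bool:
        return any(not self._cons(i) for i in range(self.j + 1))

    def _doublec(self, j: int) -> bool:
        if j < 1 or self.b[j] != self.b[j - 1]:
            return False
        return self._cons(j)

    def _cvc(self, i: int) -> bool:
        if i < 2 or not self._cons(i) or self._cons(i - 1) or not self._cons(i - 2):
            return False
        return self.b[i] not in "wxy"

    # -- suffix machinery ----------------------------------------------------

    def _ends(self, s: str) -> bool:
        length = len(s)
        if length > self.k + 1 or self.b[self.k - length + 1 : self.k + 1] != s:
            return False
        self.j = self.k - length
        return True

    def _setto(self, s: str) -> None:
        self.b = self.b[: self.j + 1] + s
        self.k = len(self.b) - 1

    def _r(self, s: str) -> None:
        if self._m() > 0:
            self._setto(s)

    # -- steps ----------------------------------------------------------------

    def _step1ab(self) -> None:
        if self.b[self.k] == "s":
            if self._ends("sses"):
                self.k -= 2
            elif self._ends("ies"):
                self._setto("i")
            elif self.b[self.k - 1] != "s":
                self.k -= 1
        if self._ends("eed"):
            if self._m() > 0:
                self.k -= 1
        elif (self._ends("ed") or self._ends("ing")) and self._vowel_in_stem():
            self.k = self.j
            if self._ends("at"):
                self._setto("ate")
            elif self._ends("bl"):
                self._setto("ble")
            elif self._ends("iz"):
                self._setto("ize")
            elif self._doublec(self.k):
                if self.b[self.k] not in "lsz":
                    self.k -= 1
            elif self._m() == 1 and self._cvc(self.k):
                self.j = self.k
                self._setto("e")

    def _step1c(self) -> None:
        if self._ends("y") and self._vowel_in_stem():
            self.b = self.b[: self.k] + "i"

    _STEP2 = [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("bli", "ble"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
        ("logi", "log"),
    ]

    def _step2(self) -> None:
        for suffix, repl in self._STEP2:
            if self._ends(suffix):
                self._r(repl)
                return

    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]

    def _step3(self) -> None:
        for suffix, repl in self._STEP3:
            if self._ends(suffix):
                self._r(repl)
                return

    _STEP4 = [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ]

    def _step4(self) -> None:
        for suffix in self._STEP4:
            if self._ends(suffix):
                if suffix == "ion" and self.b[self.j] not in "st":
                    continue
                if self._m() > 1:
                    self.k = self.j
                return

    def _step5(self) -> None:
        self.j = self.k
        if self.b[self.k] == "e":
            a = self._m()
            if a > 1 or (a == 1 and not self._cvc(self.k - 1)):
                self.k -= 1
        if self.b[self.k] == "l" and self._doublec(self.k) and self._m() > 1:
            self.k -= 1


class FrenchLightStemmer:
    """Minimal French stemmer: plural endings and a final mute 'e'.

    ``fleurs`` → ``fleur``, ``rouges`` → ``roug``, ``pétales`` → ``pétal``.
    """

    def stem(self, word: str) -> str:
        word = word.lower()
        if len(word) > 4 and word.endswith("aux"):
            word = word[:-3] + "al"
        elif len(word) > 3 and word.endswith(("s", "x")):
            word = word[:-1]
        if len(word) > 3 and word.endswith("e"):
            word = word[:-1]
        return word


class NoStemmer:
    """Identity stemmer for the --no-stem switch."""

    def stem(self, word: str) -> str:
        return word.lower()


_STEMMERS = {"en": PorterStemmer, "fr": FrenchLightStemmer}


def get_stemmer(language: str, stem: bool = True):
    if not stem:
        return NoStemmer()
    try:
        return _STEMMERS[language]()
    except KeyError:
        raise ValueError(f"unsupported language: {language!r}") from None
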