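"""French Snowball stemmer.

Implements the Snowball stemming algorithm for French (the Porter-family
stemmer distributed by the Snowball project and used by the R ``SnowballC``
package and NLTK). The implementation follows the published algorithm:
a marking prelude (``u``/``i`` between vowels, ``y`` next to a vowel and
``u`` after ``q`` are upper-cased so they are treated as consonants), the
``RV``/``R1``/``R2`` regions, standard suffix removal, two verb-suffix
steps, a residual step, undoubling and unaccenting.

No external stemming package is available in this stack, so the algorithm
is authored here and exercised by hand-traced reference cases in the test
suite.
"""

from __future__ import annotations

__all__ = ["stem_word"]

_VOWELS = "aeiouyâàëéêèïîôûù"


def _is_v(ch: str) -> bool:
    return ch in _VOWELS


def _mark(word: str) -> str:
    """Upper-case u/i between vowels, y next to a vowel, u after q.

    The scan runs left to right; a character already marked upper-case no
    longer counts as a vowel for the characters to its right.
    """
    chars = list(word)
    n = len(chars)
    for i, ch in enumerate(chars):
        left_v = i > 0 and _is_v(chars[i - 1])
        right_v = i + 1 < n and _is_v(word[i + 1])
        if ch == "u":
            if (i > 0 and chars[i - 1] == "q") or (left_v and right_v):
                chars[i] = "U"
        elif ch == "i":
            if left_v and right_v:
                chars[i] = "I"
        elif ch == "y":
            if left_v or right_v:
                chars[i] = "Y"
    return "".join(chars)


def _rv(word: str) -> int:
    n = len(word)
    if n >= 3 and _is_v(word[0]) and _is_v(word[1]):
        return 3
    if word[:3] in ("par", "col", "tap"):
        return 3
    for i in range(1, n):
        if _is_v(word[i]):
            return i + 1
    return n


def _r_region(word: str, start: int) -> int:
    for i in range(start, len(word) - 1):
        if _is_v(word[i]) and not _is_v(word[i + 1]):
            return i + 2
    return len(word)


# Step-1 suffixes, longest first inside each lookup.
_S1_DELETE_R2 = (
    "ances", "iqUes", "ismes", "ables", "istes",
    "ance", "iqUe", "isme", "able", "iste", "eux",
)
_S1_AT = ("atrices", "ateurs", "ations", "atrice", "ateur", "ation")
_S1_LOGIE = ("logies", "logie")
_S1_USION = ("usions", "utions", "usion", "ution")
_S1_ENCE = ("ences", "ence")
_S1_EMENT = ("ements", "ement")
_S1_ITE = ("ités", "ité")
_S1_IF = ("ives", "ifs", "ive", "if")
_S1_ISSEMENT = ("issements", "issement")

_ALL_S1 = sorted(
    _S1_DELETE_R2 + _S1_AT + _S1_LOGIE + _S1_USION + _S1_ENCE + _S1_EMENT
    + _S1_ITE + _S1_IF + _S1_ISSEMENT
    + ("eaux", "aux", "euses", "euse", "amment", "emment", "ments", "ment"),
    key=len,
    reverse=True,
)

_S2A = sorted(
    (
        "îmes", "ît", "îtes", "i", "ie", "ies", "ir", "ira", "irai",
        "iraIent", "irais", "irait", "iras", "irent", "irez", "iriez",
        "irions", "irons", "iront", "is", "issaIent", "issais", "issait",
        "issant", "issante", "issantes", "issants", "isse", "issent",
        "isses", "issez", "issiez", "issions", "issons", "it",
    ),
    key=len,
    reverse=True,
)

_S2B_DELETE = (
    "eraIent", "erions", "èrent", "erais", "erait", "eriez", "erons",
    "eront", "erai", "eras", "erez", "ées", "era", "iez", "ée", "és",
    "er", "ez", "é",
)
_S2B_DELETE_E = (
    "assions", "assiez", "assent", "aIent", "antes", "asses", "âmes",
    "âtes", "ante", "ants", "asse", "ais", "ait", "ant", "as", "ai",
    "a", "ât",
)
_S2B = sorted(("ions",) + _S2B_DELETE + _S2B_DELETE_E, key=len, reverse=True)


class _Word:
    """Mutable word with fixed R1/R2/RV offsets into the current string."""

    def __init__(self, s: str):
        self.s = s
        self.rv = _rv(s)
        self.r1 = _r_region(s, 0)
        self.r2 = _r_region(s, self.r1)

    def ends(self, suf: str) -> bool:
        return self.s.endswith(suf)

    def pos(self, suf: str) -> int:
        return len(self.s) - len(suf)

    def in_r1(self, suf: str) -> bool:
        return self.ends(suf) and self.pos(suf) >= self.r1

    def in_r2(self, suf: str) -> bool:
        return self.ends(suf) and self.pos(suf) >= self.r2

    def in_rv(self, suf: str) -> bool:
        return self.ends(suf) and self.pos(suf) >= self.rv

    def chop(self, n: int) -> None:
        self.s = self.s[:-n]

    def replace(self, n: int, repl: str) -> None:
        self.s = self.s[:-n] + repl


def _step1(w: _Word) -> tuple[bool, bool]:
    """Standard suffix removal.

    Returns (altered, step1_success).  A ``ment``-family removal alters the
    word but does not count as success, so the verb steps still run — this
    mirrors the ``fail`` markers in the reference algorithm.
    """
    suf = next((s for s in _ALL_S1 if w.ends(s)), None)
    if suf is None:
        return False, False

    if suf in _S1_DELETE_R2:
        if w.in_r2(suf):
            w.chop(len(suf))
            return True, True
        return False, False

    if suf in _S1_AT:
        if not w.in_r2(suf):
            return False, False
        w.chop(len(suf))
        if w.ends("ic"):
            if w.in_r2("ic"):
                w.chop(2)
            else:
                w.replace(2, "iqU")
        return True, True

    if suf in _S1_LOGIE:
        if w.in_r2(suf):
            w.replace(len(suf), "log")
            return True, True
        return False, False

    if suf in _S1_USION:
        if w.in_r2(suf):
            w.replace(len(suf), "u")
            return True, True
        return False, False

    if suf in _S1_ENCE:
        if w.in_r2(suf):
            w.replace(len(suf), "ent")
            return True, True
        return False, False

    if suf in _S1_EMENT:
        if not w.in_rv(suf):
            return False, False
        w.chop(len(suf))
        if w.in_r2("iv"):
            w.chop(2)
            if w.in_r2("at"):
                w.chop(2)
        elif w.ends("eus"):
            if w.in_r2("eus"):
                w.chop(3)
            elif w.in_r1("eus"):
                w.replace(3, "eux")
        elif w.in_r2("abl") or w.in_r2("iqU"):
            w.chop(3)
        elif w.in_rv("ièr") or w.in_rv("Ièr"):
            w.replace(3, "i")
        return True, True

    if suf in _S1_ITE:
        if not w.in_r2(suf):
            return False, False
        w.chop(len(suf))
        if w.ends("abil"):
            if w.in_r2("abil"):
                w.chop(4)
            else:
                w.replace(4, "abl")
        elif w.ends("ic"):
            if w.in_r2("ic"):
                w.chop(2)
            else:
                w.replace(2, "iqU")
        elif w.in_r2("iv"):
            w.chop(2)
        return True, True

    if suf in _S1_IF:
        if not w.in_r2(suf):
            return False, False
        w.chop(len(suf))
        if w.in_r2("at"):
            w.chop(2)
            if w.ends("ic"):
                if w.in_r2("ic"):
                    w.chop(2)
                else:
                    w.replace(2, "iqU")
        return True, True

    if suf == "eaux":
        w.replace(4, "eau")
        return True, True

    if suf == "aux":
        if w.in_r1(suf):
            w.replace(3, "al")
            return True, True
        return False, False

    if suf in ("euses", "euse"):
        if w.in_r2(suf):
            w.chop(len(suf))
            return True, True
        if w.in_r1(suf):
            w.replace(len(suf), "eux")
            return True, True
        return False, False

    if suf in _S1_ISSEMENT:
        p = w.pos(suf)
        if p >= w.r1 and p > 0 and not _is_v(w.s[p - 1]):
            w.chop(len(suf))
            return True, True
        return False, False

    if suf == "amment":
        if w.in_rv(suf):
            w.replace(6, "ant")
            return True, False
        return False, False

    if suf == "emment":
        if w.in_rv(suf):
            w.replace(6, "ent")
            return True, False
        return False, False

    # ment / ments: delete when preceded by a vowel lying in RV
    p = w.pos(suf)
    if p - 1 >= w.rv and _is_v(w.s[p - 1]):
        w.chop(len(suf))
        return True, False
    return False, False


def _step2a(w: _Word) -> bool:
    for suf in _S2A:
        if w.in_rv(suf):
            p = w.pos(suf)
            if p - 1 >= w.rv and not _is_v(w.s[p - 1]):
                w.chop(len(suf))
                return True
            return False
    return False


def _step2b(w: _Word) -> bool:
    for suf in _S2B:
        if not w.in_rv(suf):
            continue
        if suf == "ions":
            if w.in_r2(suf):
                w.chop(4)
                return True
            return False
        if suf in _S2B_DELETE:
            w.chop(len(suf))
            return True
        # a-group: delete, plus a preceding 'e' inside RV
        w.chop(len(suf))
        if w.ends("e") and w.pos("e") >= w.rv:
            w.chop(1)
        return True
    return False


def _step4(w: _Word) -> None:
    if w.ends("s") and len(w.s) >= 2 and w.s[-2] not in "aiouès":
        w.chop(1)
    for suf in ("ière", "Ière", "ion", "ier", "Ier", "e", "ë"):
        if not w.in_rv(suf):
            continue
        if suf == "ion":
            p = w.pos(suf)
            if p >= w.r2 and p - 1 >= w.rv and w.s[p - 1] in "st":
                w.chop(3)
            return
        if suf in ("ière", "Ière", "ier", "Ier"):
            w.replace(len(suf), "i")
            return
        if suf == "e":
            w.chop(1)
            return
        if suf == "ë":
            if w.s.endswith("guë"):
                w.chop(1)
            return


def _step5(w: _Word) -> None:
    for suf in ("enn", "onn", "ett", "ell", "eill"):
        if w.ends(suf):
            w.chop(1)
            return


def _step6(w: _Word) -> None:
    i = len(w.s)
    while i > 0 and not _is_v(w.s[i - 1]):
        i -= 1
    if i < len(w.s) and i > 0 and w.s[i - 1] in "éè":
        w.s = w.s[: i - 1] + "e" + w.s[i:]


def stem_word(word: str) -> str:
    """Return the French Snowball stem of a single lower-case word."""
    if len(word) <= 2:
        return word
    w = _Word(_mark(word))

    altered1, ok1 = _step1(w)
    did_verb = False
    if not ok1:
        did2a = _step2a(w)
        if did2a:
            did_verb = True
        else:
            did_verb = _step2b(w)
    if ok1 or did_verb:
        if w.ends("Y"):
            w.replace(1, "i")
        elif w.ends("ç"):
            w.replace(1, "c")
    else:
        _step4(w)
    _step5(w)
    _step6(w)
    return w.s.translate(str.maketrans("IUY", "iuy"))
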