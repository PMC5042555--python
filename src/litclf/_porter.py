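"""Porter stemmer (1980 suffix-stripping algorithm, revised rules).

This is the classic five-step measure-based stemmer, implemented with the
author's later revisions to the published rule table:

* step 2 uses ``(m>0) bli -> ble`` in place of the original
  ``(m>0) abli -> able``;
* step 2 gains a ``logi -> log`` rule.  The ``l`` is counted with the stem
  when the measure condition is evaluated, so short scientific stems behave
  uniformly: ``biology``/``geology`` stem to ``biolog``/``geolog`` just as
  ``archaeology`` stems to ``archaeolog``.

Words of length <= 2 are returned unchanged, as in the reference
implementation.  Input is expected to be lowercase; tokens containing
digits are best left unstemmed by the caller.
"""

from __future__ import annotations

__all__ = ["porter_stem"]

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        # y is a consonant at the start of a word or after a vowel
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions (the m of [C](VC)^m[V])."""
    m = 0
    prev_cons = True
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if cons and not prev_cons:
            m += 1
        prev_cons = cons
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _apply_rules(word: str, rules: list[tuple[str, str, int]]) -> str:
    """First matching suffix wins; replace when m(stem) > threshold."""
    for suffix, repl, min_m in rules:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > min_m:
                return stem + repl
            return word
    return word


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            return word[:-1]
        return word
    stripped = None
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        stripped = word[:-2]
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        stripped = word[:-3]
    if stripped is None:
        return word
    if stripped.endswith(("at", "bl", "iz")):
        return stripped + "e"
    if _ends_double_consonant(stripped) and not stripped.endswith(("l", "s", "z")):
        return stripped[:-1]
    if _measure(stripped) == 1 and _ends_cvc(stripped):
        return stripped + "e"
    return stripped


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


_STEP2_RULES = [
    ("ational", "ate", 0),
    ("tional", "tion", 0),
    ("enci", "ence", 0),
    ("anci", "ance", 0),
    ("izer", "ize", 0),
    ("bli", "ble", 0),
    ("alli", "al", 0),
    ("entli", "ent", 0),
    ("eli", "e", 0),
    ("ousli", "ous", 0),
    ("ization", "ize", 0),
    ("ation", "ate", 0),
    ("ator", "ate", 0),
    ("alism", "al", 0),
    ("iveness", "ive", 0),
    ("fulness", "ful", 0),
    ("ousness", "ous", 0),
    ("aliti", "al", 0),
    ("iviti", "ive", 0),
    ("biliti", "ble", 0),
]


def _step2(word: str) -> str:
    if word.endswith("logi"):
        # the l belongs to the stem for the measure test (see module doc)
        if _measure(word[:-3]) > 0:
            return word[:-1]
        return word
    return _apply_rules(word, _STEP2_RULES)


_STEP3_RULES = [
    ("icate", "ic", 0),
    ("ative", "", 0),
    ("alize", "al", 0),
    ("iciti", "ic", 0),
    ("ical", "ic", 0),
    ("ful", "", 0),
    ("ness", "", 0),
]


def _step3(word: str) -> str:
    return _apply_rules(word, _STEP3_RULES)


_STEP4_SUFFIXES = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _step4(word: str) -> str:
    for suffix in _STEP4_SUFFIXES:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if suffix == "ion" and not stem.endswith(("s", "t")):
                return word
            if _measure(stem) > 1:
                return stem
            return word
    return word


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return word


def _step5b(word: str) -> str:
    if _measure(word) > 1 and _ends_double_consonant(word) and word.endswith("l"):
        return word[:-1]
    return word


def porter_stem(word: str) -> str:
    """Return the Porter stem of a lowercase word."""
    if len(word) <= 2:
        return word
    for step in (_step1a, _step1b, _step1c, _step2, _step3, _step4, _step5a, _step5b):
        word = step(word)
    return word
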