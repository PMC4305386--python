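"""English Snowball ("Porter2") stemmer.

Reduces an English word to its root form so that inflectional variants
("creature", "creatures") collapse onto one dictionary key ("creatur").
Implements the standard Snowball English algorithm: the R1/R2 regions,
the y/Y consonant marking, steps 0-5 and the exceptional word lists.
Input is expected lowercase; output is lowercase.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDINGS = frozenset("cdeghkmnrt")

# Full-word exceptional forms applied before the numbered steps.
_EXCEPTIONS = {
    "skis": "ski", "skies": "sky",
    "dying": "die", "lying": "lie", "tying": "tie",
    "idly": "idl", "gently": "gentl", "ugly": "ugli",
    "early": "earli", "only": "onli", "singly": "singl",
    "sky": "sky", "news": "news", "howe": "howe",
    "atlas": "atlas", "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}

# Words left untouched after step 1a.
_EXCEPTIONS_POST_1A = frozenset(
    ("inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed")
)

_STEP2_RULES = [
    # (suffix, replacement) — longest match wins; applied only inside R1.
    ("ization", "ize"), ("ational", "ate"), ("fulness", "ful"),
    ("ousness", "ous"), ("iveness", "ive"), ("tional", "tion"),
    ("biliti", "ble"), ("lessli", "less"), ("entli", "ent"),
    ("ation", "ate"), ("alism", "al"), ("aliti", "al"),
    ("ousli", "ous"), ("iviti", "ive"), ("fulli", "ful"),
    ("enci", "ence"), ("anci", "ance"), ("abli", "able"),
    ("izer", "ize"), ("ator", "ate"), ("alli", "al"),
    ("bli", "ble"), ("ogi", "og"), ("li", ""),
]

_STEP3_RULES = [
    ("ational", "ate"), ("tional", "tion"), ("alize", "al"),
    ("icate", "ic"), ("iciti", "ic"), ("ative", ""),
    ("ical", "ic"), ("ness", ""), ("ful", ""),
]

_STEP4_SUFFIXES = [
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize", "ion",
    "al", "er", "ic",
]


def _is_vowel(word: str, i: int) -> bool:
    return word[i] in _VOWELS  # 'Y' marks a consonant, lowercase y a vowel


def _regions(word: str) -> tuple[int, int]:
    """Start offsets of R1 and R2.

    R1 is the region after the first non-vowel that follows a vowel; R2 is
    the same construction applied within R1. Words beginning gener-,
    commun- or arsen- take R1 right after that prefix.
    """
    r1 = len(word)
    for prefix in ("gener", "commun", "arsen"):
        if word.startswith(prefix):
            r1 = len(prefix)
            break
    else:
        for i in range(1, len(word)):
            if not _is_vowel(word, i) and _is_vowel(word, i - 1):
                r1 = i + 1
                break
    r2 = len(word)
    for i in range(r1 + 1, len(word)):
        if not _is_vowel(word, i) and _is_vowel(word, i - 1):
            r2 = i + 1
            break
    return r1, r2


def _ends_short_syllable(word: str) -> bool:
    """True if the word ends in a short syllable.

    Either a vowel at position 0 followed by a non-vowel, or
    non-vowel + vowel + non-vowel(≠ w, x, Y) at the end.
    """
    if len(word) == 2:
        return _is_vowel(word, 0) and not _is_vowel(word, 1)
    if len(word) >= 3:
        a, b, c = word[-3], word[-2], word[-1]
        return (b in _VOWELS and c not in _VOWELS and c not in "wxY"
                and a not in _VOWELS)
    return False


def _contains_vowel(segment: str) -> bool:
    return any(ch in _VOWELS for ch in segment)


def stem(word: str) -> str:
    """Return the Snowball English stem of a lowercase word."""
    if word.startswith("'"):
        word = word[1:]
    if len(word) <= 2:
        return word
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]

    # Mark y's that function as consonants.
    if word[0] == "y":
        word = "Y" + word[1:]
    chars = list(word)
    for i in range(1, len(chars)):
        if chars[i] == "y" and chars[i - 1] in _VOWELS:
            chars[i] = "Y"
    word = "".join(chars)

    r1, r2 = _regions(word)

    # Step 0: possessive endings.
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # Step 1a: plural endings.
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-3] + ("i" if len(word) > 4 else "ie")
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if _contains_vowel(word[:-2]):
            word = word[:-1]

    if word in _EXCEPTIONS_POST_1A:
        return word.replace("Y", "y")

    # Step 1b: -ed / -ing endings.
    step1b_suffix = None
    for suf in ("eedly", "ingly", "edly", "ing", "eed", "ed"):
        if word.endswith(suf):
            step1b_suffix = suf
            break
    if step1b_suffix in ("eed", "eedly"):
        if len(word) - len(step1b_suffix) >= r1:
            word = word[: -len(step1b_suffix)] + "ee"
    elif step1b_suffix is not None:
        stem_part = word[: -len(step1b_suffix)]
        if _contains_vowel(stem_part):
            word = stem_part
            if word.endswith(("at", "bl", "iz")):
                word += "e"
            elif word.endswith(_DOUBLES):
                word = word[:-1]
            elif r1 >= len(word) and _ends_short_syllable(word):
                word += "e"

    # Step 1c: final y/Y after a non-vowel (not the word's first letter).
    if (len(word) > 2 and word[-1] in "yY"
            and word[-2] not in _VOWELS):
        word = word[:-1] + "i"

    # Step 2 (in R1).
    for suf, repl in _STEP2_RULES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ogi":
                    if word.endswith("logi"):
                        word = word[:-1]
                elif suf == "li":
                    if word[-3] in _LI_ENDINGS:
                        word = word[:-2]
                else:
                    word = word[: -len(suf)] + repl
            break

    # Step 3 (in R1; -ative only in R2).
    for suf, repl in _STEP3_RULES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ative":
                    if len(word) - 5 >= r2:
                        word = word[:-5]
                else:
                    word = word[: -len(suf)] + repl
            break

    # Step 4 (in R2).
    for suf in _STEP4_SUFFIXES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # Step 5: final -e / -l.
    if word.endswith("e"):
        if len(word) - 1 >= r2 or (
            len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1])
        ):
            word = word[:-1]
    elif word.endswith("ll") and len(word) - 1 >= r2:
        word = word[:-1]

    return word.replace("Y", "y")
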