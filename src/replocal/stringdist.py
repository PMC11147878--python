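"""Orthographic and phonological edit distances for predicted RDMs.

Orthographic dissimilarity between two words is the plain Levenshtein
distance over letters (unit insertion/deletion/substitution costs, case
folded).  Phonological dissimilarity runs the same dynamic program over
phoneme sequences, but substitution between two phonemes of the same class
costs the fraction of mismatching phonetic features — place and manner of
articulation for consonants, height and backness for vowels — so that, e.g.,
/k/ -> /b/ (velar stop -> bilabial stop) costs 0.5 rather than 1.  Phonemes
of different classes (consonant vs vowel) substitute at full cost.

The phoneme feature table ships as a packaged ARPABET TSV and can be
overridden with any table holding the same columns.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_FEATURE_COLUMNS = ("phoneme", "class", "place", "manner", "voicing", "height", "backness")

_CONSONANT_FEATURES = ("place", "manner")
_VOWEL_FEATURES = ("height", "backness")


class UnknownPhonemeError(KeyError):
    """A transcription symbol is absent from the feature table."""


def load_phoneme_features(path=None) -> pd.DataFrame:
    """Load a phoneme feature table, indexed by phoneme symbol.

    Without ``path`` the packaged ARPABET table is used.
    """
    if path is None:
        src = resources.files("replocal.data") / "phoneme_features.tsv"
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t", dtype=str)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if table["phoneme"].duplicated().any():
        raise ValueError("feature table has duplicate phoneme symbols")
    table = table.set_index("phoneme")
    for sym, row in table.iterrows():
        if row["class"] == "consonant":
            need = _CONSONANT_FEATURES
        elif row["class"] == "vowel":
            need = _VOWEL_FEATURES
        else:
            raise ValueError(f"phoneme {sym!r}: class must be consonant or vowel")
        for feat in need:
            if pd.isna(row[feat]) or row[feat] == "":
                raise ValueError(f"phoneme {sym!r} lacks required feature {feat!r}")
    return table


def parse_transcription(text: str) -> list[str]:
    """Split a whitespace-separated phoneme string into a symbol list."""
    return str(text).split()


def substitution_cost(p1: str, p2: str, features: pd.DataFrame,
                      include_voicing: bool = False) -> float:
    """Feature-mismatch substitution cost between two phonemes in [0, 1]."""
    if p1 == p2:
        return 0.0
    for sym in (p1, p2):
        if sym not in features.index:
            raise UnknownPhonemeError(f"unknown phoneme symbol {sym!r}")
    r1, r2 = features.loc[p1], features.loc[p2]
    if r1["class"] != r2["class"]:
        return 1.0
    feats = _CONSONANT_FEATURES if r1["class"] == "consonant" else _VOWEL_FEATURES
    if include_voicing:
        feats = feats + ("voicing",)
    mismatch = sum(r1[f] != r2[f] for f in feats)
    return mismatch / len(feats)


def weighted_edit_distance(seq1, seq2, sub_cost, indel_cost: float = 1.0) -> float:
    """Generic Wagner-Fischer dynamic program with a pluggable sub cost."""
    n, m = len(seq1), len(seq2)
    prev = np.arange(m + 1, dtype=float) * indel_cost
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = i * indel_cost
        a = seq1[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + indel_cost,
                cur[j - 1] + indel_cost,
                prev[j - 1] + sub_cost(a, seq2[j - 1]),
            )
        prev = cur
    return float(prev[m])


def orthographic_edit_distance(s1: str, s2: str) -> int:
    """Levenshtein distance between two words, case folded, unit costs."""
    a, b = str(s1).casefold(), str(s2).casefold()
    return int(weighted_edit_distance(a, b, lambda x, y: 0.0 if x == y else 1.0))


def phonological_edit_distance(t1, t2, features: pd.DataFrame = None,
                               include_voicing: bool = False,
                               unit_substitution: bool = False) -> float:
    """Feature-weighted edit distance between two phoneme sequences.

    Insertions and deletions cost 1; substitutions cost the phonetic feature
    mismatch fraction (see :func:`substitution_cost`).  With
    ``unit_substitution`` the cost collapses to plain Levenshtein over
    phoneme symbols.
    """
    if isinstance(t1, str):
        t1 = parse_transcription(t1)
    if isinstance(t2, str):
        t2 = parse_transcription(t2)
    if unit_substitution:
        return weighted_edit_distance(
            list(t1), list(t2), lambda x, y: 0.0 if x == y else 1.0
        )
    if features is None:
        features = load_phoneme_features()
    for sym in list(t1) + list(t2):
        if sym not in features.index:
            raise UnknownPhonemeError(f"unknown phoneme symbol {sym!r}")
    return weighted_edit_distance(
        list(t1), list(t2),
        lambda x, y: substitution_cost(x, y, features, include_voicing),
    )


def pairwise_distance_matrix(items, distance_fn, labels=None):
    """Symmetric zero-diagonal distance matrix over a sequence of items."""
    from .rdm import RDM  # local import to avoid a cycle

    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items for a distance matrix")
    n = len(items)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = distance_fn(items[i], items[j])
            except Exception as exc:
                raise RuntimeError(
                    f"distance failed for pair ({items[i]!r}, {items[j]!r}): {exc}"
                ) from exc
            D[i, j] = D[j, i] = d
    if labels is None:
        labels = [str(x) for x in items]
    return RDM(np.asarray(labels), D)
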