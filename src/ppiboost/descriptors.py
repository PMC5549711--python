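"""The five descriptor families and the 347/694-dimensional feature vectors.

Per protein, five descriptors are computed from the thirteen property
encodings:

* **frequency** (20 values): fraction of each amino acid in the sequence;
* **composition C** (3 per qualitative property): fraction of residues in
  each property group;
* **transition T** (3 per qualitative property): percent of adjacent residue
  pairs whose groups differ, split by unordered group pair (1,2), (1,3),
  (2,3);
* **distribution D** (15 per qualitative property): percent chain position of
  the first, 25%, 50%, 75% and 100% occurrence of each group;
* **auto-covariance AC** (30 lags per quantitative property): lag-indexed
  covariance of the standardized property profile with itself,

      AC(lag) = (1/(n-lag)) * sum_{i=1}^{n-lag} (v_i - vbar)(v_{i+lag} - vbar)

  with vbar the mean over all n positions.

Assembled in fixed order — frequency(20), then per qualitative property
[C(3), T(3), D(15)] (7 x 21 = 147), then per quantitative property AC lags
1..30 (6 x 30 = 180) — this yields the 347-value protein vector; a pair
vector is the 694-value concatenation of the two protein vectors in pair
order. Fractions (frequency, C) live in [0, 1]; percents (T, D) in [0, 100].
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    PropertyTableSet,
    builtin_property_tables,
    encode_qualitative,
    encode_quantitative,
    normalize_property_scale,
)
from .sequence_io import ALPHABET, InteractionPair, ProteinSequence

#: Default maximum auto-covariance lag; sequences must be longer than this.
DEFAULT_MAX_LAG = 30

#: Number of values in a single-protein feature vector at max_lag = 30.
PROTEIN_VECTOR_LENGTH = 347

#: Number of values in a pair vector (two concatenated protein vectors).
PAIR_VECTOR_LENGTH = 694

_TRANSITION_PAIRS = ((1, 2), (1, 3), (2, 3))
_DISTRIBUTION_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)
_FRACTION_TAGS = ("first", "p25", "p50", "p75", "p100")


class DescriptorError(ValueError):
    """Raised when a sequence is unsuitable for a descriptor (e.g. too short)."""


def frequency_descriptor(seq: ProteinSequence | str) -> np.ndarray:
    """Amino-acid frequencies in alphabet order ACDEFGHIKLMNPQRSTVWY; sums to 1."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    counts = np.zeros(20)
    index = {r: i for i, r in enumerate(ALPHABET)}
    for r in residues:
        counts[index[r]] += 1
    return counts / len(residues)


def composition(groups: np.ndarray) -> np.ndarray:
    """Fraction of positions in groups 1, 2, 3; entries sum to 1."""
    groups = np.asarray(groups)
    if groups.size == 0:
        raise DescriptorError("composition: empty group sequence")
    n = groups.size
    return np.array([(groups == k).sum() / n for k in (1, 2, 3)])


def transition(groups: np.ndarray) -> np.ndarray:
    """Percent of adjacent positions crossing between two groups.

    Returned for unordered group pairs (1,2), (1,3), (2,3) in that order,
    each as 100 * count / (n - 1).
    """
    groups = np.asarray(groups)
    n = groups.size
    if n < 2:
        raise DescriptorError(
            "transition: needs a sequence of length >= 2 "
            f"(got {n})"
        )
    a, b = groups[:-1], groups[1:]
    out = np.empty(3)
    for k, (g, h) in enumerate(_TRANSITION_PAIRS):
        out[k] = 100.0 * (((a == g) & (b == h)) | ((a == h) & (b == g))).sum() / (n - 1)
    return out


def distribution(groups: np.ndarray) -> np.ndarray:
    """Percent chain positions of the first/25%/50%/75%/100% group occurrences.

    For each group k = 1..3 with m occurrences, reports 100 * pos/n for the
    1-based sequence position of the ceil(q*m)-th occurrence, q in
    {first, 0.25, 0.5, 0.75, 1.0} (first = 1st occurrence, 100% = m-th);
    a group with no occurrences contributes five zeros. 15 values, groups
    concatenated in order.
    """
    groups = np.asarray(groups)
    n = groups.size
    if n == 0:
        raise DescriptorError("distribution: empty group sequence")
    out = np.zeros(15)
    for k in (1, 2, 3):
        positions = np.flatnonzero(groups == k) + 1  # 1-based
        m = positions.size
        if m == 0:
            continue
        for qi, q in enumerate(_DISTRIBUTION_FRACTIONS):
            occ = 1 if q == 0.0 else math.ceil(q * m)
            out[(k - 1) * 5 + qi] = 100.0 * positions[occ - 1] / n
    return out


def auto_covariance(
    values: np.ndarray, max_lag: int = DEFAULT_MAX_LAG
) -> np.ndarray:
    """Auto-covariance of a numeric profile at lags 1..max_lag.

    AC(lag) = (1/(n-lag)) * sum_i (v_i - vbar)(v_{i+lag} - vbar), vbar the
    mean over all n positions. Requires n > max_lag.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n <= max_lag:
        raise DescriptorError(
            f"auto_covariance: sequence length {n} must exceed max_lag "
            f"{max_lag} (minimum length {max_lag + 1})"
        )
    centered = v - v.mean()
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        out[lag - 1] = centered[: n - lag] @ centered[lag:] / (n - lag)
    return out


def feature_names(
    tables: PropertyTableSet | None = None, max_lag: int = DEFAULT_MAX_LAG
) -> list[str]:
    """Column names for the protein feature vector, in vector order.

    Naming scheme: ``f.<residue>``, ``c.<prop>.g<k>``, ``t.<prop>.g<i>g<j>``,
    ``d.<prop>.g<k>.<frac>``, ``ac.<prop>.lag<l>``.
    """
    tables = tables or builtin_property_tables()
    names = [f"f.{r}" for r in ALPHABET]
    for prop in tables.qualitative:
        names += [f"c.{prop.name}.g{k}" for k in (1, 2, 3)]
        names += [f"t.{prop.name}.g{i}g{j}" for i, j in _TRANSITION_PAIRS]
        names += [
            f"d.{prop.name}.g{k}.{tag}"
            for k in (1, 2, 3)
            for tag in _FRACTION_TAGS
        ]
    for prop in tables.quantitative:
        names += [f"ac.{prop.name}.lag{l}" for l in range(1, max_lag + 1)]
    return names


def protein_features(
    seq: ProteinSequence,
    tables: PropertyTableSet | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
) -> np.ndarray:
    """The full multi-scale descriptor vector of one protein (347 values).

    Requires sequence length > max_lag (i.e. >= 31 at the default).
    """
    tables = tables or builtin_property_tables()
    if len(seq) <= max_lag:
        raise DescriptorError(
            f"protein {seq.id!r}: length {len(seq)} too short for "
            f"auto-covariance at max_lag {max_lag} (minimum {max_lag + 1})"
        )
    blocks = [frequency_descriptor(seq)]
    for prop in tables.qualitative:
        g = encode_qualitative(seq, prop)
        blocks += [composition(g), transition(g), distribution(g)]
    for prop in tables.quantitative:
        scale = normalize_property_scale(prop)
        v = encode_quantitative(seq, scale)
        blocks.append(auto_covariance(v, max_lag))
    return np.concatenate(blocks)


def pair_features(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Concatenate two protein feature vectors into one pair vector (A then B)."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.shape != fb.shape or fa.ndim != 1:
        raise DescriptorError(
            f"pair_features: mismatched vector shapes {fa.shape} vs {fb.shape}"
        )
    return np.concatenate([fa, fb])


def feature_matrix(
    pairs: Sequence[InteractionPair],
    sequences: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
    tables: PropertyTableSet | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair-vector design matrix and label vector for a labelled pair set.

    Each protein's feature vector is computed once and reused across pairs.
    Returns (X of shape (n_pairs, 2 * protein_dim), y of 0/1 labels).
    """
    if not isinstance(sequences, Mapping):
        sequences = {s.id: s for s in sequences}
    tables = tables or builtin_property_tables()
    cache: dict[str, np.ndarray] = {}

    def features_of(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = protein_features(sequences[pid], tables, max_lag)
        return cache[pid]

    X = np.stack(
        [pair_features(features_of(p.id_a), features_of(p.id_b)) for p in pairs]
    )
    y = np.array([p.label for p in pairs], dtype=int)
    return X, y


def write_feature_csv(
    X: np.ndarray,
    path: str | Path,
    names: Iterable[str] | None = None,
    index: Iterable[str] | None = None,
) -> None:
    """Write a feature matrix as headered CSV (one row per protein or pair)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        if X.shape[1] == PROTEIN_VECTOR_LENGTH:
            names = feature_names()
        elif X.shape[1] == PAIR_VECTOR_LENGTH:
            base = feature_names()
            names = [f"a.{n}" for n in base] + [f"b.{n}" for n in base]
        else:
            names = [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=list(names))
    if index is not None:
        df.insert(0, "id", list(index))
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a headered feature CSV; returns (matrix, row ids or indices)."""
    df = pd.read_csv(path)
    if "id" in df.columns:
        ids = df["id"].astype(str).tolist()
        df = df.drop(columns=["id"])
    else:
        ids = [str(i) for i in range(len(df))]
    return df.to_numpy(dtype=float), ids
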