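"""Independent, deliberately naive reference implementations for the tests.

Each function is a literal loop-based transcription of the descriptor
definitions, kept free of numpy vectorization so it can serve as an oracle
for the optimized implementations.
"""

from __future__ import annotations

import math


def composition_oracle(groups: list[int]) -> list[float]:
    n = len(groups)
    return [sum(1 for g in groups if g == k) / n for k in (1, 2, 3)]


def transition_oracle(groups: list[int]) -> list[float]:
    n = len(groups)
    out = []
    for a, b in ((1, 2), (1, 3), (2, 3)):
        count = 0
        for i in range(n - 1):
            pair = {groups[i], groups[i + 1]}
            if pair == {a, b}:
                count += 1
        out.append(100.0 * count / (n - 1))
    return out


def distribution_oracle(groups: list[int]) -> list[float]:
    n = len(groups)
    out = []
    for k in (1, 2, 3):
        positions = [i + 1 for i, g in enumerate(groups) if g == k]
        m = len(positions)
        if m == 0:
            out.extend([0.0] * 5)
            continue
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            occ = 1 if q == 0.0 else math.ceil(q * m)
            out.append(100.0 * positions[occ - 1] / n)
    return out


def auto_covariance_oracle(values: list[float], max_lag: int) -> list[float]:
    n = len(values)
    mean = sum(values) / n
    out = []
    for lag in range(1, max_lag + 1):
        total = 0.0
        for i in range(n - lag):
            total += (values[i] - mean) * (values[i + lag] - mean)
        out.append(total / (n - lag))
    return out


def frequency_oracle(residues: str, alphabet: str) -> list[float]:
    return [residues.count(r) / len(residues) for r in alphabet]
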