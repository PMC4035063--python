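"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — direct enumeration and direct
definition-level arithmetic — so it shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_candidates(alleles: np.ndarray, f: float) -> set[tuple]:
    """All maximal (start, end, allele-string) candidates at frequency f.

    Enumerates every interval and every observed allele string, keeps those
    whose carrier count ``k`` satisfies ``k / H >= f``, and retains only the
    maximal ones: no one-SNP extension on either side admits a string with a
    carrier count still at or above the threshold.
    """
    H, M = alleles.shape
    c = max(1, math.ceil(f * H - 1e-9))
    out: set[tuple] = set()
    for i in range(M):
        for j in range(i, M):
            strings: dict[tuple, int] = {}
            for h in range(H):
                s = tuple(alleles[h, i : j + 1])
                strings[s] = strings.get(s, 0) + 1
            for s, k in strings.items():
                if k < c:
                    continue
                # right extension
                if j + 1 < M:
                    best = max(
                        sum(
                            1
                            for h in range(H)
                            if tuple(alleles[h, i : j + 2]) == s + (a,)
                        )
                        for a in (0, 1)
                    )
                    if best >= c:
                        continue
                # left extension
                if i - 1 >= 0:
                    best = max(
                        sum(
                            1
                            for h in range(H)
                            if tuple(alleles[h, i - 1 : j + 1]) == (a,) + s
                        )
                        for a in (0, 1)
                    )
                    if best >= c:
                        continue
                out.add((i, j, s, k))
    return out


def brute_force_score(
    span: float, n_snps: int, null_spans: list, null_counts: list
) -> float:
    """HaploPS-style score by direct counting against a pooled null."""
    n = len(null_spans)
    c1 = max(1, sum(1 for v in null_spans if v >= span))
    c2 = max(1, sum(1 for v in null_counts if v >= n_snps))
    return (c1 / n) * (c2 / n) * n


def naive_ehh(alleles: np.ndarray, focal: int, carriers: np.ndarray, x: int) -> float:
    """EHH at SNP x: fraction of carrier pairs identical over [focal, x]."""
    lo, hi = min(focal, x), max(focal, x)
    n = len(carriers)
    pairs = 0
    for a, b in itertools.combinations(carriers, 2):
        if np.array_equal(alleles[a, lo : hi + 1], alleles[b, lo : hi + 1]):
            pairs += 1
    return pairs / (n * (n - 1) / 2)


def textbook_fst(n1: int, p1: float, n2: int, p2: float) -> float:
    """Two-population variance-components Fst from allele counts (haploid).

    Written straight from the ANOVA definition: MSP/MSG mean squares with
    the n_c correction, independent of the package's vectorized form.
    """
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
    denom = msp + (nc - 1) * msg
    if denom == 0:
        return float("nan")
    return (msp - msg) / denom
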