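"""Compiled inner loops.

Two hot spots live here:

* :func:`enumerate_maximal_blocks` — the exhaustive search underlying the
  long-haplotype scan.  For every interval start it refines the partition of
  haplotypes by their allele string and records each block at the moment it
  can no longer be extended, together with the range of carrier-count
  thresholds for which it is maximal.
* :func:`ehh_fill` — extended haplotype homozygosity decay away from a focal
  SNP, by the same partition-refinement idea restricted to a carrier set.

Both are exact (integer partition arithmetic, no hashing collisions: block
ids are compacted each step so keys stay below ``2 * n_blocks``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["enumerate_maximal_blocks", "ehh_fill"]


@njit(cache=True)
def enumerate_maximal_blocks(alleles):  # pragma: no cover - exercised via haplops
    """Enumerate all maximal (interval, allele-string) haplotype blocks.

    Parameters
    ----------
    alleles : uint8 (H, M) matrix

    Returns
    -------
    int64 array of shape (n_candidates, 5) with columns
    ``start, end, size, climit, rep`` where ``size`` is the carrier count,
    ``rep`` a representative haplotype row, and the block is maximal exactly
    for integer carrier thresholds ``c`` with ``climit < c <= size``
    (``climit`` = largest carrier count achievable by any one-SNP extension).
    """
    H, M = alleles.shape
    cap = 2 * H * M + 16
    out = np.empty((cap, 5), np.int64)
    nout = 0

    ids = np.zeros(H, np.int64)
    newids = np.zeros(H, np.int64)
    size = np.zeros(2 * H + 2, np.int64)
    csize = np.zeros(2 * H + 2, np.int64)
    keymap = np.full(2 * (2 * H + 2), -1, np.int64)

    for i in range(M):
        # partition of haplotypes by allele at column i
        nb = 0
        a_id = np.full(2, -1, np.int64)
        for h in range(H):
            a = alleles[h, i]
            if a_id[a] < 0:
                a_id[a] = nb
                nb += 1
            ids[h] = a_id[a]
        for b in range(nb):
            size[b] = 0
        for h in range(H):
            size[ids[h]] += 1

        for j in range(i + 1, M):
            nb_new = 0
            for k in range(2 * nb):
                keymap[k] = -1
            for h in range(H):
                key = ids[h] * 2 + alleles[h, j]
                if keymap[key] < 0:
                    keymap[key] = nb_new
                    nb_new += 1
                newids[h] = keymap[key]
            for b in range(nb_new):
                csize[b] = 0
            for h in range(H):
                csize[newids[h]] += 1
            # blocks that split at column j die with end = j - 1
            for b in range(nb):
                c0 = keymap[2 * b]
                c1 = keymap[2 * b + 1]
                if c0 >= 0 and c1 >= 0:
                    maxchild = csize[c0]
                    if csize[c1] > maxchild:
                        maxchild = csize[c1]
                    # left extension: split members of b by allele at i-1
                    leftmax = 0
                    rep = -1
                    if i > 0:
                        l0 = 0
                        l1 = 0
                        for h in range(H):
                            if ids[h] == b:
                                if rep < 0:
                                    rep = h
                                if alleles[h, i - 1] == 0:
                                    l0 += 1
                                else:
                                    l1 += 1
                        leftmax = l0 if l0 > l1 else l1
                    else:
                        for h in range(H):
                            if ids[h] == b:
                                rep = h
                                break
                    climit = maxchild if maxchild > leftmax else leftmax
                    if size[b] > climit:
                        out[nout, 0] = i
                        out[nout, 1] = j - 1
                        out[nout, 2] = size[b]
                        out[nout, 3] = climit
                        out[nout, 4] = rep
                        nout += 1
            tmp = ids
            ids = newids
            newids = tmp
            nb = nb_new
            for b in range(nb):
                size[b] = csize[b]

        # blocks alive at the region end die there (no right extension)
        for b in range(nb):
            leftmax = 0
            rep = -1
            if i > 0:
                l0 = 0
                l1 = 0
                for h in range(H):
                    if ids[h] == b:
                        if rep < 0:
                            rep = h
                        if alleles[h, i - 1] == 0:
                            l0 += 1
                        else:
                            l1 += 1
                leftmax = l0 if l0 > l1 else l1
            else:
                for h in range(H):
                    if ids[h] == b:
                        rep = h
                        break
            if size[b] > leftmax:
                out[nout, 0] = i
                out[nout, 1] = M - 1
                out[nout, 2] = size[b]
                out[nout, 3] = leftmax
                out[nout, 4] = rep
                nout += 1

    return out[:nout].copy()


@njit(cache=True)
def ehh_fill(sub, focal):  # pragma: no cover - exercised via ehhstats
    """EHH of the carrier set ``sub`` (n, M) at every SNP, core at ``focal``.

    Identity is evaluated over the closed column interval between ``focal``
    and each SNP (the focal column included).  Returns a float64 (M,) array.
    """
    n, M = sub.shape
    out = np.zeros(M, np.float64)
    denom = n * (n - 1.0)
    ids = np.zeros(n, np.int64)
    newids = np.zeros(n, np.int64)
    cnt = np.zeros(n + 2, np.int64)
    keymap = np.full(2 * (2 * n + 2), -1, np.int64)

    for direction in range(2):
        nb = 1
        for h in range(n):
            ids[h] = 0
        j = focal
        while 0 <= j < M:
            nb_new = 0
            for k in range(2 * nb):
                keymap[k] = -1
            for h in range(n):
                key = ids[h] * 2 + sub[h, j]
                if keymap[key] < 0:
                    keymap[key] = nb_new
                    nb_new += 1
                newids[h] = keymap[key]
            for b in range(nb_new):
                cnt[b] = 0
            for h in range(n):
                cnt[newids[h]] += 1
            s = 0.0
            for b in range(nb_new):
                s += cnt[b] * (cnt[b] - 1.0)
            out[j] = s / denom
            tmp = ids
            ids = newids
            newids = tmp
            nb = nb_new
            if s == 0.0:
                # all singletons: EHH stays 0 further out
                j2 = j + 1 if direction == 0 else j - 1
                while 0 <= j2 < M:
                    out[j2] = 0.0
                    j2 = j2 + 1 if direction == 0 else j2 - 1
                break
            j = j + 1 if direction == 0 else j - 1

    return out
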