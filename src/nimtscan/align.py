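"""Alignment primitives.

Two distinct needs are served:

* edit-distance style divergence on arbitrary-length sequences — delegated
  to edlib (global "NW" task), with the alignment length recovered from
  the CIGAR string;
* per-column mapping between a short tRNA reference and a candidate,
  where the traceback tie-break matters for downstream classification —
  a small unit-cost dynamic program with an explicit preference order
  (substitution/match over deletion over insertion).
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def edit_distance(a: str, b: str) -> tuple[int, int]:
    """Global unit-cost edit distance and alignment length.

    Returns ``(distance, alignment_length)`` where the alignment length is
    the number of columns of an optimal global alignment (matches +
    mismatches + indels).
    """
    if not a or not b:
        raise ValueError("edit_distance requires non-empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    aln_len = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return res["editDistance"], aln_len


def global_align_columns(ref: str, cand: str) -> list[tuple[int | None, int | None]]:
    """Optimal unit-cost global alignment as a list of column pairs.

    Each element is ``(ref_index, cand_index)``; ``None`` marks a gap.
    Among co-optimal alignments, substitutions are preferred over indels,
    and deletions (gap in candidate) over insertions, so that equal-length
    inputs always align column-to-column.
    """
    n, m = len(ref), len(cand)
    if n == 0 or m == 0:
        raise ValueError("global_align_columns requires non-empty sequences")
    import numpy as np

    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        ri = ref[i - 1]
        row = D[i]
        prev = D[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (ri != cand[j - 1])
            dele = prev[j] + 1
            ins = row[j - 1] + 1
            row[j] = min(sub, dele, ins)
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (ref[i - 1] != cand[j - 1]):
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return cols
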