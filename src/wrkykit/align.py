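"""Global protein alignment: affine-gap pairwise alignment and progressive MSA.

Pairwise alignment is delegated to :class:`Bio.Align.PairwiseAligner`
(Needleman–Wunsch with affine gaps; a gap of length k costs
``open + (k-1) * extend``, end gaps included).  The progressive multiple
aligner computes pairwise identity distances, builds a UPGMA guide tree and
merges profiles with a Gotoh profile–profile dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0

_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
GAP = "-"


def load_substitution_matrix(name: str = "BLOSUM62"):
    """Load a named substitution matrix (BLOSUM62 by default)."""
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with score and fractional identity."""

    aligned_a: str
    aligned_b: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        """Matches divided by alignment columns; 0 for an empty alignment."""
        if not self.aligned_a:
            return 0.0
        matches = sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != GAP
        )
        return matches / self.n_columns


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        matrix if matrix is not None else load_substitution_matrix()
    )
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Empty input yields the defined degenerate result: the other sequence
    aligned against gaps, identity 0.
    """
    if not a or not b:
        gaps = GAP * (len(a) + len(b))
        if not a and not b:
            return PairwiseAlignment("", "", 0.0)
        cost = gap_open + (len(a) + len(b) - 1) * gap_extend
        return PairwiseAlignment(
            a if a else GAP * len(b), b if b else GAP * len(a), -cost
        )
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return PairwiseAlignment(str(alignment[0]), str(alignment[1]), alignment.score)


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------


def _matrix_as_array(matrix) -> np.ndarray:
    """21x21 symbol-pair score array: 20 amino acids + gap (gap pairs score 0)."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    m = np.zeros((21, 21))
    for i, x in enumerate(aas):
        for j, y in enumerate(aas):
            m[i, j] = matrix[x, y]
    return m


_AA_INDEX = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
_AA_INDEX[GAP] = 20


def _profile_freq(rows: Sequence[str]) -> np.ndarray:
    """Per-column symbol frequencies of an aligned block (columns x 21)."""
    ncol = len(rows[0])
    freq = np.zeros((ncol, 21))
    for row in rows:
        for j, ch in enumerate(row):
            freq[j, _AA_INDEX.get(ch, _AA_INDEX.get("A"))] += 1
    return freq / len(rows)


def _profile_align(
    rows_a: Sequence[str],
    rows_b: Sequence[str],
    marray: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Gotoh affine DP between two aligned blocks; returns gapped row sets."""
    fa = _profile_freq(rows_a)
    fb = _profile_freq(rows_b)
    S = fa @ marray @ fb.T  # column-pair substitution scores
    la, lb = S.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best, src = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, src = Y[i - 1, j - 1], 2
            M[i, j] = best + S[i - 1, j - 1]
            ptrM[i, j] = src
            xo = M[i - 1, j] - gap_open
            xe = X[i - 1, j] - gap_extend
            if xo >= xe:
                X[i, j], ptrX[i, j] = xo, 0
            else:
                X[i, j], ptrX[i, j] = xe, 1
            yo = M[i, j - 1] - gap_open
            ye = Y[i, j - 1] - gap_extend
            if yo >= ye:
                Y[i, j], ptrY[i, j] = yo, 0
            else:
                Y[i, j], ptrY[i, j] = ye, 2
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    cols: list[str] = []  # 'M', 'X', 'Y' per column, reversed
    while i > 0 or j > 0:
        if state == 0:
            cols.append("M")
            prev = ptrM[i, j]
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            cols.append("X")
            prev = ptrX[i, j]
            i -= 1
            state = 0 if prev == 0 else 1
        else:
            cols.append("Y")
            prev = ptrY[i, j]
            j -= 1
            state = 0 if prev == 0 else 2
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    cols.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for c in cols:
        if c in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if c in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def _upgma_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA agglomeration order over a condensed distance matrix.

    Returns merge pairs referring to cluster indices: leaves are 0..n-1,
    the i-th merge creates cluster n+i.
    """
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((i, j))
        members = active[i] + active[j]
        ni, nj = len(active[i]), len(active[j])
        del active[i], active[j]
        newd = {}
        for k in active:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            newd[k] = (d[a] * ni + d[b] * nj) / (ni + nj)
        d = {
            (a, b): v
            for (a, b), v in d.items()
            if a not in (i, j) and b not in (i, j)
        }
        for k, v in newd.items():
            d[(min(k, nxt), max(k, nxt))] = v
        active[nxt] = members
        nxt += 1
    return merges


def build_msa(
    sequences: Sequence[str],
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[str]:
    """Progressive multiple alignment; returns gapped rows in input order.

    Guide tree: UPGMA on pairwise identity distances (1 - fractional
    identity of the optimal global pairwise alignment).
    """
    if len(sequences) < 2:
        raise ValueError("build_msa requires at least 2 sequences")
    if matrix is None:
        matrix = load_substitution_matrix()
    n = len(sequences)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - align_pair(
                sequences[i], sequences[j], matrix, gap_open, gap_extend
            ).identity
    marray = _matrix_as_array(matrix)
    # cluster id -> (row strings, original indices)
    profiles: dict[int, tuple[list[str], list[int]]] = {
        i: ([sequences[i]], [i]) for i in range(n)
    }
    nxt = n
    for i, j in _upgma_order(dist):
        rows_a, idx_a = profiles.pop(i)
        rows_b, idx_b = profiles.pop(j)
        out_a, out_b = _profile_align(rows_a, rows_b, marray, gap_open, gap_extend)
        profiles[nxt] = (out_a + out_b, idx_a + idx_b)
        nxt += 1
    rows, idx = profiles.popitem()[1]
    ordered = [""] * n
    for row, k in zip(rows, idx):
        ordered[k] = row
    return ordered
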