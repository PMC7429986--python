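"""Pairwise global alignment, percent identity and progressive MSA.

This is the shared engine behind candidate validation (anchoring catalytic
positions onto annotated references) and phylogrouping (percent-identity
matrices, bootstrap column resampling).  The aligner is a three-state
affine-gap dynamic programme (Gotoh) over BLOSUM62 with deterministic
tie-breaking; a gap of length ``g`` costs ``open + (g-1)*extend``, and
transitions between the two gap states are permitted so the optimum equals
the best score over *all* alignment strings.

The ambiguity code ``X`` scores 0 against every residue (including
itself), so unknown positions neither reward nor punish an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}
NEG_INF = -1e30

GAP_IN_B = "gap_in_b"  # column consumes a residue of `a`, gap in `b`
GAP_IN_A = "gap_in_a"  # column consumes a residue of `b`, gap in `a`


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for global alignment.

    ``gap_open`` is the cost of the first gapped column in a run and
    ``gap_extend`` the cost of each further column, i.e. a run of length
    ``g`` costs ``gap_open + (g - 1) * gap_extend``.  Both are positive
    penalties (subtracted from the score).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


DEFAULT_PARAMS = AlignmentParams()


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a 21x21 substitution matrix over `ALPHABET`.

    Loaded from biopython's bundled tables; the X row/column is zeroed so
    unknown residues are scoring-neutral.
    """
    src = substitution_matrices.load(name)
    mat = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0.0
            else:
                mat[i, j] = src[a, b]
    if not np.allclose(mat, mat.T):
        raise ValueError(f"substitution matrix {name!r} is not symmetric")
    return mat


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences, with gaps as ``-``."""

    a_aligned: str
    b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned strings differ in length")

    @property
    def a(self) -> str:
        return self.a_aligned.replace("-", "")

    @property
    def b(self) -> str:
        return self.b_aligned.replace("-", "")

    @property
    def identity(self) -> float:
        return percent_identity(self)


def _fill_matrices(ai: np.ndarray, bi: np.ndarray, params: AlignmentParams):
    """Forward pass; returns the three (n+1)x(m+1) state matrices."""
    sub = load_matrix(params.matrix)
    go, ge = params.gap_open, params.gap_extend
    n, m = len(ai), len(bi)
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b)
    M[0, 0] = 0.0
    if m:
        Iy[0, 1:] = -(go + ge * np.arange(m))
    col_idx = np.arange(1, m + 1) if m else None
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + ge * (i - 1))
        if m == 0:
            continue
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub[ai[i - 1], bi] + prev_best[:-1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) - go, Ix[i - 1, 1:] - ge
        )
        # Iy[i, j] = max_{k<j} max(M[i,k], Ix[i,k]) - go - (j-1-k)*ge,
        # computed with a running max over c[k] = max(M,Ix)[i,k] + ge*k.
        c = np.maximum(M[i, :-1], Ix[i, :-1]) + ge * np.arange(m)
        Iy[i, 1:] = np.maximum.accumulate(c) - go - ge * (col_idx - 1)
    return M, Ix, Iy


def _traceback(a: str, b: str, M, Ix, Iy, params: AlignmentParams):
    """Backward pass with deterministic tie-breaking.

    On ties the diagonal (match/mismatch) state is preferred, then a gap
    in ``b``, then a gap in ``a``.
    """
    sub = load_matrix(params.matrix)
    go, ge = params.gap_open, params.gap_extend
    i, j = len(a), len(b)
    states = {"M": M, "Ix": Ix, "Iy": Iy}
    order = ("M", "Ix", "Iy")
    state = max(order, key=lambda s: (states[s][i, j], -order.index(s)))
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            score = M[i, j] - sub[_INDEX[a[i - 1]], _INDEX[b[j - 1]]]
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i, j = i - 1, j - 1
            for nxt, cost in (("M", 0.0), ("Ix", 0.0), ("Iy", 0.0)):
                if states[nxt][i, j] == score:
                    state = nxt
                    break
            else:  # pragma: no cover - would indicate a filler bug
                raise AssertionError("traceback failed in state M")
        elif state == "Ix":
            target = Ix[i, j]
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            for nxt, cost in (("M", go), ("Ix", ge), ("Iy", go)):
                if states[nxt][i, j] - cost == target:
                    state = nxt
                    break
            else:  # pragma: no cover
                raise AssertionError("traceback failed in state Ix")
        else:  # Iy
            target = Iy[i, j]
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            for nxt, cost in (("M", go), ("Iy", ge), ("Ix", go)):
                if states[nxt][i, j] - cost == target:
                    state = nxt
                    break
            else:  # pragma: no cover
                raise AssertionError("traceback failed in state Iy")
    return "".join(reversed(cols_a)), "".join(reversed(cols_b))


def global_align(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Returns the (deterministically tie-broken) optimal alignment under the
    affine-gap model described in the module docstring.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ai, bi = encode(a), encode(b)
    M, Ix, Iy = _fill_matrices(ai, bi, params)
    score = float(max(M[-1, -1], Ix[-1, -1], Iy[-1, -1]))
    a_aln, b_aln = _traceback(a, b, M, Ix, Iy, params)
    return PairwiseAlignment(a_aln, b_aln, score)


def align_score(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Optimal global alignment score only (skips the traceback)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    M, Ix, Iy = _fill_matrices(encode(a), encode(b), params)
    return float(max(M[-1, -1], Ix[-1, -1], Iy[-1, -1]))


def percent_identity_cols(a_aligned: str, b_aligned: str, gap_free: bool = False) -> float:
    """Percent identity of two aligned rows.

    Default denominator counts every column in which at least one row has
    a residue (the convention used for the clustering identity matrix);
    ``gap_free=True`` restricts it to columns where both rows have one.
    Columns that are gap in both rows (possible in an MSA context) are
    always ignored.
    """
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned rows differ in length")
    ident = denom = 0
    for x, y in zip(a_aligned, b_aligned):
        if x == "-" and y == "-":
            continue
        both = x != "-" and y != "-"
        if gap_free:
            if both:
                denom += 1
                ident += x == y
        else:
            denom += 1
            ident += both and x == y
    if denom == 0:
        raise ValueError("alignment has no residue-bearing columns")
    return 100.0 * ident / denom


def percent_identity(aln: PairwiseAlignment, gap_free: bool = False) -> float:
    """Percent identity of a pairwise alignment (see `percent_identity_cols`)."""
    return percent_identity_cols(aln.a_aligned, aln.b_aligned, gap_free=gap_free)


def map_positions(aln: PairwiseAlignment, positions: list[int]) -> dict[int, int | None]:
    """Map 1-based residue positions of sequence ``a`` onto sequence ``b``.

    Each requested reference index maps to the 1-based index of the ``b``
    residue in the same alignment column, or ``None`` when that column is
    a gap in ``b``.  Mapped (non-None) values are strictly increasing.
    """
    ref_len = len(aln.a)
    wanted = set()
    for p in positions:
        if not 1 <= p <= ref_len:
            raise IndexError(f"reference position {p} out of range 1..{ref_len}")
        wanted.add(p)
    out: dict[int, int | None] = {}
    ia = ib = 0
    for x, y in zip(aln.a_aligned, aln.b_aligned):
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if x != "-" and ia in wanted:
            out[ia] = ib if y != "-" else None
    return {p: out[p] for p in positions}


def _merge_into_msa(rows: list[str], center_aligned: str, new_center: str, new_row: str) -> list[str]:
    """Merge one center/new-sequence alignment into an existing MSA.

    ``rows`` is the current MSA (row 0 tracks the center, with all gaps
    accumulated so far); ``new_center``/``new_row`` is a fresh pairwise
    alignment of the *ungapped* center against the incoming sequence.
    Gaps, once introduced, are never removed ("once a gap, always a gap").
    """
    merged: list[list[str]] = [[] for _ in rows]
    merged_new: list[str] = []
    i = j = 0  # i -> master columns, j -> pairwise columns
    master = center_aligned
    while i < len(master) or j < len(new_center):
        master_res = i < len(master) and master[i] != "-"
        pair_res = j < len(new_center) and new_center[j] != "-"
        if i < len(master) and not master_res:
            # column where earlier merges gapped the center
            for k, row in enumerate(rows):
                merged[k].append(row[i])
            merged_new.append("-")
            i += 1
        elif j < len(new_center) and not pair_res:
            # new sequence inserts relative to the center
            for k in range(len(rows)):
                merged[k].append("-")
            merged_new.append(new_row[j])
            j += 1
        else:
            for k, row in enumerate(rows):
                merged[k].append(row[i])
            merged_new.append(new_row[j])
            i += 1
            j += 1
    out = ["".join(r) for r in merged]
    out.append("".join(merged_new))
    return out


def progressive_msa(seqs: list[str], params: AlignmentParams = DEFAULT_PARAMS) -> list[str]:
    """Center-star progressive multiple alignment.

    The center is the sequence maximising summed pairwise identity to all
    others (ties broken by input order); every other sequence is aligned
    to the center and merged.  Rows are returned in input order.  With two
    inputs the result equals `global_align`.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    if any(not s for s in seqs):
        raise ValueError("cannot align an empty sequence")
    n = len(seqs)
    pair: dict[tuple[int, int], PairwiseAlignment] = {}
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], params)
            pair[(i, j)] = aln
            pid = percent_identity(aln)
            total[i] += pid
            total[j] += pid
    center = int(np.argmax(total))
    order = [k for k in range(n) if k != center]
    rows = [seqs[center]]
    row_ids = [center]
    for k in order:
        i, j = (center, k) if center < k else (k, center)
        aln = pair[(i, j)]
        c_aln, k_aln = (aln.a_aligned, aln.b_aligned) if i == center else (aln.b_aligned, aln.a_aligned)
        rows = _merge_into_msa(rows, rows[0], c_aln, k_aln)
        row_ids.append(k)
    # restore input order
    ordered = [None] * n
    for row, k in zip(rows, row_ids):
        ordered[k] = row
    return ordered  # type: ignore[return-value]


def write_aligned_fasta(ids: list[str], rows: list[str], path) -> None:
    """Write an MSA as aligned FASTA."""
    with open(path, "w") as fh:
        for name, row in zip(ids, rows):
            fh.write(f">{name}\n{row}\n")
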