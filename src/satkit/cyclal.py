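"""Rotation- and strand-aware comparison of tandem-repeat units.

A tandem repeat unit is a circular object: the array ``...ABCABCABC...`` can
be read starting from any phase, so two units are "the same" if one is a
cyclic permutation (rotation) of the other, possibly on the opposite strand.
This module scores a pair of units by global alignment (match +1, mismatch 0,
gap -0.5, linear gaps) maximised over every rotation of the second unit and
over both orientations, normalised by the longer unit length so that
``score(a, a) == 1`` exactly.  It also builds the per-column majority
consensus of a set of units after rotating them into a common register.

The dynamic programme is vectorised with numpy and batched over all rotations
at once; the per-row gap recurrence is resolved with a running-maximum trick
so no inner Python loop over columns is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: linear gap penalty, subtracted per gap column
GAP = 0.5

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    """Reverse complement of an ACGT string."""
    return s.translate(_COMP)[::-1]


def rotate(s: str, r: int) -> str:
    """Cyclic rotation: ``rotate("AAACCC", 3) == "CCCAAA"``."""
    if not s:
        return s
    r %= len(s)
    return s[r:] + s[:r]


def _encode(s: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in s], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in repeat unit") from exc


@dataclass(frozen=True)
class CyclicAlignment:
    """Best normalised alignment of two repeat units over rotations/strands.

    Attributes
    ----------
    score : float
        Normalised similarity in [0, 1] (raw score / max(len a, len b)).
    rotation : int
        Rotation offset applied to the second sequence, in [0, len(b) - 1].
    orientation : str
        ``"forward"`` or ``"reverse"`` (second sequence reverse-complemented,
        or literally reversed when ``reverse_mode="literal"``).
    aligned_length : int
        Number of columns in the best global alignment.
    """

    score: float
    rotation: int
    orientation: str
    aligned_length: int


def _nw_scores_batch(a_codes: np.ndarray, b_mat: np.ndarray) -> np.ndarray:
    """Global-alignment raw scores of ``a`` vs each row of ``b_mat``.

    match +1, mismatch 0, gap -GAP.  The within-row dependency
    ``H[i, j] = max(..., H[i, j-1] - GAP)`` is a running maximum of
    ``candidate[j] + GAP*j``, so each row is one vectorised pass.
    """
    n_rows, lb = b_mat.shape
    la = a_codes.shape[0]
    jgap = GAP * np.arange(lb + 1)
    h = np.broadcast_to(-jgap, (n_rows, lb + 1)).copy()
    for i in range(1, la + 1):
        match = (b_mat == a_codes[i - 1]).astype(np.float64)
        diag = h[:, :-1] + match
        up = h[:, 1:] - GAP
        cand = np.maximum(diag, up)
        t = np.empty_like(h)
        t[:, 0] = -GAP * i
        t[:, 1:] = cand + jgap[1:]
        np.maximum.accumulate(t, axis=1, out=t)
        h = t - jgap
    return h[:, -1]


def _rotation_matrix(codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    idx = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    return codes[idx]


def _nw_traceback(a: str, b: str) -> tuple[float, int]:
    """Raw score and column count of one global alignment (diag-preferred)."""
    la, lb = len(a), len(b)
    ac, bc = _encode(a), _encode(b)
    jgap = GAP * np.arange(lb + 1)
    h = np.empty((la + 1, lb + 1))
    h[0] = -jgap
    for i in range(1, la + 1):
        match = (bc == ac[i - 1]).astype(np.float64)
        cand = np.maximum(h[i - 1, :-1] + match, h[i - 1, 1:] - GAP)
        t = np.empty(lb + 1)
        t[0] = -GAP * i
        t[1:] = cand + jgap[1:]
        np.maximum.accumulate(t, out=t)
        h[i] = t - jgap
    i, j, cols = la, lb, 0
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(h[i, j] - (h[i - 1, j - 1] + (1.0 if a[i - 1] == b[j - 1] else 0.0))) < eps:
            i, j = i - 1, j - 1
        elif i > 0 and abs(h[i, j] - (h[i - 1, j] - GAP)) < eps:
            i -= 1
        else:
            j -= 1
        cols += 1
    return float(h[la, lb]), cols


def cyclic_pairwise_score(a: str, b: str, *, reverse_mode: str = "complement") -> CyclicAlignment:
    """Best normalised global alignment of ``a`` against all rotations of ``b``.

    Both strands are considered: ``reverse_mode="complement"`` (default)
    compares against rotations of the reverse complement of ``b``, which is
    the biologically meaningful strand symmetry for double-stranded satellite
    DNA; ``"literal"`` uses the plain reversed string; ``"none"`` disables
    the reverse orientation.  Ties are broken forward-before-reverse, then by
    the smaller rotation offset.
    """
    if not a or not b:
        raise ValueError("repeat units must be non-empty")
    if reverse_mode not in ("complement", "literal", "none"):
        raise ValueError(f"unknown reverse_mode {reverse_mode!r}")
    ac = _encode(a)
    bc = _encode(b)
    norm = float(max(len(a), len(b)))

    candidates: list[tuple[str, str, np.ndarray]] = [("forward", b, bc)]
    if reverse_mode == "complement":
        br = revcomp(b)
        candidates.append(("reverse", br, _encode(br)))
    elif reverse_mode == "literal":
        br = b[::-1]
        candidates.append(("reverse", br, _encode(br)))

    best_score = -np.inf
    best: tuple[str, str, int] | None = None
    for orientation, b_str, codes in candidates:
        raw = _nw_scores_batch(ac, _rotation_matrix(codes))
        r = int(np.argmax(raw))  # argmax returns the first (smallest) offset
        if raw[r] > best_score + 1e-9:
            best_score = float(raw[r])
            best = (orientation, b_str, r)
    assert best is not None
    orientation, b_str, r = best
    _, cols = _nw_traceback(a, rotate(b_str, r))
    score = min(1.0, max(0.0, best_score / norm))
    return CyclicAlignment(score=score, rotation=r, orientation=orientation, aligned_length=cols)


def consensus_repeat(units: list[str], *, reverse_mode: str = "complement") -> str:
    """Per-column majority consensus of repeat units in a common register.

    Every unit after the first is rotated (and, if its best alignment is on
    the opposite strand, reverse-complemented first) into the register of the
    first unit using :func:`cyclic_pairwise_score`.  Units shorter or longer
    than the first are read cyclically, so the output always has the length
    of the first unit.  Column ties go to the alphabetically smallest base.
    """
    if not units:
        raise ValueError("consensus of zero units is undefined")
    first = units[0]
    _encode(first)  # validate
    width = len(first)
    registered = [first]
    for u in units[1:]:
        aln = cyclic_pairwise_score(first, u, reverse_mode=reverse_mode)
        v = u
        if aln.orientation == "reverse":
            v = revcomp(u) if reverse_mode == "complement" else u[::-1]
        registered.append(rotate(v, aln.rotation))
    out = []
    for j in range(width):
        counts = {b: 0 for b in _BASES}
        for v in registered:
            counts[v[j % len(v)]] += 1
        best = max(counts.values())
        out.append(next(b for b in _BASES if counts[b] == best))
    return "".join(out)


def score_matrix(seqs: list[str], *, reverse_mode: str = "complement") -> np.ndarray:
    """Symmetric matrix of pairwise cyclic alignment scores."""
    n = len(seqs)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = cyclic_pairwise_score(seqs[i], seqs[j], reverse_mode=reverse_mode).score
            m[i, j] = m[j, i] = s
    return m
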