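"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive (plain Python loops, no shared code
with the package internals) so the tests compare two independent routes to
the same answer.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def minimal_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i + p] for i in range(len(s) - p)):
            return p
    return len(s)


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """All N-free k-mers that are not repetitions of a shorter block."""
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        p = minimal_period(kmer)
        if "N" in kmer or (p < k and k % p == 0):
            continue
        out.setdefault(kmer, []).append(i + 1)
    return out


def perfect_tandem_arrays(seq: str, min_period: int = 10, max_period: int = 200,
                          min_copies: int = 4) -> list[tuple[int, int, int]]:
    """Maximal perfect tandem arrays as (start, end, period), 1-based.

    For each period p, scan the lag-p self-match profile for maximal exact
    runs; keep runs spanning >= min_copies copies whose leading unit has
    minimal period p (so harmonics of a shorter unit are not re-reported).
    """
    L = len(seq)
    found = []
    for p in range(min_period, min(max_period, L // 2) + 1):
        i = 0
        n = L - p
        while i < n:
            if seq[i] != seq[i + p] or seq[i] == "N":
                i += 1
                continue
            j = i
            while j + 1 < n and seq[j + 1] == seq[j + 1 + p] and seq[j + 1] != "N":
                j += 1
            run = j - i + 1
            total = run + p
            if total // p >= min_copies:
                q = minimal_period(seq[i:i + p])
                if not (q < p and p % q == 0):
                    found.append((i + 1, i + total, p))
            i = j + 1
    return sorted(found)


def nw_score(a: str, b: str, gap: float = 0.5) -> float:
    """Global alignment raw score: match +1, mismatch 0, linear gap -gap."""
    la, lb = len(a), len(b)
    prev = [-gap * j for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [-gap * i] + [0.0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            m = prev[j - 1] + (1.0 if ai == b[j - 1] else 0.0)
            cur[j] = max(m, prev[j] - gap, cur[j - 1] - gap)
        prev = cur
    return prev[lb]


def cyclic_best(a: str, b: str, reverse_mode: str = "complement",
                ) -> tuple[float, int, str]:
    """Exhaustive best normalised score over rotations and orientations."""
    norm = max(len(a), len(b))
    variants = [("forward", b)]
    if reverse_mode == "complement":
        variants.append(("reverse", revcomp(b)))
    elif reverse_mode == "literal":
        variants.append(("reverse", b[::-1]))
    best = None
    for orientation, s in variants:
        for r in range(len(s)):
            rot = s[r:] + s[:r]
            score = nw_score(a, rot) / norm
            key = (-score, 0 if orientation == "forward" else 1, r)
            if best is None or key < best[0]:
                best = (key, (max(0.0, min(1.0, score)), r, orientation))
    return best[1]
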