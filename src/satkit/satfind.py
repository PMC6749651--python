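"""Satellite (long tandem repeat) detection.

The detector follows a seed-and-extend strategy over one replicon:

1. every k-mer (decamer by default) with no internal repetition is indexed;
2. k-mers recurring at least ``min_copies`` times inside an 800-nt sliding
   region form seed clusters; clusters of different rotations of the same
   unit overlap and are merged;
3. the repeat period is estimated as the mode of seed spacings;
4. the array is delimited as the maximal genomic run that is self-similar at
   lag ``period`` (identity >= 0.7 per period-length window), bridging the
   short register-shift gap an internal indel creates;
5. the array is cut into repeat units at occurrences of a seed k-mer, the
   regularity rule (>= 60% of units share the modal length) is applied, and
   the surviving Ni modal-length units are scored column-wise.

A satellite is kept when it has at least four copies of a 10–200 nt unit
(the 260-nt ceiling reported for some runs is available via ``max_period``)
and passes the regularity rule.  There is no upper limit on total satellite
length.  All tie-breaks are deterministic so output is bit-reproducible, and
every step is mirror-symmetric so calling the reverse complement of a
replicon yields mirrored coordinates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .cyclal import consensus_repeat
from .seqio import SatelliteCall, SequenceRecord, make_sat_id

log = logging.getLogger(__name__)

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _CODE_TABLE[ord(_c)] = _i


@dataclass
class DetectionParams:
    """Tunable detection parameters.

    k: seed length (nt).  window: region size within which a seed must recur
    (nt).  min_copies: minimum seed occurrences and minimum repeat copies.
    min_period / max_period: allowed repeat unit lengths (nt).
    min_regular_frac: minimum fraction of units sharing the modal length.
    seed_merge_overlap: span-overlap fraction above which clusters of
    different seed k-mers are considered the same candidate array.
    extension_identity: per-period identity required to remain inside the
    array while delimiting it.  bridge_slack: extra nucleotides allowed when
    bridging the self-match gap around an internal indel.
    """

    k: int = 10
    window: int = 800
    min_copies: int = 4
    min_period: int = 10
    max_period: int = 200
    min_regular_frac: float = 0.6
    seed_merge_overlap: float = 0.5
    extension_identity: float = 0.7
    bridge_slack: int = 4

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.window <= self.k:
            raise ValueError("window must exceed k")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")
        if self.min_period < self.k:
            raise ValueError("min_period must be >= k")
        if self.max_period < self.min_period:
            raise ValueError("max_period must be >= min_period")
        if not 0 < self.min_regular_frac <= 1:
            raise ValueError("min_regular_frac must be in (0, 1]")
        if not 0 < self.seed_merge_overlap <= 1:
            raise ValueError("seed_merge_overlap must be in (0, 1]")


@dataclass
class SeedCluster:
    """A k-mer recurring with the required local density.

    positions are 1-based occurrence starts, strictly ascending; the span is
    [first, last + k - 1].
    """

    kmer: str
    positions: tuple[int, ...]

    @property
    def start(self) -> int:
        return self.positions[0]

    def end_for(self, k: int) -> int:
        return self.positions[-1] + k - 1


@dataclass
class RawArray:
    """A delimited, unit-segmented candidate array (pre-filtering)."""

    replicon_id: str
    start: int
    end: int
    period_estimate: int
    unit_boundaries: list[int]  # 1-based cut starts; first == start
    def unit_lengths(self) -> list[int]:
        cuts = self.unit_boundaries + [self.end + 1]
        return [cuts[i + 1] - cuts[i] for i in range(len(cuts) - 1)]

    def units(self, seq: str) -> list[str]:
        cuts = self.unit_boundaries + [self.end + 1]
        return [seq[cuts[i] - 1:cuts[i + 1] - 1] for i in range(len(cuts) - 1)]


def minimal_period(s: str) -> int:
    """Smallest p with s[i] == s[i+p] for all valid i (KMP border)."""
    n = len(s)
    fail = [0] * n
    j = 0
    for i in range(1, n):
        while j and s[i] != s[j]:
            j = fail[j - 1]
        if s[i] == s[j]:
            j += 1
        fail[i] = j
    return n - fail[-1] if n else 0


def seed_eligible(kmer: str, k: int) -> bool:
    """A seed k-mer must not be an exact repetition of a shorter block.

    ``AAAAAAAAAA`` (period 1) and ``ACACACACAC`` (period 2) cannot anchor a
    unique repeat phase; a k-mer whose minimal period merely fails to divide
    k (e.g. a rotation with a 1-nt border) is a perfectly good anchor.
    """
    p = minimal_period(kmer)
    return not (p < k and k % p == 0)


def _codes(seq: str) -> np.ndarray:
    arr = _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        pos = int(np.argmax(arr == 255)) + 1
        raise ValueError(f"illegal character at position {pos}")
    return arr


def enumerate_seed_kmers(record: SequenceRecord, params: DetectionParams) -> dict[str, list[int]]:
    """Index every N-free k-mer without internal repetition.

    Returns a mapping k-mer -> ascending list of 1-based start positions.
    Self-repetitive k-mers (see :func:`seed_eligible`) are excluded.
    """
    k = params.k
    seq = record.seq
    index: dict[str, list[int]] = {}
    period_ok: dict[str, bool] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        ok = period_ok.get(kmer)
        if ok is None:
            ok = "N" not in kmer and seed_eligible(kmer, k)
            period_ok[kmer] = ok
        if ok:
            index.setdefault(kmer, []).append(i + 1)
    return index


def _decode_kmer(value: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(value >> shift) & 3])
    return "".join(out)


def _frequent_seed_index(seq: str, params: DetectionParams) -> dict[str, np.ndarray]:
    """Fast path: positions of eligible k-mers with >= min_copies occurrences.

    Equivalent to filtering :func:`enumerate_seed_kmers` by occurrence count;
    uses a rolling 2-bit encoding and one argsort instead of a Python dict
    over every window, so whole genomes stay cheap.
    """
    k = params.k
    if 2 * k > 62:
        raise ValueError("seed length too large for packed encoding")
    codes = _codes(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return {}
    is_n = (codes == 4).astype(np.int32)
    ncum = np.concatenate([[0], np.cumsum(is_n)])
    has_n = (ncum[k:] - ncum[:-k]) > 0
    vals = np.zeros(n, dtype=np.int64)
    base = np.where(codes == 4, 0, codes).astype(np.int64)
    for j in range(k):
        vals = (vals << 2) | base[j:j + n]
    valid = ~has_n
    pos_all = np.nonzero(valid)[0]
    v = vals[valid]
    order = np.argsort(v, kind="stable")
    sv = v[order]
    if sv.size == 0:
        return {}
    bounds = np.concatenate([[0], np.nonzero(np.diff(sv))[0] + 1, [sv.size]])
    out: dict[str, np.ndarray] = {}
    for gi in range(len(bounds) - 1):
        lo, hi = bounds[gi], bounds[gi + 1]
        if hi - lo < params.min_copies:
            continue
        kmer = _decode_kmer(int(sv[lo]), k)
        if not seed_eligible(kmer, k):
            continue
        out[kmer] = np.sort(pos_all[order[lo:hi]]) + 1
    return out


def detect_seed_clusters(index: dict[str, "list[int] | np.ndarray"],
                         params: DetectionParams) -> list[SeedCluster]:
    """Windowed seed runs, merged across rotations of the same unit.

    For each k-mer, every maximal run of occurrences in which each
    ``min_copies`` consecutive occurrences span at most ``window`` nt becomes
    one cluster.  Clusters of different k-mers whose spans overlap by at
    least ``seed_merge_overlap`` of the shorter span (rotated phases of one
    repeat unit always co-occur) are merged, keeping the cluster with most
    occurrences (tie: lexicographically smallest k-mer).
    """
    m = params.min_copies
    span_limit = params.window - params.k
    clusters: list[SeedCluster] = []
    for kmer in sorted(index):
        pos = np.asarray(index[kmer], dtype=np.int64)
        if pos.size < m:
            continue
        good = pos[m - 1:] - pos[:-(m - 1)] <= span_limit
        i = 0
        while i < good.size:
            if not good[i]:
                i += 1
                continue
            j = i
            while j + 1 < good.size and good[j + 1]:
                j += 1
            clusters.append(SeedCluster(kmer, tuple(int(p) for p in pos[i:j + m])))
            i = j + 1
    clusters.sort(key=lambda c: (c.start, c.end_for(params.k), c.kmer))

    kept: list[SeedCluster] = []
    for c in clusters:
        c_start, c_end = c.start, c.end_for(params.k)
        merged = False
        for idx in range(len(kept) - 1, -1, -1):
            kc = kept[idx]
            k_start, k_end = kc.start, kc.end_for(params.k)
            ov = min(c_end, k_end) - max(c_start, k_start) + 1
            if ov <= 0:
                continue
            shorter = min(c_end - c_start + 1, k_end - k_start + 1)
            if ov / shorter >= params.seed_merge_overlap:
                better = _better_cluster(kc, c)
                kept[idx] = better
                merged = True
                break
        if not merged:
            kept.append(c)
    kept.sort(key=lambda c: (c.start, c.kmer))
    return kept


def _better_cluster(a: SeedCluster, b: SeedCluster) -> SeedCluster:
    if len(a.positions) != len(b.positions):
        return a if len(a.positions) > len(b.positions) else b
    return a if a.kmer <= b.kmer else b


def estimate_period(cluster: SeedCluster, params: DetectionParams) -> int | None:
    """Mode of successive seed spacings within [min_period, max_period].

    Ties go to the smaller spacing; ``None`` if no spacing is in range (the
    candidate is then dropped).
    """
    pos = np.asarray(cluster.positions)
    diffs = np.diff(pos)
    diffs = diffs[(diffs >= params.min_period) & (diffs <= params.max_period)]
    if diffs.size == 0:
        return None
    counts = Counter(int(d) for d in diffs)
    best = max(counts.values())
    return min(d for d, c in counts.items() if c == best)


def _self_match_runs(sub_codes: np.ndarray, p: int, thresh: float,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Lag-p self-match profile m and its period-smoothed 'good' profile."""
    m = (sub_codes[:-p] == sub_codes[p:]) & (sub_codes[:-p] != 4)
    if m.size < p:
        return m, np.zeros(0, dtype=bool)
    cs = np.concatenate([[0], np.cumsum(m)])
    wsum = cs[p:] - cs[:-p]
    good = wsum >= thresh * p - 1e-9
    return m, good


def _good_runs(good: np.ndarray) -> list[tuple[int, int]]:
    if good.size == 0:
        return []
    d = np.diff(good.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if good[0]:
        starts.insert(0, 0)
    if good[-1]:
        ends.append(good.size - 1)
    return list(zip(starts, ends))


def delimit_and_segment(record: SequenceRecord, cluster: SeedCluster,
                        period: int, params: DetectionParams) -> RawArray | None:
    """Delimit the array around a seed cluster and cut it into repeat units.

    The array is the maximal run around the cluster whose lag-``period``
    self-identity stays >= ``extension_identity`` per period-length window;
    runs separated by at most ``2*period + bridge_slack`` nt (the smoothed
    register-shift gap an internal 1-nt indel produces) are bridged.  The final interval
    is then cut at occurrences of a seed k-mer; the cutting phase is chosen
    to maximise the occurrence count so that flanks stay minimal.  Gaps of
    two or more periods (a seed destroyed by mutation) are split into
    near-equal sub-units.
    """
    seq = record.seq
    L = len(seq)
    p = period
    reach = max(8 * p, 1024)
    while True:
        lo = max(1, cluster.start - reach)
        hi = min(L, cluster.end_for(params.k) + reach)
        sub = seq[lo - 1:hi]
        sub_codes = _CODE_TABLE[np.frombuffer(sub.encode("ascii"), dtype=np.uint8)]
        if len(sub) <= 2 * p:
            return None
        m, good = _self_match_runs(sub_codes, p, params.extension_identity)
        runs = _good_runs(good)
        if not runs:
            return None
        anchors = [q - lo for q in cluster.positions if 0 <= q - lo < good.size]
        anchor_run = None
        for a, b in runs:
            if any(a <= x <= b for x in anchors):
                anchor_run = (a, b)
                break
        if anchor_run is None:
            return None
        ri = runs.index(anchor_run)
        first, last = ri, ri
        bridge = 2 * p + params.bridge_slack
        while first > 0 and runs[first][0] - runs[first - 1][1] - 1 <= bridge:
            first -= 1
        while last + 1 < len(runs) and runs[last + 1][0] - runs[last][1] - 1 <= bridge:
            last += 1
        s_loc = runs[first][0]
        e_loc = min(runs[last][1] + 2 * p - 1, len(sub) - 1)
        touches_left = s_loc == 0 and lo > 1
        touches_right = runs[last][1] >= good.size - 1 and hi < L
        if touches_left or touches_right:
            reach *= 2
            continue
        break

    # base-level trim: the smoothed run can admit a sub-period background
    # flank anchored on chance lag-p matches; require a clean run of w
    # consecutive matches before accepting a boundary (the rule reads only
    # the match profile, so it is exactly mirror-symmetric)
    w = min(6, p)
    while s_loc + w <= min(e_loc - p + 1, m.size) and not m[s_loc:s_loc + w].all():
        s_loc += 1
    while e_loc - p - w + 1 >= s_loc and not m[e_loc - p - w + 1:e_loc - p + 1].all():
        e_loc -= 1
    if e_loc - s_loc + 1 < params.min_copies * params.min_period:
        return None
    start = lo + s_loc
    end = lo + e_loc
    if end - start + 1 < params.min_copies * params.min_period:
        log.debug("candidate at %s rejected: degenerate extension (%d nt)",
                  cluster.start, end - start + 1)
        return None

    interval = seq[start - 1:end]
    cut_positions = _segment_cuts(interval, p, params)
    if cut_positions is None or len(cut_positions) < params.min_copies:
        return None

    boundaries = [start + c for c in cut_positions]
    return RawArray(record.id, start, end, p, boundaries)


def _segment_cuts(interval: str, p: int, params: DetectionParams) -> list[int] | None:
    """0-based unit cut offsets within the interval (first cut always 0)."""
    k = params.k
    T = len(interval)
    if T < k:
        return None
    best: tuple[int, int] | None = None  # (-count, phase)
    best_occ: list[int] | None = None
    for d in range(min(p, T - k + 1)):
        kmer = interval[d:d + k]
        if "N" in kmer or not seed_eligible(kmer, k):
            continue
        occ = []
        at = interval.find(kmer)
        while at != -1:
            if not occ or at - occ[-1] >= max(k, params.min_period - 2):
                occ.append(at)
            at = interval.find(kmer, at + 1)
        key = (-len(occ), d)
        if occ and (best is None or key < best):
            best, best_occ = key, occ
    if best_occ is None:
        # no usable cutting k-mer (highly repetitive interior): fixed grid
        best_occ = list(range(0, T - p + 1, p))
    occ = best_occ
    # flank before the first occurrence attaches to the first unit; the
    # first cut is always the array start
    segs = [0] + [o for o in occ if o > 0] + [T]
    cuts: list[int] = []
    for i in range(len(segs) - 1):
        a, b = segs[i], segs[i + 1]
        g = b - a
        nsplit = max(1, round(g / p))
        if i == 0 and occ[0] > 0:
            # leading flank: do not let it masquerade as extra copies
            nsplit = max(1, round((g - occ[0]) / p))
        for j in range(nsplit):
            cuts.append(a + (g * j) // nsplit)
    return sorted(set(cuts))


def regularity_filter(array: RawArray, params: DetectionParams,
                      ) -> tuple[bool, int, int]:
    """Apply the 60% identical-unit-length rule.

    Returns (accepted, Ni, modal_length); the modal unit length ties toward
    the smaller value.
    """
    lengths = array.unit_lengths()
    counts = Counter(lengths)
    best = max(counts.values())
    modal = min(l for l, c in counts.items() if c == best)
    ni = counts[modal]
    accepted = ni / len(lengths) >= params.min_regular_frac - 1e-9
    return accepted, ni, modal


def score_repeats(units: list[str]) -> float:
    """Identity score of equal-length repeat copies.

    The Ni units are stacked without gaps; each column contributes the
    frequency of its majority base; the score is the column mean.  1 iff all
    units are identical.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units to score")
    width = len(units[0])
    if any(len(u) != width for u in units):
        raise ValueError("units must have identical length")
    arr = np.array([_codes(u) for u in units])
    counts = (arr[:, :, None] == np.arange(4)[None, None, :]).sum(axis=0)
    return float(counts.max(axis=1).mean() / len(units))


def _call_from_array(record: SequenceRecord, ra: RawArray,
                     params: DetectionParams) -> SatelliteCall | None:
    """Regularity-filter and score one delimited array."""
    accepted, ni, modal = regularity_filter(ra, params)
    if not accepted:
        return None
    if not (params.min_period <= modal <= params.max_period):
        return None
    units = ra.units(record.seq)
    if len(units) < params.min_copies:
        return None
    modal_units = [u for u in units if len(u) == modal]
    if len(modal_units) < 2 or any("N" in u for u in modal_units):
        return None
    score = score_repeats(modal_units)
    consensus = consensus_repeat(modal_units)
    return SatelliteCall(
        sat_id=make_sat_id(record.id, ra.start, ra.end),
        replicon_id=record.id, start=ra.start, end=ra.end,
        period=modal, n_copies=len(units), ni=ni, score=score,
        consensus=consensus, sequence=record.seq[ra.start - 1:ra.end])


def find_satellites(record: SequenceRecord,
                    params: DetectionParams | None = None) -> list[SatelliteCall]:
    """Full detection on one replicon; calls sorted by start coordinate."""
    params = params or DetectionParams()
    index = _frequent_seed_index(record.seq, params)
    clusters = detect_seed_clusters(index, params)
    candidates: list[SatelliteCall] = []
    for cl in clusters:
        p = estimate_period(cl, params)
        if p is None:
            continue
        # one windowed seed run can cover several nearby arrays of the same
        # unit; delimit, then re-anchor on the positions left outside the
        # delimited interval until the cluster is exhausted
        positions = list(cl.positions)
        while len(positions) >= params.min_copies:
            sub = SeedCluster(cl.kmer, tuple(positions))
            ra = delimit_and_segment(record, sub, p, params)
            if ra is None:
                break
            remaining = [q for q in positions if q < ra.start - p or q > ra.end + p]
            call = _call_from_array(record, ra, params)
            if call is not None:
                candidates.append(call)
            if len(remaining) == len(positions):
                break
            positions = remaining

    # deduplicate overlapping candidates (harmonics / rotation leftovers):
    # keep larger copies*period, then larger score, then leftmost start
    candidates.sort(key=lambda c: (-(c.n_copies * c.period), -c.score, c.start, c.end))
    kept: list[SatelliteCall] = []
    for c in candidates:
        dup = False
        for a in kept:
            ov = min(c.end, a.end) - max(c.start, a.start) + 1
            if ov > 0 and ov / min(c.length, a.length) >= 0.5:
                dup = True
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda c: (c.start, c.end))
    return kept
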