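"""Grouping satellites into families of related repeat units.

Two satellites belong to the same family when their repeat consensuses align
above a similarity threshold (0.6 by default) under the rotation- and
strand-aware score of :mod:`satkit.cyclal`.  Clustering is progressive
average-linkage agglomeration over the fixed pairwise score matrix: the two
clusters with the highest mean inter-cluster score are merged repeatedly
until the best mean drops below the threshold.

Families are named ``Fam_a_b_c``: *a* is the rank by member count (1 =
largest), *b* the family repeat length in nt (modal member period), *c* the
member count.  Unique satellites appear at the end of the list as
single-member families.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cyclal import consensus_repeat, score_matrix
from .seqio import SatelliteCall

DEFAULT_THRESHOLD = 0.6


@dataclass
class Family:
    name: str
    order_a: int
    repeat_b: int
    members_c: int
    member_ids: list[str]
    family_consensus: str


def name_family(order_a: int, repeat_b: int, members_c: int) -> str:
    """Fam_a_b_c name from rank, repeat length and member count."""
    if order_a <= 0 or repeat_b <= 0 or members_c <= 0:
        raise ValueError("family name components must be positive integers")
    return f"Fam_{order_a}_{repeat_b}_{members_c}"


def family_repeat_length(members: list[SatelliteCall]) -> int:
    """Modal member period; ties go to the smallest length."""
    if not members:
        raise ValueError("a family needs at least one member")
    counts = Counter(c.period for c in members)
    best = max(counts.values())
    return min(p for p, n in counts.items() if n == best)


def _average_linkage(scores: np.ndarray, threshold: float,
                     allowed: np.ndarray | None = None) -> list[list[int]]:
    """Merge clusters while the best mean inter-cluster score >= threshold.

    Ties are broken toward the pair with the smallest first-member index,
    then the smallest second index, so clustering is deterministic.
    """
    n = scores.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if allowed is not None and not allowed[clusters[i][0], clusters[j][0]]:
                    continue
                mean = float(scores[np.ix_(clusters[i], clusters[j])].mean())
                key = (-mean, min(clusters[i][0], clusters[j][0]),
                       max(clusters[i][0], clusters[j][0]))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        if best_pair is None or -best_key[0] < threshold:
            break
        i, j = best_pair
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    return clusters


def cluster_families(calls: list[SatelliteCall],
                     threshold: float = DEFAULT_THRESHOLD,
                     *, per_replicon: bool = False) -> list[Family]:
    """Group satellite calls into named families.

    Every call must carry a repeat consensus.  With ``per_replicon=True``
    satellites from different replicons are never merged (families otherwise
    may span replicons and species).  Returns families sorted by descending
    member count, then ascending repeat length, then first member id, with
    ``order_a`` assigned 1..F in that order — singletons therefore come last.
    """
    if not calls:
        return []
    order = sorted(range(len(calls)), key=lambda i: (calls[i].replicon_id, calls[i].start,
                                                     calls[i].end, calls[i].sat_id))
    ordered = [calls[i] for i in order]
    scores = score_matrix([c.consensus for c in ordered])
    allowed = None
    if per_replicon:
        reps = [c.replicon_id for c in ordered]
        allowed = np.array([[a == b for b in reps] for a in reps])
    groups = _average_linkage(scores, threshold, allowed)

    prelim = []
    for g in groups:
        members = [ordered[i] for i in g]  # g ascending == coordinate order
        b = family_repeat_length(members)
        consensus = consensus_repeat([m.consensus for m in members])
        prelim.append((members, b, consensus))
    prelim.sort(key=lambda t: (-len(t[0]), t[1], t[0][0].sat_id))

    families = []
    for a, (members, b, consensus) in enumerate(prelim, start=1):
        c = len(members)
        families.append(Family(
            name=name_family(a, b, c), order_a=a, repeat_b=b, members_c=c,
            member_ids=[m.sat_id for m in members], family_consensus=consensus))
    return families


def write_family_list(families: list[Family], path: str | Path) -> None:
    """Summary TSV: one row per family (name, repeat length, members, consensus)."""
    with open(path, "w") as fh:
        fh.write("family_name\trepeat_length\tn_members\tconsensus\n")
        for f in families:
            fh.write(f"{f.name}\t{f.repeat_b}\t{f.members_c}\t{f.family_consensus}\n")


def write_family_members(families: list[Family], calls: list[SatelliteCall],
                         path: str | Path) -> None:
    """Per-family member file: each member's repeat under its family header."""
    by_id = {c.sat_id: c for c in calls}
    with open(path, "w") as fh:
        for f in families:
            for sid in f.member_ids:
                c = by_id[sid]
                fh.write(f">{f.name}|{sid}|{c.period}\n{c.consensus}\n")
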