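"""Per-genome satellite statistics.

Mirrors the per-replicon summary a satellite survey reports: genome size,
%CG, satellite count and density per Mb, the proportion of satellites with a
long repeat unit (> 30 nt, strict by default), the number of satellites
longer than 1.5 kb, and the fraction of repeat lengths that are multiples of
3 nt (a proxy for amino-acid repeats inside coding sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import SatelliteCall, SequenceRecord

#: repeat lengths strictly above this count as "long"
LONG_REPEAT_NT = 30
#: satellites strictly longer than this count as "long satellites"
LONG_SATELLITE_NT = 1500


@dataclass
class GenomeSummary:
    replicon_id: str
    size_mb: float
    pct_cg: float
    n_sats: int
    sats_per_mb: float
    pct_long_repeat: float
    n_over_1500: int
    pct_multiple_of_3: float

    def to_row(self) -> dict:
        """Rounded presentation row (2 dp sizes/densities, 1 dp percentages)."""
        return {
            "replicon_id": self.replicon_id,
            "size_mb": round(self.size_mb, 2),
            "pct_cg": round(self.pct_cg, 1),
            "n_sats": self.n_sats,
            "sats_per_mb": round(self.sats_per_mb, 2),
            "pct_long_repeat": round(self.pct_long_repeat, 1),
            "n_over_1500": self.n_over_1500,
            "pct_multiple_of_3": round(self.pct_multiple_of_3, 1),
        }


def _pct_cg(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return 100.0 * (seq.count("C") + seq.count("G")) / acgt


def genome_summary(record: SequenceRecord, calls: list[SatelliteCall],
                   *, long_repeat_inclusive: bool = False) -> GenomeSummary:
    """Summary statistics for one replicon and its satellite calls.

    ``long_repeat_inclusive=True`` counts repeats of exactly 30 nt as long
    (the survey literature is ambiguous on this boundary; strict is the
    default).
    """
    for c in calls:
        if c.replicon_id != record.id:
            raise ValueError(f"call {c.sat_id} is not on replicon {record.id}")
    size_mb = len(record.seq) / 1e6
    n = len(calls)
    floor = LONG_REPEAT_NT - 1 if long_repeat_inclusive else LONG_REPEAT_NT
    n_long = sum(1 for c in calls if c.period > floor)
    n_over = sum(1 for c in calls if c.length > LONG_SATELLITE_NT)
    n_mult3 = sum(1 for c in calls if c.period % 3 == 0)
    return GenomeSummary(
        replicon_id=record.id,
        size_mb=size_mb,
        pct_cg=_pct_cg(record.seq),
        n_sats=n,
        sats_per_mb=n / size_mb,
        pct_long_repeat=100.0 * n_long / n if n else 0.0,
        n_over_1500=n_over,
        pct_multiple_of_3=100.0 * n_mult3 / n if n else 0.0,
    )


def summary_table(records: list[SequenceRecord],
                  calls: list[SatelliteCall], **kwargs) -> pd.DataFrame:
    """One rounded summary row per replicon."""
    rows = []
    for rec in records:
        rows.append(genome_summary(
            rec, [c for c in calls if c.replicon_id == rec.id], **kwargs).to_row())
    return pd.DataFrame(rows)


def repeat_length_distribution(calls: list[SatelliteCall],
                               bin_width: int = 1) -> pd.DataFrame:
    """Histogram of repeat unit lengths.

    Bins are [lo, lo + width); the bin centre (lo for width 1, else the
    midpoint rounded down) is flagged when it is a multiple of 3 nt.  Counts
    sum to the number of calls.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not calls:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count", "center_multiple_of_3"])
    rows = {}
    for c in calls:
        lo = (c.period // bin_width) * bin_width
        rows[lo] = rows.get(lo, 0) + 1
    out = []
    for lo in sorted(rows):
        center = lo + (bin_width - 1) // 2
        out.append({"bin_lo": lo, "bin_hi": lo + bin_width, "count": rows[lo],
                    "center_multiple_of_3": center % 3 == 0})
    return pd.DataFrame(out)


def length_vs_period_table(calls: list[SatelliteCall]) -> pd.DataFrame:
    """One (period, satellite length) row per call, sorted by period."""
    rows = [{"sat_id": c.sat_id, "period": c.period, "length": c.length}
            for c in calls]
    df = pd.DataFrame(rows, columns=["sat_id", "period", "length"])
    return df.sort_values(["period", "sat_id"], kind="stable").reset_index(drop=True)
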