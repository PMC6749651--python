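"""Reading genomes and serialising satellite calls.

Genome input is plain FASTA (single replicons or multi-record files).
Satellite output comes in two interchangeable forms: a FASTA file whose
headers carry every call property pipe-separated, and a tab-separated
catalog with one row per satellite including its family assignment.
Coordinates are 1-based inclusive everywhere in serialised output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

_ALPHABET = set("ACGTN")

CATALOG_COLUMNS = [
    "sat_id", "replicon_id", "start", "end", "length", "period",
    "n_copies", "ni", "score", "family_name", "consensus",
]


@dataclass
class SequenceRecord:
    """One replicon: identifier, free-text description, uppercase sequence."""

    id: str
    description: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SatelliteCall:
    """One detected satellite (tandem array) on a replicon.

    ``start``/``end`` are 1-based inclusive.  ``period`` is the modal repeat
    unit length, ``n_copies`` the total number of units, ``ni`` the number of
    units with the modal length, and ``score`` the identity score over those
    ``ni`` units (1 means all identical).
    """

    sat_id: str
    replicon_id: str
    start: int
    end: int
    period: int
    n_copies: int
    ni: int
    score: float
    consensus: str
    sequence: str

    def validate(self, replicon_length: int | None = None,
                 min_copies: int = 4, min_regular_frac: float = 0.6,
                 max_period: int | None = None) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.sat_id}: bad coordinates {self.start}-{self.end}")
        if replicon_length is not None and self.end > replicon_length:
            raise ValueError(f"{self.sat_id}: end beyond replicon length")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(f"{self.sat_id}: sequence length != span")
        if self.n_copies < min_copies:
            raise ValueError(f"{self.sat_id}: fewer than {min_copies} copies")
        if self.period < 10 or (max_period is not None and self.period > max_period):
            raise ValueError(f"{self.sat_id}: period {self.period} out of range")
        if self.ni < math.ceil(min_regular_frac * self.n_copies):
            raise ValueError(f"{self.sat_id}: Ni {self.ni} below regularity floor")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"{self.sat_id}: score outside [0, 1]")
        if len(self.consensus) != self.period:
            raise ValueError(f"{self.sat_id}: consensus length != period")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def make_sat_id(replicon_id: str, start: int, end: int) -> str:
    return f"{replicon_id}:{start}-{end}"


def _normalize(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _ALPHABET
    if bad:
        for pos, c in enumerate(seq, start=1):
            if c not in _ALPHABET:
                raise ValueError(
                    f"record {rec_id!r}: illegal character {c!r} at position {pos}")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a genome FASTA; uppercase, U→T, reject non-ACGTN characters."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, desc, _normalize(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def _wrap(seq: str, width: int = 80) -> Iterable[str]:
    for i in range(0, len(seq), width):
        yield seq[i:i + width]


def write_satellite_fasta(calls: list[SatelliteCall], path: str | Path) -> None:
    """Write one FASTA entry per call; the header encodes all properties.

    Header fields, pipe-separated: sat_id, replicon_id, start-end, period,
    n_copies, ni, score (3 decimals), consensus.  ``read_satellite_fasta``
    inverts this exactly.
    """
    with open(path, "w") as fh:
        for c in calls:
            header = "|".join([
                c.sat_id, c.replicon_id, f"{c.start}-{c.end}", str(c.period),
                str(c.n_copies), str(c.ni), f"{c.score:.3f}", c.consensus,
            ])
            fh.write(f">{header}\n")
            for line in _wrap(c.sequence):
                fh.write(line + "\n")


def read_satellite_fasta(path: str | Path) -> list[SatelliteCall]:
    calls = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 8:
            raise ValueError(f"malformed satellite header: {rec.description!r}")
        sat_id, replicon_id, span, period, n_copies, ni, score, consensus = fields
        start_s, end_s = span.split("-")
        calls.append(SatelliteCall(
            sat_id=sat_id, replicon_id=replicon_id,
            start=int(start_s), end=int(end_s), period=int(period),
            n_copies=int(n_copies), ni=int(ni), score=float(score),
            consensus=consensus, sequence=str(rec.seq)))
    return calls


def _family_map(calls: list[SatelliteCall], families: Iterable) -> dict[str, str]:
    """Map sat_id -> family name, insisting on exactly one family per call."""
    if isinstance(families, Mapping):
        mapping = dict(families)
    else:
        mapping = {}
        for fam in families:
            for sid in fam.member_ids:
                if sid in mapping:
                    raise ValueError(f"satellite {sid} assigned to two families")
                mapping[sid] = fam.name
    for c in calls:
        if c.sat_id not in mapping:
            raise ValueError(f"satellite {c.sat_id} has no family assignment")
    return mapping


def write_catalog(calls: list[SatelliteCall], families: Iterable,
                  path: str | Path) -> pd.DataFrame:
    """Write the tabular satellite catalog (TSV), sorted by coordinate.

    ``families`` is either a mapping sat_id -> family name or an iterable of
    objects with ``name`` and ``member_ids`` attributes; every call must be
    assigned to exactly one family (singletons included).
    """
    mapping = _family_map(calls, families)
    rows = [{
        "sat_id": c.sat_id, "replicon_id": c.replicon_id,
        "start": c.start, "end": c.end, "length": c.length,
        "period": c.period, "n_copies": c.n_copies, "ni": c.ni,
        "score": c.score, "family_name": mapping[c.sat_id],
        "consensus": c.consensus,
    } for c in calls]
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    df = df.sort_values(["replicon_id", "start"], kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sat_id": str, "replicon_id": str,
                                              "family_name": str, "consensus": str})


def calls_from_catalog(df: pd.DataFrame) -> list[SatelliteCall]:
    """Rebuild calls from a catalog table (sequence unavailable → consensus tiling)."""
    calls = []
    for row in df.itertuples(index=False):
        length = int(row.end) - int(row.start) + 1
        seq = (row.consensus * (length // len(row.consensus) + 1))[:length]
        calls.append(SatelliteCall(
            sat_id=row.sat_id, replicon_id=row.replicon_id,
            start=int(row.start), end=int(row.end), period=int(row.period),
            n_copies=int(row.n_copies), ni=int(row.ni), score=float(row.score),
            consensus=row.consensus, sequence=seq))
    return calls
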