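"""Synthetic genomes with planted satellite arrays and a call evaluator.

The generator emulates what the detector is asked to find in real replicons:
i.i.d. background sequence of configurable GC content with tandem arrays of
known unit, copy number and divergence inserted at known positions,
including multi-locus "families" of arrays planted from one unit.  Planting
inserts (never overwrites), so background composition is undisturbed and
earlier truth records are shifted right of each insertion point.  All
randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .satfind import minimal_period
from .seqio import SatelliteCall, SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """One array to plant: unit, copies, divergence and insertion point."""

    unit: str
    copies: int
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    position: "int | str" = "random"
    family_label: str = ""

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("unit must be non-empty")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not (0 <= self.sub_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground-truth coordinates of a planted array in the emitted genome."""

    replicon_id: str
    start: int
    end: int
    unit: str
    copies: int
    family_label: str = ""


@dataclass
class EvalMetrics:
    recall: float
    precision: float
    precision_defined: bool
    mean_period_error: float
    n_truth: int
    n_calls: int
    n_matched: int
    family_recovery: float | None = None


def random_genome(length: int, gc: float, seed: int,
                  replicon_id: str = "sim") -> SequenceRecord:
    """I.i.d. background sequence with P(C)=P(G)=gc/2; seed-deterministic."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=probs))
    return SequenceRecord(replicon_id, "synthetic background", seq)


def _mutate_copy(unit: str, sub_rate: float, indel_rate: float,
                 rng: np.random.Generator) -> str:
    chars = list(unit)
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for i in hits:
            alternatives = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alternatives[rng.integers(3)]
    if indel_rate > 0 and rng.random() < indel_rate:
        if rng.random() < 0.5 or len(chars) == 1:
            at = int(rng.integers(len(chars) + 1))
            chars.insert(at, "ACGT"[rng.integers(4)])
        else:
            del chars[int(rng.integers(len(chars)))]
    return "".join(chars)


def plant_satellite_array(record: SequenceRecord, spec: PlantSpec, seed: int,
                          truths: list[TruthRecord] | None = None,
                          ) -> tuple[SequenceRecord, TruthRecord]:
    """Insert one mutated tandem array; shift earlier truth records.

    The array block (copies of ``unit``, each independently mutated at the
    given rates) is inserted before 1-based ``position`` — drawn uniformly
    when ``position="random"`` — and the genome grows by the block length.
    Truth records in ``truths`` lying at or right of the insertion point are
    shifted in place.
    """
    rng = np.random.default_rng(seed)
    if minimal_period(spec.unit) < 10:
        import warnings
        warnings.warn("unit minimal period < 10: array will be seed-ineligible",
                      stacklevel=2)
    block = "".join(_mutate_copy(spec.unit, spec.sub_rate, spec.indel_rate, rng)
                    for _ in range(spec.copies))
    L = len(record.seq)
    if spec.position == "random":
        pos = int(rng.integers(1, L + 2))
    else:
        pos = int(spec.position)
        if not 1 <= pos <= L + 1:
            raise ValueError(f"insertion point {pos} outside sequence")
    seq = record.seq[:pos - 1] + block + record.seq[pos - 1:]
    truth = TruthRecord(record.id, pos, pos + len(block) - 1,
                        spec.unit, spec.copies, spec.family_label)
    if truths is not None:
        for t in truths:
            if t.start >= pos:
                t.start += len(block)
                t.end += len(block)
    return replace(record, seq=seq), truth


def simulate_genome(length: int, gc: float, plants: list[PlantSpec], seed: int,
                    replicon_id: str = "sim",
                    avoid_existing: bool = True,
                    ) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Background plus a list of planted arrays, with consistent truth.

    With ``avoid_existing`` (default) random insertion points are redrawn
    until they fall outside previously planted arrays, so every truth
    interval remains one intact array.
    """
    rng = np.random.default_rng(seed)
    record = random_genome(length, gc, int(rng.integers(2 ** 31)), replicon_id)
    truths: list[TruthRecord] = []
    for spec in plants:
        if spec.position == "random" and avoid_existing:
            for _ in range(1000):
                pos = int(rng.integers(1, len(record.seq) + 2))
                if all(not (t.start - 1 <= pos <= t.end + 1) for t in truths):
                    break
            spec = replace(spec, position=pos)
        record, truth = plant_satellite_array(
            record, spec, int(rng.integers(2 ** 31)), truths)
        truths.append(truth)
    truths.sort(key=lambda t: t.start)
    return record, truths


def random_unit(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """A random unit whose minimal period equals its length (seed-eligible)."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    while True:
        u = "".join(rng.choice(_BASES, size=length, p=probs))
        if minimal_period(u) == length:
            return u


def study_genome(seed: int, *, length: int = 100_000, gc: float = 0.4,
                 n_arrays: int = 10, unit_range: tuple[int, int] = (10, 100),
                 copy_range: tuple[int, int] = (4, 20),
                 max_sub_rate: float = 0.02, max_indel_rate: float = 0.05,
                 ) -> tuple[SequenceRecord, list[TruthRecord]]:
    """One replicate of the standard parameter-recovery experiment.

    Defaults are the study conditions: a 100-kb GC-0.4 background with 10
    planted arrays, unit lengths 10–100 nt, 4–20 copies, per-base
    substitution rate up to 0.02 and per-copy 1-nt indel rate up to 0.05.
    """
    rng = np.random.default_rng(seed)
    plants = []
    for i in range(n_arrays):
        unit = random_unit(rng, int(rng.integers(unit_range[0], unit_range[1] + 1)))
        plants.append(PlantSpec(
            unit=unit,
            copies=int(rng.integers(copy_range[0], copy_range[1] + 1)),
            sub_rate=float(rng.uniform(0, max_sub_rate)),
            indel_rate=float(rng.uniform(0, max_indel_rate)),
            family_label=f"arr{i}"))
    return simulate_genome(length, gc, plants, int(rng.integers(2 ** 31)),
                           replicon_id=f"sim{seed}")


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def evaluate_calls(truth: list[TruthRecord], calls: list[SatelliteCall],
                   families=None) -> EvalMetrics:
    """Match calls to truth at reciprocal overlap >= 0.5 and score them.

    Greedy one-to-one matching by descending overlap.  Precision over an
    empty call set is reported as 1.0 with ``precision_defined=False``.
    When ``families`` (iterable with ``member_ids``) is given, the family
    recovery rate is the fraction of multi-locus truth labels whose matched
    calls all land in a single predicted family.
    """
    pairs = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if c.replicon_id != t.replicon_id:
                continue
            r = _reciprocal_overlap((t.start, t.end), (c.start, c.end))
            if r >= 0.5:
                pairs.append((r, ti, ci))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_t: dict[int, int] = {}
    matched_c: set[int] = set()
    for r, ti, ci in pairs:
        if ti in matched_t or ci in matched_c:
            continue
        matched_t[ti] = ci
        matched_c.add(ci)
    # calls that overlap a matched truth (e.g. a split array) still count as
    # true positives for precision
    tp_calls = set(matched_c)
    for ci, c in enumerate(calls):
        if ci in tp_calls:
            continue
        for t in truth:
            if c.replicon_id == t.replicon_id and \
                    _reciprocal_overlap((t.start, t.end), (c.start, c.end)) >= 0.5:
                tp_calls.add(ci)
                break
    recall = len(matched_t) / len(truth) if truth else 1.0
    if calls:
        precision, defined = len(tp_calls) / len(calls), True
    else:
        precision, defined = 1.0, False
    if matched_t:
        err = float(np.mean([abs(calls[ci].period - len(truth[ti].unit))
                             for ti, ci in matched_t.items()]))
    else:
        err = float("nan")
    fam_recovery = None
    if families is not None:
        fam_of = {}
        for f in families:
            for sid in f.member_ids:
                fam_of[sid] = f.name
        labels: dict[str, set[str]] = {}
        planted: dict[str, int] = {}
        for ti, t in enumerate(truth):
            if not t.family_label:
                continue
            planted[t.family_label] = planted.get(t.family_label, 0) + 1
            if ti in matched_t:
                labels.setdefault(t.family_label, set()).add(
                    fam_of.get(calls[matched_t[ti]].sat_id, "?"))
        multi = [lab for lab, n in planted.items() if n >= 2]
        if multi:
            ok = sum(1 for lab in multi if len(labels.get(lab, set())) == 1)
            fam_recovery = ok / len(multi)
    return EvalMetrics(recall=recall, precision=precision, precision_defined=defined,
                       mean_period_error=err, n_truth=len(truth), n_calls=len(calls),
                       n_matched=len(matched_t), family_recovery=fam_recovery)


def write_truth(truths: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon_id\tstart\tend\tunit\tcopies\tfamily_label\n")
        for t in truths:
            fh.write(f"{t.replicon_id}\t{t.start}\t{t.end}\t{t.unit}\t"
                     f"{t.copies}\t{t.family_label}\n")
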