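"""isomiR classification, filtering and per-locus profiling.

A mature miRNA locus accumulates sequence variants (isomiRs) from inexact
Dicer/Drosha processing and non-templated tailing.  Mapped unique
sequences are anchored to the mature window on their precursor and
annotated with a (possibly multi-label) class set:

- ``reference``  exact match to the database mature sequence
- ``trim5`` / ``trim3``  shortened at the 5'/3' end (positive offsets);
  templated extensions beyond the mature ends are recorded as *negative*
  trims, since they copy the precursor and are not additions
- ``subst``  internal base differences within the mature span
- ``add3``  a non-templated suffix past the mature 3' end

Three filters separate signal from noise: a raw-count frequency filter
(count > 3), a contribution cut-off (an isomiR must contribute more than
10% of its locus's variant reads), and a binomial Z-score filter that
removes substitution variants explainable by sequencing error.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_processing import DEFAULT_PAD, MiRNAReference

REFERENCE = "reference"
TRIM5 = "trim5"
TRIM3 = "trim3"
SUBST = "subst"
ADD3 = "add3"

#: precedence used when a multi-label variant is tallied once for summaries.
PRIMARY_PRECEDENCE = (SUBST, ADD3, TRIM5, TRIM3)
ALL_CLASSES = (REFERENCE, TRIM5, TRIM3, SUBST, ADD3)


class ClassificationError(ValueError):
    """Sequence cannot be anchored within the padded precursor window."""


@dataclasses.dataclass
class IsomiRRecord:
    """A unique sequence at a locus with its class annotation.

    ``contribution`` is the percentage of the locus's total *variant*
    (non-reference) reads for variant records, and of the locus's total
    reads for the reference record.  ``z`` is filled in by the Z filter
    (minimum over the record's substitution positions).
    """

    sequence: str
    locus: str
    count: int
    classes: dict
    contribution: float | None = None
    z: float | None = None

    @property
    def is_reference(self) -> bool:
        return REFERENCE in self.classes

    @property
    def primary_class(self) -> str:
        for cls in PRIMARY_PRECEDENCE:
            if cls in self.classes:
                return cls
        return REFERENCE


def classify_variant(
    sequence: str,
    locus: str,
    reference: MiRNAReference,
    pad: int = DEFAULT_PAD,
) -> dict:
    """Annotate a mapped sequence with its isomiR classes.

    The sequence is anchored at its best ungapped offset (fewest
    mismatches, ties broken toward the mature start) within the padded
    precursor window.  Returns a class dict, e.g. ``{"trim3": 2}``,
    ``{"add3": "AG"}``, ``{"subst": [(pos, ref, alt)]}`` (positions are
    mature-relative), or ``{"reference": True}``.
    """
    sequence = sequence.upper()
    pre_id, ms, me = reference.matures[locus]
    P = reference.precursors[pre_id]
    L = len(sequence)
    lo = max(0, ms - pad)
    hi = min(len(P), me + pad)
    if L > hi - lo or L == 0:
        raise ClassificationError(
            f"sequence of length {L} not alignable within window of locus {locus}"
        )
    best: tuple[int, int, int] | None = None  # (mism, |o-ms|, o)
    for o in range(lo, hi - L + 1):
        mism = sum(1 for j in range(L) if sequence[j] != P[o + j])
        key = (mism, abs(o - ms), o)
        if best is None or key < best:
            best = key
    assert best is not None
    n_mism, _, o = best
    end = o + L
    mism_pos = [o + j for j in range(L) if sequence[j] != P[o + j]]

    classes: dict = {}
    off5 = o - ms
    if off5 != 0:
        classes[TRIM5] = off5  # negative = templated 5' extension
    if end <= me:
        if me - end > 0:
            classes[TRIM3] = me - end
        subst_pos = mism_pos
    else:
        trailing = [p for p in mism_pos if p >= me]
        j0 = min(trailing) if trailing else None
        if j0 is None:
            classes[TRIM3] = -(end - me)  # templated 3' extension
            subst_pos = mism_pos
        else:
            if j0 > me:
                classes[TRIM3] = -(j0 - me)  # templated part of the tail
            classes[ADD3] = sequence[j0 - o :]
            subst_pos = [p for p in mism_pos if p < me]
    if subst_pos:
        classes[SUBST] = [
            (p - ms, P[p], sequence[p - o]) for p in subst_pos
        ]
    if not classes:
        classes = {REFERENCE: True}
    return classes


def build_isomir_records(
    assigned: Iterable[tuple[str, str]] | Mapping[tuple[str, str], int],
    reference: MiRNAReference,
    pad: int = DEFAULT_PAD,
) -> list[IsomiRRecord]:
    """Aggregate (sequence, locus) assignments into annotated records.

    Accepts either an iterable of per-read ``(sequence, locus)`` pairs or a
    precomputed ``{(sequence, locus): count}`` mapping.  Contributions are
    computed here, over each locus's variant total, and frozen on the
    records (see :func:`filter_isomirs`).
    """
    if isinstance(assigned, Mapping):
        counter = Counter(dict(assigned))
    else:
        counter = Counter(assigned)
    records = []
    for (seq, locus), cnt in sorted(counter.items()):
        if cnt < 0:
            raise ValueError("negative counts")
        classes = classify_variant(seq, locus, reference, pad=pad)
        records.append(IsomiRRecord(seq, locus, int(cnt), classes))
    locus_total: Counter = Counter()
    variant_total: Counter = Counter()
    for r in records:
        locus_total[r.locus] += r.count
        if not r.is_reference:
            variant_total[r.locus] += r.count
    for r in records:
        denom = locus_total[r.locus] if r.is_reference else variant_total[r.locus]
        r.contribution = 100.0 * r.count / denom if denom > 0 else 0.0
    return records


def _substitution_z(records: Sequence[IsomiRRecord], err_rate: float) -> None:
    """Fill in ``z`` for substitution records (binomial one-sided Z).

    z = (x - n p) / sqrt(n p (1-p)) with x the reads bearing that specific
    nucleotide change (position and alternative base, pooled over records
    that share it), n the locus total and p the global per-base error
    rate.  A genuine variant concentrates all its reads on one change and
    exceeds the error expectation; sequencing errors scatter over the
    three alternative bases, each at roughly a third of the error rate,
    and fall below it.  A record with several substitutions gets the
    minimum over its changes.
    """
    by_locus: dict[str, list[IsomiRRecord]] = {}
    for r in records:
        by_locus.setdefault(r.locus, []).append(r)
    for locus, recs in by_locus.items():
        n = sum(r.count for r in recs)
        change_counts: Counter = Counter()
        for r in recs:
            for change in r.classes.get(SUBST, []):
                change_counts[tuple(change)] += r.count
        for r in recs:
            if SUBST in r.classes and r.z is None:
                zs = []
                for change in r.classes[SUBST]:
                    x = change_counts[tuple(change)]
                    mu = n * err_rate
                    sd = math.sqrt(n * err_rate * (1.0 - err_rate))
                    zs.append((x - mu) / sd if sd > 0 else math.inf)
                r.z = min(zs)


def filter_isomirs(
    records: Sequence[IsomiRRecord],
    min_freq: int = 3,
    contribution_cutoff: float = 10.0,
    z_threshold: float = 1.96,
    err_rate: float | None = None,
) -> list[IsomiRRecord]:
    """Apply the frequency, contribution and Z-score filters.

    Retains records with ``count > min_freq`` (strict); variant records
    must additionally contribute more than ``contribution_cutoff`` percent
    of their locus's variant reads, and substitution records must have
    ``z > z_threshold``.  Contributions and Z statistics are the ones
    frozen on the records when first computed, which makes the filter
    idempotent and monotone in the cut-off.
    """
    if any(r.count < 0 for r in records):
        raise ValueError("negative counts")
    has_subst = any(SUBST in r.classes for r in records)
    if has_subst and any(r.z is None for r in records if SUBST in r.classes):
        if err_rate is None or err_rate <= 0:
            raise ValueError("err_rate > 0 required when substitution records present")
        _substitution_z(records, err_rate)
    kept = []
    for r in records:
        if r.count <= min_freq:
            continue
        if not r.is_reference:
            if r.contribution is None or r.contribution <= contribution_cutoff:
                continue
            if SUBST in r.classes and not (r.z is not None and r.z > z_threshold):
                continue
        kept.append(r)
    return kept


def summarize_locus(
    replicates: Sequence[Sequence[IsomiRRecord]],
    condition: str,
) -> pd.DataFrame:
    """Per-locus class percentages: mean and sd across replicates.

    Each read is tallied once under the primary-class precedence
    (subst > add3 > trim5 > trim3), percentages within a replicate summing
    to 100 over the five classes.  Loci empty in a replicate are omitted
    from that replicate (with a warning); sd is 0 for a single replicate.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    per_rep: dict[str, dict[str, list[float]]] = {}
    for rep in replicates:
        totals: Counter = Counter()
        by_class: dict[str, Counter] = {}
        for r in rep:
            totals[r.locus] += r.count
            by_class.setdefault(r.locus, Counter())[r.primary_class] += r.count
        for locus, total in totals.items():
            if total == 0:
                warnings.warn(f"locus {locus} empty in a replicate; omitted")
                continue
            slot = per_rep.setdefault(locus, {c: [] for c in ALL_CLASSES})
            for cls in ALL_CLASSES:
                slot[cls].append(100.0 * by_class[locus].get(cls, 0) / total)
    rows = []
    for locus in sorted(per_rep):
        for cls in ALL_CLASSES:
            vals = np.array(per_rep[locus][cls], dtype=float)
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "locus": locus,
                    "condition": condition,
                    "class": cls,
                    "mean_pct": float(vals.mean()),
                    "sd_pct": sd,
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(rows)


def compare_profiles(
    control: Sequence[IsomiRRecord],
    treated: Sequence[IsomiRRecord],
) -> tuple[dict[str, float], float]:
    """Pearson correlation of per-isomiR normalized counts between
    conditions, per shared locus and pooled.

    Counts are normalized to within-locus fractions (scale invariance);
    sequences absent from one condition contribute zero.  Correlations
    undefined because of constant vectors are reported as NaN.
    """

    def index(records: Sequence[IsomiRRecord]) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for r in records:
            out.setdefault(r.locus, {})[r.sequence] = (
                out.get(r.locus, {}).get(r.sequence, 0) + r.count
            )
        return out

    ctl = index(control)
    trt = index(treated)
    shared = sorted(set(ctl) & set(trt))
    per_locus: dict[str, float] = {}
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for locus in shared:
        seqs = sorted(set(ctl[locus]) | set(trt[locus]))
        x = np.array([ctl[locus].get(s, 0) for s in seqs], dtype=float)
        y = np.array([trt[locus].get(s, 0) for s in seqs], dtype=float)
        if x.sum() > 0:
            x = x / x.sum()
        if y.sum() > 0:
            y = y / y.sum()
        pooled_x.extend(x)
        pooled_y.extend(y)
        if len(seqs) < 2 or x.std() == 0 or y.std() == 0:
            per_locus[locus] = float("nan")
        else:
            per_locus[locus] = float(np.corrcoef(x, y)[0, 1])
    px = np.array(pooled_x)
    py = np.array(pooled_y)
    if len(px) < 2 or px.std() == 0 or py.std() == 0:
        pooled = float("nan")
    else:
        pooled = float(np.corrcoef(px, py)[0, 1])
    return per_locus, pooled
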