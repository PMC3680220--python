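"""Synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the study conditions of a three-platform miRNA
differential-expression design — 3 platforms x 3 replicates of log2
ratios with partial probe overlap and planted regulated miRNAs — plus
adapter-ligated 36-nt small-RNA reads carrying isomiR variation and a
position-dependent error rate, a validated-target database with optional
planted enrichment, and qPCR Ct tables with two housekeeping assays.
Every generator is deterministic given its seed and returns truth labels,
so downstream stages can be benchmarked without external data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import isomir
from .enrichment import TargetDB
from .consensus import PlatformRatioMatrix
from .read_processing import MiRNAReference, ReadRecord

BASES = "ACGT"

#: default per-class isomiR proportions used by the demo pipeline.
DEFAULT_ISOMIR_PROFILE = {
    isomir.REFERENCE: 0.60,
    isomir.TRIM3: 0.20,
    isomir.TRIM5: 0.10,
    isomir.SUBST: 0.05,
    isomir.ADD3: 0.05,
}

#: the 3' adapter recognized during trimming (DNA alphabet).
DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTGT"


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the cross-platform ratio-matrix simulation."""

    n_mirnas: int = 300
    n_platforms: int = 3
    n_replicates: int = 3
    coverage: float = 0.8
    n_up: int = 10
    n_down: int = 0
    effect_log2: float = 1.5
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_platforms < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        if self.n_up + self.n_down > self.n_mirnas:
            raise ValueError("n_up + n_down exceeds n_mirnas")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclasses.dataclass
class GroundTruth:
    """Truth labels returned alongside generated data (fields filled per
    generator; identifiers always exist in the generated output)."""

    regulated_up: set[str] | None = None
    regulated_down: set[str] | None = None
    read_truth: pd.DataFrame | None = None
    enriched_mirnas: set[str] | None = None
    planted_enrichment: float | None = None
    true_fc: dict[str, float] | None = None


def _mirna_ids(n: int) -> list[str]:
    return [f"mir-{i + 1:04d}" for i in range(n)]


def gen_platform_matrices(
    config: SimulationConfig,
) -> tuple[list[PlatformRatioMatrix], GroundTruth]:
    """Simulate per-platform replicate log2-ratio matrices.

    Each platform probes an independent Bernoulli(coverage) subset of the
    miRNAs.  Unregulated entries are Normal(0, noise_sd); planted up/down
    miRNAs are Normal(+/- effect_log2, noise_sd).
    """
    rng = np.random.default_rng(config.seed)
    mirnas = np.array(_mirna_ids(config.n_mirnas))
    regulated = rng.choice(
        config.n_mirnas, size=config.n_up + config.n_down, replace=False
    )
    up_idx = regulated[: config.n_up]
    down_idx = regulated[config.n_up :]
    effects = np.zeros(config.n_mirnas)
    effects[up_idx] = config.effect_log2
    effects[down_idx] = -config.effect_log2
    matrices = []
    for p in range(config.n_platforms):
        covered = rng.random(config.n_mirnas) < config.coverage
        vals = rng.normal(
            loc=np.repeat(effects[covered, None], config.n_replicates, axis=1),
            scale=config.noise_sd,
        )
        df = pd.DataFrame(
            vals,
            index=mirnas[covered],
            columns=[f"rep{j + 1}" for j in range(config.n_replicates)],
        )
        matrices.append(PlatformRatioMatrix(platform=f"platform{p + 1}", log2ratio=df))
    truth = GroundTruth(
        regulated_up=set(mirnas[up_idx]), regulated_down=set(mirnas[down_idx])
    )
    return matrices, truth


def gen_reference(
    n_loci: int,
    precursor_len: int = 70,
    mature_len: int = 22,
    seed: int = 0,
    flank: int = 5,
    max_retries: int = 100,
) -> MiRNAReference:
    """Random precursors with embedded mature windows.

    The mature window is placed with at least ``flank`` templated bases on
    each side so that templated trims/extensions exist.  All mature
    sequences are pairwise distinct (bounded retries, then an error).
    """
    if mature_len >= precursor_len:
        raise ValueError("mature_len must be smaller than precursor_len")
    if precursor_len - mature_len < 2 * flank:
        raise ValueError("precursor too short for the required flanks")
    rng = np.random.default_rng(seed)
    precursors: dict[str, str] = {}
    matures: dict[str, tuple[str, int, int]] = {}
    seen: set[str] = set()
    for i in range(n_loci):
        for attempt in range(max_retries):
            seq = "".join(
                BASES[b] for b in rng.integers(0, 4, size=precursor_len)
            )
            start = int(rng.integers(flank, precursor_len - mature_len - flank + 1))
            mature = seq[start : start + mature_len]
            if mature not in seen:
                break
        else:
            raise RuntimeError("could not generate distinct mature sequences")
        seen.add(mature)
        locus = f"mir-{i + 1:04d}"
        pre = f"pre-{i + 1:04d}"
        precursors[pre] = seq
        matures[locus] = (pre, start, start + mature_len)
    return MiRNAReference(precursors=precursors, matures=matures)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def _make_insert(
    rng: np.random.Generator,
    reference: MiRNAReference,
    locus: str,
    cls: str,
    max_trim: int = 3,
    max_add: int = 2,
) -> str:
    pre_id, ms, me = reference.matures[locus]
    P = reference.precursors[pre_id]
    mature = P[ms:me]
    if cls == isomir.REFERENCE:
        return mature
    if cls == isomir.TRIM3:
        k = int(rng.integers(1, max_trim + 1))
        return mature[:-k]
    if cls == isomir.TRIM5:
        k = int(rng.integers(1, max_trim + 1))
        return mature[k:]
    if cls == isomir.SUBST:
        pos = int(rng.integers(0, len(mature)))
        alt = _other_base(rng, mature[pos])
        return mature[:pos] + alt + mature[pos + 1 :]
    if cls == isomir.ADD3:
        k = int(rng.integers(1, max_add + 1))
        # first added base must be non-templated; later ones are free
        tail = _other_base(rng, P[me])
        for j in range(1, k):
            tail += BASES[int(rng.integers(0, 4))]
        return mature + tail
    raise ValueError(f"unknown isomiR class {cls!r}")


def gen_reads(
    reference: MiRNAReference,
    isomir_profile: Mapping[str, float] | None = None,
    adapter: str = DEFAULT_ADAPTER,
    read_len: int = 36,
    err_rate: float = 0.0,
    n_reads: int = 10_000,
    seed: int = 0,
) -> tuple[list[ReadRecord], GroundTruth]:
    """Simulate adapter-ligated small-RNA reads with isomiR variation.

    Each read is a (possibly isomiR-modified) mature sequence followed by
    the adapter, padded with random bases and truncated to ``read_len``.
    Sequencing errors follow a linear positional ramp from err_rate/2 at
    the first base to 3*err_rate/2 at the last.  The truth table records
    one row per read: locus, variant class and true adapter start.
    """
    profile = dict(isomir_profile or DEFAULT_ISOMIR_PROFILE)
    if abs(sum(profile.values()) - 1.0) > 1e-9:
        raise ValueError("isomiR class proportions must sum to 1")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    shortest = min(len(reference.mature_sequence(l)) for l in reference.matures) - 3
    if read_len < shortest:
        raise ValueError("read_len shorter than the shortest possible insert")
    rng = np.random.default_rng(seed)
    loci = sorted(reference.matures)
    classes = sorted(profile)
    probs = np.array([profile[c] for c in classes])
    cum = np.cumsum(probs)
    if read_len > 1:
        pos_err = err_rate * (0.5 + np.arange(read_len) / (read_len - 1))
    else:
        pos_err = np.full(1, err_rate)
    reads: list[ReadRecord] = []
    truth_rows = []
    for i in range(n_reads):
        locus = loci[int(rng.integers(0, len(loci)))]
        cls = classes[int(np.searchsorted(cum, rng.random(), side="right"))]
        insert = _make_insert(rng, reference, locus, cls)
        seq = insert + adapter
        while len(seq) < read_len:
            seq += BASES[int(rng.integers(0, 4))]
        seq = seq[:read_len]
        if err_rate > 0:
            hits = np.flatnonzero(rng.random(read_len) < pos_err)
            if hits.size:
                chars = list(seq)
                for p in hits:
                    chars[p] = _other_base(rng, chars[p])
                seq = "".join(chars)
        read_id = f"read-{i + 1:06d}"
        reads.append(ReadRecord(read_id, seq, "I" * read_len))
        truth_rows.append(
            {
                "read_id": read_id,
                "locus": locus,
                "variant_class": cls,
                "adapter_start": len(insert),
                "insert": insert,
            }
        )
    truth = GroundTruth(read_truth=pd.DataFrame(truth_rows))
    return reads, truth


def gen_target_db(
    mirnas: Sequence[str],
    n_genes: int = 2000,
    targets_per_mirna: int = 20,
    de_up: Sequence[str] = (),
    de_down: Sequence[str] = (),
    planted_enrichment: float = 1.0,
    enriched_mirnas: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[TargetDB, GroundTruth]:
    """Simulate a validated-target database.

    With ``planted_enrichment == 1`` every miRNA's targets are a uniform
    without-replacement sample of the gene universe (the null).  With a
    factor > 1, the designated miRNAs oversample the ``de_down`` genes by
    that factor, planting the down-list enrichment signal.
    """
    if planted_enrichment < 1.0:
        raise ValueError("planted_enrichment must be >= 1")
    if targets_per_mirna > n_genes:
        raise ValueError("targets_per_mirna exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{j + 1:05d}" for j in range(n_genes)])
    gene_set = set(genes)
    for lst, name in ((de_up, "de_up"), (de_down, "de_down")):
        unknown = set(lst) - gene_set
        if unknown:
            raise ValueError(f"{name} contains genes outside the universe")
    enriched = set(enriched_mirnas or [])
    down_mask = np.isin(genes, list(de_down))
    rows = []
    for m in mirnas:
        if planted_enrichment > 1.0 and m in enriched:
            w = np.where(down_mask, planted_enrichment, 1.0)
            w = w / w.sum()
            chosen = rng.choice(n_genes, size=targets_per_mirna, replace=False, p=w)
        else:
            chosen = rng.choice(n_genes, size=targets_per_mirna, replace=False)
        for j in chosen:
            rows.append((m, genes[j]))
    db = TargetDB(pd.DataFrame(rows, columns=["mirna", "gene"]))
    truth = GroundTruth(
        enriched_mirnas=enriched or None, planted_enrichment=planted_enrichment
    )
    return db, truth


def gen_qpcr(
    true_fc: Mapping[str, float],
    ref_genes: Sequence[str] = ("SNORD44", "SNORD48"),
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_technical: int = 2,
    calibrator: str = "calibrator",
    treated: str = "treated",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a two-sample Ct table for ddCt validation.

    Treated-sample target Cts drop by log2(true fold change) relative to
    the calibrator; reference-gene Cts are constant up to noise.  Returns
    a long table with columns (sample, assay, replicate, ct).
    """
    if any(fc <= 0 for fc in true_fc.values()):
        raise ValueError("fold changes must be positive")
    if len(ref_genes) < 1:
        raise ValueError("at least one reference assay required")
    rng = np.random.default_rng(seed)
    rows = []
    base_ct = {a: 24.0 + 4.0 * rng.random() for a in sorted(true_fc)}
    base_ct.update({r: 20.0 + 2.0 * rng.random() for r in ref_genes})
    shifts = {a: -np.log2(fc) for a, fc in true_fc.items()}
    for assay in sorted(base_ct):
        for sample in (calibrator, treated):
            shift = shifts.get(assay, 0.0) if sample == treated else 0.0
            for rep in range(n_technical):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample": sample,
                        "assay": assay,
                        "replicate": rep + 1,
                        "ct": base_ct[assay] + shift + noise,
                    }
                )
    table = pd.DataFrame(rows)
    return table, GroundTruth(true_fc=dict(true_fc))
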