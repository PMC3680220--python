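"""End-to-end demo pipeline on synthetic data, with a run manifest.

``run_pipeline`` wires the stages simulate -> trim -> map -> count ->
normalize -> isomir -> merge -> rankprod -> consensus -> enrich -> qpcr.
Each stage draws its randomness from a stream derived deterministically
from the global seed and the stage name, so stages can be re-run in
isolation and two runs with the same config are byte-identical.  The
manifest lists every artifact with a content hash plus per-stage record
counts and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import consensus as cns
from . import enrichment as enr
from . import io as mio
from . import isomir as iso
from . import qpcr as qp
from . import read_processing as rp
from . import synthetic as syn

log = logging.getLogger("mirconsensus")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """Resolved parameters for every stage of the demo pipeline."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    # expression simulation
    n_mirnas: int = 120
    n_platforms: int = 3
    n_replicates: int = 3
    coverage: float = 0.8
    n_up: int = 8
    n_down: int = 0
    effect_log2: float = 1.5
    noise_sd: float = 0.4
    # sequencing simulation + read processing
    n_loci: int = 30
    n_reads: int = 5000
    read_len: int = 36
    err_rate: float = 0.005
    adapter: str = syn.DEFAULT_ADAPTER
    min_overlap: int = 5
    max_penalty: float = 2.5
    max_mm: int = 2
    # isomiR filters
    min_freq: int = 3
    contribution_cutoff: float = 10.0
    z_threshold: float = 1.96
    # consensus
    n_perm: int = 1000
    q_max: float = 0.05
    fc_min: float = 1.2
    # enrichment
    run_enrichment: bool = True
    n_genes: int = 1500
    targets_per_mirna: int = 20
    n_de_genes: int = 150
    planted_enrichment: float = 5.0
    enrich_n_perm: int = 400
    # qPCR
    qpcr_true_fc: float = 2.73
    qpcr_noise_sd: float = 0.1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_json(out / "config.json")
    manifest: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": {}}

    def record(stage: str, seed: int | None, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": seed,
            "counts": counts,
            "outputs": {f.name: _sha256(f) for f in files},
        }
        log.info("stage %s: %s", stage, counts)

    # --- simulate expression matrices -------------------------------------
    sim_seed = stage_seed(config.seed, "simulate_matrices")
    sim_cfg = syn.SimulationConfig(
        n_mirnas=config.n_mirnas,
        n_platforms=config.n_platforms,
        n_replicates=config.n_replicates,
        coverage=config.coverage,
        n_up=config.n_up,
        n_down=config.n_down,
        effect_log2=config.effect_log2,
        noise_sd=config.noise_sd,
        seed=sim_seed,
    )
    matrices, expr_truth = syn.gen_platform_matrices(sim_cfg)
    files = []
    for m in matrices:
        f = out / f"ratios_{m.platform}.tsv"
        mio.write_ratio_matrix(m, f)
        files.append(f)
    truth_f = out / "expression_truth.tsv"
    pd.DataFrame(
        {
            "mirna": sorted(expr_truth.regulated_up | expr_truth.regulated_down),
        }
    ).assign(
        direction=lambda d: [
            "up" if m in expr_truth.regulated_up else "down" for m in d["mirna"]
        ]
    ).to_csv(truth_f, sep="\t", index=False)
    files.append(truth_f)
    record(
        "simulate_matrices",
        sim_seed,
        {"platforms": len(matrices), "mirnas": config.n_mirnas},
        files,
    )

    # --- simulate reference + reads ---------------------------------------
    ref_seed = stage_seed(config.seed, "simulate_reference")
    reference = syn.gen_reference(config.n_loci, seed=ref_seed)
    ref_fa = out / "reference.fa"
    ref_tsv = out / "mature.tsv"
    mio.write_reference(reference, ref_fa, ref_tsv)
    reads_seed = stage_seed(config.seed, "simulate_reads")
    reads, read_truth = syn.gen_reads(
        reference,
        adapter=config.adapter,
        read_len=config.read_len,
        err_rate=config.err_rate,
        n_reads=config.n_reads,
        seed=reads_seed,
    )
    fq = out / "reads.fastq"
    mio.write_fastq(reads, fq)
    rt = out / "read_truth.tsv"
    read_truth.read_truth.to_csv(rt, sep="\t", index=False)
    record(
        "simulate_reads",
        reads_seed,
        {"loci": config.n_loci, "reads": len(reads)},
        [ref_fa, ref_tsv, fq, rt],
    )

    # --- trim -> map -> count ---------------------------------------------
    trims = rp.trim_adapters(
        reads, config.adapter, config.min_overlap, config.max_penalty
    )
    trimmed_f = out / "trimmed.fa"
    mio.write_fasta({r.id: t.insert for r, t in zip(reads, trims)}, trimmed_f)
    mapper = rp.ReadMapper(reference, max_mm=config.max_mm)
    assignments = mapper.map([t.insert for t in trims])
    assign_f = out / "assignments.tsv"
    pd.DataFrame(
        {
            "read_id": [r.id for r in reads],
            "status": [a.status for a in assignments],
            "locus": [a.locus or "" for a in assignments],
            "mismatches": [a.mismatches if a.mismatches is not None else -1 for a in assignments],
        }
    ).to_csv(assign_f, sep="\t", index=False)
    n_trimmed = sum(t.adapter_found for t in trims)
    n_assigned = sum(a.status == rp.ASSIGNED for a in assignments)
    counts_col = rp.count_unambiguous(assignments, "sample1", loci=list(reference.matures))
    if not (n_assigned <= len(trims) <= len(reads)):
        raise RuntimeError("conservation violated: counted <= trimmed <= input")
    record(
        "read_processing",
        None,
        {
            "input_reads": len(reads),
            "adapter_found": int(n_trimmed),
            "assigned": int(n_assigned),
            "ambiguous": int(sum(a.status == rp.AMBIGUOUS for a in assignments)),
            "unmapped": int(sum(a.status == rp.UNMAPPED for a in assignments)),
        },
        [trimmed_f, assign_f],
    )

    # two in-silico samples from split halves, so normalization has >= 2 columns
    half = len(assignments) // 2
    col_a = rp.count_unambiguous(assignments[:half], "sampleA", loci=list(reference.matures))
    col_b = rp.count_unambiguous(assignments[half:], "sampleB", loci=list(reference.matures))
    table = rp.CountTable(pd.concat([col_a, col_b], axis=1))
    normalized = rp.normalize_counts(table)
    counts_f = out / "counts.tsv"
    norm_f = out / "counts_normalized.tsv"
    normalized.counts.rename_axis("locus").to_csv(counts_f, sep="\t")
    normalized.normalized.rename_axis("locus").to_csv(norm_f, sep="\t")
    record(
        "normalize",
        None,
        {"loci": int(table.counts.shape[0]), "samples": int(table.counts.shape[1])},
        [counts_f, norm_f],
    )

    # --- isomiR -----------------------------------------------------------
    pairs = [
        (a.insert, a.locus) for a in assignments if a.status == rp.ASSIGNED
    ]
    records = iso.build_isomir_records(pairs, reference)
    filtered = iso.filter_isomirs(
        records,
        min_freq=config.min_freq,
        contribution_cutoff=config.contribution_cutoff,
        z_threshold=config.z_threshold,
        err_rate=config.err_rate if config.err_rate > 0 else None,
    )
    iso_f = out / "isomirs.tsv"
    pd.DataFrame(
        [
            {
                "sequence": r.sequence,
                "locus": r.locus,
                "count": r.count,
                "classes": json.dumps(r.classes, sort_keys=True),
                "contribution": r.contribution,
                "z": r.z,
            }
            for r in filtered
        ]
    ).to_csv(iso_f, sep="\t", index=False)
    summary = iso.summarize_locus([filtered], condition="demo")
    sum_f = out / "isomir_summary.tsv"
    summary.to_csv(sum_f, sep="\t", index=False)
    record(
        "isomir",
        None,
        {"records_in": len(records), "records_kept": len(filtered)},
        [iso_f, sum_f],
    )

    # --- merge -> rankprod -> consensus -----------------------------------
    merged = cns.merge_platforms(matrices)
    rp_seed = stage_seed(config.seed, "rankprod")
    results = cns.rank_product_analysis(merged, n_perm=config.n_perm, seed=rp_seed)
    res_f = out / "rankprod_results.tsv"
    results.assign(pattern=results["pattern"].map(lambda p: "+".join(p))).to_csv(
        res_f, sep="\t"
    )
    cons = cns.consensus_list(results, q_max=config.q_max, fc_min=config.fc_min)
    cons_f = out / "consensus.tsv"
    cons.assign(pattern=cons["pattern"].map(lambda p: "+".join(p))).to_csv(
        cons_f, sep="\t"
    )
    record(
        "consensus",
        rp_seed,
        {"union_mirnas": int(len(results)), "consensus": int(len(cons))},
        [res_f, cons_f],
    )

    manifest_extra: dict[str, Any] = {}

    # --- enrichment -------------------------------------------------------
    if config.run_enrichment:
        enr_seed = stage_seed(config.seed, "enrichment")
        rng = np.random.default_rng(enr_seed)
        mirna_ids = sorted(merged.patterns.index)
        genes = [f"gene{j + 1:05d}" for j in range(config.n_genes)]
        de_idx = rng.choice(config.n_genes, size=2 * config.n_de_genes, replace=False)
        de_down = [genes[j] for j in de_idx[: config.n_de_genes]]
        de_up = [genes[j] for j in de_idx[config.n_de_genes :]]
        regulated = sorted(cons.index) or sorted(expr_truth.regulated_up)
        db, _ = syn.gen_target_db(
            mirna_ids,
            n_genes=config.n_genes,
            targets_per_mirna=config.targets_per_mirna,
            de_up=de_up,
            de_down=de_down,
            planted_enrichment=config.planted_enrichment,
            enriched_mirnas=regulated,
            seed=int(rng.integers(2**31)),
        )
        results_json = {}
        for label, de in (("down", de_down), ("up", de_up)):
            for strategy in (enr.MIRNA_NULL, enr.GENE_NULL):
                r = enr.enrichment_test(
                    db,
                    regulated,
                    de,
                    strategy=strategy,
                    n_perm=config.enrich_n_perm,
                    seed=int(rng.integers(2**31)),
                    gene_list_label=label,
                )
                results_json[f"{strategy}_{label}"] = r.summary()
        enr_f = out / "enrichment.json"
        enr_f.write_text(json.dumps(results_json, indent=2, sort_keys=True) + "\n")
        record(
            "enrichment",
            enr_seed,
            {"regulated_mirnas": len(regulated), "tests": len(results_json)},
            [enr_f],
        )
        manifest_extra["enrichment"] = results_json

    # --- qPCR -------------------------------------------------------------
    q_seed = stage_seed(config.seed, "qpcr")
    ct_table, _ = syn.gen_qpcr(
        {"target-mir": config.qpcr_true_fc},
        ct_noise_sd=config.qpcr_noise_sd,
        seed=q_seed,
    )
    ct_f = out / "ct_table.tsv"
    ct_table.to_csv(ct_f, sep="\t", index=False)
    fc = qp.delta_delta_ct(
        ct_table, "target-mir", ["SNORD44", "SNORD48"], calibrator="calibrator"
    )
    fc_f = out / "qpcr_fc.tsv"
    fc.rename_axis("sample").to_frame("fc").to_csv(fc_f, sep="\t")
    record("qpcr", q_seed, {"assays": 3, "samples": 2}, [ct_f, fc_f])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
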