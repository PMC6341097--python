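"""End-to-end orchestration: simulate/ingest -> VOI -> enrichment ->
burden -> TDT, with a run manifest for reproducibility.

Outputs are plain TSVs with fixed column orders and floats printed at six
significant digits, so diffing two runs is trivial; re-running with the
same config and seed reproduces every output byte-for-byte.  Logging goes
to stderr, results only to files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .burden import run_burden_scan
from .enrichment import EnrichmentConfig, run_enrichment
from .io_formats import (
    read_gmt,
    read_ped,
    read_variants,
    write_annotation,
    write_burden_results,
    write_enrichment_results,
    write_gmt,
    write_ped,
    write_tdt_result,
    write_vcf,
    write_voi_records,
)
from .prioritization import identify_vois
from .simulate import (
    SimConfig,
    rng_streams,
    simulate_cohort,
    simulate_enrichment_input,
    simulate_families,
    simulate_gene_sets,
    simulate_transmissions,
)
from .tdt import tdt_from_events
from .types import FilterConfig, FilterMode

logger = logging.getLogger("rarefam")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Inputs for a full run.

    When ``sim`` is set the pipeline generates its own inputs (and writes
    them under the output directory); otherwise the file paths must be
    provided.
    """

    out_dir: Path
    sim: SimConfig | None = None
    ped: Path | None = None
    vcf: Path | None = None
    annot: Path | None = None
    gmt: Path | None = None
    cases: Path | None = None    # one sample id per line
    controls: Path | None = None
    genes: Path | None = None    # one gene symbol per line
    voi_filter: FilterConfig = field(default_factory=FilterConfig)
    burden_filter: FilterConfig = field(
        default_factory=lambda: FilterConfig(mode=FilterMode.RARE)
    )
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    log_level: str = "INFO"


def _config_hash(cfg: PipelineConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if hasattr(obj, "value"):
            return obj.value
        return obj

    payload = encode(cfg)
    payload.pop("out_dir", None)  # hash the analysis config, not the destination
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _require(cfg: PipelineConfig, *names: str) -> None:
    missing = [n for n in names if getattr(cfg, n) is None]
    if missing:
        raise PipelineError(
            f"config is missing required field(s): {', '.join(missing)}"
        )


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_sha256": _config_hash(cfg),
        "seed": cfg.sim.seed if cfg.sim else None,
        "outputs": {},
    }

    try:
        if cfg.sim is not None:
            streams = rng_streams(cfg.sim.seed)
            fam_cohort, fam_variants, fam_truth = simulate_families(
                cfg.sim, streams["pedigree"]
            )
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            write_ped([p for p, _ in fam_cohort], inputs / "families.ped")
            write_annotation(fam_variants, inputs / "families.annot.tsv")
            variants, gtable, case_ids, control_ids, cohort_truth = (
                simulate_cohort(cfg.sim, streams["cohort"])
            )
            write_annotation(variants, inputs / "cohort.annot.tsv")
            events, trans_truth = simulate_transmissions(
                cfg.sim, streams["transmissions"]
            )
            gene_sets = simulate_gene_sets(streams["gene_sets"])
            write_gmt(gene_sets, inputs / "gene_sets.gmt")
            planted_set = next(
                gs for gs in gene_sets
                if cfg.enrichment.min_set_size
                <= len(gs.members)
                <= cfg.enrichment.max_set_size
            )
            enr_input = simulate_enrichment_input(
                gene_sets, planted_set.set_id, 200, streams["gene_sets"]
            )
            genes = list(cfg.sim.genes)
            enr_cfg = cfg.enrichment
        else:
            _require(cfg, "ped", "vcf", "annot")
            fam_peds = read_ped(cfg.ped)
            variants, gtable = read_variants(cfg.vcf, cfg.annot)
            fam_cohort = [(p, gtable) for p in fam_peds]
            fam_variants = variants
            case_ids = (
                Path(cfg.cases).read_text().split() if cfg.cases else []
            )
            control_ids = (
                Path(cfg.controls).read_text().split() if cfg.controls else []
            )
            genes = (
                Path(cfg.genes).read_text().split()
                if cfg.genes
                else sorted({v.gene for v in variants})
            )
            gene_sets = read_gmt(cfg.gmt) if cfg.gmt else []
            enr_input = None
            events = None
            enr_cfg = cfg.enrichment
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - error path plumbing
        raise PipelineError(f"input stage failed: {exc}") from exc

    # stage 1: VOI prioritization
    try:
        vois, per_family, gene_counts = identify_vois(
            fam_cohort, fam_variants, cfg.voi_filter
        )
        write_voi_records(vois, out / "vois.tsv")
        with open(out / "voi_family_summary.tsv", "w") as fh:
            fh.write("family_id\tn_vois\n")
            for fam in sorted(per_family):
                fh.write(f"{fam}\t{per_family[fam]}\n")
        manifest["outputs"]["voi"] = "vois.tsv"
        logger.info("VOI stage: %d records", len(vois))
    except Exception as exc:
        raise PipelineError(f"voi stage failed: {exc}") from exc

    # stage 2: enrichment (on the simulated planted list, or the VOI genes)
    try:
        if enr_input is None:
            enr_input = sorted({r.variant.gene for r in vois})
        if gene_sets and enr_input:
            enr = run_enrichment(enr_input, gene_sets, enr_cfg)
            write_enrichment_results(enr, out / "enrichment.tsv")
            manifest["outputs"]["enrichment"] = "enrichment.tsv"
            logger.info("enrichment stage: %d sets tested", len(enr))
    except Exception as exc:
        raise PipelineError(f"enrichment stage failed: {exc}") from exc

    # stage 3: case-control burden
    try:
        if case_ids and control_ids:
            results = run_burden_scan(
                genes, variants, gtable, case_ids, control_ids,
                cfg.burden_filter,
            )
            write_burden_results(results, out / "burden.tsv")
            manifest["outputs"]["burden"] = "burden.tsv"
            logger.info("burden stage: %d genes", len(results))
    except Exception as exc:
        raise PipelineError(f"burden stage failed: {exc}") from exc

    # stage 4: TDT
    try:
        if events is not None:
            result = tdt_from_events(events)
            write_tdt_result(result, out / "tdt.tsv")
            manifest["outputs"]["tdt"] = "tdt.tsv"
            logger.info("TDT stage: T=%d U=%d", result.T, result.U)
    except Exception as exc:
        raise PipelineError(f"tdt stage failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
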