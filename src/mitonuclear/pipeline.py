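"""End-to-end orchestration: simulate -> morphology -> qc -> scan ->
significance -> survival, with one config and deterministic seeding.

Each stage reads the previous stage's files and writes its own; no
stage mutates another stage's output. The run config is serialized into
a ``#``-prefixed provenance header of every TSV and into
``config_used.yaml``. A single global seed is fanned out to per-stage
child seeds through ``numpy.random.SeedSequence`` so stages can be
rerun in isolation reproducibly.

The interaction scan consumes the simulated (model-generated)
phenotypes — those carry the plantable interaction coefficient; the
morphology stage demonstrates the tile-to-phenotype extraction on the
synthetic tiles and writes its features alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_qc as gq
from . import io as mio
from . import morphology as morph
from . import significance as sig
from . import survival as surv
from .scan import scan as run_scan
from .simulate import SimConfig, generate_genotypes, generate_phenotype, generate_survival, generate_tiles

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "morphology", "qc", "scan", "significance", "survival")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; threshold defaults are the analysis
    defaults quoted throughout this package (call rate 0.95, HWE 1e-3,
    MAF 0.05, VAF 0.05, q 0.05, Bonferroni 0.05, radii 10/15/10,
    percentiles 75/25, 5 PCs)."""

    outdir: str = "pipeline_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    planted_nusnp: int | None = None  # default: the highest-MAF nuSNP
    planted_mtsnp: int | None = None  # default: the most common mtSNP
    n_tile_subjects: int = 3
    tiles_per_subject: int = 2
    nuclei_per_tile: int = 10
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-3
    maf_min: float = 0.05
    vaf_min: float = 0.05
    gene_bed: str | None = None
    flank: int = 10_000
    q_threshold: float = 0.05
    bonferroni_alpha: float = 0.05
    min_radius: float = 10.0
    max_radius: float = 15.0
    search_radius: float = 10.0
    n_pcs: int = 5
    survival_n: int = 300
    survival_hazard_ratio: float = 1.7
    survival_censor_rate: float = 0.3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _child_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(seed).spawn(len(STAGES))[idx]
    return int(ss.generate_state(1)[0] % 2**31)


def _write(df: pd.DataFrame, path: Path, config_line: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(config_line)
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of output paths and key results."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_line = "# config: " + json.dumps(config.to_dict(), default=str) + "\n"
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    results: dict = {"outdir": str(out)}

    # -- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.sim, seed=_child_seed(config.seed, stage))
        cohort = generate_genotypes(sim_cfg)
        nu_idx = (config.planted_nusnp if config.planted_nusnp is not None
                  else int(np.argmax(cohort.nuclear_maf)))
        mt_idx = (config.planted_mtsnp if config.planted_mtsnp is not None
                  else int(np.argmax(np.minimum(cohort.mito_vaf,
                                                1 - cohort.mito_vaf))))
        rng = np.random.default_rng(_child_seed(config.seed, stage) + 1)
        y = generate_phenotype(cohort, sim_cfg, nu_idx, mt_idx, rng=rng)
        phen = pd.DataFrame({"log2_size_per_nucleus": y},
                            index=cohort.nuclear_genotypes.index)
        mio.write_vcf(out / "genotypes.vcf", cohort.subjects,
                      cohort.nuclear_genotypes, cohort.mito_genotypes,
                      nuclear_pos=cohort.nuclear_pos, mito_pos=cohort.mito_pos)
        _write(phen, out / "phenotypes.tsv", cfg_line)
        tile_dir = out / "tiles"
        tile_dir.mkdir(exist_ok=True)
        import imageio.v3 as iio

        for i in range(config.n_tile_subjects):
            sid = cohort.subjects[i]
            tiles = generate_tiles(
                config.tiles_per_subject, config.nuclei_per_tile,
                seed=_child_seed(config.seed, stage) + 100 + i, subject_id=sid)
            for t in tiles:
                iio.imwrite(tile_dir / f"{sid}_{t.tile_id}.png", t.pixels)
        surv_tab = generate_survival(
            config.survival_n, config.survival_hazard_ratio,
            config.survival_censor_rate,
            seed=_child_seed(config.seed, stage) + 2)
        _write(surv_tab, out / "survival.tsv", cfg_line)
        results.update(planted_nusnp=cohort.nuclear_genotypes.columns[nu_idx],
                       planted_mtsnp=cohort.mito_genotypes.columns[mt_idx],
                       cohort=cohort)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- morphology -------------------------------------------------------
    stage = "morphology"
    try:
        rows = []
        subj_rows = []
        by_subject: dict[str, list] = {}
        for png in sorted(tile_dir.glob("*.png")):
            sid, tile_id = png.stem.split("_", 1)
            import imageio.v3 as iio

            feats = morph.process_tile(
                iio.imread(png), tile_id, config.min_radius,
                config.max_radius, config.search_radius)
            if feats is None:
                logger.info("tile %s excluded by QC", png.name)
                continue
            by_subject.setdefault(sid, []).append(feats)
            rows.append({"subject_id": sid, "tile_id": tile_id,
                         "n_nuclei": feats.n_nuclei,
                         "size_area": feats.size_area,
                         "intensity": feats.intensity,
                         "circularity": feats.circularity})
        for sid, feats in sorted(by_subject.items()):
            ph = morph.aggregate_subject(feats, sid)
            subj_rows.append({
                "subject_id": sid,
                "log2_size_per_nucleus": ph.log2_size_per_nucleus,
                "log2_intensity_per_nucleus": ph.log2_intensity_per_nucleus,
                "mean_n_nuclei": ph.mean_n_nuclei,
                "mean_circularity": ph.mean_circularity,
            })
        _write(pd.DataFrame(rows), out / "tile_features.tsv", cfg_line, index=False)
        _write(pd.DataFrame(subj_rows), out / "morphology_phenotypes.tsv",
               cfg_line, index=False)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- qc ---------------------------------------------------------------
    stage = "qc"
    try:
        nuclear, mito, meta = mio.read_vcf(out / "genotypes.vcf")
        nuc_meta = [m for m in meta if not m.is_mito]
        nuclear, nuc_meta = gq.filter_nuclear_snps(
            nuclear, nuc_meta, config.call_rate_min, config.hwe_p_min,
            config.maf_min)
        if config.gene_bed:
            intervals = mio.read_bed(config.gene_bed)
            nuc_meta = gq.restrict_to_gene_set(nuc_meta, intervals, config.flank)
            nuclear = nuclear[[m.snp_id for m in nuc_meta]]
        mito, _ = gq.filter_mito_snps(mito, [m for m in meta if m.is_mito],
                                      config.vaf_min)
        nuclear = gq.impute_panel(nuclear, _child_seed(config.seed, stage))
        nuclear, mito = gq.code_genotypes(nuclear, mito)
        K = gq.compute_kinship(nuclear.to_numpy(float))
        pcs = gq.compute_pcs(nuclear.to_numpy(float), n_pcs=config.n_pcs)
        _write(nuclear, out / "nuclear_coded.tsv", cfg_line)
        _write(mito, out / "mito_coded.tsv", cfg_line)
        _write(pd.DataFrame(K, index=nuclear.index, columns=nuclear.index),
               out / "kinship.tsv", cfg_line)
        _write(pd.DataFrame(pcs.scores, index=nuclear.index,
                            columns=[f"PC{i+1}" for i in range(config.n_pcs)]),
               out / "pcs.tsv", cfg_line)
        pos = {m.snp_id: m.position for m in meta}
        results.update(n_nusnps_retained=nuclear.shape[1],
                       n_mtsnps_retained=mito.shape[1])
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- scan -------------------------------------------------------------
    stage = "scan"
    try:
        phen = mio.read_tsv(out / "phenotypes.tsv")
        nuclear_pos = pd.Series({c: pos[c] for c in nuclear.columns})
        mito_pos = pd.Series({c: pos[c] for c in mito.columns})
        scan_tab = run_scan(nuclear, mito, phen, pcs.scores, K,
                            nuclear_pos=nuclear_pos, mito_pos=mito_pos)
        _write(scan_tab, out / "scan.tsv", cfg_line, index=False)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- significance -----------------------------------------------------
    stage = "significance"
    try:
        hits = sig.evaluate_hits(scan_tab, phen, nuclear, mito,
                                 alpha=config.q_threshold,
                                 seed=_child_seed(config.seed, stage))
        _write(hits, out / "hits.tsv", cfg_line, index=False)
        results["n_significant"] = int(hits["significant"].sum())
        results["hits"] = hits
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- survival ---------------------------------------------------------
    stage = "survival"
    try:
        surv_tab = mio.read_tsv(out / "survival.tsv")
        fit = surv.cox_fit(surv_tab, ["group"])
        km = surv.kaplan_meier_logrank(surv_tab)
        cox_rows = [{"covariate": k, "hazard_ratio": v,
                     "ci_low": fit.ci95[k][0], "ci_high": fit.ci95[k][1],
                     "lrt_stat": fit.lrt_stat, "lrt_df": fit.lrt_df,
                     "lrt_p": fit.lrt_p}
                    for k, v in fit.hazard_ratio.items()]
        _write(pd.DataFrame(cox_rows), out / "cox.tsv", cfg_line, index=False)
        km_rows = [{"group": g, "time": t, "survival": s}
                   for g, curve in km["curves"].items()
                   for t, s in zip(curve["time"], curve["survival"])]
        _write(pd.DataFrame(km_rows), out / "km_curves.tsv", cfg_line, index=False)
        results["cox_fit"] = fit
        results["logrank_p"] = km["logrank_p"]
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    return results
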