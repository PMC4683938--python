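"""End-to-end orchestration: QC -> statistics -> report bundle.

Populations are analyzed jointly for distances/AMOVA/tree and
independently for Ne, diversity and GRM summaries.  Every stage writes a
plain TSV/JSON/Newick artifact so intermediate state is inspectable; a
manifest records the seed and stage timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .amova import amova_one_level
from .genotype_io import GenotypeMatrix, PopulationPartition, read_plink_text, subset
from .grm import build_grm, grm_summaries, pca_from_grm
from .ne_ld import ne_genome, project_heterozygosity
from .phylo import bootstrap_support
from .popstats import diversity_metrics, fst_scan, pairwise_fst
from .qc import QCConfig, apply_qc
from .rarefaction import richness_table

log = logging.getLogger("herdvar")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    ped_path: str | Path | None = None
    map_path: str | Path | None = None
    pops_path: str | Path | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    maf_min: float = 0.05
    n_boot_fst: int = 100
    n_boot_tree: int = 10_000
    n_perm_amova: int = 1000
    forecast_horizon: int = 50
    seed: int = 1
    out_dir: str | Path = "herdvar_out"

    def __post_init__(self) -> None:
        for name in ("n_boot_fst", "n_boot_tree", "n_perm_amova"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.forecast_horizon < 0:
            raise ValueError("forecast_horizon must be >= 0")


def run_full_analysis(
    config: RunConfig,
    gm: GenotypeMatrix | None = None,
    partition: PopulationPartition | None = None,
) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Either pass ``gm``/``partition`` directly or set the PED/MAP/pops paths
    in the config.  Returns the manifest dict.  A stage failure aborts with
    the stage named; artifacts written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    stage = "load"
    t_all = time.time()
    try:
        if gm is None:
            gm = read_plink_text(config.ped_path, config.map_path)
        if partition is None:
            partition = PopulationPartition.from_tsv(config.pops_path)
        partition.validate_against(gm)

        def _done(name: str, t0: float) -> None:
            dt = time.time() - t0
            manifest["stages"][name] = round(dt, 3)
            log.info("stage %s done in %.2fs", name, dt)

        stage = "qc"
        t0 = time.time()
        gm, qc_report = apply_qc(gm, config.qc, partition)
        qc_report.to_tsv(out / "qc_report.tsv")
        # samples removed by QC leave the partition too
        partition = PopulationPartition(
            {s: p for s, p in partition.mapping.items() if s in set(gm.sample_ids)}
        )
        _done(stage, t0)

        stage = "diversity"
        t0 = time.time()
        diversity_metrics(gm, partition).to_tsv(out / "diversity_table.tsv")
        _done(stage, t0)

        stage = "richness"
        t0 = time.time()
        try:
            richness_table(gm, partition).to_tsv(out / "richness_table.tsv")
        except ValueError as e:  # e.g. single population or g < 2
            log.warning("richness skipped: %s", e)
        _done(stage, t0)

        pops = partition.populations

        stage = "fst"
        t0 = time.time()
        if len(pops) >= 2:
            distances = pairwise_fst(gm, partition, config.n_boot_fst, seed=config.seed)
            distances.to_tsv(out / "distance_matrix.tsv")
            for i, a in enumerate(pops):
                for b in pops[i + 1 :]:
                    scan = fst_scan(gm, partition, a, b)
                    scan.to_bed_tsv(out / f"fst_scan_{a}_vs_{b}.tsv")
        _done(stage, t0)

        stage = "ne"
        t0 = time.time()
        for pop in pops:
            est = ne_genome(gm, partition, pop, maf_min=config.maf_min)
            est.to_tsv(out / f"ne_{pop}.tsv")
            row = diversity_metrics(subset(gm, sample_ids=partition.samples_in(pop)),
                                    PopulationPartition({s: pop for s in partition.samples_in(pop)}))
            h0 = row.rows[0].het_obs_mean
            if np.isfinite(est.ne_mean) and est.ne_mean > 0.5:
                project_heterozygosity(h0, est.ne_mean, config.forecast_horizon).to_tsv(
                    out / f"forecast_{pop}.tsv"
                )
        _done(stage, t0)

        stage = "grm"
        t0 = time.time()
        grm_all = build_grm(gm)
        grm_all.to_tsv(out / "grm.tsv")
        summaries = grm_summaries(gm, partition)
        with open(out / "grm_summaries.tsv", "w") as fh:
            fh.write("population\tmean_diag\tmean_offdiag\n")
            for pop, (dg, od) in summaries.items():
                fh.write(f"{pop}\t{dg:.6g}\t{od:.6g}\n")
        coords, explained = pca_from_grm(grm_all, min(10, gm.n_samples))
        with open(out / "pca_coordinates.tsv", "w") as fh:
            fh.write("sample_id\t" + "\t".join(f"PC{i+1}" for i in range(coords.shape[1])) + "\n")
            for sid, row_c in zip(gm.sample_ids, coords):
                fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row_c) + "\n")
        manifest["pca_explained"] = [float(x) for x in explained]
        _done(stage, t0)

        stage = "amova"
        t0 = time.time()
        if len(pops) >= 2:
            amova_one_level(gm, partition, config.n_perm_amova, seed=config.seed).to_tsv(
                out / "amova.tsv"
            )
        _done(stage, t0)

        stage = "tree"
        t0 = time.time()
        if len(pops) >= 2:
            tree = bootstrap_support(gm, partition, config.n_boot_tree, seed=config.seed)
            tree.write_newick(out / "tree.nwk")
        _done(stage, t0)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
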