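"""End-to-end orchestration: simulate -> network -> measures -> cohorts ->
regression, with a provenance manifest.

Each stage writes delimited text outputs into the run directory; the
manifest records the config, seed, stage timings and a SHA-256 digest of
every output file, so a rerun with the same config is verifiable as
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import cohort as cohort_mod
from . import glmm, measures, network, simulate, stats
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the run directory containing all outputs."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    written: list[Path] = []

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        # timings go to the log, not the manifest, so identical configs
        # yield byte-identical manifests
        manifest["stages"].append(stage)
        written.extend(paths)
        logger.info("stage %-9s done in %.1fs", stage, time.time() - t0)

    # --- simulate --------------------------------------------------------
    stage = "simulate"
    t0 = time.time()
    try:
        population = simulate.generate_population(config.generator, config.seed)
        truth = simulate.PlantedTruth(seed=config.seed)
        encounters, assignments = simulate.generate_encounters(
            population, truth, config.generator, config.seed + 1)
        paths = list(simulate.write_population(population, out).values())
        enc_path = out / "encounters.tsv"
        encounters.to_csv(enc_path, sep="\t", index=False)
        truth_path = out / "truth.json"
        simulate.export_truth(truth, assignments, truth_path)
        record(stage, t0, paths + [enc_path, truth_path])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- network ---------------------------------------------------------
    stage = "network"
    t0 = time.time()
    try:
        incidence = network.build_incidence(
            encounters, population.patients,
            window=(config.days_before_biopsy, config.days_after_biopsy))
        graph = network.project_sharing_graph(
            incidence, config.min_shared_patients,
            config.min_patients_per_physician,
            physician_attrs=population.physicians)
        edge_path, node_path = out / "graph_edges.tsv", out / "graph_nodes.tsv"
        network.write_graph(graph, edge_path, node_path)
        record(stage, t0, [edge_path, node_path])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- measures --------------------------------------------------------
    stage = "measures"
    t0 = time.time()
    try:
        linchpin = measures.linchpin_table(
            graph, "surgeon", config.linchpin_top_fraction)
        lp_path = out / "linchpin.tsv"
        linchpin.to_csv(lp_path, sep="\t", index=False)
        record(stage, t0, [lp_path])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- cohort ----------------------------------------------------------
    stage = "cohort"
    t0 = time.time()
    try:
        flags = cohort_mod.apply_cohort_filters(population.patients, encounters)
        eligible = flags.loc[~flags.excluded, "patient_id"]
        treatments = cohort_mod.identify_treatments(
            encounters, set(eligible), population.physicians,
            network_nodes=set(graph.nodes))
        tables = cohort_mod.assemble_analysis_rows(
            population.patients, population.physicians, encounters, graph,
            treatments, flags, linchpin,
            days_before_biopsy=config.days_before_biopsy,
            cutoff=config.delay_cutoff_days)
        paths = []
        for name, df in (("cohort_surgery", tables.surgery),
                         ("cohort_adjuvant", tables.adjuvant),
                         ("exclusions", tables.exclusions)):
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        record(stage, t0, paths)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stats -----------------------------------------------------------
    stage = "stats"
    t0 = time.time()
    try:
        paths = []
        bivar = stats.bivariate_report(
            tables.surgery,
            ["age_group", "race_ethnicity", "comorbidity_bin", "deprivation_bin",
             "nci_affiliated", "patient_rurality"],
            "linchpin_exposed")
        p = out / "bivariate_patients.txt"
        p.write_text(stats.report_text(bivar))
        paths.append(p)

        fits = {}
        for name, rows in (("surgery", tables.surgery),
                           ("adjuvant", tables.adjuvant)):
            if len(rows) == 0 or rows.delayed.nunique() < 2:
                logger.warning("cohort %s degenerate; model skipped", name)
                continue
            primary = glmm.fit_crossed_glmm(rows, backend=config.glmm_backend)
            sens = glmm.sensitivity_rerun(
                rows, cutoff=config.sensitivity_cutoff_days,
                backend=config.glmm_backend)
            fits[name] = (primary, sens)
            coef = out / f"model_{name}.tsv"
            glmm.side_by_side(primary, sens).to_csv(coef, sep="\t")
            txt = out / f"model_{name}.txt"
            txt.write_text(primary.summary() + "\n--- sensitivity (cutoff "
                           f"{config.sensitivity_cutoff_days}d) ---\n"
                           + sens.summary())
            paths.extend([coef, txt])
        record(stage, t0, paths)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(set(written))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
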