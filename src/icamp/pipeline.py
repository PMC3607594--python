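"""End-to-end pipeline orchestration from a single flat config.

Stages run in order: per-study DE -> cross-study FDR table -> consistency
selection (up and down) -> immune + fold-change signature -> optional
validation concordance -> optional survival model training/validation.
Each stage writes self-describing TSV/JSON outputs and the run ends with
a reproducibility manifest (config snapshot, seeds, input checksums,
per-stage gene counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import concordance_summary, label_gene, read_evidence_table
from .datatypes import ExpressionStudy, PipelineConfig
from .io import (
    read_expression_study,
    read_gene_set_gmt,
    sha256_of,
    write_results_table,
    write_risk_model_json,
)
from .meta import select_consistent_genes
from .rankprod import assemble_fdr_table, run_de
from .signature import build_signature
from .survival import IgisModel, SurvivalCohort

log = logging.getLogger(__name__)


def read_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` text config; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{i}: expected 'key = value'")
            k, v = line.split("=", 1)
            cfg[k.strip()] = v.strip()
    return cfg


def _pipeline_config(cfg: dict) -> PipelineConfig:
    kwargs = {}
    for key, cast in [
        ("n_label_permutations", int), ("n_fdrg_permutations", int),
        ("fdrg_target", float), ("min_called", int),
        ("fc_exclusion_min_studies", int), ("fc_cutoff", float),
        ("n_pairs", int), ("seed", int),
    ]:
        if key in cfg:
            kwargs[key] = cast(cfg[key])
    if "fdr_threshold_grid" in cfg:
        kwargs["fdr_threshold_grid"] = [
            float(x) for x in cfg["fdr_threshold_grid"].split(",")
        ]
    return PipelineConfig(**kwargs)


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the output directory.

    Any stage error aborts with an exception naming the stage.
    """
    cfg = read_config(config_path)
    pc = _pipeline_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", "icamp_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config": dict(cfg),
        "seed": pc.seed,
        "inputs": {},
        "stage_counts": {},
    }

    # ---- inputs: either simulate or read study TSVs ----
    stage = "inputs"
    try:
        studies: list[ExpressionStudy]
        truth = None
        if cfg.get("simulate", "false").lower() == "true":
            from .simulate import generate_multistudy

            studies, truth = generate_multistudy(
                n_studies=int(cfg.get("n_studies", 7)),
                n_genes=int(cfg.get("n_genes", 2000)),
                n_consistent_up=int(cfg.get("n_consistent_up", 60)),
                n_consistent_down=int(cfg.get("n_consistent_down", 60)),
                n_sporadic=int(cfg.get("n_sporadic", 100)),
                n_per_class=int(cfg.get("n_per_class", 20)),
                missing_fraction=float(cfg.get("missing_fraction", 0.0)),
                seed=pc.seed,
            )
        else:
            paths = [p for p in cfg.get("studies", "").split(",") if p]
            classes = [p for p in cfg.get("classes", "").split(",") if p]
            if not paths or len(paths) != len(classes):
                raise ValueError(
                    "config needs matching comma-separated 'studies' and "
                    "'classes' paths (or simulate = true)"
                )
            studies = []
            for i, (mp, cp) in enumerate(zip(paths, classes)):
                sid = Path(mp).stem
                studies.append(read_expression_study(mp, sid, cp))
                manifest["inputs"][mp] = sha256_of(mp)
                manifest["inputs"][cp] = sha256_of(cp)
        gene_sets = None
        if cfg.get("gene_sets"):
            gene_sets = read_gene_set_gmt(cfg["gene_sets"])
            manifest["inputs"][cfg["gene_sets"]] = sha256_of(cfg["gene_sets"])
        elif truth is not None:
            gene_sets = [truth.immune_gene_set()]
        if gene_sets is None:
            raise ValueError("signature stage needs 'gene_sets' (GMT path)")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- DE per study ----
    stage = "de"
    try:
        results = []
        for i, study in enumerate(studies):
            r = run_de(study, n_pairs=pc.n_pairs,
                       n_permutations=pc.n_label_permutations,
                       seed=pc.seed + i)
            write_results_table(
                r.table.reset_index(), out / f"de_{study.study_id}.tsv"
            )
            results.append(r)
        manifest["stage_counts"]["de"] = {
            r.study_id: len(r.table) for r in results
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- consistency meta-analysis ----
    stage = "cdep"
    try:
        table = assemble_fdr_table(results)
        selections = {}
        for direction in ("up", "down"):
            sel = select_consistent_genes(table, direction, pc, seed=pc.seed)
            selections[direction] = sel
            if sel.gene_table is not None:
                write_results_table(
                    sel.gene_table.reset_index(), out / f"cdep_{direction}.tsv"
                )
        with open(out / "cdep_summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    d: {
                        "l": s.l,
                        "min_called": s.min_called_used,
                        "fdr_g": s.fdr_g,
                        "n_selected": s.observed_count,
                        "mixtures": {
                            sid: asdict(m) for sid, m in s.mixture_fits.items()
                        },
                    }
                    for d, s in selections.items()
                },
                fh, indent=2,
            )
        manifest["stage_counts"]["cdep"] = {
            d: s.observed_count for d, s in selections.items()
        }
        log.info("consistency selection: %d up, %d down",
                 selections["up"].observed_count,
                 selections["down"].observed_count)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- signature ----
    stage = "signature"
    try:
        sig = build_signature(
            {d: s.selected_genes for d, s in selections.items()},
            studies, gene_sets, pc,
        )
        rows = []
        for sg in sig:
            row = {"gene": sg.gene, "direction": sg.direction,
                   "immune": sg.immune,
                   "n_fc_below": sg.n_studies_fc_below_cutoff,
                   "retained": sg.retained}
            for s in studies:
                fc = sg.fc_per_study.get(s.study_id)
                row[f"fc_{s.study_id}"] = float("nan") if fc is None else fc
            rows.append(row)
        write_results_table(rows, out / "signature.tsv")
        retained = [sg for sg in sig if sg.retained]
        manifest["stage_counts"]["signature"] = {
            "candidates": len(sig),
            "retained_up": sum(sg.direction == "up" for sg in retained),
            "retained_down": sum(sg.direction == "down" for sg in retained),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- optional concordance ----
    if cfg.get("evidence"):
        stage = "concordance"
        try:
            manifest["inputs"][cfg["evidence"]] = sha256_of(cfg["evidence"])
            evidence = read_evidence_table(cfg["evidence"])
            labels = {ev.gene: label_gene(ev) for ev in evidence}
            summary = concordance_summary(labels, retained)
            write_results_table(summary.table, out / "concordance.tsv")
            manifest["stage_counts"]["concordance"] = {
                "n_concordant": summary.n_concordant,
                "n_genes": summary.n_genes,
            }
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- optional survival model ----
    if cfg.get("training_cohort"):
        stage = "igis"
        try:
            train = _read_cohort(cfg["training_cohort"], "training")
            manifest["inputs"][cfg["training_cohort"]] = sha256_of(
                cfg["training_cohort"])
            genes = [g for g in cfg.get("igis_genes", "").split(",") if g] or None
            model = IgisModel(genes=genes).fit(train)
            write_risk_model_json(model.to_dict(), out / "risk_model.json")
            manifest["stage_counts"]["igis"] = {
                "model_genes": len(model.gene_risks_)}
            if cfg.get("validation_cohort"):
                val = _read_cohort(cfg["validation_cohort"], "validation")
                manifest["inputs"][cfg["validation_cohort"]] = sha256_of(
                    cfg["validation_cohort"])
                res = model.validate(val)
                with open(out / "igis_validation.json", "w",
                          encoding="utf-8") as fh:
                    json.dump({"rr_per_unit": res.rr_per_unit, "p": res.p,
                               "rr_group": res.rr_group,
                               "p_group": res.p_group,
                               "degenerate": res.degenerate}, fh, indent=2)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _read_cohort(path: str, cohort_id: str) -> SurvivalCohort:
    return SurvivalCohort(cohort_id=cohort_id,
                          table=pd.read_csv(path, sep="\t"))
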