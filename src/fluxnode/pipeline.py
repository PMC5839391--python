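"""End-to-end pipeline: prep → network → E-flux FBA → flux changes → response models.

A :class:`PipelineConfig` (YAML-loadable) either points at user files — a
metabolic model, a proteinGroups table with a design, a GMT annotation and a
viability table — or carries a ``simulate`` block that generates the whole
input bundle from the synthetic module.  :func:`run_pipeline` executes the
stages, writes every intermediate as TSV under the output directory, and
finishes with a manifest recording the seed, package versions and a sha256
checksum of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose import ViabilityTable, dose_at_effect, fit_median_effect, fit_table, read_viability
from .eflux import apply_eflux, normalize_scores, score_reactions
from .fba import fba, fva, max_l1_solution, sample_optimal_face
from .fluxchange import consistency_check, detect_changes, flux_activity_table
from .model import MetabolicModel
from .network import (
    build_tree,
    default_branch_count,
    fit_response_model,
    label_branches,
    node_activities,
    read_gmt,
    split_branches,
    write_gmt,
    write_graphml,
)
from .prep import compute_deltas, filter_quantifiable, normalize, read_maxquant, select_changed
from .synth import (
    SyntheticExperimentSpec,
    ToyModelSpec,
    make_annotation,
    make_expression,
    make_toy_model,
    make_viability,
    toy_model_genes,
)

log = logging.getLogger("fluxnode")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    paths: Dict[str, str] = field(default_factory=dict)
    parameters: Dict[str, object] = field(default_factory=dict)
    simulate: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(
            seed=int(d.get("seed", 0)),
            paths=dict(d.get("paths", {})),
            parameters=dict(d.get("parameters", {})),
            simulate=d.get("simulate"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            required = ["model", "matrix", "design", "annotation"]
            missing = [k for k in required if k not in self.paths]
            if missing:
                raise ValueError(f"config missing paths: {missing}")
            absent = [k for k in self.paths if not Path(self.paths[k]).exists()]
            if absent:
                raise FileNotFoundError(f"config paths do not exist: {absent}")
        p = self.parameters
        if not 0 < p.get("min_detect_frac", 0.75) <= 1:
            raise ValueError("min_detect_frac out of range")
        if not 0 < p.get("change_frac", 0.95) <= 1:
            raise ValueError("change_frac out of range")

    def param(self, key, default):
        return self.parameters.get(key, default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_inputs(cfg: PipelineConfig, outdir: Path):
    sim = cfg.simulate or {}
    model = make_toy_model(ToyModelSpec(**{**sim.get("toy_model", {}), "seed": cfg.seed}))
    genes = toy_model_genes(model)
    ann_sizes = sim.get("annotation", {"module_a": 12, "module_b": 12})
    exp_kwargs = dict(sim.get("experiment", {}))
    exp_kwargs.setdefault("n_proteins", max(120, len(genes) + 40))
    spec = SyntheticExperimentSpec(
        **exp_kwargs,
        effect_map=sim.get("effects", {}),
        seed=cfg.seed,
        protein_ids=genes,
    )
    # annotate only non-gene proteins so planted modules stay separate
    # from the metabolic gene stand-ins
    all_proteins = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    pool = [p for p in (genes + all_proteins[len(genes):])]
    annotation = make_annotation(pool[len(genes):], ann_sizes, seed=cfg.seed)
    x = make_expression(spec, annotation)

    via_cfg = sim.get("viability", {})
    doses = via_cfg.get("doses", [0, 5, 10, 20, 40, 80, 160])
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    lines = sorted(x.samples["cell_line"].unique())
    for i, line in enumerate(lines):
        Dm = via_cfg.get("Dm_base", 10.0) * (1.0 + 0.5 * i) * (1 + 0.05 * rng.standard_normal())
        vt = make_viability(
            via_cfg.get("m", 1.5), Dm, doses, noise_sd=via_cfg.get("noise_sd", 0.0),
            seed=cfg.seed + 10 + i, name=line,
        )
        rows.append(vt.data)
    viability = ViabilityTable(data=pd.concat(rows))

    model.save_json(outdir / "model.json")
    x.to_maxquant(outdir / "proteinGroups.txt")
    x.to_design(outdir / "design.tsv")
    write_gmt(annotation, outdir / "annotation.gmt")
    viability.to_tsv(outdir / "viability.tsv")
    return model, x, annotation, viability


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns the manifest dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    stage = "config"
    t0 = time.time()
    try:
        cfg.validate()

        stage = "inputs"
        ts = time.time()
        if cfg.simulate is not None:
            model, x, annotation, viability = _simulate_inputs(cfg, outdir)
            outputs += ["model.json", "proteinGroups.txt", "design.tsv", "annotation.gmt", "viability.tsv"]
        else:
            model = MetabolicModel.load_json(cfg.paths["model"])
            design = pd.read_csv(cfg.paths["design"], sep="\t", index_col=0)
            x = read_maxquant(cfg.paths["matrix"], design)
            annotation = read_gmt(cfg.paths["annotation"])
            viability = read_viability(cfg.paths["viability"]) if "viability" in cfg.paths else None
        log.info("stage %s done in %.2fs", stage, time.time() - ts)

        stage = "prep"
        ts = time.time()
        filt = filter_quantifiable(
            x, int(cfg.param("min_peptides", 2)), float(cfg.param("min_detect_frac", 0.75))
        )
        norm = normalize(filt, seed=cfg.seed)
        deltas = compute_deltas(norm)
        changed = select_changed(deltas, float(cfg.param("delta_threshold", 1.5)))
        norm.intensities.to_csv(outdir / "normalized.tsv", sep="\t")
        deltas.deltas.to_csv(outdir / "deltas.tsv", sep="\t")
        with open(outdir / "changed_proteins.tsv", "w") as fh:
            fh.write("cell_line\tdrug\tproteins\n")
            for (cl, drug), prots in sorted(changed.items()):
                fh.write(f"{cl}\t{drug}\t{','.join(sorted(prots))}\n")
        outputs += ["normalized.tsv", "deltas.tsv", "changed_proteins.tsv"]
        log.info("stage %s done in %.2fs", stage, time.time() - ts)

        stage = "network"
        ts = time.time()
        net = build_tree(norm)
        nb = cfg.param("n_branches", None) or default_branch_count(len(net.nodes))
        net = split_branches(net, int(nb))
        net = label_branches(net, annotation, float(cfg.param("alpha", 0.05)))
        acts = node_activities(net, deltas)
        net.to_edgelist().to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        write_graphml(net, outdir / "network.graphml")
        net.enrichment.to_csv(outdir / "branch_enrichment.tsv", sep="\t", index=False)
        acts.to_csv(outdir / "node_activities.tsv", sep="\t")
        outputs += ["network_edges.tsv", "network.graphml", "branch_enrichment.tsv", "node_activities.tsv"]
        log.info("stage %s done in %.2fs", stage, time.time() - ts)

        stage = "eflux_fba"
        ts = time.time()
        frac = float(cfg.param("fva_fraction", 1.0))
        mc_n = int(cfg.param("mc_samples", 20))
        meta = x.samples
        per_cond: Dict[str, dict] = {}
        for cl in sorted(meta["cell_line"].unique()):
            for cond in sorted(meta["condition"].unique()):
                cols = meta.index[(meta["cell_line"] == cl) & (meta["condition"] == cond)]
                if len(cols) == 0:
                    continue
                expr = filt.intensities[cols].mean(axis=1).to_dict()
                scored = normalize_scores(score_reactions(model, expr))
                bounded = apply_eflux(model, scored)
                per_cond[(cl, cond)] = {
                    "model": bounded,
                    "fba": fba(bounded),
                    "l1": max_l1_solution(bounded),
                    "fva": fva(bounded, frac),
                    "mc": sample_optimal_face(bounded, mc_n, seed=cfg.seed),
                }
        growth = pd.DataFrame(
            [
                {"cell_line": cl, "condition": cond, "growth_rate": d["fba"].objective_value}
                for (cl, cond), d in per_cond.items()
            ]
        )
        growth.to_csv(outdir / "growth_rates.tsv", sep="\t", index=False)
        outputs.append("growth_rates.tsv")
        log.info("stage %s done in %.2fs", stage, time.time() - ts)

        stage = "flux_changes"
        ts = time.time()
        change_frac = float(cfg.param("change_frac", 0.95))
        activity_frames = []
        change_rows = []
        support_rows = []
        for cl in sorted(meta["cell_line"].unique()):
            sols = {cond: d["l1"] for (c, cond), d in per_cond.items() if c == cl}
            tab = flux_activity_table(sols, model)
            tab.insert(0, "cell_line", cl)
            activity_frames.append(tab)
            for cond in sols:
                if cond == "control" or (cl, "control") not in per_cond:
                    continue
                ctrl_d, trt_d = per_cond[(cl, "control")], per_cond[(cl, cond)]
                rep = detect_changes(ctrl_d["l1"], trt_d["l1"], ctrl_d["fva"], trt_d["fva"], change_frac)
                support = consistency_check(rep, ctrl_d["mc"], trt_d["mc"], change_frac)
                rep = rep.assign(cell_line=cl, drug=cond, mc_support=support)
                change_rows.append(rep.reset_index())
        pd.concat(activity_frames).to_csv(outdir / "flux_activities.tsv", sep="\t")
        if change_rows:
            pd.concat(change_rows).to_csv(outdir / "flux_changes.tsv", sep="\t", index=False)
            outputs.append("flux_changes.tsv")
        outputs.append("flux_activities.tsv")
        log.info("stage %s done in %.2fs", stage, time.time() - ts)

        stage = "dose_response"
        ts = time.time()
        response = None
        if viability is not None:
            fits = fit_table(viability)
            fits.to_csv(outdir / "dose_response_fits.tsv", sep="\t")
            outputs.append("dose_response_fits.tsv")
            line_fits = {
                line: fit_median_effect(viability.doses, viability.data.loc[line].values)
                for line in viability.data.index
            }
            # perturbation dose: configured, or the cohort's median IC70
            response_dose = cfg.param("response_dose", None)
            if response_dose is None:
                response_dose = float(
                    np.median([dose_at_effect(f, 0.7) for f in line_fits.values()])
                )
            resp = {}
            for line, fit in line_fits.items():
                fa = 1.0 / (1.0 + (fit.Dm / float(response_dose)) ** fit.m)
                resp[line] = 100.0 * (1.0 - fa)
            response = pd.Series(resp, name="viability_at_dose")
        log.info("stage %s done in %.2fs", stage, time.time() - ts)

        stage = "regression"
        ts = time.time()
        if response is not None and not acts.empty:
            drugs = sorted({drug for (_, drug) in acts.columns})
            reg_rows = []
            for drug in drugs:
                feats = acts.xs(drug, axis=1, level="drug").T  # cell_line x node
                common = [cl for cl in feats.index if cl in response.index]
                if len(common) >= 3 and feats.shape[1] >= 1:
                    res = fit_response_model(
                        feats.loc[common], response.loc[common],
                        max_terms=int(cfg.param("max_terms", 2)),
                    )
                    reg_rows.append(
                        {
                            "drug": drug,
                            "predictors": ";".join(res.predictors),
                            "adjusted_R2": res.adjusted_r2,
                            "R2": res.r2,
                            "n": res.n_obs,
                        }
                    )
            if reg_rows:
                pd.DataFrame(reg_rows).to_csv(outdir / "response_models.tsv", sep="\t", index=False)
                outputs.append("response_models.tsv")
        log.info("stage %s done in %.2fs", stage, time.time() - ts)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {name: _sha256(outdir / name) for name in outputs},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        (outdir / "failed").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(stage, exc) from exc
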