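"""End-to-end orchestration: generate → fit affinity → fit potency →
predict PK → NCA → simulate challenge → fit leakage → report.

`run_pipeline` executes the whole chain on a seeded synthetic study, writes
machine-readable (JSON/CSV) and human-readable (markdown) reports to an
output directory, and returns a :class:`PipelineReport`. All randomness is
derived from the single seed, so outputs are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binding import fit_ncurve, write_binding_curves
from .challenge import find_design_window, protection_timecourse
from .config import (
    ASSAY_LLOQ_UG_PER_ML,
    StudyConfig,
    default_study_config,
    load_study_config,
)
from .errors import OcuvegfError
from .leakage import (
    apply_exclusions,
    dichotomize,
    fit_leakage_logistic,
    write_leakage_data,
)
from .pk import nca, predict_vitreal_half_life, profile_from_frame, write_concentration_data
from .potency import compare_potencies, fit_4pl
from .synthetic import (
    SyntheticStudySpec,
    generate_kinexa_dataset,
    generate_leakage_dataset,
    generate_potency_dataset,
    generate_vitreous_pk_dataset,
)

log = logging.getLogger("ocuvegf.pipeline")

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    affinity_summary: dict = field(default_factory=dict)
    potency_summary: dict = field(default_factory=dict)
    pk_summary: dict = field(default_factory=dict)
    pd_summary: pd.DataFrame | None = None
    design_window: dict = field(default_factory=dict)
    leakage_model: dict = field(default_factory=dict)
    backcalc_table: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "affinity_summary": self.affinity_summary,
            "potency_summary": self.potency_summary,
            "pk_summary": self.pk_summary,
            "design_window": self.design_window,
            "leakage_model": self.leakage_model,
            "backcalc_table": self.backcalc_table,
            "provenance": self.provenance,
        }


def _config_hash(config: StudyConfig) -> str:
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config_path=None, seed: int = 0, out_dir=None,
                 make_plot: bool = True) -> PipelineReport:
    """Run the full synthetic-study analysis chain.

    Any stage failure aborts with the stage name attached; partial outputs
    already written to ``out_dir`` are preserved for inspection.
    """
    config = load_study_config(config_path) if config_path else default_study_config()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    spec = SyntheticStudySpec(seed=seed, agents=config.agents,
                              geometry=config.geometry, design=config.design)
    report = PipelineReport()
    report.provenance = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "ocuvegf_version": __version__,
        "agents": [a.name for a in config.agents],
    }

    stage = "generate"
    try:
        _stage(stage)
        kinexa = {a.name: generate_kinexa_dataset(spec, a.name) for a in config.agents}
        potency_curves = generate_potency_dataset(spec)
        pk_data = generate_vitreous_pk_dataset(spec)
        leakage_data = generate_leakage_dataset(spec)
        if out:
            for name, curves in kinexa.items():
                write_binding_curves(curves, out / f"kinexa_{name}.csv")
            write_concentration_data(pk_data, out / "vitreous_pk.csv")
            write_leakage_data(leakage_data, out / "leakage_scores.csv")

        stage = "fit-kinexa"
        _stage(stage)
        for name, curves in kinexa.items():
            fit = fit_ncurve(curves)
            report.affinity_summary[name] = fit.to_dict()

        stage = "fit-ic50"
        _stage(stage)
        fits = []
        for curve in potency_curves:
            agent_name = curve.replicate_id.rsplit("_rep", 1)[0]
            fits.append(fit_4pl(curve, label=agent_name))
        comparison = compare_potencies(fits)
        by_label: dict[str, list[float]] = {}
        for f in fits:
            by_label.setdefault(f.label, []).append(f.ic50)
        report.potency_summary = {
            "ic50_nM": {k: sum(v) / len(v) for k, v in by_label.items()},
            "potency_order": comparison.attrs["potency_order"],
            "pairwise": comparison.to_dict(orient="records"),
        }

        stage = "nca"
        _stage(stage)
        nca_t_half = {}
        for agent in config.agents:
            prof = profile_from_frame(pk_data, agent.name,
                                      lloq=ASSAY_LLOQ_UG_PER_ML.get(agent.name, 0.0))
            result = nca(prof, dose_ug=agent.dose_mass)
            report.pk_summary[agent.name] = result.to_dict()
            nca_t_half[agent.name] = result.t_half

        stage = "predict-pk"
        _stage(stage)
        # anchor the size-scaling prediction to the NCA-recovered ranibizumab
        # half-life so the prediction is self-contained in the study data
        anchor_agent = config.agent("ranibizumab") if any(
            a.name == "ranibizumab" for a in config.agents) else config.agents[0]
        anchor = (anchor_agent.molecular_weight, nca_t_half[anchor_agent.name])
        for agent in config.agents:
            pred = predict_vitreal_half_life(agent, config.geometry, anchor=anchor)
            report.pk_summary[agent.name]["t_half_predicted"] = pred

        stage = "fit-leakage"
        _stage(stage)
        obs = dichotomize(leakage_data)
        obs, exclusion_log = apply_exclusions(obs)
        model = fit_leakage_logistic(obs)
        report.leakage_model = model.to_dict()
        report.leakage_model["n_excluded"] = int(len(exclusion_log))
        report.backcalc_table = {
            f"{p:.1f}": model.backcalc(p) for p in (0.2, 0.5, 0.8)
        }

        stage = "simulate-challenge"
        _stage(stage)
        frames = [
            protection_timecourse(agent, config.geometry, config.design, model,
                                  t_half_days=nca_t_half[agent.name])
            for agent in config.agents
        ]
        report.pd_summary = pd.concat(frames, ignore_index=True)

        stage = "design-window"
        _stage(stage)
        window = find_design_window(config.agents, config.geometry, config.design,
                                    model, t_halves=nca_t_half)
        report.design_window = {
            "start_day": window.start_day, "end_day": window.end_day,
            "empty": window.empty, "crossing_days": window.crossing_days,
        }
    except OcuvegfError as exc:
        raise OcuvegfError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out:
        _write_outputs(report, out, make_plot=make_plot)
    return report


def _write_outputs(report: PipelineReport, out: Path, make_plot: bool) -> None:
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=float) + "\n")
    if report.pd_summary is not None:
        report.pd_summary.to_csv(out / "protection_timecourse.csv", index=False)
    (out / "report.md").write_text(_markdown_report(report))
    if make_plot:
        _plot_leakage_model(report, out / "leakage_model.png")


def _markdown_report(report: PipelineReport) -> str:
    lines = ["# Synthetic anti-VEGF study report", ""]
    prov = report.provenance
    lines += [f"Seed {prov['seed']}, config {prov['config_hash']}, "
              f"ocuvegf {prov['ocuvegf_version']}", ""]
    lines += ["## Affinity (global N-curve fits)", "",
              "| agent | K_D (M) | 95% CI low | 95% CI high |", "|---|---|---|---|"]
    for name, fit in report.affinity_summary.items():
        lines.append(f"| {name} | {fit['kd_molar']:.3e} | {fit['kd_ci_low_molar']:.3e} "
                     f"| {fit['kd_ci_high_molar']:.3e} |")
    lines += ["", "## Potency (4PL IC50, mean of replicates)", "",
              "| agent | IC50 (nM) |", "|---|---|"]
    for name, ic in report.potency_summary.get("ic50_nM", {}).items():
        lines.append(f"| {name} | {ic:.2f} |")
    lines += ["", "## Vitreous NCA", "",
              "| agent | AUC (day·µg/mL) | C_0 (µg/mL) | CL (mL/day) | V_ss (mL) "
              "| t_1/2 (d) | predicted t_1/2 (d) |", "|---|---|---|---|---|---|---|"]
    for name, r in report.pk_summary.items():
        lines.append(f"| {name} | {r['AUC']:.0f} | {r['C_0']:.0f} | {r['CL']:.2f} "
                     f"| {r['V_ss']:.2f} | {r['t_1/2']:.2f} "
                     f"| {r.get('t_half_predicted', float('nan')):.2f} |")
    lm = report.leakage_model
    lines += ["", "## Leakage exposure-response", "",
              f"x50 = {lm['x50']:.1f}% free VEGF, slope = {lm['slope']:.2f} %/logit, "
              f"accuracy = {lm['accuracy']:.2f} (n = {lm['n_obs']}, "
              f"{lm['n_excluded']} excluded)", "",
              "| probability | % free VEGF |", "|---|---|"]
    for p, x in report.backcalc_table.items():
        lines.append(f"| {p} | {x:.1f} |")
    dw = report.design_window
    lines += ["", "## Design window", ""]
    if dw.get("empty"):
        lines.append("No discriminating window found.")
    else:
        lines.append(f"Discriminating window: day {dw['start_day']:.0f} to "
                     f"day {dw['end_day']:.0f}; protection lost (p ≥ 0.5) at "
                     + ", ".join(f"{k}: day {v:.0f}" for k, v in
                                 dw["crossing_days"].items()))
    lines.append("")
    return "\n".join(lines)


def _plot_leakage_model(report: PipelineReport, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    lm = report.leakage_model
    x = np.linspace(0, 120, 300)
    p = 1.0 / (1.0 + np.exp(-(x - lm["x50"]) / lm["slope"]))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(x, p, label="fitted logistic")
    ax.axvline(lm["x50"], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("free VEGF in observation interval (%)")
    ax.set_ylabel("P(moderate-to-severe leakage)")
    ax.set_title(f"x50 = {lm['x50']:.1f}%, slope = {lm['slope']:.1f} %/logit")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
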