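"""Pipeline orchestration: fit -> classify -> validate-q -> itemfit -> accuracy.

This is the package's batch surface: a validated configuration object, a
``run_pipeline`` function that executes the requested stages in dependency
order and writes every artifact (plus a run manifest with input hashes and
seeds, enough to reproduce deterministic stages byte-for-byte), and a
``render_report`` function that summarizes the artifacts of a run as
Markdown.  Each stage's outputs round-trip through the package's own
readers.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .accuracy import classification_accuracy
from .classification import classify, group_mastery, tetrachoric_matrix
from .estimation import EMConfig, class_likelihoods, em_fit, information_criteria
from .io import fit_to_json, file_sha256, read_responses
from .item_fit import itemfit_report
from .latent_space import read_qmatrix, write_qmatrix
from .qmatrix_tools import validate_qmatrix

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

STAGES = ("fit", "classify", "validate_q", "itemfit", "accuracy")


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = {"extra": "forbid"}

    responses: str
    qmatrix: str
    out_dir: str
    model: str = "gdina"
    stages: tuple[str, ...] = STAGES
    pvaf_cutoff: float = Field(0.95, ge=0.0, le=1.0)
    apply_q_revision: bool = False  # revised Q is advisory unless explicitly applied
    itemfit_alpha: float = Field(0.1, gt=0.0, lt=1.0)
    bonferroni: bool = True
    grouping_quantile: float = Field(0.5, gt=0.0, lt=1.0)
    seed: int = 1
    em_tol: float = 1e-4
    em_max_iter: int = 1000


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    Artifacts land in ``config.out_dir``: fit JSON, per-examinee mastery
    CSV, group profiles, revised Q-matrix + PVAF tables, item-fit tables,
    accuracy report, and ``manifest.json``.  A stage failure stops the
    downstream stages with the error recorded in the manifest.
    """
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "tool": "cdmkit",
        "version": __version__,
        "config": config.model_dump(),
        "inputs": {
            "responses": {"path": config.responses, "sha256": file_sha256(config.responses)},
            "qmatrix": {"path": config.qmatrix, "sha256": file_sha256(config.qmatrix)},
        },
        "seed": config.seed,
        "started": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "stages": {},
    }
    (out / "config.json").write_text(json.dumps(config.model_dump(), indent=1), encoding="utf-8")

    X, ids = read_responses(config.responses)
    q = read_qmatrix(config.qmatrix)
    if X.shape[1] != q.J:
        raise ValueError(
            f"{config.responses} has {X.shape[1]} items but {config.qmatrix} has {q.J} rows"
        )
    em_config = EMConfig(tol=config.em_tol, max_iter=config.em_max_iter, seed=config.seed)

    fit = None
    estimates = None
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            if stage == "fit":
                fit = em_fit(X, q, model=config.model, config=em_config)
                fit_to_json(fit, out / "fit.json", q_path=config.qmatrix)
            elif stage == "classify":
                fit = fit or em_fit(X, q, model=config.model, config=em_config)
                lik = class_likelihoods(fit.irf, X, fit.space)
                estimates = classify(fit.posterior, fit.space, likelihood=lik)
                estimates.to_frame(ids).to_csv(out / "mastery.csv", index=False)
                profiles = group_mastery(estimates, total_scores=X.sum(axis=1),
                                         quantile=config.grouping_quantile)
                rows = []
                for label, prof in profiles.items():
                    for k in range(estimates.K):
                        rows.append({"group": label, "attribute": f"A{k + 1}",
                                     "mean_eap": prof.mean_eap[k],
                                     "share_map_master": prof.share_map_master[k],
                                     "n": prof.n})
                pd.DataFrame(rows).to_csv(out / "group_profiles.csv", index=False)
                R = tetrachoric_matrix(estimates.map_pattern)
                pd.DataFrame(R, index=q.attr_names, columns=q.attr_names).to_csv(
                    out / "tetrachoric.csv"
                )
            elif stage == "validate_q":
                fit = fit or em_fit(X, q, model=config.model, config=em_config)
                val = validate_qmatrix(X, q, cutoff=config.pvaf_cutoff,
                                       fit=fit if config.model == "gdina" else None,
                                       config=em_config)
                write_qmatrix(val.q_revised, out / "q_revised.csv")
                pd.concat(
                    [t.assign(item=j + 1) for j, t in enumerate(val.tables)],
                    ignore_index=True,
                ).to_csv(out / "pvaf.csv", index=False)
                val.changes.to_csv(out / "q_changes.csv", index=False)
                lines = [f"{len(val.changes)} of {q.J} items changed "
                         f"(PVAF cutoff {config.pvaf_cutoff})"]
                for _, row in val.changes.iterrows():
                    lines.append(f"item {row['item']}: {row['old_q']} -> {row['new_q']}")
                if not config.apply_q_revision:
                    lines.append("revision is advisory; set apply_q_revision to adopt it")
                (out / "q_changes.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
            elif stage == "itemfit":
                fit = fit or em_fit(X, q, model=config.model, config=em_config)
                rep = itemfit_report(fit, X, alpha=config.itemfit_alpha,
                                     bonferroni=config.bonferroni)
                rep.pairs.to_csv(out / "itemfit_pairs.csv", index=False)
                rep.items.to_csv(out / "itemfit_items.csv", index=False)
                rep.summary.to_csv(out / "itemfit_summary.csv")
            elif stage == "accuracy":
                fit = fit or em_fit(X, q, model=config.model, config=em_config)
                if estimates is None:
                    lik = class_likelihoods(fit.irf, X, fit.space)
                    estimates = classify(fit.posterior, fit.space, likelihood=lik)
                acc = classification_accuracy(fit.posterior, estimates, fit.space)
                acc.pattern_level.to_csv(out / "accuracy_patterns.csv", index=False)
                acc.prevalence.to_csv(out / "pattern_prevalence.csv", index=False)
                payload = {
                    "test_level": acc.test_level,
                    "attribute_level": {f"A{k + 1}": float(v)
                                        for k, v in enumerate(acc.attribute_level)},
                    "attribute_mean": acc.attribute_mean,
                    "kappa": {f"A{k + 1}": float(v) for k, v in enumerate(acc.kappa)},
                    "kappa_mode": acc.kappa_mode,
                }
                (out / "accuracy.json").write_text(json.dumps(payload, indent=1),
                                                   encoding="utf-8")
            manifest["stages"][stage] = {"status": "ok"}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "error", "error": repr(exc)}
        manifest["finished"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
        raise
    manifest["finished"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


_PATTERN_COLS = "ABCDEFGHIJKLMNOP"


def _item_parameter_table(fit_json: dict) -> str:
    """Item probabilities in the reduced-pattern layout (columns A..P)."""
    irf = fit_json["irf"]
    width = max(len(p) for p in irf.probs)
    header = "| item | " + " | ".join(_PATTERN_COLS[:width]) + " |"
    sep = "|" + "---|" * (width + 1)
    lines = [header, sep]
    for j, p in enumerate(irf.probs):
        cells = [f"{v:.2f}" for v in p] + [""] * (width - len(p))
        lines.append(f"| {j + 1} | " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_report(out_dir) -> str:
    """Summarize the artifacts of a completed run as a Markdown document.

    Missing artifacts skip their section with a notice; an empty directory
    yields a document saying so.
    """
    out = Path(out_dir)
    from .io import fit_from_json

    sections = ["# cdmkit run report", ""]
    found = False
    fit_path = out / "fit.json"
    if fit_path.exists():
        found = True
        data = fit_from_json(fit_path)
        sections += [
            "## Model fit",
            "",
            f"Model: **{data['model']}** on {data['N']} examinees, "
            f"{data['irf'].q.J} items, {data['irf'].q.K} attributes.",
            "",
            f"-2LL = {data['neg2ll']:.2f}, AIC = {data['aic']:.2f}, "
            f"BIC = {data['bic']:.2f} ({data['n_params']} parameters; "
            f"converged: {data['converged']} in {data['n_iter']} iterations)",
            "",
            "### Item parameters (success probability per reduced pattern)",
            "",
            _item_parameter_table(data),
            "",
        ]
    else:
        sections += ["## Model fit", "", "_no fit artifact found_", ""]
    for name, title in [
        ("itemfit_summary.csv", "Item fit (l / r / p)"),
        ("group_profiles.csv", "Group mastery profiles"),
        ("accuracy_patterns.csv", "Pattern-level classification accuracy"),
        ("q_changes.csv", "Q-matrix validation"),
    ]:
        path = out / name
        if path.exists():
            found = True
            df = pd.read_csv(path)
            sections += [f"## {title}", "", df.to_markdown(index=False), ""]
        else:
            sections += [f"## {title}", "", "_no artifact found_", ""]
    if not found:
        sections = ["# cdmkit run report", "", "_no artifacts in this directory_", ""]
    text = "\n".join(sections)
    (out / "report.md").write_text(text, encoding="utf-8")
    return text
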