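"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` chains the stages — peptide table (loaded or simulated),
confidence filter, log2 + quantile normalization, protein roll-up, the
per-protein nested ANOVA with BH q-values, priority classification, the
study summary, spike-in QC and LDA panel selection — and writes a
deterministic report bundle.  Every output file carries the config hash
and seed in a header comment so reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import normalization, panel as panel_mod, priority, quantify
from .errors import DataValidationError, InvalidConfigError
from .synthetic import SPIKEIN_ACCESSION, GroundTruth, SyntheticConfig, generate_peptide_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "lfq_out"
    peptide_table: str | None = None  # None -> simulate
    min_confidence: float = 90.0
    q_max: float = 0.05
    min_abs_fc: float = 1.3
    mass_mode: str = "monoisotopic"
    seed: int = 0
    case_label: str = "AT"
    control_label: str = "control"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def flatten(self) -> dict[str, str]:
        flat = {}
        for f in fields(self):
            if f.name == "synthetic":
                continue
            flat[f.name] = "" if getattr(self, f.name) is None else str(
                getattr(self, f.name)
            )
        for f in fields(self.synthetic):
            v = getattr(self.synthetic, f.name)
            if isinstance(v, (tuple, list)):
                v = ":".join(str(x) for x in v)
            flat[f"synthetic.{f.name}"] = str(v)
        return flat

    def config_hash(self) -> str:
        # out_dir names where the bundle lands, not what is computed
        items = {k: v for k, v in self.flatten().items() if k != "out_dir"}
        blob = "\n".join(f"{k}={v}" for k, v in sorted(items.items()))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_file(self, path) -> None:
        lines = [f"{k}={v}" for k, v in sorted(self.flatten().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InvalidConfigError(f"config file not found: {path}")
        raw: dict[str, str] = {}
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InvalidConfigError(f"{path}, line {i}: expected key=value")
            k, _, v = line.partition("=")
            raw[k.strip()] = v.strip()

        def _pair(s, cast):
            parts = s.split(":")
            return tuple(cast(x) for x in parts)

        syn_kwargs = {}
        for f in fields(SyntheticConfig):
            key = f"synthetic.{f.name}"
            if key not in raw:
                continue
            v = raw[key]
            if f.name in ("n_samples_per_group",):
                syn_kwargs[f.name] = _pair(v, int)
            elif f.name in ("baseline_log2",):
                syn_kwargs[f.name] = _pair(v, float)
            elif f.name == "peptides_per_protein":
                syn_kwargs[f.name] = _pair(v, int) if ":" in v else int(v)
            elif f.name in ("n_proteins", "n_replicates", "seed"):
                syn_kwargs[f.name] = int(v)
            elif f.name == "informative_missing":
                syn_kwargs[f.name] = v.lower() in ("true", "1")
            else:
                syn_kwargs[f.name] = float(v)
        kwargs = {}
        for f in fields(cls):
            if f.name == "synthetic" or f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "seed":
                kwargs[f.name] = int(v)
            elif f.name in ("min_confidence", "q_max", "min_abs_fc"):
                kwargs[f.name] = float(v)
            elif f.name == "peptide_table":
                kwargs[f.name] = v or None
            else:
                kwargs[f.name] = v
        return cls(synthetic=SyntheticConfig(**syn_kwargs), **kwargs)


@dataclass
class ReportBundle:
    peptide_table: pd.DataFrame
    priorities: pd.DataFrame
    results: pd.DataFrame
    summary: priority.StudySummary
    panel: panel_mod.PanelModel | None
    qc: quantify.QCReport | None
    report_text: str
    ground_truth: GroundTruth | None = None


def _header(config: PipelineConfig) -> str:
    return f"# lfqpipe config_hash={config.config_hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index=True):
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def load_peptide_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidConfigError(f"peptide table not found: {path}")
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein", "peptide", "confidence", "sample", "group", "replicate",
                "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise DataValidationError(f"peptide table lacks columns {sorted(missing)}")
    return table


def run_pipeline(config: PipelineConfig, write: bool = True) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report bundle."""
    truth = None
    if config.peptide_table is not None:
        logger.info("stage load: reading %s", config.peptide_table)
        table = load_peptide_table(config.peptide_table)
    else:
        syn = replace(config.synthetic, seed=config.seed)
        logger.info("stage simulate: %d proteins, seed %d", syn.n_proteins, config.seed)
        table, truth = generate_peptide_table(syn)
    logger.info("stage load: %d peptide rows", len(table))

    priorities = priority.classify_proteins(table, config.min_confidence)
    retained_best = (
        table.groupby(["protein", "peptide"])["confidence"].transform("max")
        >= config.min_confidence
    )
    filtered = table.loc[retained_best]
    logger.info(
        "stage filter: retained %d/%d peptide rows at >= %.1f%% confidence",
        len(filtered), len(table), config.min_confidence,
    )

    matrix = normalization.peptide_table_to_matrix(filtered)
    design_df = normalization.injection_design(filtered)
    design = quantify.StudyDesign(
        design_df, case_label=config.case_label, control_label=config.control_label
    )
    log2m = normalization.log2_transform(matrix)
    normed = normalization.quantile_normalize(log2m)
    logger.info("stage normalize: %d features x %d injections", *normed.shape)

    protein_matrix = quantify.rollup_protein(normed)
    results = quantify.quantify_proteins(
        protein_matrix, design, q_max=config.q_max, min_abs_fc=config.min_abs_fc
    )
    results = results.join(priorities, how="left")
    logger.info(
        "stage quantify: %d proteins, %d significant",
        len(results), int(results["significant"].sum()),
    )

    summary = priority.summarize_study(results)

    qc = None
    if SPIKEIN_ACCESSION in results.index:
        qc = quantify.qc_spikein_check(results, max_abs_fc=config.min_abs_fc,
                                       min_q=config.q_max)
        logger.info("stage qc: spike-in fc %.3f q %.3f (%s)",
                    qc.fold_change, qc.q_value, "pass" if qc.passed else "FAIL")

    model = None
    candidates = [
        p for p in results.index
        if results.loc[p, "significant"]
        and results.loc[p, "priority"] == priority.PRIORITY_1
        and p != SPIKEIN_ACCESSION
    ]
    if candidates:
        sample_means = (
            protein_matrix.T.groupby(
                design.table["sample"].reindex(protein_matrix.columns)
            ).mean()
        )
        X = sample_means[candidates].dropna(axis=1)
        labels = design.table.drop_duplicates("sample").set_index("sample")["group"]
        labels = labels.reindex(X.index)
        if X.shape[1] > 0:
            model = panel_mod.forward_select_panel(
                X, labels, case_label=config.case_label,
                control_label=config.control_label,
            )
            logger.info("stage panel: %s", model.proteins)

    report_text = render_report(results, summary, model, qc, config)
    bundle = ReportBundle(table, priorities, results, summary, model, qc,
                          report_text, truth)

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(table, out / "peptide_table.tsv", config, index=False)
        _write_tsv(results, out / "protein_results.tsv", config)
        _write_tsv(summary.table, out / "study_summary.tsv", config)
        if model is not None:
            payload = {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "proteins": model.proteins,
                "weights": list(map(float, model.weights)),
                "threshold": model.threshold,
                "loo_misclassifications": model.loo_misclassifications,
            }
            (out / "panel.json").write_text(json.dumps(payload, indent=2) + "\n")
        (out / "report.md").write_text(report_text)
        config.to_file(out / "config.txt")
        logger.info("wrote report bundle to %s", out)
    return bundle


def render_report(
    results: pd.DataFrame,
    summary: priority.StudySummary,
    model: panel_mod.PanelModel | None,
    qc: quantify.QCReport | None,
    config: PipelineConfig | None = None,
) -> str:
    """Deterministic markdown report of a pipeline run."""
    lines = ["# Differential protein expression report", ""]
    if config is not None:
        lines += [f"config hash: `{config.config_hash()}`  seed: {config.seed}", ""]
    lines += ["## Study summary", "", summary.table.to_string(), ""]

    sig = results.loc[results["significant"]].copy()
    lines.append("## Significant proteins")
    lines.append("")
    if sig.empty:
        lines.append("no significant proteins")
    else:
        sig["abs_fc"] = sig["fold_change"].abs()
        sig = sig.rename_axis("protein").reset_index().set_index("protein")
        sig = sig.sort_values(["abs_fc", "protein"],
                              ascending=[False, True], kind="stable")
        for prot, row in sig.iterrows():
            lines.append(
                f"- {prot}: fold-change {row['fold_change']:+.2f}, "
                f"q = {row['q_value']:.3g}, priority {int(row['priority'])}"
            )
    lines.append("")
    if qc is not None:
        status = "PASS" if qc.passed else "FAIL"
        lines += [
            "## Spike-in QC",
            "",
            f"{qc.accession}: fold-change {qc.fold_change:+.3f}, "
            f"q = {qc.q_value:.3g} -> {status}",
            "",
        ]
    if model is not None:
        lines += [
            "## Biomarker panel",
            "",
            f"proteins: {', '.join(model.proteins)}",
            f"leave-one-out misclassifications: {model.loo_misclassifications}",
            "",
        ]
    return "\n".join(lines)
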