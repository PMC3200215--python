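"""Protein roll-up, per-protein nested ANOVA, fold-changes, q-values, %CVs.

Each protein's quantile-normalized log2 peptide intensities are averaged
into a single log2 protein intensity per injection, then fit with the
two-level model

    log2(intensity) = Group + Sample(Group) + replicate error,

where Sample(Group) is a random biological-sample effect nested within
group.  With a balanced replicate structure (every sample injected r
times) the model is fit by expected-mean-squares ANOVA: the group effect
is tested against the sample-within-group mean square on (1, N_samples-2)
degrees of freedom, and the variance components are

    sigma_rep^2    = MS_rep
    sigma_sample^2 = max(0, (MS_sample - MS_rep) / r).

With a single replicate per sample the fit collapses to a one-way ANOVA on
sample means (then F equals the squared pooled two-sample t statistic);
unbalanced replicate counts are first collapsed to per-sample means, which
keeps the group test exact at the cost of discarding the replicate
variance component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataValidationError, InferenceError
from .normalization import NORMALIZED, _require_scale
from .synthetic import SPIKEIN_ACCESSION, signed_fold_change

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyDesign:
    """Injection-level design: injection -> (sample, group, replicate)."""

    table: pd.DataFrame  # indexed by injection
    case_label: str = "AT"
    control_label: str = "control"

    def __post_init__(self):
        required = {"sample", "group", "replicate"}
        if not required.issubset(self.table.columns):
            raise DataValidationError(f"design needs columns {sorted(required)}")
        groups = set(self.table["group"])
        if not groups <= {self.case_label, self.control_label}:
            raise DataValidationError(
                f"unknown group labels {groups - {self.case_label, self.control_label}}"
            )
        per_sample = self.table.groupby("sample")["group"].nunique()
        if (per_sample > 1).any():
            raise DataValidationError("a sample maps to more than one group")


@dataclass
class ModelFit:
    """Result of the per-protein group/sample ANOVA."""

    diff_log2: float  # case mean - control mean
    mean_case: float
    mean_control: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    sigma2_sample: float
    sigma2_rep: float  # NaN when replicates cannot be separated
    n_samples: int
    n_replicates: int


def rollup_protein(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average peptide log2 intensities into protein log2 intensities.

    Input is the normalized (protein, peptide) x injection matrix; output is
    protein x injection with an added ``n_peptides`` attribute column count
    stored in ``attrs``.  A protein with no present peptide in an injection
    gets a missing cell.
    """
    _require_scale(matrix, NORMALIZED)
    if not isinstance(matrix.index, pd.MultiIndex) or matrix.index.nlevels != 2:
        raise DataValidationError("expected a (protein, peptide) row MultiIndex")
    protein = matrix.groupby(level="protein", sort=True).mean()
    counts = matrix.groupby(level="protein", sort=True).size()
    protein.attrs["scale"] = NORMALIZED
    protein.attrs["n_peptides"] = counts.to_dict()
    return protein


def fit_group_sample_model(y: pd.Series, design: StudyDesign) -> ModelFit:
    """Fit the nested Group + Sample(Group) model to one protein's data.

    ``y`` holds log2 protein intensities indexed by injection.  Missing
    cells are dropped before fitting.
    """
    d = design.table.loc[design.table.index.intersection(y.index)].copy()
    d["y"] = y.reindex(d.index)
    d = d.dropna(subset=["y"])
    if d.empty:
        raise InferenceError("no observations for this protein")

    sample_means = d.groupby("sample").agg(y=("y", "mean"), group=("group", "first"))
    n_per_group = sample_means.groupby("group").size()
    for label in (design.case_label, design.control_label):
        if n_per_group.get(label, 0) < 2:
            raise InferenceError(
                f"need >= 2 samples with data in group {label!r} for inference"
            )

    reps = d.groupby("sample").size()
    r = int(reps.iloc[0])
    balanced = bool((reps == r).all()) and r >= 2

    mean_case = float(
        sample_means.loc[sample_means["group"] == design.case_label, "y"].mean()
    )
    mean_control = float(
        sample_means.loc[sample_means["group"] == design.control_label, "y"].mean()
    )
    diff = mean_case - mean_control

    if balanced:
        grand = d["y"].mean()
        group_means = d.groupby("group")["y"].mean()
        group_n = sample_means.groupby("group").size()  # samples per group
        ss_group = float(
            sum(r * group_n[g] * (group_means[g] - grand) ** 2 for g in group_means.index)
        )
        persample = sample_means["y"]
        ss_sample = float(
            r
            * sum(
                (persample[s] - group_means[sample_means.loc[s, "group"]]) ** 2
                for s in persample.index
            )
        )
        within = d.set_index("sample")["y"] - persample
        ss_rep = float((within**2).sum())
        n_samples = len(persample)
        df_sample = n_samples - 2
        df_rep = n_samples * (r - 1)
        ms_sample = ss_sample / df_sample
        ms_rep = ss_rep / df_rep if df_rep > 0 else np.nan
        sigma2_rep = float(ms_rep)
        sigma2_sample = float(max(0.0, (ms_sample - ms_rep) / r))
    else:
        # collapse to per-sample means (r effectively 1)
        vals = sample_means["y"]
        grps = sample_means["group"]
        grand = vals.mean()
        group_means = vals.groupby(grps).mean()
        group_n = vals.groupby(grps).size()
        ss_group = float(
            sum(group_n[g] * (group_means[g] - grand) ** 2 for g in group_means.index)
        )
        ss_sample = float(sum((vals - group_means[grps].to_numpy()) ** 2))
        n_samples = len(vals)
        df_sample = n_samples - 2
        ms_sample = ss_sample / df_sample
        sigma2_rep = float("nan")
        sigma2_sample = float(ms_sample)
        r = 1

    # scale-aware degeneracy guard: constant data leave O(eps^2) rounding
    # residue in the sums of squares, which must not masquerade as signal
    eps = 1e-12 * max(1.0, float(grand) ** 2)
    if ms_sample <= eps:
        if ss_group > eps:
            warnings.warn("zero sample-level variance; reporting p = 0")
            f_stat, p = float("inf"), 0.0
        else:
            f_stat, p = 0.0, 1.0
    else:
        f_stat = (ss_group / 1.0) / ms_sample
        p = float(stats.f.sf(f_stat, 1, df_sample))

    return ModelFit(
        diff_log2=diff,
        mean_case=mean_case,
        mean_control=mean_control,
        f_statistic=float(f_stat),
        df=(1, df_sample),
        p_value=p,
        sigma2_sample=sigma2_sample,
        sigma2_rep=sigma2_rep,
        n_samples=n_samples,
        n_replicates=r,
    )


def fold_change(diff_log2: float) -> float:
    """Back-transform a log2 group difference into a signed fold-change.

    2**diff when the ratio is >= 1; otherwise the negative reciprocal, so a
    halving is reported as -2.0 ("2-fold down").
    """
    if not np.isfinite(diff_log2):
        raise DataValidationError("log2 difference must be finite")
    return signed_fold_change(diff_log2)


def estimate_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cv_summaries(
    raw_matrix: pd.DataFrame, design: StudyDesign
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-protein replicate %CV and replicate+sample %CV, plus medians.

    Operates on raw-scale (back-transformed) protein intensities.  The
    replicate %CV is 100*sd/mean across the replicate injections of one
    sample, averaged over samples with >= 2 replicates; the rep+sample %CV
    is 100*sd/mean across all injections of one group, averaged over the
    two groups.  Units with zero mean are excluded with a warning.
    """
    rep_cvs, tot_cvs = {}, {}
    d = design.table
    sample_of = d["sample"]
    group_of = d["group"]
    for protein, row in raw_matrix.iterrows():
        vals = row.dropna()
        if vals.empty:
            rep_cvs[protein] = np.nan
            tot_cvs[protein] = np.nan
            continue
        per_sample = []
        for _, sub in vals.groupby(sample_of.reindex(vals.index)):
            if len(sub) >= 2:
                mean = sub.mean()
                if mean == 0:
                    warnings.warn(f"zero mean for {protein}; CV undefined")
                    continue
                per_sample.append(100.0 * sub.std(ddof=1) / mean)
        rep_cvs[protein] = float(np.mean(per_sample)) if per_sample else np.nan
        per_group = []
        for _, sub in vals.groupby(group_of.reindex(vals.index)):
            if len(sub) >= 2:
                mean = sub.mean()
                if mean == 0:
                    warnings.warn(f"zero mean for {protein}; CV undefined")
                    continue
                per_group.append(100.0 * sub.std(ddof=1) / mean)
        tot_cvs[protein] = float(np.mean(per_group)) if per_group else np.nan
    table = pd.DataFrame({"cv_replicate": rep_cvs, "cv_rep_sample": tot_cvs})
    table.index = pd.Index(table.index) if table.index.nlevels == 1 else table.index
    if table.index.nlevels == 1:
        table = table.rename_axis("protein")
    medians = {
        "median_cv_replicate": float(table["cv_replicate"].median()),
        "median_cv_rep_sample": float(table["cv_rep_sample"].median()),
    }
    return table, medians


def flag_significant(
    fold_change_value: float, q_value: float, q_max: float = 0.05,
    min_abs_fc: float = 1.3
) -> bool:
    """Significance gate: q below threshold and |fold-change| at least 1.3."""
    return bool(q_value < q_max and abs(fold_change_value) >= min_abs_fc)


@dataclass
class QCReport:
    accession: str
    fold_change: float
    q_value: float
    passed: bool
    max_abs_fold_change: float
    min_q: float


def qc_spikein_check(
    results: pd.DataFrame,
    spikein_accession: str = SPIKEIN_ACCESSION,
    max_abs_fc: float = 1.3,
    min_q: float = 0.05,
) -> QCReport:
    """Check the constant-amount spike-in protein looks unchanged.

    Passes iff the spike-in's |fold-change| stays at or below ``max_abs_fc``
    and its q-value is at or above ``min_q`` — i.e. the pipeline does not
    call a protein spiked at constant amount differentially expressed.
    """
    if spikein_accession not in results.index:
        raise DataValidationError(
            f"spike-in {spikein_accession!r} absent from results"
        )
    row = results.loc[spikein_accession]
    fc, q = float(row["fold_change"]), float(row["q_value"])
    passed = abs(fc) <= max_abs_fc and q >= min_q
    return QCReport(spikein_accession, fc, q, passed, max_abs_fc, min_q)


def quantify_proteins(
    protein_matrix: pd.DataFrame,
    design: StudyDesign,
    q_max: float = 0.05,
    min_abs_fc: float = 1.3,
) -> pd.DataFrame:
    """Fit every protein and assemble the full results table.

    Returns a DataFrame indexed by protein with the group means, log2
    difference, signed fold-change, p, BH q, variance components, %CVs and
    the significance flag.  Proteins whose design degenerates (fewer than
    two samples with data per group) are reported with NaN statistics.
    """
    _require_scale(protein_matrix, NORMALIZED)
    n_peptides = protein_matrix.attrs.get("n_peptides", {})
    records = {}
    for protein, row in protein_matrix.iterrows():
        try:
            fit = fit_group_sample_model(row, design)
        except InferenceError as exc:
            logger.warning("skipping %s: %s", protein, exc)
            records[protein] = dict.fromkeys(
                ["diff_log2", "mean_case", "mean_control", "p_value",
                 "sigma2_sample", "sigma2_rep", "f_statistic"], np.nan
            )
            continue
        records[protein] = {
            "diff_log2": fit.diff_log2,
            "mean_case": fit.mean_case,
            "mean_control": fit.mean_control,
            "f_statistic": fit.f_statistic,
            "p_value": fit.p_value,
            "sigma2_sample": fit.sigma2_sample,
            "sigma2_rep": fit.sigma2_rep,
        }
    results = pd.DataFrame.from_dict(records, orient="index").rename_axis("protein")
    results["n_peptides"] = [n_peptides.get(p, np.nan) for p in results.index]
    results["fold_change"] = [
        signed_fold_change(d) if np.isfinite(d) else np.nan
        for d in results["diff_log2"]
    ]
    fitted = results["p_value"].notna()
    qvals = np.full(len(results), np.nan)
    if fitted.any():
        qvals[fitted.to_numpy()] = estimate_qvalues(results.loc[fitted, "p_value"])
    results["q_value"] = qvals

    raw = pd.DataFrame(
        2.0 ** protein_matrix.to_numpy(),
        index=protein_matrix.index,
        columns=protein_matrix.columns,
    )
    cv_table, _ = cv_summaries(raw, design)
    results = results.join(cv_table)
    results["significant"] = [
        flag_significant(fc, q, q_max, min_abs_fc)
        if np.isfinite(fc) and np.isfinite(q)
        else False
        for fc, q in zip(results["fold_change"], results["q_value"])
    ]
    return results
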