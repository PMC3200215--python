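"""Peptide-confidence filtering, Priority 1/2 assignment, study summary.

Proteins are classed by identification strength: Priority 1 when two or
more unique peptide sequences survive the >= 90% confidence filter,
Priority 2 when exactly one does, and filtered when none do.  "Unique
peptide" means a distinct amino-acid sequence (charge states and
modifications are not distinguished); peptides shared across proteins
count for every mapped protein unless ``unique_to_protein`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError

PRIORITY_1 = 1
PRIORITY_2 = 2
FILTERED = 0

DEFAULT_MIN_CONFIDENCE = 90.0


def filter_confidence(
    peptides: list[tuple[str, float]], min_confidence: float = DEFAULT_MIN_CONFIDENCE
) -> list[tuple[str, float]]:
    """Retain peptides whose best confidence meets the threshold (inclusive)."""
    for seq, conf in peptides:
        if not 0.0 <= conf <= 100.0:
            raise DataValidationError(
                f"confidence for {seq!r} out of range [0, 100]: {conf}"
            )
    return [(seq, conf) for seq, conf in peptides if conf >= min_confidence]


def assign_priority(peptides: list[tuple[str, float]]) -> int:
    """Priority from the count of distinct retained peptide sequences."""
    n_unique = len({seq for seq, _ in peptides})
    if n_unique >= 2:
        return PRIORITY_1
    if n_unique == 1:
        return PRIORITY_2
    return FILTERED


def classify_proteins(
    peptide_table: pd.DataFrame,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    unique_to_protein: bool = False,
) -> pd.DataFrame:
    """Per-protein confidence filter + priority from a long peptide table.

    Expects columns (protein, peptide, confidence); per-peptide confidence
    is the best over its rows.  Returns a DataFrame indexed by protein with
    n_peptides_retained and priority.
    """
    required = {"protein", "peptide", "confidence"}
    if not required.issubset(peptide_table.columns):
        raise DataValidationError(f"need columns {sorted(required)}")
    best = (
        peptide_table.groupby(["protein", "peptide"])["confidence"].max().reset_index()
    )
    if unique_to_protein:
        shared = best.groupby("peptide")["protein"].transform("nunique")
        best = best.loc[shared == 1]
    out = {
        protein: {"n_peptides_retained": 0, "priority": FILTERED}
        for protein in peptide_table["protein"].unique()
    }
    for protein, grp in best.groupby("protein"):
        retained = filter_confidence(
            list(zip(grp["peptide"], grp["confidence"])), min_confidence
        )
        out[protein] = {
            "n_peptides_retained": len({s for s, _ in retained}),
            "priority": assign_priority(retained),
        }
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("protein")


@dataclass
class StudySummary:
    table: pd.DataFrame  # rows: priority strata + overall

    def __str__(self) -> str:
        return self.table.to_string()


def summarize_study(
    results: pd.DataFrame,
    n_total_by_priority: dict[int, int] | None = None,
) -> StudySummary:
    """Build the per-priority study summary.

    ``results`` must carry columns priority, significant, fold_change and
    (optionally) cv_replicate / cv_rep_sample.  Each stratum row reports the
    protein count, significant count, maximum |fold-change| and median %CVs;
    the overall row is the sum (counts) / aggregate (max, median) of the
    strata.  ``n_total_by_priority`` overrides the protein counts when the
    results table holds only a subset (e.g. only the significant proteins)
    of a larger identification set.
    """
    if results.empty:
        raise DataValidationError("cannot summarize an empty results table")
    required = {"priority", "significant", "fold_change"}
    if not required.issubset(results.columns):
        raise DataValidationError(f"need columns {sorted(required)}")
    rows = []
    strata = sorted(p for p in results["priority"].unique() if p != FILTERED)
    for prio in strata:
        sub = results.loc[results["priority"] == prio]
        n_total = (
            n_total_by_priority.get(int(prio), len(sub))
            if n_total_by_priority
            else len(sub)
        )
        rows.append(
            {
                "priority": int(prio),
                "n_proteins": int(n_total),
                "n_significant": int(sub["significant"].sum()),
                "max_abs_fold_change": float(sub["fold_change"].abs().max()),
                "median_cv_replicate": float(sub["cv_replicate"].median())
                if "cv_replicate" in sub
                else np.nan,
                "median_cv_rep_sample": float(sub["cv_rep_sample"].median())
                if "cv_rep_sample" in sub
                else np.nan,
            }
        )
    overall_sub = results.loc[results["priority"] != FILTERED]
    rows.append(
        {
            "priority": "overall",
            "n_proteins": int(sum(r["n_proteins"] for r in rows)),
            "n_significant": int(sum(r["n_significant"] for r in rows)),
            "max_abs_fold_change": float(overall_sub["fold_change"].abs().max()),
            "median_cv_replicate": float(overall_sub["cv_replicate"].median())
            if "cv_replicate" in overall_sub
            else np.nan,
            "median_cv_rep_sample": float(overall_sub["cv_rep_sample"].median())
            if "cv_rep_sample" in overall_sub
            else np.nan,
        }
    )
    return StudySummary(pd.DataFrame(rows).set_index("priority"))
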