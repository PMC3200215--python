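"""MRM (multiple-reaction-monitoring) assay design and quantification.

Peptide and fragment m/z values are computed with pyteomics.  By
convention precursors validated against the printed assay table use
average masses (which that table matches) while fragment ions use
monoisotopic masses; both modes are exposed.  Collision energy follows the
charge-specific linear calibrations

    CE = 0.05  * (m/z) + 8   for doubly charged precursors
    CE = 0.044 * (m/z) + 8   for triply charged precursors,

the declustering potential is fixed at 100 V and dwell times lie in the
20-30 ms range (default 25 ms).  Cysteines may carry the fixed ethanolyl
modification (+44.0262 Da) introduced by 2-iodoethanol alkylation during
sample preparation; the printed Cys-containing transitions only reconcile
with this modification applied.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as pmass
from scipy import stats

from .errors import DataValidationError, InvalidConfigError
from .synthetic import signed_fold_change

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: ethanolyl-Cys fixed modification (C2H4O) from 2-iodoethanol alkylation
CYS_ETHANOLYL_MONO = pmass.calculate_mass(formula="C2H4O")
CYS_ETHANOLYL_AVG = pmass.calculate_mass(formula="C2H4O", average=True)

DP_VOLTS = 100.0
DWELL_MS_RANGE = (20.0, 30.0)


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_RESIDUES:
            raise DataValidationError(
                f"unknown residue {aa!r} at position {i} of {sequence!r}"
            )


def _cys_mod_mass(sequence: str, cys_ethanolyl: bool, average: bool) -> float:
    if not cys_ethanolyl:
        return 0.0
    n = sequence.count("C")
    return n * (CYS_ETHANOLYL_AVG if average else CYS_ETHANOLYL_MONO)


def peptide_precursor_mz(
    sequence: str,
    charge: int,
    mass_mode: str = "monoisotopic",
    cys_ethanolyl: bool = False,
) -> float:
    """Precursor m/z of a peptide: (residues + water + z protons) / z."""
    _check_sequence(sequence)
    if charge < 1:
        raise DataValidationError(f"charge must be >= 1, got {charge}")
    if mass_mode not in ("monoisotopic", "average"):
        raise InvalidConfigError(f"unknown mass mode {mass_mode!r}")
    average = mass_mode == "average"
    mz = pmass.calculate_mass(sequence=sequence, charge=charge, average=average)
    return mz + _cys_mod_mass(sequence, cys_ethanolyl, average) / charge


def fragment_mz(
    sequence: str,
    ion_series: str,
    index: int,
    charge: int = 1,
    mass_mode: str = "monoisotopic",
    cys_ethanolyl: bool = False,
) -> float:
    """m/z of a y- or b-series fragment ion.

    y_i is the C-terminal suffix of length i (plus water and protons);
    b_i is the N-terminal prefix of length i (plus protons).
    """
    _check_sequence(sequence)
    if ion_series not in ("y", "b"):
        raise InvalidConfigError(f"unsupported ion series {ion_series!r}")
    if not 1 <= index < len(sequence):
        raise DataValidationError(
            f"fragment index {index} out of range for length {len(sequence)}"
        )
    if charge < 1:
        raise DataValidationError(f"charge must be >= 1, got {charge}")
    sub = sequence[-index:] if ion_series == "y" else sequence[:index]
    average = mass_mode == "average"
    mz = pmass.fast_mass(sub, ion_type=ion_series, charge=charge)
    if average:
        # fast_mass is monoisotopic-only; recompute from average residue masses
        neutral = pmass.calculate_mass(sequence=sub, average=True)
        if ion_series == "b":
            neutral -= pmass.calculate_mass(formula="H2O", average=True)
        proton = 1.00739  # average proton/charge carrier mass
        mz = (neutral + charge * proton) / charge
    return mz + _cys_mod_mass(sub, cys_ethanolyl, average) / charge


def collision_energy(precursor_mz: float, charge: int) -> float:
    """Charge-specific linear CE calibration (V)."""
    if charge == 2:
        return 0.05 * precursor_mz + 8.0
    if charge == 3:
        return 0.044 * precursor_mz + 8.0
    raise DataValidationError(
        f"collision energy calibration only covers charges 2 and 3, got {charge}"
    )


@dataclass(frozen=True)
class MRMTransition:
    protein: str
    peptide: str
    precursor_charge: int
    precursor_mz: float
    product_label: str  # e.g. "y6" or "y8^2+"
    product_mz: float
    collision_energy: float
    declustering_potential: float = DP_VOLTS
    dwell_ms: float = 25.0

    def __post_init__(self):
        if not DWELL_MS_RANGE[0] <= self.dwell_ms <= DWELL_MS_RANGE[1]:
            raise InvalidConfigError(
                f"dwell time {self.dwell_ms} ms outside {DWELL_MS_RANGE}"
            )


def build_transition_list(
    targets: list[dict],
    precursor_mass_mode: str = "average",
    dwell_ms: float = 25.0,
) -> list[MRMTransition]:
    """Expand assay targets into a flat transition list.

    Each target is a dict with keys protein, peptide, charge, products
    (list of (series, index, charge) tuples) and optionally cys_ethanolyl.
    """
    transitions = []
    for target in targets:
        products = target.get("products", [])
        if not products:
            warnings.warn(
                f"no product ions for {target['peptide']}; nothing to monitor"
            )
            continue
        cys = bool(target.get("cys_ethanolyl", False))
        prec = peptide_precursor_mz(
            target["peptide"], target["charge"], precursor_mass_mode, cys
        )
        ce = collision_energy(prec, target["charge"])
        for series, index, pcharge in products:
            pmz = fragment_mz(
                target["peptide"], series, index, pcharge, "monoisotopic", cys
            )
            label = f"{series}{index}" + (f"^{pcharge}+" if pcharge > 1 else "")
            transitions.append(
                MRMTransition(
                    protein=target["protein"],
                    peptide=target["peptide"],
                    precursor_charge=target["charge"],
                    precursor_mz=prec,
                    product_label=label,
                    product_mz=pmz,
                    collision_energy=ce,
                    dwell_ms=dwell_ms,
                )
            )
    return transitions


def parse_product_label(label: str) -> tuple[str, int, int]:
    """Parse a product-ion label like ``y6`` or ``y8^2+`` into (series, index, charge)."""
    m = re.fullmatch(r"([yb])(\d+)(?:\^(\d+)\+)?", label.strip())
    if not m:
        raise DataValidationError(f"unparseable product ion label {label!r}")
    return m.group(1), int(m.group(2)), int(m.group(3) or 1)


def targets_from_fixture(transitions: pd.DataFrame) -> list[dict]:
    """Convert a printed-assay transition table into build targets.

    Rows with ``detected == 0`` (the peptide the original assay failed to
    observe) are skipped.  Expects the fixture column layout produced by
    :func:`lfqpipe.synthetic.load_table_fixtures`.
    """
    targets: dict[tuple[str, str, int], dict] = {}
    for row in transitions.itertuples(index=False):
        if not int(row.detected):
            continue
        key = (row.protein_name, row.peptide, int(row.precursor_charge))
        t = targets.setdefault(
            key,
            {
                "protein": row.accession,
                "peptide": row.peptide,
                "charge": int(row.precursor_charge),
                "cys_ethanolyl": bool(int(row.cys_ethanolyl)),
                "products": [],
            },
        )
        t["products"].append(
            (str(row.product_series), int(row.product_index), int(row.product_charge))
        )
    return list(targets.values())


def transitions_to_frame(transitions: list[MRMTransition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": t.protein,
                "peptide": t.peptide,
                "precursor_mz": t.precursor_mz,
                "charge": t.precursor_charge,
                "product": t.product_label,
                "product_mz": t.product_mz,
                "CE": t.collision_energy,
                "DP": t.declustering_potential,
                "dwell_ms": t.dwell_ms,
            }
            for t in transitions
        ]
    )


def quantify_mrm(
    chromatograms: pd.DataFrame,
    case_label: str = "AT",
    control_label: str = "control",
) -> pd.DataFrame:
    """Relative protein quantification from transition AUCs.

    ``chromatograms`` is long-format with columns (protein, peptide,
    transition, sample, group, auc).  Per peptide the transition AUCs are
    averaged within each sample, log2-transformed, and the group difference
    back-transformed into a signed fold-change; a protein's fold-change is
    the arithmetic mean of its peptides' signed fold-changes.  The p-value
    comes from a one-way ANOVA of the per-sample protein-level log2 values.
    Proteins present in the input but with no AUC data are reported with
    ``detected = False`` rather than raising.
    """
    required = {"protein", "peptide", "transition", "sample", "group", "auc"}
    if not required.issubset(chromatograms.columns):
        raise DataValidationError(f"need columns {sorted(required)}")
    records = []
    for protein, prot_df in chromatograms.groupby("protein", sort=True):
        prot_df = prot_df.dropna(subset=["auc"])
        if prot_df.empty or (prot_df["auc"] <= 0).all():
            records.append(
                {
                    "protein": protein,
                    "fold_change": np.nan,
                    "p_value": np.nan,
                    "n_peptides": 0,
                    "detected": False,
                }
            )
            continue
        pep_fcs = []
        sample_log2 = {}
        for peptide, pep_df in prot_df.groupby("peptide", sort=True):
            per_sample = pep_df.groupby(["sample", "group"])["auc"].mean()
            log2_vals = np.log2(per_sample)
            grp = log2_vals.index.get_level_values("group")
            diff = (
                log2_vals[grp == case_label].mean()
                - log2_vals[grp == control_label].mean()
            )
            pep_fcs.append(signed_fold_change(float(diff)))
            for (sample, group), v in log2_vals.items():
                sample_log2.setdefault((sample, group), []).append(v)
        protein_log2 = pd.Series(
            {k: float(np.mean(v)) for k, v in sample_log2.items()}
        )
        groups = protein_log2.index.get_level_values(1)
        case_vals = protein_log2[groups == case_label].to_numpy()
        ctrl_vals = protein_log2[groups == control_label].to_numpy()
        if len(case_vals) >= 2 and len(ctrl_vals) >= 2:
            if np.ptp(protein_log2.to_numpy()) == 0.0:
                p = 1.0  # no variation at all: no evidence of change
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = stats.f_oneway(case_vals, ctrl_vals)
                p = float(p)
        else:
            p = np.nan
        records.append(
            {
                "protein": protein,
                "fold_change": float(np.mean(pep_fcs)),
                "p_value": p,
                "n_peptides": len(pep_fcs),
                "detected": True,
            }
        )
    return pd.DataFrame(records).set_index("protein")
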