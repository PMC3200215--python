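"""Synthetic LC/MS peptide-intensity data with a known ground truth.

The generator emulates the statistical structure assumed by the downstream
differential-expression analysis: peptide intensities are lognormal on the
raw scale, i.e. Gaussian on log2, with

    log2(intensity_ijsr) = baseline_i + offset_ij + delta_i * I(s in case)
                           + b_s + e_sr

where ``b_s ~ N(0, sigma_sample^2)`` is a biological sample effect shared by
every peptide and replicate injection of sample ``s``, and
``e_sr ~ N(0, sigma_rep^2)`` is replicate-level technical noise.  A constant
spike-in QC protein (chicken lysozyme in the real experiment) is appended
with a true group effect of exactly zero.

Default variance parameters are back-solved from the study-level median
coefficients of variation of the CSF experiment this pipeline models
(replicate %CV 11.97, replicate+sample %CV 19.16) via the lognormal
CV identity implemented in :func:`cv_to_log2_sd`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FixtureParseError, InvalidConfigError

LN2 = math.log(2.0)

#: accession used for the constant-amount spike-in QC protein
SPIKEIN_ACCESSION = "LYSC_CHICK"

#: study-level median %CVs the default noise parameters reproduce
MEDIAN_CV_REPLICATE = 11.97
MEDIAN_CV_REP_SAMPLE = 19.16


def cv_to_log2_sd(cv_percent: float) -> float:
    """Convert a raw-scale %CV into a log2-scale standard deviation.

    Uses the lognormal identity ``CV^2 = exp(sigma_ln^2) - 1`` so that
    ``sd_log2 = sqrt(ln(1 + (cv/100)^2)) / ln 2``.
    """
    if cv_percent < 0:
        raise InvalidConfigError(f"%CV must be nonnegative, got {cv_percent}")
    c = cv_percent / 100.0
    return math.sqrt(math.log1p(c * c)) / LN2


def log2_sd_to_cv(sd_log2: float) -> float:
    """Inverse of :func:`cv_to_log2_sd` (returns a %CV)."""
    if sd_log2 < 0:
        raise InvalidConfigError(f"sd must be nonnegative, got {sd_log2}")
    return 100.0 * math.sqrt(math.expm1((sd_log2 * LN2) ** 2))


DEFAULT_SIGMA_REP = cv_to_log2_sd(MEDIAN_CV_REPLICATE)
_TOTAL_SD = cv_to_log2_sd(MEDIAN_CV_REP_SAMPLE)
DEFAULT_SIGMA_SAMPLE = math.sqrt(max(0.0, _TOTAL_SD**2 - DEFAULT_SIGMA_REP**2))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the peptide-table generator.

    ``n_samples_per_group`` is (case, control); the defaults mirror the
    8 A-T vs 5 control design of the CSF study.  ``effect_log2`` is the
    magnitude of the true group effect on the log2 scale (log2(1.5) by
    default, i.e. a 1.5-fold change); the sign of each changed protein's
    effect is drawn at random.
    """

    n_proteins: int = 100
    peptides_per_protein: int | tuple[int, int] = (1, 4)
    n_samples_per_group: tuple[int, int] = (8, 5)
    n_replicates: int = 2
    frac_changed: float = 0.1
    effect_log2: float | Sequence[float] = math.log2(1.5)
    sigma_sample: float = DEFAULT_SIGMA_SAMPLE
    sigma_rep: float = DEFAULT_SIGMA_REP
    baseline_log2: tuple[float, float] = (22.0, 2.0)
    missing_rate: float = 0.0
    informative_missing: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins <= 0:
            raise InvalidConfigError("n_proteins must be positive")
        lo, hi = self._peptide_range()
        if lo <= 0 or hi < lo:
            raise InvalidConfigError(
                f"peptides_per_protein must be a positive count or (lo, hi) "
                f"range, got {self.peptides_per_protein}"
            )
        if any(n <= 0 for n in self.n_samples_per_group):
            raise InvalidConfigError("sample counts must be positive")
        if self.n_replicates <= 0:
            raise InvalidConfigError("n_replicates must be positive")
        if not 0.0 <= self.frac_changed <= 1.0:
            raise InvalidConfigError("frac_changed must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.sigma_sample < 0 or self.sigma_rep < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")
        if self.baseline_log2[1] < 0:
            raise InvalidConfigError("baseline spread must be >= 0")

    def _peptide_range(self) -> tuple[int, int]:
        if isinstance(self.peptides_per_protein, (tuple, list)):
            lo, hi = self.peptides_per_protein
            return int(lo), int(hi)
        k = int(self.peptides_per_protein)
        return k, k


@dataclass
class GroundTruth:
    """True per-protein parameters of a generated dataset."""

    table: pd.DataFrame  # indexed by protein accession
    sigma_sample: float
    sigma_rep: float

    @property
    def changed(self) -> pd.Index:
        return self.table.index[self.table["changed"]]

    @property
    def spikein(self) -> str:
        flagged = self.table.index[self.table["spikein"]]
        return str(flagged[0])


def signed_fold_change(diff_log2: float) -> float:
    """Signed fold-change convention: 2**d when >= 1, else -2**(-d)."""
    ratio = 2.0**diff_log2
    return ratio if ratio >= 1.0 else -1.0 / ratio


def generate_peptide_table(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format peptide intensity table plus its ground truth.

    Returns a DataFrame with columns (protein, peptide, confidence, sample,
    group, replicate, intensity) on the raw scale, and a :class:`GroundTruth`
    recording every protein's true signed fold-change, changed/unchanged
    label and spike-in flag.  The same config and seed always produce a
    bit-identical table.
    """
    rng = np.random.default_rng(config.seed)
    n_case, n_ctrl = config.n_samples_per_group
    samples = [f"AT{i + 1}" for i in range(n_case)] + [
        f"C{i + 1}" for i in range(n_ctrl)
    ]
    groups = ["AT"] * n_case + ["control"] * n_ctrl

    width = len(str(config.n_proteins))
    proteins = [f"P{i + 1:0{width}d}" for i in range(config.n_proteins)]
    n_changed = int(round(config.frac_changed * config.n_proteins))
    changed_idx = rng.choice(config.n_proteins, size=n_changed, replace=False)
    changed = np.zeros(config.n_proteins, dtype=bool)
    changed[changed_idx] = True

    magnitudes = np.asarray(config.effect_log2, dtype=float).ravel()
    delta = np.zeros(config.n_proteins)
    signs = rng.choice([-1.0, 1.0], size=n_changed)
    delta[changed_idx] = signs * rng.choice(magnitudes, size=n_changed)

    lo, hi = config._peptide_range()
    n_peps = rng.integers(lo, hi + 1, size=config.n_proteins)

    # spike-in appended after the random draws so the per-protein stream is
    # unaffected by toggling it
    proteins.append(SPIKEIN_ACCESSION)
    delta = np.append(delta, 0.0)
    changed = np.append(changed, False)
    n_peps = np.append(n_peps, max(2, lo))

    mu0, tau = config.baseline_log2
    baselines = rng.normal(mu0, tau, size=len(proteins))
    b_sample = rng.normal(0.0, config.sigma_sample, size=len(samples))

    rows = []
    for i, prot in enumerate(proteins):
        offsets = rng.normal(0.0, 0.5, size=n_peps[i])
        confidences = rng.uniform(90.0, 100.0, size=n_peps[i])
        for j in range(n_peps[i]):
            pep = f"{prot}_pep{j + 1}"
            for s, (samp, grp) in enumerate(zip(samples, groups)):
                mean_log2 = (
                    baselines[i]
                    + offsets[j]
                    + (delta[i] if grp == "AT" else 0.0)
                    + b_sample[s]
                )
                noise = rng.normal(0.0, config.sigma_rep, size=config.n_replicates)
                for r in range(config.n_replicates):
                    rows.append(
                        (
                            prot,
                            pep,
                            round(confidences[j], 2),
                            samp,
                            grp,
                            r + 1,
                            2.0 ** (mean_log2 + noise[r]),
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein",
            "peptide",
            "confidence",
            "sample",
            "group",
            "replicate",
            "intensity",
        ],
    )

    if config.missing_rate > 0:
        if config.informative_missing:
            # low-intensity cells are preferentially dropped
            q = table["intensity"].rank(pct=True).to_numpy()
            p_drop = config.missing_rate * 2.0 * (1.0 - q)
            keep = rng.random(len(table)) >= np.clip(p_drop, 0.0, 1.0)
        else:
            keep = rng.random(len(table)) >= config.missing_rate
        table = table.loc[keep].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "delta_log2": delta,
            "true_fold_change": [signed_fold_change(d) for d in delta],
            "changed": changed,
            "spikein": [p == SPIKEIN_ACCESSION for p in proteins],
        },
        index=pd.Index(proteins, name="protein"),
    )
    return table, GroundTruth(truth, config.sigma_sample, config.sigma_rep)


# ---------------------------------------------------------------------------
# raw feature runs for the alignment stage
# ---------------------------------------------------------------------------


@dataclass
class FeatureRun:
    """All detected features of one simulated LC/MS run."""

    run_id: str
    features: pd.DataFrame  # feature_id, mz, charge, rt_min, fragments, trace


def _triangle_trace(center: float, half_width: float, area: float, n: int = 9):
    """Symmetric triangular peak with exact trapezoidal area ``area``."""
    height = area / half_width
    t = np.linspace(center - half_width, center + half_width, n)
    y = height * (1.0 - np.abs(t - center) / half_width)
    y = np.clip(y, 0.0, None)
    return t, y


def generate_feature_runs(
    config: SyntheticConfig,
    n_runs: int = 3,
    n_features: int | None = None,
    mz_jitter: float = 0.1,
    rt_jitter: float = 0.1,
    rt_shifts: Sequence[float] | None = None,
    n_fragments: int = 6,
    peak_half_width: float = 0.25,
) -> tuple[list[FeatureRun], pd.DataFrame]:
    """Simulate per-run feature lists with known cross-run correspondence.

    Each ground-truth feature appears once per run with uniform m/z jitter in
    ``±mz_jitter``, uniform RT jitter in ``±rt_jitter``, a per-run global RT
    shift, and a triangular chromatographic trace whose trapezoidal area
    equals the feature's intended intensity.  Returns the runs and a
    correspondence table (feature_id, run, mz, rt) for recovery checks.
    """
    if n_runs <= 0:
        raise InvalidConfigError("n_runs must be positive")
    rng = np.random.default_rng(config.seed)
    if n_features is None:
        lo, hi = config._peptide_range()
        n_features = config.n_proteins * (lo + hi) // 2
    if rt_shifts is None:
        rt_shifts = rng.normal(0.0, 1.0, size=n_runs)
    elif len(rt_shifts) != n_runs:
        raise InvalidConfigError("rt_shifts must have one entry per run")

    mz = rng.uniform(400.0, 1200.0, size=n_features)
    charge = rng.choice([2, 3], size=n_features)
    rt = rng.uniform(10.0, 140.0, size=n_features)
    mu0, tau = config.baseline_log2
    area = 2.0 ** rng.normal(mu0, tau, size=n_features)
    fragments = [
        np.sort(rng.uniform(200.0, 1300.0, size=n_fragments)) for _ in range(n_features)
    ]

    runs = []
    records = []
    for k in range(n_runs):
        run_id = f"run{k + 1}"
        obs_mz = mz + rng.uniform(-mz_jitter, mz_jitter, size=n_features)
        obs_rt = (
            rt + rt_shifts[k] + rng.uniform(-rt_jitter, rt_jitter, size=n_features)
        )
        rows = []
        for f in range(n_features):
            t, y = _triangle_trace(obs_rt[f], peak_half_width, area[f])
            rows.append(
                (
                    f"F{f + 1}",
                    obs_mz[f],
                    int(charge[f]),
                    obs_rt[f],
                    tuple(fragments[f]),
                    t,
                    y,
                )
            )
            records.append((f"F{f + 1}", run_id, obs_mz[f], obs_rt[f]))
        runs.append(
            FeatureRun(
                run_id,
                pd.DataFrame(
                    rows,
                    columns=[
                        "feature_id",
                        "mz",
                        "charge",
                        "rt_min",
                        "fragments",
                        "trace_times",
                        "trace_intensities",
                    ],
                ),
            )
        )
    correspondence = pd.DataFrame(records, columns=["feature_id", "run", "mz", "rt"])
    return runs, correspondence


def write_run_tsv(run: FeatureRun, path) -> None:
    """Serialize one feature run to the on-disk TSV layout."""
    df = run.features.copy()
    df["fragment_mzs"] = [";".join(f"{m:.4f}" for m in fr) for fr in df["fragments"]]
    df["trace"] = [
        ";".join(f"{t:.4f}:{y:.4f}" for t, y in zip(ts, ys))
        for ts, ys in zip(df["trace_times"], df["trace_intensities"])
    ]
    df[["feature_id", "mz", "charge", "rt_min", "fragment_mzs", "trace"]].to_csv(
        path, sep="\t", index=False
    )


def read_run_tsv(path, run_id: str | None = None) -> FeatureRun:
    df = pd.read_csv(path, sep="\t")
    df["fragments"] = [
        tuple(float(x) for x in str(s).split(";")) if pd.notna(s) else ()
        for s in df["fragment_mzs"]
    ]
    times, intens = [], []
    for s in df["trace"]:
        pairs = [p.split(":") for p in str(s).split(";")]
        times.append(np.array([float(a) for a, _ in pairs]))
        intens.append(np.array([float(b) for _, b in pairs]))
    df["trace_times"] = times
    df["trace_intensities"] = intens
    name = run_id if run_id is not None else str(path)
    return FeatureRun(name, df)


# ---------------------------------------------------------------------------
# packaged fixtures transcribed from the study's printed tables
# ---------------------------------------------------------------------------


@dataclass
class DifferentialProtein:
    """One protein row of the printed differential-expression table."""

    protein_name: str
    priority: int
    accession: str
    peptides: list[tuple[str, float]]
    fold_change: float


@dataclass
class TableFixtures:
    design: pd.DataFrame  # study samples (age, gender, group)
    summary: pd.DataFrame  # printed per-priority identification summary
    proteins: list[DifferentialProtein]
    transitions: pd.DataFrame  # printed MRM transitions


def _fixture_path(name: str):
    return resources.files("lfqpipe.fixtures") / name


def _read_fixture(name: str, numeric: dict[str, bool]) -> pd.DataFrame:
    """Line-by-line TSV parse that reports the offending line on error."""
    path = _fixture_path(name)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise FixtureParseError(name, 1, "empty fixture")
    header = lines[0].split("\t")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FixtureParseError(
                name, i, f"expected {len(header)} fields, found {len(fields)}"
            )
        rows.append(fields)
    df = pd.DataFrame(rows, columns=header)
    for col, required in numeric.items():
        try:
            parsed = pd.to_numeric(df[col].replace("", np.nan))
        except (ValueError, KeyError) as exc:
            bad = 2
            for i, v in enumerate(df[col]):
                try:
                    if v != "":
                        float(v)
                except ValueError:
                    bad = i + 2
                    break
            raise FixtureParseError(name, bad, f"non-numeric value in {col!r}") from exc
        if required and parsed.isna().any():
            line = int(parsed.index[parsed.isna()][0]) + 2
            raise FixtureParseError(name, line, f"missing value in {col!r}")
        df[col] = parsed
    return df


def load_table_fixtures() -> TableFixtures:
    """Load the packaged transcriptions of the study's printed tables."""
    design = _read_fixture("study_samples.tsv", {"age": True})
    summary = _read_fixture(
        "identification_summary.tsv",
        {
            "n_proteins": True,
            "n_significant": True,
            "max_abs_fold_change": True,
            "median_cv_replicate": True,
            "median_cv_rep_sample": True,
        },
    )
    t3 = _read_fixture(
        "differential_proteins.tsv",
        {"priority": True, "confidence": True, "fold_change": True},
    )
    proteins = []
    for (name, prio, acc, fc), grp in t3.groupby(
        ["protein_name", "priority", "accession", "fold_change"], sort=False
    ):
        proteins.append(
            DifferentialProtein(
                protein_name=name,
                priority=int(prio),
                accession=acc,
                peptides=list(zip(grp["peptide"], grp["confidence"].astype(float))),
                fold_change=float(fc),
            )
        )
    transitions = _read_fixture(
        "mrm_transitions.tsv",
        {
            "precursor_charge": True,
            "precursor_mz": False,
            "product_index": False,
            "product_charge": False,
            "product_mz": False,
            "cys_ethanolyl": True,
            "detected": True,
            "observed_fold_change": False,
        },
    )
    return TableFixtures(design, summary, proteins, transitions)
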