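"""Cross-run feature matching and peak integration.

Detected LC/MS peaks are matched across runs only when all four criteria
hold simultaneously: precursor m/z within tolerance, identical charge
state, fragment-ion fingerprints similar enough (cosine over 0.5-Th
presence bins by default), and retention time within a 1-minute window
after a per-run global RT-shift correction.  The per-run shift is the
median RT difference over mutual-nearest m/z+charge anchor pairs — the
simplest correction that satisfies the windowed-matching contract on
desk-scale data; no warping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataValidationError, InvalidConfigError
from .synthetic import FeatureRun

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentConfig:
    mz_tolerance: float = 0.5  # Th; unit-resolution ion trap
    rt_window: float = 1.0  # min
    fragment_similarity_threshold: float = 0.7
    fragment_bin_width: float = 0.5  # Th

    def __post_init__(self):
        if min(self.mz_tolerance, self.rt_window, self.fragment_bin_width) <= 0:
            raise InvalidConfigError("tolerances must be positive")
        if not 0.0 <= self.fragment_similarity_threshold <= 1.0:
            raise InvalidConfigError("fragment similarity threshold must be in [0,1]")


@dataclass
class FeatureObservation:
    """One detected peak in one run."""

    run: str
    mz: float
    charge: int
    rt: float
    fragments: tuple[float, ...] = ()
    area: float = 0.0
    feature_id: str | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise DataValidationError(f"m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise DataValidationError(f"RT must be nonnegative, got {self.rt}")
        if self.charge < 1:
            raise DataValidationError(f"charge must be >= 1, got {self.charge}")


@dataclass
class AlignedFeatureGroup:
    consensus_mz: float
    charge: int
    consensus_rt: float
    members: dict[str, FeatureObservation] = field(default_factory=dict)

    @property
    def areas(self) -> dict[str, float]:
        return {run: obs.area for run, obs in self.members.items()}


def integrate_auc(times, intensities) -> float:
    """Trapezoidal area under a chromatographic trace."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 2:
        raise DataValidationError("a peak trace needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise DataValidationError("trace times must be strictly increasing")
    return float(np.trapezoid(y, t))


def fragment_similarity(
    frags_a, frags_b, bin_width: float = 0.5
) -> float:
    """Cosine similarity between binned fragment-m/z presence vectors.

    Two empty fingerprints are treated as vacuously similar (1.0); one
    empty vs one populated is maximally dissimilar (0.0).
    """
    a = {int(np.floor(m / bin_width)) for m in frags_a}
    b = {int(np.floor(m / bin_width)) for m in frags_b}
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / np.sqrt(len(a) * len(b))


def run_to_observations(run: FeatureRun) -> list[FeatureObservation]:
    """Convert a simulated/parsed run table into observation objects."""
    obs = []
    for row in run.features.itertuples(index=False):
        if "trace_times" in run.features.columns and row.trace_times is not None:
            area = integrate_auc(row.trace_times, row.trace_intensities)
        else:
            area = float(getattr(row, "area"))
        obs.append(
            FeatureObservation(
                run=run.run_id,
                mz=float(row.mz),
                charge=int(row.charge),
                rt=float(row.rt_min),
                fragments=tuple(row.fragments),
                area=area,
                feature_id=getattr(row, "feature_id", None),
            )
        )
    return obs


def estimate_rt_shift(
    run_obs: list[FeatureObservation],
    reference_obs: list[FeatureObservation],
    config: AlignmentConfig = AlignmentConfig(),
) -> float:
    """Median RT difference over mutual-nearest m/z+charge anchor pairs.

    Anchor pairs are observations that are each other's nearest m/z match
    at equal charge within the m/z tolerance.  Returns 0 for a run aligned
    against itself.
    """
    diffs = []
    by_charge: dict[int, list[FeatureObservation]] = {}
    for ref in reference_obs:
        by_charge.setdefault(ref.charge, []).append(ref)

    def nearest(target, pool):
        best, best_d = None, None
        for cand in pool:
            d = abs(cand.mz - target.mz)
            if d <= config.mz_tolerance and (best_d is None or d < best_d):
                best, best_d = cand, d
        return best

    run_by_charge: dict[int, list[FeatureObservation]] = {}
    for o in run_obs:
        run_by_charge.setdefault(o.charge, []).append(o)

    for o in run_obs:
        ref = nearest(o, by_charge.get(o.charge, []))
        if ref is None:
            continue
        back = nearest(ref, run_by_charge.get(ref.charge, []))
        if back is o:
            diffs.append(o.rt - ref.rt)
    if not diffs:
        run_name = run_obs[0].run if run_obs else "<empty>"
        raise AlignmentError(f"no anchor pairs between run {run_name!r} and reference")
    return float(np.median(diffs))


def match_features(
    runs: list[list[FeatureObservation]],
    config: AlignmentConfig = AlignmentConfig(),
    correct_shifts: bool = True,
) -> list[AlignedFeatureGroup]:
    """Greedily group observations across runs under the four criteria.

    The first run (by sorted run id) is the RT reference.  Observations are
    visited in descending area (ties: ascending m/z, then run id) so the
    output is invariant to input ordering; each observation joins at most
    one group, and unmatched observations become singleton groups.
    """
    flat: list[FeatureObservation] = [o for run in runs for o in run]
    if not flat:
        return []
    run_ids = sorted({o.run for o in flat})
    shifts = {run_ids[0]: 0.0}
    if correct_shifts and len(run_ids) > 1:
        by_run = {rid: [o for o in flat if o.run == rid] for rid in run_ids}
        ref = by_run[run_ids[0]]
        for rid in run_ids[1:]:
            shifts[rid] = estimate_rt_shift(by_run[rid], ref, config)
    else:
        shifts = {rid: 0.0 for rid in run_ids}

    corrected = {id(o): o.rt - shifts[o.run] for o in flat}
    order = sorted(flat, key=lambda o: (-o.area, o.mz, o.run))
    assigned: set[int] = set()
    groups: list[AlignedFeatureGroup] = []
    by_run_sorted = {
        rid: sorted(
            (o for o in flat if o.run == rid), key=lambda o: (o.mz, o.rt, -o.area)
        )
        for rid in run_ids
    }

    for seed in order:
        if id(seed) in assigned:
            continue
        assigned.add(id(seed))
        members = {seed.run: seed}
        seed_rt = corrected[id(seed)]
        for rid in run_ids:
            if rid == seed.run:
                continue
            best, best_key = None, None
            for cand in by_run_sorted[rid]:
                if id(cand) in assigned or cand.charge != seed.charge:
                    continue
                dmz = abs(cand.mz - seed.mz)
                if dmz > config.mz_tolerance:
                    continue
                if abs(corrected[id(cand)] - seed_rt) > config.rt_window:
                    continue
                sim = fragment_similarity(
                    cand.fragments, seed.fragments, config.fragment_bin_width
                )
                if sim < config.fragment_similarity_threshold:
                    continue
                key = (dmz, abs(corrected[id(cand)] - seed_rt))
                if best_key is None or key < best_key:
                    best, best_key = cand, key
            if best is not None:
                members[rid] = best
                assigned.add(id(best))
        group = AlignedFeatureGroup(
            consensus_mz=float(np.mean([m.mz for m in members.values()])),
            charge=seed.charge,
            consensus_rt=float(
                np.mean([corrected[id(m)] for m in members.values()])
            ),
            members=members,
        )
        groups.append(group)
    logger.info("matched %d observations into %d groups", len(flat), len(groups))
    return groups


def groups_to_peptide_table(
    groups: list[AlignedFeatureGroup],
    id_assignments: dict[int, tuple[str, str, float]],
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Build a long-format peptide table from aligned groups.

    ``id_assignments`` maps group index -> (peptide, protein, confidence);
    unidentified groups are dropped (with a logged count).  ``design`` maps
    each run to (sample, group, replicate); a run missing from the design is
    an error.  Runs in which a group has no member yield no row — missing,
    not zero.
    """
    required = {"run", "sample", "group", "replicate"}
    if not required.issubset(design.columns):
        raise DataValidationError(f"design must have columns {sorted(required)}")
    design_map = design.set_index("run")
    rows = []
    dropped = 0
    for gi, group in enumerate(groups):
        if gi not in id_assignments:
            dropped += 1
            continue
        peptide, protein, confidence = id_assignments[gi]
        for run, obs in group.members.items():
            if run not in design_map.index:
                raise DataValidationError(f"run {run!r} absent from design")
            d = design_map.loc[run]
            rows.append(
                (
                    protein,
                    peptide,
                    confidence,
                    d["sample"],
                    d["group"],
                    int(d["replicate"]),
                    obs.area,
                )
            )
    if dropped:
        logger.info("dropped %d unidentified aligned groups", dropped)
    return pd.DataFrame(
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
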