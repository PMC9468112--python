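"""Target registration error (TRE) metrics and the RAD-sweep experiment.

TRE is the Euclidean distance between a target landmark mapped by the
estimated vs. the true vertebra pose.  Two landmarks per vertebra are used
— the vertebral-body center and the left-pedicle center, both on a typical
pedicle-screw trajectory — and their TRE difference serves as a purely
translational indicator of rotational error.  Cohort summaries use medians,
linear-interpolation quartiles and Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .geometry import RigidPose, apply_pose
from .phantom import CaseConfig, make_test_case
from .register import RegistrationConfig, register_case

__all__ = [
    "compute_tre",
    "axis_decomposition",
    "rotational_error_indicator",
    "summarize",
    "rad_sweep_experiment",
    "RAD_PAIRS",
    "summarize_sweep",
]

# opposed C-arm angulation pairs realizing each rotation angle difference
RAD_PAIRS = {
    40: (-20.0, 20.0),
    56: (-28.0, 28.0),
    60: (-30.0, 30.0),
    64: (-32.0, 32.0),
    90: (-45.0, 45.0),
}


def compute_tre(est: RigidPose, truth: RigidPose, target) -> float:
    """Euclidean distance (mm) between the target point mapped by the
    estimated and by the true pose."""
    return float(np.linalg.norm(apply_pose(est, target) - apply_pose(truth, target)))


def axis_decomposition(est: RigidPose, truth: RigidPose, target) -> np.ndarray:
    """Signed per-axis error ``est(target) - truth(target)`` (mm) in patient
    axes; positive z is toward the dorsal side."""
    return apply_pose(est, target) - apply_pose(truth, target)


def rotational_error_indicator(est: RigidPose, truth: RigidPose, body_center, left_pedicle) -> float:
    """TRE(left pedicle) - TRE(body center), signed mm.  Zero for a purely
    translational registration error; non-zero indicates rotation."""
    return compute_tre(est, truth, left_pedicle) - compute_tre(est, truth, body_center)


def summarize(values, strata=None) -> dict:
    """Median / quartile / Tukey-fence summary of a sample.

    Quartiles use linear interpolation; outliers are exactly the values
    outside the fences.  With ``strata`` (one label per value) a per-stratum
    breakdown is added.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out_idx = np.nonzero((v < lo) | (v > hi))[0]
    summary = {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "lower_fence": float(lo),
        "upper_fence": float(hi),
        "outliers": v[out_idx].tolist(),
        "outlier_indices": out_idx.tolist(),
        "max": float(v.max()),
    }
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape[0] != v.size:
            raise ValueError("one stratum label per value required")
        summary["by_stratum"] = {
            str(s): summarize(v[strata == s]) for s in pd.unique(strata)
        }
    return summary


def evaluate_case(results, vertebrae) -> pd.DataFrame:
    """Per-vertebra TRE table for one registered case."""
    truth = {v.label: v for v in vertebrae}
    rows = []
    for r in results:
        v = truth[r.label]
        row = {
            "label": r.label,
            "captured": r.captured,
            "converged": r.converged,
            "tre_body_mm": np.nan,
            "tre_pedicle_mm": np.nan,
            "ex_mm": np.nan,
            "ey_mm": np.nan,
            "ez_mm": np.nan,
            "rot_indicator_mm": np.nan,
        }
        if r.pose is not None:
            est = r.pose
            tru = v.true_pose
            row["tre_body_mm"] = compute_tre(est, tru, v.body_center)
            row["tre_pedicle_mm"] = compute_tre(est, tru, v.left_pedicle)
            ex, ey, ez = axis_decomposition(est, tru, v.body_center)
            row.update(ex_mm=ex, ey_mm=ey, ez_mm=ez)
            row["rot_indicator_mm"] = rotational_error_indicator(
                est, tru, v.body_center, v.left_pedicle
            )
        rows.append(row)
    return pd.DataFrame(rows)


def rad_sweep_experiment(
    base_config: CaseConfig = CaseConfig(),
    rads=(40, 56, 60, 64, 90),
    replicates: int = 20,
    seed: int = 0,
    reg_config: RegistrationConfig = RegistrationConfig(),
    vertebra_subset=None,
) -> pd.DataFrame:
    """Full simulate -> register -> evaluate loop per RAD per replicate.

    ``vertebra_subset`` optionally restricts registration/evaluation to the
    listed labels (e.g. only the centered vertebra) to keep sweeps cheap.
    Failed registrations are kept in the table, flagged, never dropped.
    Deterministic in ``(configs, seed)``.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    ss = np.random.SeedSequence(seed)
    for rad in rads:
        if rad not in RAD_PAIRS:
            raise ValueError(f"unsupported RAD {rad}; choose from {sorted(RAD_PAIRS)}")
        pair = RAD_PAIRS[rad]
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            s_case, s_reg = [int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2)]
            config = replace(base_config, angulation_pair=pair)
            tc = make_test_case(config, seed=s_case)
            vertebrae = tc.vertebrae
            if vertebra_subset is not None:
                keep = set(vertebra_subset)
                tc.vertebrae = [v for v in vertebrae if v.label in keep]
            results, info = register_case(tc, reg_config, seed=s_reg)
            df = evaluate_case(results, tc.vertebrae)
            df.insert(0, "rad_deg", rad)
            df.insert(1, "replicate", rep)
            df["rad_estimated_deg"] = info["rad_deg"]
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-RAD median [IQR] summary of a sweep table (successful
    registrations only; failures are counted, not silently dropped)."""
    recs = []
    for rad, grp in table.groupby("rad_deg"):
        ok = grp[grp["captured"] & grp["converged"]]
        rec = {"rad_deg": rad, "n": len(grp), "n_registered": len(ok)}
        if len(ok):
            s = summarize(ok["tre_body_mm"].to_numpy())
            rec.update(
                median_tre_mm=s["median"],
                q1_mm=s["q1"],
                q3_mm=s["q3"],
                max_tre_mm=s["max"],
                n_outliers=len(s["outliers"]),
            )
            for ax in ("ex_mm", "ey_mm", "ez_mm"):
                rec[f"median_abs_{ax}"] = float(ok[ax].abs().median())
                rec[f"median_{ax}"] = float(ok[ax].median())
        recs.append(rec)
    return pd.DataFrame(recs).sort_values("rad_deg").reset_index(drop=True)
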