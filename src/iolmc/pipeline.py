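"""End-to-end orchestration and cohort/report I/O.

The cohort interchange format is a tidy CSV, one row per eye:

    patient_id, eye (OD/OS), lens_name, K_D, ACD_mm, AL_mm,
    implanted_power_D, postop_se_D, preop_se_D (optional)

Reports mirror the clinical-study layout: a clinical-analog table
(per formula, per lens group: MedAE with IQR, MAE with SD, mean error
with range, threshold counts/percentages, Mann–Whitney and chi-square
comparisons) and a Monte Carlo table (one row per replicate per formula
per group, plus an aggregate block). Dioptric values are carried at full
precision; report formatting rounds to 2 decimals (1 for percentages).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import formula_engine as fe
from . import monte_carlo as mc
from . import outcome_statistics as ostat
from .types import ACD_BOUNDS, AL_BOUNDS, EyeBiometry, FormulaName, IOLModel, K_BOUNDS

MANDATORY_COLUMNS = [
    "patient_id", "eye", "lens_name", "K_D", "ACD_mm", "AL_mm",
    "implanted_power_D", "postop_se_D",
]
OPTIONAL_COLUMNS = ["preop_se_D"]
_BOUNDS = {"K_D": K_BOUNDS, "ACD_mm": ACD_BOUNDS, "AL_mm": AL_BOUNDS}


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort CSV (tolerates CRLF line endings)."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing mandatory columns: {missing}")
    unknown = [c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        warnings.warn(f"cohort file {path} has unknown columns: {unknown}")
    for col, (lo, hi) in _BOUNDS.items():
        bad = df.index[(df[col] < lo) | (df[col] > hi)].tolist()
        if bad:
            raise ValueError(
                f"{col} outside [{lo}, {hi}] in rows {[i + 2 for i in bad]} "
                f"of {path} (1-based, incl. header)"
            )
    bad_eye = df.index[~df["eye"].isin(["OD", "OS"])].tolist()
    if bad_eye:
        raise ValueError(f"eye must be OD/OS; bad rows {[i + 2 for i in bad_eye]}")
    return df


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort CSV at 6-decimal precision (lossless round trip)."""
    df.to_csv(path, index=False, float_format="%.6f")


def cohort_eyes(df: pd.DataFrame, lens_name: Optional[str] = None) -> List[EyeBiometry]:
    """Convert cohort rows to EyeBiometry, optionally one lens group."""
    if lens_name is not None:
        df = df[df["lens_name"] == lens_name]
    return [
        EyeBiometry(
            patient_id=str(r.patient_id),
            laterality=r.eye,
            K=r.K_D,
            ACD=r.ACD_mm,
            AL=r.AL_mm,
            implanted_power=r.implanted_power_D,
            postop_se=r.postop_se_D,
        )
        for r in df.itertuples()
    ]


def clinical_errors(
    df: pd.DataFrame, formula: FormulaName, lens: IOLModel
) -> np.ndarray:
    """Signed prediction errors for a lens group at implanted powers."""
    eyes = cohort_eyes(df, lens.name)
    return np.array(
        [
            ostat.prediction_error(
                e.postop_se,
                fe.predict_refraction(formula, e, lens, e.implanted_power),
            )
            for e in eyes
        ]
    )


def _degenerate(x: np.ndarray, y: np.ndarray) -> bool:
    return np.ptp(np.abs(x)) == 0 and np.ptp(np.abs(y)) == 0


def run_clinical_analog(
    df: pd.DataFrame,
    lenses: Sequence[IOLModel],
    formulas: Sequence[FormulaName] = (FormulaName.HAIGIS, FormulaName.SRKT),
    thresholds: Sequence[float] = ostat.DEFAULT_THRESHOLDS,
) -> Dict[str, object]:
    """Clinical-analog outcome report (two-group comparison per formula).

    Returns ``{"groups": tidy DataFrame, "comparisons": tidy DataFrame,
    "errors": {(formula, lens): per-eye errors}}``. Comparison p-values
    on the 2x2 threshold splits use uncorrected Pearson chi-square, with
    Yates alongside; degenerate inputs (all |errors| identical) flag the
    p-values as NaN rather than failing.
    """
    if len(lenses) != 2:
        raise ValueError("clinical analog compares exactly two lens groups")
    group_rows, comp_rows, errors = [], [], {}
    for formula in formulas:
        per_lens = {}
        for lens in lenses:
            errs = clinical_errors(df, formula, lens)
            if errs.size == 0:
                raise ValueError(f"no eyes for lens {lens.name!r}")
            per_lens[lens.name] = errs
            errors[(formula.value, lens.name)] = errs
            s = ostat.summarize(errs, thresholds)
            row = {
                "formula": formula.value,
                "lens": lens.name,
                "n": s.n,
                "medae_D": s.medae,
                "iqr_lo_D": s.iqr[0],
                "iqr_hi_D": s.iqr[1],
                "mae_D": s.mae,
                "mae_sd_D": float(np.std(np.abs(errs), ddof=1)) if s.n > 1 else 0.0,
                "mean_error_D": s.mean_error,
                "range_lo_D": s.range[0],
                "range_hi_D": s.range[1],
            }
            for t in thresholds:
                row[f"n_within_{t:.2f}"] = s.counts_within[float(t)]
                row[f"pct_within_{t:.2f}"] = s.pct_within[float(t)]
            row["n_over_1.00"] = s.n - s.counts_within[1.00]
            row["pct_over_1.00"] = 100.0 - s.pct_within[1.00]
            group_rows.append(row)
        x, y = (per_lens[lens.name] for lens in lenses)
        comp = {"formula": formula.value, "degenerate": bool(_degenerate(x, y))}
        if comp["degenerate"]:
            comp.update(
                mannwhitney_U=np.nan, mannwhitney_p=np.nan,
                chi2_050=np.nan, chi2_050_p=np.nan, chi2_050_p_yates=np.nan,
                chi2_025=np.nan, chi2_025_p=np.nan,
            )
        else:
            U, p = ostat.mann_whitney(np.abs(x), np.abs(y))
            comp.update(mannwhitney_U=U, mannwhitney_p=p)
            for t, tag in ((0.50, "050"), (0.25, "025")):
                a = int(np.sum(np.abs(x) <= t)); b = x.size - a
                c = int(np.sum(np.abs(y) <= t)); d = y.size - c
                try:
                    stat, pv = ostat.chi_square_2x2(a, b, c, d)
                    comp[f"chi2_{tag}"] = stat
                    comp[f"chi2_{tag}_p"] = pv
                    if tag == "050":
                        comp["chi2_050_p_yates"] = ostat.chi_square_2x2(
                            a, b, c, d, yates=True
                        )[1]
                except ValueError:
                    comp[f"chi2_{tag}"] = np.nan
                    comp[f"chi2_{tag}_p"] = np.nan
                    if tag == "050":
                        comp["chi2_050_p_yates"] = np.nan
        comp_rows.append(comp)
    return {
        "groups": pd.DataFrame(group_rows),
        "comparisons": pd.DataFrame(comp_rows),
        "errors": errors,
    }


def run_mc_study(
    df: pd.DataFrame,
    lenses: Sequence[IOLModel],
    formulas: Sequence[FormulaName] = (FormulaName.HAIGIS, FormulaName.SRKT),
    n_replicates: int = 10,
    seed: int = 0,
    thresholds: Sequence[float] = ostat.DEFAULT_THRESHOLDS,
) -> Dict[str, object]:
    """Monte Carlo tolerance study across formulas and lens groups.

    Each lens group is perturbed at its own manufacturing SD. Returns a
    per-replicate tidy table (n_replicates x formulas x groups rows), a
    per-replicate comparison table, and the aggregate blocks.
    """
    rep_rows, comp_rows = [], []
    aggregates: Dict[str, object] = {}
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(formulas) * len(lenses))
    idx = 0
    results: Dict[Tuple[str, str], mc.SimulationResult] = {}
    for formula in formulas:
        for lens in lenses:
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            cfg = mc.SimulationConfig(
                formula=formula,
                tolerance_sd=lens.tolerance_sd,
                n_replicates=n_replicates,
                seed=child_seed,
                thresholds=tuple(thresholds),
            )
            res = mc.run_study(cohort_eyes(df, lens.name), cfg, lens)
            results[(formula.value, lens.name)] = res
            aggregates[f"{formula.value}/{lens.name}"] = res.aggregate
            for r, s in enumerate(res.replicates, start=1):
                row = {
                    "formula": formula.value,
                    "lens": lens.name,
                    "tolerance_sd_D": lens.tolerance_sd,
                    "replicate": r,
                    "n": s.n,
                    "medae_D": s.medae,
                    "iqr_lo_D": s.iqr[0],
                    "iqr_hi_D": s.iqr[1],
                    "mae_D": s.mae,
                }
                for t in thresholds:
                    row[f"n_within_{t:.2f}"] = s.counts_within[float(t)]
                    row[f"pct_within_{t:.2f}"] = s.pct_within[float(t)]
                rep_rows.append(row)
    for formula in formulas:
        a_res = results[(formula.value, lenses[0].name)]
        b_res = results[(formula.value, lenses[1].name)]
        for r in range(n_replicates):
            x, y = a_res.errors[r], b_res.errors[r]
            comp = {
                "formula": formula.value,
                "replicate": r + 1,
                "degenerate": bool(_degenerate(x, y)),
            }
            if not comp["degenerate"]:
                U, p = ostat.mann_whitney(np.abs(x), np.abs(y))
                a = int(np.sum(np.abs(x) <= 0.25)); b = x.size - a
                c = int(np.sum(np.abs(y) <= 0.25)); d = y.size - c
                comp.update(mannwhitney_U=U, mannwhitney_p=p)
                try:
                    stat, pv = ostat.chi_square_2x2(a, b, c, d)
                except ValueError:
                    stat, pv = np.nan, np.nan
                comp.update(chi2_025=stat, chi2_025_p=pv)
            else:
                comp.update(
                    mannwhitney_U=np.nan, mannwhitney_p=np.nan,
                    chi2_025=np.nan, chi2_025_p=np.nan,
                )
            comp_rows.append(comp)
    return {
        "replicates": pd.DataFrame(rep_rows),
        "comparisons": pd.DataFrame(comp_rows),
        "aggregates": aggregates,
        "seed": seed,
        "config_hash": config_hash(
            {
                "formulas": [f.value for f in formulas],
                "lenses": [(l.name, l.tolerance_sd) for l in lenses],
                "n_replicates": n_replicates,
                "seed": seed,
                "thresholds": list(thresholds),
            }
        ),
    }


def config_hash(obj: object) -> str:
    """Short stable hash of a JSON-serializable config, for provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def format_groups_table(groups: pd.DataFrame) -> pd.DataFrame:
    """Report-ready view: diopters at 2 decimals, percentages at 1."""
    out = groups.copy()
    for c in out.columns:
        if c.endswith("_D"):
            out[c] = out[c].round(2)
        elif c.startswith("pct_"):
            out[c] = out[c].round(1)
    return out
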