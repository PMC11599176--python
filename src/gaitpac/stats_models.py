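"""Inferential layer: repeat averaging, mixed-effects window / group
contrasts, clinical-score correlation and group score comparisons.

Model: a linear mixed-effects model with a random intercept per patient
(the smallest structure honouring repeated measures).  The fixed-effect
test uses the REML estimate and standard error from statsmodels'
``MixedLM`` with a t reference on containment degrees of freedom:
``n_patients - 1`` for within-patient (window) contrasts and
``n_patients - 2`` for between-patient (group) contrasts.  On a balanced
paired design this is exactly the paired t-test; a normal reference would
be anticonservative at cohort sizes of ~10 patients.

C3 and C4 are averaged into one value per trial and window before
modelling ("the mean MI for C3 and C4"); pass ``channels_as_factor=True``
to keep them as separate rows instead.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SingularFitError

__all__ = [
    "ContrastResult",
    "build_frame",
    "average_repeats",
    "lmm_window_contrast",
    "lmm_group_contrast",
    "correlate_scores",
    "compare_clinical",
]

FRAME_COLUMNS = ["patient_id", "trial_id", "channel", "window_start_s",
                 "value", "fog_flag", "UPDRS3", "PIGD", "BBS"]


@dataclass
class ContrastResult:
    estimate: float
    se: float
    p: float
    df: float
    group: str
    contrast: str
    n_rows: int
    n_patients: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")


def build_frame(series_list, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble an analysis frame from MISeries / PSD window results.

    Each element contributes one row per window with its patient, trial,
    channel and FOG metadata; clinical scores are joined from the cohort
    table when given.
    """
    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.values):
            rows.append({
                "patient_id": s.meta.get("patient_id"),
                "trial_id": s.meta.get("trial_id"),
                "channel": s.meta.get("channel"),
                "window_start_s": float(t),
                "value": float(v),
                "fog_flag": bool(s.meta.get("fog", False)),
            })
    frame = pd.DataFrame(rows)
    if cohort is not None:
        frame = frame.merge(
            cohort[["trial_id", "UPDRS3", "PIGD", "BBS"]], on="trial_id",
            how="left")
    for col in FRAME_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[FRAME_COLUMNS]


def average_repeats(frame: pd.DataFrame,
                    keys=("patient_id", "trial_id", "channel", "window_start_s")
                    ) -> pd.DataFrame:
    """Collapse repeated measurements sharing (patient, condition, channel,
    window) to their mean, so patients with more recordings do not weigh
    more.  Non-key columns are averaged (numeric) or take the first value."""
    keys = [k for k in keys if k in frame.columns]
    agg = {}
    for col in frame.columns:
        if col in keys:
            continue
        agg[col] = "mean" if pd.api.types.is_numeric_dtype(frame[col]) else "first"
    out = frame.groupby(list(keys), as_index=False, sort=False).agg(agg)
    return out[[c for c in frame.columns]]


def _average_channels(frame: pd.DataFrame, channels) -> pd.DataFrame:
    sub = frame[frame["channel"].isin(list(channels))]
    keys = ["patient_id", "trial_id", "window_start_s"]
    agg = {c: ("mean" if pd.api.types.is_numeric_dtype(sub[c]) else "first")
           for c in sub.columns if c not in keys + ["channel"]}
    out = sub.groupby(keys, as_index=False, sort=False).agg(agg)
    out["channel"] = "+".join(channels)
    return out


def _fit_mixedlm(data: pd.DataFrame, fixed: str, df: float
                 ) -> tuple[float, float, float, bool]:
    """Random-intercept-per-patient fit; returns (estimate, se, p, converged)
    for the single fixed-effect contrast named by the formula term."""
    from statsmodels.formula.api import mixedlm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        # patient variance on the boundary (zero) is an expected outcome
        # under null cohorts, not a failure
        warnings.filterwarnings("ignore",
                                message="Random effects covariance is singular")
        try:
            res = mixedlm(f"value ~ {fixed}", data, groups=data["patient_id"]
                          ).fit(reml=True)
        except np.linalg.LinAlgError as exc:
            raise SingularFitError(f"mixed-model fit singular: {exc}") from exc
        if not res.converged:
            converged = False
    name = [p for p in res.fe_params.index if p != "Intercept"]
    if len(name) != 1:
        raise ValueError("expected exactly one fixed-effect contrast")
    est = float(res.fe_params[name[0]])
    se = float(res.bse_fe[name[0]])
    if not np.isfinite(se) or se == 0:
        raise SingularFitError("fixed-effect standard error undefined")
    tval = est / se
    p = float(2 * stats.t.sf(abs(tval), df))
    return est, se, p, converged


def lmm_window_contrast(frame: pd.DataFrame, fog_group: bool,
                        windows: tuple[float, float] = (-20.0, 0.0),
                        channels=("C3", "C4"),
                        channels_as_factor: bool = False) -> ContrastResult:
    """Within-group comparison of band-averaged MI (or beta power) between
    two gait-aligned windows, random intercept per patient."""
    sub = frame[frame["fog_flag"] == bool(fog_group)]
    if not channels_as_factor:
        sub = _average_channels(sub, channels)
    else:
        sub = sub[sub["channel"].isin(list(channels))]
    sub = sub[sub["window_start_s"].isin(list(windows))].copy()
    n_pat = sub["patient_id"].nunique()
    if n_pat < 2:
        raise ValueError("window contrast needs >= 2 patients in the group")
    have_both = sub.groupby("patient_id")["window_start_s"].nunique()
    if (have_both >= 2).sum() < 2:
        raise ValueError("both windows must be present for >= 2 patients")
    sub["window"] = pd.Categorical(sub["window_start_s"], categories=list(windows))
    est, se, p, conv = _fit_mixedlm(sub, "C(window)", df=n_pat - 1)
    return ContrastResult(estimate=est, se=se, p=p, df=n_pat - 1,
                          group="FOG+" if fog_group else "FOG-",
                          contrast=f"window {windows[1]} vs {windows[0]} s",
                          n_rows=len(sub), n_patients=n_pat, converged=conv)


def lmm_group_contrast(frame: pd.DataFrame,
                       windows: tuple[float, ...] = (0.0, 10.0),
                       channels=("C3", "C4")) -> ContrastResult:
    """FOG+ vs FOG- comparison of MI over the first 20 s of walking
    (windows [0,10] and [10,20]), random intercept per patient."""
    sub = _average_channels(frame, channels)
    sub = sub[sub["window_start_s"].isin(list(windows))].copy()
    groups = sub["fog_flag"].unique()
    if len(groups) < 2:
        raise ValueError("both FOG groups must be present")
    n_pat = sub["patient_id"].nunique()
    per_group = sub.groupby("fog_flag")["patient_id"].nunique()
    if per_group.min() < 2:
        raise SingularFitError(
            "fewer than 2 patients in a group: between-group variance "
            "inseparable from the patient random effect")
    sub["fog"] = sub["fog_flag"].astype(int)
    est, se, p, conv = _fit_mixedlm(sub, "fog", df=n_pat - 2)
    return ContrastResult(estimate=est, se=se, p=p, df=n_pat - 2,
                          group="FOG+ vs FOG-",
                          contrast=f"windows {windows} s", n_rows=len(sub),
                          n_patients=n_pat, converged=conv)


def correlate_scores(frame: pd.DataFrame, window_start: float = 20.0,
                     score: str = "PIGD", channels=("C3", "C4"),
                     method: str = "pearson") -> tuple[float, float]:
    """Correlation between the C3/C4-averaged MI in the window starting at
    ``window_start`` s and a clinical score; returns (r, two-sided p)."""
    sub = _average_channels(frame, channels)
    sub = sub[sub["window_start_s"] == window_start]
    sub = sub.dropna(subset=["value", score])
    if len(sub) < 3:
        raise ValueError("need >= 3 paired values for a correlation")
    x = sub["value"].to_numpy(float)
    y = sub[score].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in MI or score; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def compare_clinical(group_a, group_b, test: str = "mann_whitney") -> float:
    """Two-sided p comparing a clinical score between groups.

    Mann-Whitney uses mid-ranks for ties without continuity correction
    (identical groups give p = 1); ``test="t_test"`` is Welch's t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mann_whitney":
        if a.size == b.size == 1:
            return 1.0   # no power in 1 vs 1
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 use_continuity=False, method="auto")
        return float(min(res.pvalue, 1.0))
    if test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue)
    raise ValueError("test must be 'mann_whitney' or 't_test'")
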