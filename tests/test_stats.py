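"""Mixed-model contrasts, correlations and clinical comparisons."""
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import gaitpac.stats_models as sm
from gaitpac import load_table2
from gaitpac.exceptions import SingularFitError


def _frame(rows):
    df = pd.DataFrame(rows)
    for col in sm.FRAME_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[sm.FRAME_COLUMNS]


def _paired_frame(n_patients, delta, seed, fog=False, noise=1.0):
    """Balanced two-window frame: value = patient effect + window delta."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        base = rng.normal(0, 1)
        for w, shift in ((-20.0, 0.0), (0.0, delta)):
            for ch in ("C3", "C4"):
                rows.append({"patient_id": f"P{p}", "trial_id": f"T{p}",
                             "channel": ch, "window_start_s": w,
                             "value": base + shift + rng.normal(0, noise),
                             "fog_flag": fog})
    return _frame(rows)


# ---------------------------------------------------------------------------
# average_repeats
# ---------------------------------------------------------------------------

def test_average_repeats_collapses_duplicates_to_mean():
    f = _frame([
        {"patient_id": "P1", "trial_id": "T1", "channel": "C3",
         "window_start_s": 0.0, "value": 2.0, "fog_flag": False},
        {"patient_id": "P1", "trial_id": "T1", "channel": "C3",
         "window_start_s": 0.0, "value": 4.0, "fog_flag": False},
    ])
    out = sm.average_repeats(f)
    assert len(out) == 1
    assert out["value"].iloc[0] == pytest.approx(3.0)


def test_average_repeats_identity_on_unique_keys():
    f = _paired_frame(3, 1.0, seed=0)
    out = sm.average_repeats(f)
    assert len(out) == len(f)
    assert sorted(out["value"]) == pytest.approx(sorted(f["value"]))


# ---------------------------------------------------------------------------
# window contrast
# ---------------------------------------------------------------------------

def test_identical_windows_give_zero_estimate():
    f = _paired_frame(4, 0.0, seed=1, noise=0.0)
    res = sm.lmm_window_contrast(f, False, windows=(-20.0, 0.0))
    assert res.estimate == pytest.approx(0.0, abs=1e-10)


def test_window_contrast_requires_two_patients():
    f = _paired_frame(1, 1.0, seed=2)
    with pytest.raises(ValueError):
        sm.lmm_window_contrast(f, False, windows=(-20.0, 0.0))


def test_window_contrast_detects_large_shift():
    f = _paired_frame(8, 3.0, seed=3, noise=0.5)
    res = sm.lmm_window_contrast(f, False, windows=(-20.0, 0.0))
    assert res.p < 0.01
    assert res.estimate == pytest.approx(3.0, abs=1.0)
    assert res.df == 7


def test_p_invariant_to_row_order_and_affine_rescale():
    f = _paired_frame(6, 1.5, seed=4)
    res0 = sm.lmm_window_contrast(f, False, windows=(-20.0, 0.0))
    shuffled = f.sample(frac=1.0, random_state=9).reset_index(drop=True)
    res1 = sm.lmm_window_contrast(shuffled, False, windows=(-20.0, 0.0))
    rescaled = f.copy()
    rescaled["value"] = 3.0 * rescaled["value"] + 7.0
    res2 = sm.lmm_window_contrast(rescaled, False, windows=(-20.0, 0.0))
    assert res1.p == pytest.approx(res0.p, abs=1e-6)
    assert res2.p == pytest.approx(res0.p, abs=1e-6)
    assert res2.estimate == pytest.approx(3.0 * res0.estimate, rel=1e-6)


def test_duplicated_rows_average_back_to_original_contrast():
    # balanced design: averaging repeats reproduces the unduplicated fit
    f = _paired_frame(6, 2.0, seed=5)
    doubled = pd.concat([f, f], ignore_index=True)
    res0 = sm.lmm_window_contrast(f, False, windows=(-20.0, 0.0))
    res1 = sm.lmm_window_contrast(sm.average_repeats(doubled), False,
                                  windows=(-20.0, 0.0))
    assert res1.estimate == pytest.approx(res0.estimate, abs=1e-8)
    assert res1.p == pytest.approx(res0.p, abs=1e-6)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available for the cross-check")
def test_window_contrast_matches_lmer_oracle(tmp_path):
    """Independent oracle: lme4/lmerTest on the same balanced frame gives
    the same estimate, SE and (Satterthwaite == containment here) p."""
    f = _paired_frame(8, 1.0, seed=6)
    sub = f[f["channel"] == "C3"].copy()   # keep one channel: simplest model
    res = sm.lmm_window_contrast(sub, False, windows=(-20.0, 0.0),
                                 channels=("C3",))
    csv = tmp_path / "frame.csv"
    sub.to_csv(csv, index=False)
    script = f"""
    suppressMessages(library(lmerTest))
    d <- read.csv("{csv}")
    d$window <- factor(d$window_start_s)
    m <- lmer(value ~ window + (1|patient_id), data=d, REML=TRUE)
    s <- summary(m)$coefficients
    cat(s[2,1], s[2,2], s[2,5], sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    est_r, se_r, p_r = map(float, out.stdout.strip().split())
    assert res.estimate == pytest.approx(est_r, rel=1e-4)
    assert res.se == pytest.approx(se_r, rel=1e-3)
    assert res.p == pytest.approx(p_r, rel=1e-2, abs=1e-4)


# ---------------------------------------------------------------------------
# group contrast
# ---------------------------------------------------------------------------

def test_group_contrast_requires_both_groups():
    f = _paired_frame(4, 1.0, seed=7, fog=False)
    f["window_start_s"] = f["window_start_s"].map({-20.0: 0.0, 0.0: 10.0})
    with pytest.raises(ValueError):
        sm.lmm_group_contrast(f)


def test_single_patient_per_group_is_reported_not_silent():
    rows = []
    for p, fog in (("P1", False), ("P2", True)):
        for w in (0.0, 10.0):
            for ch in ("C3", "C4"):
                rows.append({"patient_id": p, "trial_id": p, "channel": ch,
                             "window_start_s": w, "value": float(fog),
                             "fog_flag": fog})
    with pytest.raises(SingularFitError):
        sm.lmm_group_contrast(_frame(rows))


def test_group_contrast_detects_separation():
    rng = np.random.default_rng(8)
    rows = []
    for p in range(10):
        fog = p < 5
        base = rng.normal(0, 0.3)
        for w in (0.0, 10.0):
            for ch in ("C3", "C4"):
                rows.append({"patient_id": f"P{p}", "trial_id": f"T{p}",
                             "channel": ch, "window_start_s": w,
                             "value": base + 3.0 * fog + rng.normal(0, 0.3),
                             "fog_flag": fog})
    res = sm.lmm_group_contrast(_frame(rows))
    assert res.p < 0.01 and res.estimate > 0


# ---------------------------------------------------------------------------
# correlations and clinical comparisons
# ---------------------------------------------------------------------------

def test_perfectly_linear_score_gives_r_one():
    rng = np.random.default_rng(9)
    rows = []
    for p in range(6):
        v = rng.normal(0, 1)
        for ch in ("C3", "C4"):
            rows.append({"patient_id": f"P{p}", "trial_id": f"T{p}",
                         "channel": ch, "window_start_s": 20.0, "value": v,
                         "fog_flag": False, "PIGD": 2.0 * v + 5.0})
    r, p = sm.correlate_scores(_frame(rows), window_start=20.0, score="PIGD")
    assert r == pytest.approx(1.0, abs=1e-12)


def test_correlation_error_contracts():
    rows = [{"patient_id": f"P{p}", "trial_id": f"T{p}", "channel": "C3",
             "window_start_s": 20.0, "value": 1.0, "fog_flag": False,
             "PIGD": p} for p in range(5)]
    with pytest.raises(ValueError, match="variance"):
        sm.correlate_scores(_frame(rows), score="PIGD")
    with pytest.raises(ValueError, match=">= 3"):
        sm.correlate_scores(_frame(rows[:2]), score="PIGD")


def test_correlation_null_type_one_rate():
    """Score independent of the measured value: ~5% of 200 seeds reject."""
    rejections = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        rows = [{"patient_id": f"P{p}", "trial_id": f"T{p}", "channel": "C3",
                 "window_start_s": 20.0, "value": rng.normal(0, 1),
                 "fog_flag": False, "PIGD": rng.normal(10, 3)}
                for p in range(12)]
        _, p_val = sm.correlate_scores(_frame(rows), score="PIGD")
        rejections += p_val < 0.05
    assert 0.05 * 200 - 3 * np.sqrt(200 * 0.05 * 0.95) <= rejections \
        <= 0.05 * 200 + 3 * np.sqrt(200 * 0.05 * 0.95)


def test_mann_whitney_identical_groups_p_one():
    assert sm.compare_clinical([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_one_vs_one_has_no_power():
    assert sm.compare_clinical([5.0], [7.0]) == pytest.approx(1.0)


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        sm.compare_clinical([], [1.0])


def test_published_pigd_split_is_significant():
    """PIGD from the shipped trial table, included trials, split by FOG."""
    meta = load_table2()
    inc = meta[meta["include_flag"]]
    pos = inc.loc[inc.fog_flag, "PIGD"]
    neg = inc.loc[~inc.fog_flag, "PIGD"]
    p = sm.compare_clinical(pos, neg)
    assert p == pytest.approx(0.0123, abs=2e-3)
    assert p < 0.05
    assert sm.compare_clinical(pos, neg, test="t_test") < 0.05
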