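"""Epoch feature extraction and descriptive statistics.

Each labeled epoch is reduced to four scalars: the median of the absolute
values of COPv, shear force (SH), head acceleration (HA) and time-to-boundary
(TTB) over a −300..−50 ms window before the epoch center (the window stops at
−50 ms, on the order of vestibular afferent latencies, so that only signal
preceding the cortical response is used).  The median is the default
summary — robust to outliers — with the mean available by option.

Descriptive statistics mirror the screening a combined classifier needs:
per-feature Shapiro–Wilk normality p-values, the six pairwise Pearson
correlations (with a |r| >= 0.7 collinearity flag), and Instability-vs-Control
contrasts (group means ± SE, Welch t-tests, pooled-SD Cohen's d).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .n1 import LabeledEpoch

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureVector",
    "compute_features",
    "feature_table",
    "cohens_d",
    "correlation_screen",
    "class_contrast",
]

DEFAULT_FEATURE_WINDOW_MS = (-300.0, -50.0)
FEATURE_COLUMNS = ["med_abs_copv", "med_abs_sh", "med_abs_ha", "med_abs_ttb"]
_CHANNEL_FOR = {"med_abs_copv": "copv", "med_abs_sh": "shear",
                "med_abs_ha": "head_acc", "med_abs_ttb": "ttb"}
STRONG_R = 0.7


@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    label: int
    med_abs_copv: float
    med_abs_sh: float
    med_abs_ha: float
    med_abs_ttb: float


def compute_features(epoch: LabeledEpoch,
                     window_ms: tuple = DEFAULT_FEATURE_WINDOW_MS,
                     summary: str = "median") -> FeatureVector:
    """Median (or mean) of |samples| per channel over the closed window
    ``window_ms`` relative to the epoch center."""
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    agg = np.median if summary == "median" else np.mean
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    vals = {}
    for col, ch in _CHANNEL_FOR.items():
        t_rel, x = epoch.traces[ch]
        m = (t_rel >= lo - 1e-9) & (t_rel <= hi + 1e-9)
        if not np.any(m):
            raise ValueError(f"channel '{ch}' has no samples in the feature window")
        vals[col] = float(agg(np.abs(x[m])))
    return FeatureVector(subject_id=epoch.subject_id, label=epoch.label, **vals)


def feature_table(epochs: list, window_ms: tuple = DEFAULT_FEATURE_WINDOW_MS,
                  summary: str = "median") -> pd.DataFrame:
    """One row per epoch: ``subject_id, label`` plus the four features."""
    rows = [compute_features(e, window_ms, summary) for e in epochs]
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["subject_id", "label"] + FEATURE_COLUMNS)


def cohens_d(a, b) -> float:
    """Cohen's d with the (n_a−1, n_b−1)-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return float((a.mean() - b.mean()) / pooled)


def correlation_screen(features: pd.DataFrame) -> dict:
    """Shapiro–Wilk p per feature and the six pairwise Pearson coefficients,
    flagging strong (|r| >= 0.7) pairs; constant features are reported as
    undefined rather than raising."""
    if len(features) < 3:
        raise ValueError("need at least 3 feature vectors")
    shapiro_p = {}
    for col in FEATURE_COLUMNS:
        x = features[col].to_numpy()
        shapiro_p[col] = float(sps.shapiro(x).pvalue) if x.std() > 0 else float("nan")
    pearson = {}
    flags = []
    for c1, c2 in combinations(FEATURE_COLUMNS, 2):
        x, y = features[c1].to_numpy(), features[c2].to_numpy()
        key = f"{c1}~{c2}"
        if x.std() == 0 or y.std() == 0:
            pearson[key] = {"r": None, "p": None, "note": "constant feature"}
            continue
        r, p = sps.pearsonr(x, y)
        pearson[key] = {"r": float(r), "p": float(p)}
        if abs(r) >= STRONG_R:
            flags.append(key)
    return {"shapiro_p": shapiro_p, "pearson": pearson, "strong_pairs": flags}


def class_contrast(features: pd.DataFrame) -> dict:
    """Instability-vs-Control contrast per feature: group means ± SE, Welch
    two-sample t-test, and pooled-SD Cohen's d (class 1 minus class 0)."""
    g1 = features[features["label"] == 1]
    g0 = features[features["label"] == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("both classes must be present with n >= 2")
    out = {}
    for col in FEATURE_COLUMNS:
        a, b = g1[col].to_numpy(), g0[col].to_numpy()
        t, p = sps.ttest_ind(a, b, equal_var=False)
        out[col] = {
            "instability_mean": float(a.mean()),
            "instability_se": float(a.std(ddof=1) / np.sqrt(a.size)),
            "control_mean": float(b.mean()),
            "control_se": float(b.std(ddof=1) / np.sqrt(b.size)),
            "cohens_d": cohens_d(a, b),
            "welch_p": float(p),
        }
    return out
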