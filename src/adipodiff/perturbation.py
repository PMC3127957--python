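"""Perturbation screen: knockout vs wild-type profile distances, and qPCR
validation by the delta-delta-Ct method.

Each EST carries a short (3 time point) log2 fold-change profile in the
perturbed model (A) and the wild-type model (B).  Four distance measures
summarise the deregulation: the signed sum of differences (the selection
statistic; positive = up in the perturbed model), Manhattan distance,
Euclidean distance, and the Pearson correlation of the two profiles
(undefined on constant profiles).  Deregulated ESTs are selected by
strict thresholds on the sum of differences (+/- 4 by default, with a
tighter +/- 5 display subset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProfileDistances",
    "profile_distances",
    "build_records",
    "select_deregulated",
    "ddct_quantify",
    "validate_agreement",
    "RegressionReport",
]

UP_THRESHOLD = 4.0
DOWN_THRESHOLD = -4.0
DISPLAY_THRESHOLD = 5.0


@dataclass(frozen=True)
class ProfileDistances:
    sum_of_differences: float
    manhattan: float
    euclidean: float
    pearson: float  # nan when undefined (constant profile)


def profile_distances(profile_a, profile_b) -> ProfileDistances:
    """The four distance measures between two equal-length profiles.

    Pearson correlation is reported as NaN when either profile is
    constant (zero variance), where it is mathematically undefined.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"profiles must be equal-length vectors, got {a.shape} vs {b.shape}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("profiles must not contain missing values")
    d = a - b
    if a.std() == 0 or b.std() == 0:
        pearson = math.nan
    else:
        pearson = float(np.corrcoef(a, b)[0, 1])
    return ProfileDistances(
        sum_of_differences=float(d.sum()),
        manhattan=float(np.abs(d).sum()),
        euclidean=float(np.sqrt((d ** 2).sum())),
        pearson=pearson,
    )


def build_records(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                  up: float = UP_THRESHOLD, down: float = DOWN_THRESHOLD) -> pd.DataFrame:
    """Distance table for every EST shared by the two profile matrices.

    Returns columns ``sum_of_differences, manhattan, euclidean, pearson,
    cls`` indexed by EST; ``cls`` is 'up', 'down' or 'neither' by the
    strict sum-of-differences thresholds.
    """
    common = profiles_a.index.intersection(profiles_b.index)
    if len(common) == 0:
        raise ValueError("no shared EST ids between the two models")
    rows = []
    for est in common:
        dist = profile_distances(profiles_a.loc[est].to_numpy(),
                                 profiles_b.loc[est].to_numpy())
        s = dist.sum_of_differences
        cls = "up" if s > up else ("down" if s < down else "neither")
        rows.append((est, s, dist.manhattan, dist.euclidean, dist.pearson, cls))
    return pd.DataFrame(rows, columns=["est_id", "sum_of_differences", "manhattan",
                                       "euclidean", "pearson", "cls"]).set_index("est_id")


def select_deregulated(records: pd.DataFrame, up: float = UP_THRESHOLD,
                       down: float = DOWN_THRESHOLD,
                       display: float = DISPLAY_THRESHOLD) -> dict[str, list]:
    """Strict-threshold selection on the sum of differences.

    Returns the +/-``up``/``down`` selections and the tighter
    +/-``display`` subsets used for heatmap display.  Idempotent and
    independent of record order.
    """
    s = records["sum_of_differences"]
    return {
        "up": sorted(s.index[s > up]),
        "down": sorted(s.index[s < down]),
        "display_up": sorted(s.index[s > display]),
        "display_down": sorted(s.index[s < -display]),
    }


def ddct_quantify(ct_table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative quantification by the delta-delta-Ct method.

    ``ct_table`` columns: ``sample, gene, ct_target, ct_reference`` (the
    reference is the normaliser transcript, e.g. 18S rRNA or Uxt).  For
    each gene, ``dCt = ct_target - ct_reference`` per sample and
    ``ddCt = dCt_sample - dCt_calibrator``; the ideal-efficiency fold
    change is ``2 ** (-ddCt)`` and the log2 fold change ``-ddCt``.
    """
    if (ct_table[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    out_rows = []
    for gene, grp in ct_table.groupby("gene"):
        cal = grp[grp["sample"] == calibrator]
        if cal.empty:
            raise ValueError(f"gene {gene!r}: no calibrator sample {calibrator!r}")
        dct_cal = float((cal["ct_target"] - cal["ct_reference"]).mean())
        for row in grp.itertuples(index=False):
            ddct = (row.ct_target - row.ct_reference) - dct_cal
            out_rows.append((row.sample, gene, ddct, 2.0 ** (-ddct), -ddct))
    return pd.DataFrame(out_rows, columns=["sample", "gene", "ddct", "fold_change",
                                           "log2_fold_change"])


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    n: int


def validate_agreement(qpcr_log2fc, array_log2fc) -> RegressionReport:
    """OLS regression of qPCR vs microarray log2 fold changes.

    For the simple regression R-squared equals the squared Pearson r;
    both are reported.  Needs >= 3 paired points.
    """
    x = np.asarray(array_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.size != y.size:
        raise ValueError("paired measurements required")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired points for the regression")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    assert math.isclose(r2, fit.rvalue ** 2)
    return RegressionReport(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(r2), pearson_r=float(fit.rvalue),
                            n=int(x.size))
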