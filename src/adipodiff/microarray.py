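"""Two-colour microarray normalisation and differential-expression calling.

The processing chain mirrors a classic spotted-cDNA workflow:

1. per-array global median normalisation of log2(Cy5/Cy3) ratios,
2. dye-swap combination of paired hybridisations (the swap partner carries
   the biological signal with reversed sign, so (a - b) / 2 cancels
   dye-specific bias),
3. per-EST collapse of replicate spots (median after MAD-based outlier
   removal),
4. array-wise z-scores of the collapsed ratios,
5. a replication p-value across biological replicate experiments,
6. the DE rule: an EST is differentially expressed iff at some time point
   |z| > 1.5 (configurable to one-sided z > 1.5) and the replication p is
   below 0.05.

All tabular interfaces are tidy pandas DataFrames with columns
``est_id, experiment, array_id, time, spot, flag, log2_ratio`` (spot-level)
or ``est_id, experiment, time, value`` (collapsed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEConfig",
    "normalize_global_median",
    "dye_swap_combine",
    "remove_outliers_mad",
    "collapse_replicate_spots",
    "collapse_spot_table",
    "compute_z_scores",
    "replication_pvalue",
    "call_differential",
    "process_experiments",
]

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.5
P_THRESHOLD = 0.05


@dataclass
class DEConfig:
    """Thresholds and method switches for the DE-calling chain.

    ``z_mode='absolute'`` applies the z cutoff to |z| so repressed ESTs
    qualify as well; ``'positive'`` restricts to induced ESTs.
    ``replication_test`` is 'z' (one-sample z test against the standard
    normal) or 't' (one-sample t test).
    """

    z_threshold: float = Z_THRESHOLD
    p_threshold: float = P_THRESHOLD
    z_mode: str = "absolute"
    replication_test: str = "z"
    mad_multiplier: float = 3.0


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_global_median(spots: pd.DataFrame, value_col: str = "log2_ratio",
                            array_col: str = "array_id",
                            flag_col: str = "flag") -> pd.DataFrame:
    """Subtract the per-array median of unflagged spots from every spot.

    After normalisation each array's unflagged median log2 ratio is 0;
    applying the operation twice is a no-op.
    """
    out = spots.copy()
    has_flags = flag_col in out.columns
    for array_id, idx in out.groupby(array_col).groups.items():
        sub = out.loc[idx]
        good = sub if not has_flags else sub[~sub[flag_col].astype(bool)]
        if good.empty:
            raise ValueError(f"array {array_id!r}: every spot is flagged")
        out.loc[idx, value_col] = sub[value_col] - good[value_col].median()
    return out


def dye_swap_combine(forward: pd.DataFrame, partner: pd.DataFrame | None,
                     value_col: str = "log2_ratio",
                     on: tuple[str, ...] = ("est_id", "spot")) -> pd.DataFrame:
    """Combine an array with its reversed-dye partner, spot by spot.

    The partner hybridisation carries the true ratio with flipped sign, so
    ``(forward - partner) / 2`` recovers the signal while dye bias common
    to both cancels.  Spots missing in either array propagate as missing.
    Without a partner the array passes through unchanged (warned).
    """
    if partner is None:
        logger.warning("array without dye-swap partner passes through uncombined")
        return forward.copy()
    keys = list(on)
    merged = forward.merge(partner[keys + [value_col]], on=keys, how="outer",
                           suffixes=("", "_partner"))
    merged[value_col] = (merged[value_col] - merged[f"{value_col}_partner"]) / 2.0
    return merged.drop(columns=[f"{value_col}_partner"])


# ---------------------------------------------------------------------------
# replicate-spot collapse
# ---------------------------------------------------------------------------

def remove_outliers_mad(values: np.ndarray, multiplier: float = 3.0) -> np.ndarray:
    """Drop values further than ``multiplier`` * MAD from the median (strict).

    With a zero MAD (e.g. two identical spots plus one deviant) anything
    not equal to the median is treated as an outlier.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size <= 1:
        return values
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return values[np.abs(values - med) <= multiplier * mad]


def collapse_replicate_spots(values, multiplier: float = 3.0) -> tuple[float, int]:
    """Median of replicate spot values after MAD outlier removal.

    Returns ``(median, n_used)``; ``(nan, 0)`` when nothing survives.
    """
    kept = remove_outliers_mad(values, multiplier)
    if kept.size == 0:
        logger.warning("all replicate spots removed as outliers")
        return math.nan, 0
    return float(np.median(kept)), int(kept.size)


def collapse_spot_table(spots: pd.DataFrame, value_col: str = "log2_ratio",
                        multiplier: float = 3.0) -> pd.DataFrame:
    """Collapse replicate spots to one value per (est, experiment, time)."""
    rows = []
    for (est, exp, time), grp in spots.groupby(["est_id", "experiment", "time"]):
        med, n = collapse_replicate_spots(grp[value_col].to_numpy(), multiplier)
        rows.append((est, exp, time, med, n))
    return pd.DataFrame(rows, columns=["est_id", "experiment", "time", "value", "n_spots"])


# ---------------------------------------------------------------------------
# z-scores and replication
# ---------------------------------------------------------------------------

def compute_z_scores(values) -> np.ndarray:
    """Standardise collapsed values of one array/time point.

    ``z = (value - mean) / SD`` over all ESTs of the array, with the
    population SD, so z is referenced to the expression distribution of
    the whole array at that time point.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 3:
        raise ValueError("need at least 3 values to standardise an array")
    sd = finite.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate array: zero standard deviation")
    return (v - finite.mean()) / sd


def replication_pvalue(values, method: str = "z") -> float:
    """Two-sided p-value that the replicate mean differs from 0.

    The default 'z' method uses ``z = mean / (SD / sqrt(n))`` (sample SD)
    against the standard normal.  Degenerate replicates (SD 0) give p = 0
    for a nonzero mean and p = 1 otherwise.  Fewer than 2 replicates give
    ``nan`` (the EST cannot qualify at that time point).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        return math.nan
    mean = v.mean()
    sd = v.std(ddof=1)
    if sd == 0:
        return 1.0 if mean == 0 else 0.0
    stat = mean / (sd / math.sqrt(n))
    if method == "z":
        return float(2.0 * stats.norm.sf(abs(stat)))
    if method == "t":
        return float(2.0 * stats.t.sf(abs(stat), df=n - 1))
    raise ValueError(f"unknown replication test {method!r}")


# ---------------------------------------------------------------------------
# differential-expression call
# ---------------------------------------------------------------------------

def call_differential(profiles: pd.DataFrame, config: DEConfig | None = None) -> pd.DataFrame:
    """Flag ESTs passing the z / replication-p rule at >= 1 time point.

    ``profiles`` needs columns ``est_id, time, z, p`` (one row per EST and
    time point, z and p already aggregated across replicates).  Returns a
    table with ``est_id, differential, first_time`` where ``first_time``
    is the earliest qualifying time point (NaN when not differential).
    Both inequalities are strict, matching the selection rule z > 1.5,
    p < 0.05.
    """
    config = config or DEConfig()
    zval = profiles["z"].abs() if config.z_mode == "absolute" else profiles["z"]
    qualifies = (zval > config.z_threshold) & (profiles["p"] < config.p_threshold)
    rows = []
    for est, grp in profiles.assign(_q=qualifies).groupby("est_id"):
        hit = grp[grp["_q"]]
        if len(hit):
            rows.append((est, True, hit["time"].min()))
        else:
            rows.append((est, False, math.nan))
    return pd.DataFrame(rows, columns=["est_id", "differential", "first_time"])


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def process_experiments(spots: pd.DataFrame, config: DEConfig | None = None) -> dict:
    """Run the whole chain on a spot-level table.

    ``spots`` columns: ``est_id, experiment, array_id, dye_swap_partner,
    time, spot, flag, log2_ratio``.  Arrays listed as somebody's
    ``dye_swap_partner`` are consumed by the combination step; arrays with
    an empty/NaN partner pass through.

    Returns a dict with

    ``profile``
        wide DataFrame (index est_id, columns time) of cross-experiment
        mean log2 ratios,
    ``zscore``
        same shape, cross-experiment mean z-scores,
    ``pvalue``
        same shape, replication p-values,
    ``flags``
        the :func:`call_differential` table,
    ``collapsed``
        the long per-experiment collapsed table.
    """
    config = config or DEConfig()
    normalized = normalize_global_median(spots)

    partner_of = (spots[["array_id", "dye_swap_partner"]].drop_duplicates()
                  .set_index("array_id")["dye_swap_partner"].to_dict()
                  if "dye_swap_partner" in spots.columns else {})
    partner_ids = {p for p in partner_of.values() if isinstance(p, str) and p}

    pieces = []
    for array_id, arr in normalized.groupby("array_id"):
        if array_id in partner_ids:
            continue  # consumed as somebody's reverse-dye partner
        partner_id = partner_of.get(array_id)
        if isinstance(partner_id, str) and partner_id:
            partner = normalized[normalized["array_id"] == partner_id]
            if partner.empty:
                raise ValueError(f"array {array_id!r}: dye-swap partner "
                                 f"{partner_id!r} not present")
            pieces.append(dye_swap_combine(arr, partner))
        else:
            pieces.append(dye_swap_combine(arr, None))
    combined = pd.concat(pieces, ignore_index=True)

    collapsed = collapse_spot_table(combined, multiplier=config.mad_multiplier)

    # array-wise z within each (experiment, time); an array with zero
    # spread (e.g. the reference time point in a noise-free simulation)
    # carries no evidence of differential expression -> z = 0 throughout
    collapsed["z"] = np.nan
    for key, idx in collapsed.groupby(["experiment", "time"]).groups.items():
        vals = collapsed.loc[idx, "value"]
        finite = vals[np.isfinite(vals)]
        if finite.size >= 3 and finite.std(ddof=0) == 0:
            logger.warning("array %s: zero spread, z set to 0", key)
            collapsed.loc[idx, "z"] = 0.0
        else:
            collapsed.loc[idx, "z"] = compute_z_scores(vals)

    per_time = (collapsed.groupby(["est_id", "time"])
                .agg(value=("value", "mean"), z=("z", "mean"),
                     p=("value", lambda v: replication_pvalue(v, config.replication_test)))
                .reset_index())

    flags = call_differential(per_time, config)
    return {
        "profile": per_time.pivot(index="est_id", columns="time", values="value"),
        "zscore": per_time.pivot(index="est_id", columns="time", values="z"),
        "pvalue": per_time.pivot(index="est_id", columns="time", values="p"),
        "flags": flags,
        "collapsed": collapsed,
    }
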