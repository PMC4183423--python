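"""Condition comparisons: G1 vs S alteration typing, chi-square profile
tests and S:G1 ratio tables.

A chromosome pair's profile has two channels — the percent of nuclei with
exactly one contact (=1) and with two or more (≥2).  Between two
conditions a channel *changes* when its relative difference versus the
first condition exceeds a tolerance (default 20 %).  The five alteration
types are: 1 both channels up, 2 both down, 3 singular down with
multiples up (a switch towards multiple contacts), 4 the reverse switch,
5 no change.  Single-channel changes are assigned to types 1/2 by the
changing channel's direction.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _channel_change(v1: float, v2: float, tolerance: float) -> int:
    """-1 down, 0 within tolerance, +1 up, relative to the first value."""
    if v1 == 0.0:
        if v2 == 0.0:
            return 0
        return 1  # any gain from zero exceeds a relative tolerance
    rel = (v2 - v1) / v1
    if rel > tolerance:
        return 1
    if rel < -tolerance:
        return -1
    return 0


def classify_alteration(
    eq1_g1: float,
    ge2_g1: float,
    eq1_s: float,
    ge2_s: float,
    tolerance: float = 0.20,
    switch_convention: str = "singular_to_multiple",
) -> int:
    """Type a pair's G1→S profile alteration (types 1–5).

    ``switch_convention`` controls which switch direction is type 3:
    the default makes =1 down & ≥2 up type 3; ``'multiple_to_singular'``
    swaps types 3 and 4 (the two conventions circulate in the field).
    """
    d1 = _channel_change(eq1_g1, eq1_s, tolerance)
    d2 = _channel_change(ge2_g1, ge2_s, tolerance)
    if d1 == 0 and d2 == 0:
        return 5
    if d1 >= 0 and d2 >= 0:
        return 1
    if d1 <= 0 and d2 <= 0:
        return 2
    type3 = 3 if switch_convention == "singular_to_multiple" else 4
    type4 = 7 - type3
    return type3 if (d1 < 0 < d2) else type4


def alteration_table(
    profile_g1: pd.DataFrame,
    profile_s: pd.DataFrame,
    tolerance: float = 0.20,
    switch_convention: str = "singular_to_multiple",
) -> pd.DataFrame:
    """Per-pair alteration types with deltas and S:G1 ratios.

    Inputs are ``pair_profiles`` frames indexed by (chrom_i, chrom_j)
    computed on the two conditions.
    """
    if not profile_g1.index.equals(profile_s.index):
        raise ValueError("profiles must cover the same chromosome pairs")
    rows = []
    for pair in profile_g1.index:
        g1, s = profile_g1.loc[pair], profile_s.loc[pair]
        rows.append(
            {
                "chrom_i": pair[0],
                "chrom_j": pair[1],
                "type": classify_alteration(
                    g1["pct_eq1"], g1["pct_ge2"], s["pct_eq1"], s["pct_ge2"],
                    tolerance, switch_convention,
                ),
                "delta_eq1": s["pct_eq1"] - g1["pct_eq1"],
                "delta_ge2": s["pct_ge2"] - g1["pct_ge2"],
                "ratio_eq1": _safe_ratio(s["pct_eq1"], g1["pct_eq1"]),
                "ratio_ge2": _safe_ratio(s["pct_ge2"], g1["pct_ge2"]),
            }
        )
    return pd.DataFrame(rows).set_index(["chrom_i", "chrom_j"])


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def chi_square_profile(
    observed: Sequence[float],
    reference: Optional[Sequence[float]] = None,
) -> ChiSquareResult:
    """Pearson chi-square of an interaction-count profile.

    With ``reference=None`` the observed counts are compared to their
    uniform average (df = cells − 1).  With a second condition's counts,
    a 2×k contingency test is performed (no continuity correction).
    Counts, not percentages, must be supplied; a zero expected count
    raises with the offending cell named.
    """
    obs = np.asarray(observed, dtype=float)
    if reference is None:
        expected = np.full_like(obs, obs.sum() / obs.size)
        _check_expected(expected)
        stat = float(((obs - expected) ** 2 / expected).sum())
        df = obs.size - 1
        return ChiSquareResult(stat, df, float(stats.chi2.sf(stat, df)))
    ref = np.asarray(reference, dtype=float)
    table = np.vstack([obs, ref])
    expected = stats.contingency.expected_freq(table)
    _check_expected(expected)
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def _check_expected(expected: np.ndarray) -> None:
    bad = np.argwhere(expected == 0)
    if bad.size:
        raise ValueError(f"zero expected count in cell {tuple(bad[0])}")


def _safe_ratio(num: float, den: float) -> float:
    """S:G1 ratio; NaN flags a zero first-condition value (never infinity)."""
    if den == 0:
        return float("nan")
    return num / den


def ratio_table(profile_g1: pd.DataFrame, profile_s: pd.DataFrame) -> pd.DataFrame:
    """Elementwise S:G1 ratios for the =1 and ≥2 channels of all pairs.

    Zero G1 denominators produce NaN with ``flagged=True`` rather than
    infinities.
    """
    if not profile_g1.index.equals(profile_s.index):
        raise ValueError("profiles must cover the same chromosome pairs")
    out = pd.DataFrame(index=profile_g1.index)
    out["ratio_eq1"] = [
        _safe_ratio(s, g) for s, g in zip(profile_s["pct_eq1"], profile_g1["pct_eq1"])
    ]
    out["ratio_ge2"] = [
        _safe_ratio(s, g) for s, g in zip(profile_s["pct_ge2"], profile_g1["pct_ge2"])
    ]
    out["flagged"] = (profile_g1["pct_eq1"] == 0) | (profile_g1["pct_ge2"] == 0)
    return out
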