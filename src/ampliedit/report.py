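"""Downstream summaries: tissue tables, expression, correlation, splicing bias.

Aggregates per-sample editing estimates into tissue x timepoint tables
(mean +/- sd over biological replicates), converts qPCR Ct values to relative
expression by the dCt method with a reference gene, fits the
editing-vs-expression regression, and compares pre-mRNA and mRNA editing
through a maturation odds ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

import numpy as np
import pandas as pd
from scipy import stats

from .reference import TIMEPOINT_ORDER, SampleMeta


@dataclass
class FitResult:
    """Ordinary-least-squares fit of editing rate against expression."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    ok: bool = True


@dataclass
class SplicingBias:
    """Odds ratio of maturation for edited vs unedited transcripts.

    OR < 1 means edited transcripts are under-represented in mRNA relative
    to pre-mRNA, i.e. selection against edited transcripts during splicing.
    ``bounded`` flags degenerate inputs (a rate of exactly 0 or 1), where the
    reported value is clamped instead of infinite.
    """

    odds_ratio: float
    bounded: bool = False


def aggregate_editing(
    estimates: Iterable[tuple[SampleMeta, float]],
) -> pd.DataFrame:
    """Tissue x timepoint editing table: n, mean, sd over replicates.

    ``estimates`` pairs sample metadata with that sample's editing rate.
    Samples with missing (NaN) rates are excluded and counted in
    ``n_missing``.  Groups with a single replicate report sd 0 with
    ``single_replicate`` set.  Empty groups are omitted.  Rows are ordered by
    tissue then developmental timepoint (P0 < P21 < P120, unknown labels
    last).
    """
    rows = []
    for meta, rate in estimates:
        rows.append(
            {
                "tissue": meta.tissue,
                "timepoint": meta.timepoint,
                "replicate": meta.replicate,
                "rate": rate,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["tissue", "timepoint", "n", "mean", "sd",
                     "single_replicate", "n_missing", "rates"]
        )
    out = []
    for (tissue, tp), grp in df.groupby(["tissue", "timepoint"], sort=False):
        vals = grp["rate"].to_numpy(dtype=float)
        ok = vals[np.isfinite(vals)]
        n_missing = len(vals) - len(ok)
        if len(ok) == 0:
            logger.warning(
                "group (%s, %s): all %d replicates missing; row omitted",
                tissue, tp, len(vals),
            )
            continue
        out.append(
            {
                "tissue": tissue,
                "timepoint": tp,
                "n": len(ok),
                "mean": float(ok.mean()),
                "sd": float(ok.std(ddof=1)) if len(ok) > 1 else 0.0,
                "single_replicate": len(ok) == 1,
                "n_missing": n_missing,
                "rates": ok.tolist(),
            }
        )
    table = pd.DataFrame(out)
    table["_tp"] = table["timepoint"].map(lambda t: TIMEPOINT_ORDER.get(t, 99))
    table = table.sort_values(["tissue", "_tp"], kind="stable").drop(columns="_tp")
    return table.reset_index(drop=True)


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Relative expression 2**(-(Ct_target - Ct_reference)); NaN Ct -> NaN."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        return math.nan
    return 2.0 ** (-(ct_target - ct_reference))


def expression_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Apply the dCt method to a Ct table (sample_id, ct_target, ct_reference)."""
    out = ct.copy()
    out["relative_expression"] = [
        delta_ct(t, r) for t, r in zip(out["ct_target"], out["ct_reference"])
    ]
    return out


def correlate_editing_expression(
    pairs: Sequence[tuple[float, float]],
) -> FitResult:
    """OLS of editing rate (y) on relative expression (x); reports R^2.

    Requires at least 3 finite pairs; a predictor with zero variance yields
    an undefined, flagged fit instead of an exception.
    """
    arr = np.asarray(pairs, dtype=float)
    arr = arr[np.isfinite(arr).all(axis=1)]
    if len(arr) < 3:
        raise ValueError("need at least 3 finite (editing, expression) pairs")
    x, y = arr[:, 1], arr[:, 0]
    if np.ptp(x) == 0:
        return FitResult(math.nan, math.nan, math.nan, len(arr), ok=False)
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(arr),
        ok=True,
    )


_OR_CLAMP = 1e6


def splicing_bias(pre_rate: float, mrna_rate: float) -> SplicingBias:
    """Maturation odds ratio [m/(1-m)] / [p/(1-p)] for edited transcripts.

    ``pre_rate`` is editing in pre-mRNA, ``mrna_rate`` in spliced mRNA.
    Rates of exactly 0 or 1 give a clamped, flagged value.
    """
    for r in (pre_rate, mrna_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    degenerate = pre_rate in (0.0, 1.0) or mrna_rate in (0.0, 1.0)
    if degenerate:
        p = min(max(pre_rate, 1e-12), 1 - 1e-12)
        m = min(max(mrna_rate, 1e-12), 1 - 1e-12)
        orr = (m / (1 - m)) / (p / (1 - p))
        return SplicingBias(float(np.clip(orr, 1 / _OR_CLAMP, _OR_CLAMP)), bounded=True)
    orr = (mrna_rate / (1 - mrna_rate)) / (pre_rate / (1 - pre_rate))
    return SplicingBias(float(orr), bounded=False)


def sanger_rate(peak_a: float, peak_g: float) -> float:
    """Peak-ratio editing estimate G/(A+G); both peaks zero -> NaN."""
    if peak_a < 0 or peak_g < 0:
        raise ValueError("peak values must be non-negative")
    total = peak_a + peak_g
    if total == 0:
        return math.nan
    return peak_g / total
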