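"""Quality-filtered base counting and editing-rate estimation.

The A-to-I editing rate at a site is the fraction of quality-filtered,
site-covering reads carrying G where the genome encodes A.  The estimate
carries a Wilson 95% score interval, and detection against the sequencing
error floor (background substitution rate, measured at non-editable control
positions) uses a one-sided exact binomial test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

from .align import ReadAlignment, align_read
from .reference import AmpliconReference
from .simulate import FastqRead

DEFAULT_MIN_BASE_QUALITY = 20
DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_ERROR_FLOOR = 0.001  # background when no control positions are usable
DEFAULT_ALPHA = 0.01

_BASE_FIELD = {"A": "a", "C": "c", "G": "g", "T": "t", "N": "n"}


@dataclass
class SiteCounts:
    """Per-site base occurrence counts among reads passing all filters."""

    role: str
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    n: int = 0
    filtered_low_basequal: int = 0
    filtered_low_alignqual: int = 0

    @property
    def depth(self) -> int:
        return self.a + self.c + self.g + self.t + self.n

    def count(self, base: str) -> int:
        return getattr(self, _BASE_FIELD[base.upper()])

    def add(self, base: str) -> None:
        f = _BASE_FIELD[base.upper()]
        setattr(self, f, getattr(self, f) + 1)

    def non_reference(self, ref_base: str) -> int:
        """Mismatching A/C/G/T count (N excluded from both sides)."""
        return self.depth - self.n - self.count(ref_base)


@dataclass
class EditingEstimate:
    """Editing rate with Wilson 95% CI, error floor and detection verdict."""

    role: str
    rate: float
    ci_low: float
    ci_high: float
    depth: int
    error_floor: float | None = None
    detected: bool | None = None
    p_detect: float | None = None

    @property
    def missing(self) -> bool:
        return self.depth == 0

    def to_dict(self) -> dict:
        return asdict(self)


def count_bases(
    alignments: Iterable[tuple[ReadAlignment, str]],
    reference: AmpliconReference,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> dict[str, SiteCounts]:
    """Count bases at every catalog site over accepted alignments.

    ``alignments`` yields ``(alignment, oriented_quality)`` pairs where the
    quality string is Phred+33 in the same orientation as
    ``alignment.read_seq``.  A read contributes at a site only when it covers
    the site with an aligned (non-gap) base of quality >= the threshold
    (inclusive).  Reads whose quality string length disagrees with the read
    are skipped and tallied under the ``"__qc__"`` key.
    """
    counts = {site.role: SiteCounts(role=site.role) for _, site in reference.sites}
    qc = SiteCounts(role="__qc__")
    offsets = [(off, site.role) for off, site in reference.sites]
    for aln, qual in alignments:
        if len(qual) != len(aln.read_seq):
            qc.filtered_low_basequal += 1
            continue
        for off, role in offsets:
            i = aln.ref_to_read[off]
            if i < 0:
                continue
            if ord(qual[i]) - 33 >= min_base_quality:
                counts[role].add(aln.read_seq[i])
            else:
                counts[role].filtered_low_basequal += 1
    counts["__qc__"] = qc
    return counts


def editing_rate(counts: SiteCounts) -> EditingEstimate:
    """Editing rate G/depth with a Wilson 95% score interval.

    Zero depth yields a missing-value estimate (NaN rate and bounds) rather
    than a division by zero.
    """
    depth = counts.depth
    if depth == 0:
        return EditingEstimate(counts.role, math.nan, math.nan, math.nan, 0)
    rate = counts.g / depth
    lo, hi = proportion_confint(counts.g, depth, alpha=0.05, method="wilson")
    return EditingEstimate(counts.role, rate, float(lo), float(hi), depth)


def error_floor(control_counts: Sequence[SiteCounts], ref_bases: Sequence[str]) -> float | None:
    """Pooled non-reference base fraction across control (non-editable) positions.

    Returns None when no control position has usable depth; callers then fall
    back to :data:`DEFAULT_ERROR_FLOOR`.
    """
    mism = 0
    total = 0
    for sc, ref in zip(control_counts, ref_bases):
        usable = sc.depth - sc.n
        if usable > 0:
            mism += sc.non_reference(ref)
            total += usable
    if total == 0:
        return None
    return mism / total


def detect_editing(
    estimate: EditingEstimate,
    floor: float | None,
    alpha: float = DEFAULT_ALPHA,
) -> EditingEstimate:
    """One-sided exact binomial test of the G count against the error floor.

    ``detected`` requires both p < alpha and rate > floor; a rate exactly at
    the floor is never a detection.  Returns a new estimate with
    ``error_floor``, ``p_detect`` and ``detected`` filled in.
    """
    if estimate.missing:
        return EditingEstimate(
            estimate.role, estimate.rate, estimate.ci_low, estimate.ci_high, 0,
            error_floor=floor, detected=None, p_detect=None,
        )
    if floor is None:
        floor = DEFAULT_ERROR_FLOOR
    if not 0.0 <= floor < 1.0:
        raise ValueError("error floor must lie in [0, 1)")
    g = round(estimate.rate * estimate.depth)
    if floor == 0.0:
        p = 0.0 if g > 0 else 1.0
    else:
        p = float(binomtest(g, estimate.depth, floor, alternative="greater").pvalue)
    detected = bool(p < alpha and estimate.rate > floor)
    return EditingEstimate(
        estimate.role, estimate.rate, estimate.ci_low, estimate.ci_high,
        estimate.depth, error_floor=floor, detected=detected, p_detect=p,
    )


@dataclass
class SampleQuantification:
    """Full per-sample quantification: counts, estimates, floor, QC tallies."""

    sample_id: str
    counts: dict[str, SiteCounts]
    estimates: dict[str, EditingEstimate]
    floor: float | None
    n_reads: int
    n_aligned: int
    n_rejected: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for role, est in self.estimates.items():
            sc = self.counts[role]
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "site": role,
                    "A": sc.a, "C": sc.c, "G": sc.g, "T": sc.t, "N": sc.n,
                    "depth": sc.depth,
                    "rate": est.rate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "error_floor": est.error_floor,
                    "p_detect": est.p_detect,
                    "detected": est.detected,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "floor": self.floor,
                "n_reads": self.n_reads,
                "n_aligned": self.n_aligned,
                "n_rejected": self.n_rejected,
                "sites": {r: e.to_dict() for r, e in self.estimates.items()},
            },
            sort_keys=True,
        )


def quantify_sample(
    reads: Iterable[FastqRead],
    reference: AmpliconReference,
    sample_id: str = "sample",
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    alpha: float = DEFAULT_ALPHA,
    default_floor: float = DEFAULT_ERROR_FLOOR,
) -> SampleQuantification:
    """Align, count and estimate editing for one demultiplexed sample.

    The error floor is measured from the catalog's control (non-editable)
    positions of this very sample; when none is usable the configured default
    floor is applied instead.
    """
    accepted: list[tuple[ReadAlignment, str]] = []
    n_reads = 0
    n_rejected = 0
    for read in reads:
        n_reads += 1
        aln = align_read(read.sequence, reference, min_identity=min_identity)
        if aln is None:
            n_rejected += 1
            continue
        qual = read.quality if aln.orientation == "+" else read.quality[::-1]
        accepted.append((aln, qual))
    counts = count_bases(accepted, reference, min_base_quality=min_base_quality)
    for sc in counts.values():
        sc.filtered_low_alignqual = n_rejected
    controls = reference.control_sites
    floor = error_floor(
        [counts[s.role] for _, s in controls], [s.ref_base for _, s in controls]
    )
    estimates: dict[str, EditingEstimate] = {}
    for off, site in reference.editable_sites:
        est = editing_rate(counts[site.role])
        estimates[site.role] = detect_editing(
            est, floor if floor is not None else default_floor, alpha=alpha
        )
    return SampleQuantification(
        sample_id=sample_id,
        counts=counts,
        estimates=estimates,
        floor=floor,
        n_reads=n_reads,
        n_aligned=n_reads - n_rejected,
        n_rejected=n_rejected,
    )
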