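"""Maximum-entropy 5' splice-site (donor) scoring and editing-variant ranking.

A donor site is a 9-mer: the last 3 exonic bases followed by the first 6
intronic bases.  The maximum-entropy model assigns it a log2-odds score of a
trained joint distribution over the 7 non-consensus positions (times fixed
consensus factors for the near-invariant GT at intron positions +1/+2)
against a genomic background; higher scores mean stronger donors.

Two model classes are provided:

* :class:`MaxEntDonorModel` -- loads the published score5ss-dialect tables
  (a ``me2x5`` file of 16384 probability ratios indexed by the 7 free
  positions).  These trained tables are an external data dependency; place
  them under a directory and point :func:`load_splice_model` at it.
* :class:`PwmDonorModel` -- a self-contained position-weight-matrix fallback
  built from donor-site consensus base frequencies.  Its scores preserve the
  qualitative ordering of variants but are NOT numerically comparable to
  maximum-entropy scores (``comparable_to_maxent`` is False).

Editing turns adenosines into (apparent) guanosines, so the editing variants
of a junction are enumerated by substituting G at editable A positions.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

DONOR_LENGTH = 9
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# score5ss dialect constants: genomic background and the consensus factors
# for the near-invariant G(+1)/T(+2) intron positions.
BACKGROUND = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
CONSENSUS_P1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0032}
CONSENSUS_P2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884}

# Canonical mammalian donor-site base frequencies (positions -3..+6,
# literature-typical values around the MAG|GTRAGT consensus) used by the
# PWM fallback.
CANONICAL_DONOR_FREQS: tuple[dict[str, float], ...] = (
    {"A": 0.33, "C": 0.37, "G": 0.18, "T": 0.12},  # -3
    {"A": 0.60, "C": 0.13, "G": 0.12, "T": 0.15},  # -2
    {"A": 0.08, "C": 0.04, "G": 0.81, "T": 0.07},  # -1
    {"A": 0.001, "C": 0.001, "G": 0.997, "T": 0.001},  # +1
    {"A": 0.001, "C": 0.001, "G": 0.001, "T": 0.997},  # +2
    {"A": 0.55, "C": 0.03, "G": 0.37, "T": 0.05},  # +3
    {"A": 0.68, "C": 0.09, "G": 0.12, "T": 0.11},  # +4
    {"A": 0.07, "C": 0.06, "G": 0.81, "T": 0.06},  # +5
    {"A": 0.16, "C": 0.17, "G": 0.21, "T": 0.46},  # +6
)


class SpliceModelError(ValueError):
    pass


def _check_nine_mer(nine_mer: str) -> str:
    s = nine_mer.upper()
    if len(s) != DONOR_LENGTH:
        raise SpliceModelError(f"donor sequence must be 9 nt, got {len(s)}")
    if set(s) - set("ACGT"):
        raise SpliceModelError(f"donor sequence must be over ACGT: {nine_mer!r}")
    return s


@dataclass
class MaxEntDonorModel:
    """The trained maximum-entropy donor model (score5ss table dialect)."""

    me2x5: np.ndarray
    source: str
    checksum: str
    comparable_to_maxent: bool = True

    def score(self, nine_mer: str) -> float:
        s = _check_nine_mer(nine_mer)
        consensus = (
            CONSENSUS_P1[s[3]]
            * CONSENSUS_P2[s[4]]
            / (BACKGROUND[s[3]] * BACKGROUND[s[4]])
        )
        rest = s[:3] + s[5:]
        idx = 0
        for ch in rest:
            idx = idx * 4 + _BASE_INDEX[ch]
        return math.log2(consensus * float(self.me2x5[idx]))


@dataclass
class PwmDonorModel:
    """Position-weight-matrix fallback: sum of per-position log2(f/background)."""

    frequencies: tuple[dict[str, float], ...] = CANONICAL_DONOR_FREQS
    pseudocount: float = 1e-4
    source: str = "canonical donor consensus"
    comparable_to_maxent: bool = False

    def __post_init__(self) -> None:
        if len(self.frequencies) != DONOR_LENGTH:
            raise SpliceModelError("PWM must cover 9 donor positions")
        self.checksum = hashlib.sha256(
            repr(sorted((i, b, f) for i, col in enumerate(self.frequencies)
                        for b, f in sorted(col.items()))).encode()
        ).hexdigest()

    def score(self, nine_mer: str) -> float:
        s = _check_nine_mer(nine_mer)
        total = 0.0
        for i, ch in enumerate(s):
            f = self.frequencies[i].get(ch, 0.0) + self.pseudocount
            total += math.log2(f / BACKGROUND[ch])
        return total


def load_splice_model(path: str | Path) -> MaxEntDonorModel:
    """Load score5ss-dialect maximum-entropy tables from a directory.

    Expects a file ``me2x5`` holding 16384 whitespace-separated probability
    ratios in base-4 order of the 7 free donor positions (A<C<G<T).  Missing
    or truncated tables raise a hard error naming the file; use
    :class:`PwmDonorModel` as the offline fallback (its scores are flagged
    non-comparable to maximum-entropy scores).
    """
    path = Path(path)
    table = path / "me2x5"
    if not table.is_file():
        raise SpliceModelError(
            f"maximum-entropy donor tables not found: {table} "
            "(supply the score5ss model directory, or use PwmDonorModel)"
        )
    raw = table.read_bytes()
    values = np.array(raw.split(), dtype=float)
    if values.size != 4**7:
        raise SpliceModelError(
            f"{table}: expected {4**7} entries, found {values.size} (truncated?)"
        )
    if not np.isfinite(values).all() or (values <= 0).any():
        raise SpliceModelError(f"{table}: entries must be finite and positive")
    model = MaxEntDonorModel(
        me2x5=values,
        source=str(path),
        checksum=hashlib.sha256(raw).hexdigest(),
    )
    for probe in ("CAGGTGAGG", "AAAAAAAAA", "TTTGTTTTT"):
        if not math.isfinite(model.score(probe)):
            raise SpliceModelError(f"{table}: non-finite score for probe {probe}")
    return model


def score5ss(model, nine_mer: str) -> float:
    """Score a donor 9-mer (case-insensitive) under the given model."""
    return model.score(nine_mer)


@dataclass
class SpliceVariant:
    """One editing variant of a donor junction.

    ``edit_mask`` lists the 0-based 9-mer offsets carrying G instead of the
    unedited A; the exonic part is reported upper-case and the intronic part
    lower-case, Table-style.
    """

    exonic3: str
    intronic6: str
    edit_mask: tuple[int, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.exonic3) != 3 or len(self.intronic6) != 6:
            raise SpliceModelError("junction must be 3 exonic + 6 intronic bases")
        for off in self.edit_mask:
            if self.nine_mer[off] != "G":
                raise SpliceModelError(
                    f"edit_mask offset {off} inconsistent with sequence"
                )

    @property
    def nine_mer(self) -> str:
        return (self.exonic3 + self.intronic6).upper()

    @property
    def display(self) -> str:
        return self.exonic3.upper() + self.intronic6.lower()

    @property
    def n_edits(self) -> int:
        return len(self.edit_mask)


def enumerate_variants(
    exonic3: str, intronic6: str, editable_offsets: Sequence[int]
) -> list[SpliceVariant]:
    """All 2^k editing variants of a junction; the unedited variant first.

    ``editable_offsets`` are 0-based offsets into the 9-mer and must point at
    adenosines of the unedited junction.
    """
    base = _check_nine_mer(exonic3 + intronic6)
    offsets = sorted(set(int(o) for o in editable_offsets))
    for off in offsets:
        if not 0 <= off < DONOR_LENGTH:
            raise SpliceModelError(f"editable offset {off} outside the 9-mer")
        if base[off] != "A":
            raise SpliceModelError(
                f"editable offset {off} is {base[off]}, expected A"
            )
    variants = []
    for mask_bits in range(2 ** len(offsets)):
        seq = list(base)
        mask = []
        for k, off in enumerate(offsets):
            if mask_bits >> k & 1:
                seq[off] = "G"
                mask.append(off)
        nine = "".join(seq)
        variants.append(
            SpliceVariant(
                exonic3=nine[:3], intronic6=nine[3:], edit_mask=tuple(mask)
            )
        )
    # binary counting puts the unedited variant first already
    return variants


def rank_variants(model, variants: Sequence[SpliceVariant]):
    """Score and order variants by descending donor strength.

    Ties break by edit count (fewer edits first), then lexicographic 9-mer;
    tied scores are flagged.  Returns a pandas DataFrame with columns
    exonic, intronic, n_edits, score, rank, tie.
    """
    import pandas as pd

    if not variants:
        raise SpliceModelError("need at least one variant")
    scored = [
        SpliceVariant(v.exonic3, v.intronic6, v.edit_mask, score=model.score(v.nine_mer))
        for v in variants
    ]
    scored.sort(key=lambda v: (-v.score, v.n_edits, v.nine_mer))
    rows = []
    for rank, v in enumerate(scored, start=1):
        tie = any(
            w is not v and w.score == v.score for w in scored
        )
        rows.append(
            {
                "exonic": v.exonic3.upper(),
                "intronic": v.intronic6.lower(),
                "n_edits": v.n_edits,
                "score": v.score,
                "rank": rank,
                "tie": tie,
            }
        )
    return pd.DataFrame(rows)


# The Flnb exon 41 donor junction: Q/R adenosine at 9-mer offset 1 (exonic),
# intron+4 adenosine at offset 6.
FLNB_EXONIC = "CAG"
FLNB_INTRONIC = "GTGAGG"
FLNB_EDITABLE_OFFSETS = (1, 6)


def flnb_variants() -> list[SpliceVariant]:
    return enumerate_variants(FLNB_EXONIC, FLNB_INTRONIC, FLNB_EDITABLE_OFFSETS)
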