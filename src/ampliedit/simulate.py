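"""Generative model for barcoded amplicon libraries with known editing truth.

The generator emulates the statistical structure of a multiplexed Flnb-style
amplicon study:

* per-sample read depth drawn from a negative binomial around a configurable
  mean (default 7,824 reads, with overdispersion motivated by the wide
  observed per-sample spread of such libraries);
* three editable adenosines per molecule (S/G, Q/R, intron+4) whose joint
  editing state follows either independent marginals or an explicit 8-state
  joint distribution;
* editing-state-dependent splicing: a molecule's probability of maturing into
  spliced mRNA is ``logistic(lambda0 - lambda1*[Q/R edited] -
  lambda2*[intron+4 edited])``, so edited transcripts are under-represented
  in the mRNA pool;
* uniform per-base substitution errors at rate ``e`` (default 0.001, the
  typical amplicon-sequencing error floor), coupled to the emitted Phred+33
  quality strings so that low-quality bases carry more errors;
* dual 8-nt barcodes (i5 + insert + i7 read layout, single-end).

Every operation takes an explicit seed or ``numpy.random.Generator`` and is
deterministic given it.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference import (
    AmpliconReference,
    BarcodePair,
    SampleMeta,
    SampleSheet,
    combined_distance,
)

SITE_ROLES = ("S/G", "Q/R", "intron+4")  # order of the editing-state vector
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    Parameters
    ----------
    depth_mean, depth_dispersion
        Negative-binomial read-depth model: mean ``mu`` and size ``k``
        (variance ``mu + mu**2/k``).  Defaults emulate a deeply sequenced
        amplicon sample (median-like 7,824 reads, moderate overdispersion).
    error_rate
        Mean per-base substitution error ``e`` (uniform over positions and
        substitution classes), default 0.001.
    editing_marginals
        Per-site marginal editing probabilities in :data:`SITE_ROLES` order
        (S/G, Q/R, intron+4); sites independent unless ``joint`` is given.
    joint
        Optional explicit joint over the 8 editing states, shape (2,2,2)
        indexed ``[sg, qr, in4]``; overrides the marginals.
    splice_logit_base, splice_penalty_qr, splice_penalty_intron
        Splicing log-odds decomposition (lambda0, lambda1, lambda2).  The
        defaults place pre-mRNA Q/R editing near 0.85 and spliced-mRNA Q/R
        editing near 0.55, the qualitative adult-brain regime.
    library_type
        Which molecule pool the library samples: ``"mrna"`` (spliced only,
        the exon-primed assay), ``"pre_mrna"`` (unspliced only) or ``"all"``.
    phred_mean, phred_sd
        Gaussian model for per-base quality scores; when ``phred_mean`` is
        None it defaults to ``-10*log10(error_rate)`` so qualities and the
        error rate agree.
    """

    depth_mean: float = 7824.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.001
    editing_marginals: tuple[float, float, float] = (0.35, 0.85, 0.5)
    joint: np.ndarray | None = None
    splice_logit_base: float = 1.0
    splice_penalty_qr: float = 2.5
    splice_penalty_intron: float = 1.0
    library_type: str = "mrna"
    phred_mean: float | None = None
    phred_sd: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.05:
            raise SimulationError("error_rate must lie in [0, 0.05]")
        if self.depth_mean <= 0:
            raise SimulationError("depth_mean must be positive")
        if self.library_type not in ("mrna", "pre_mrna", "all"):
            raise SimulationError(f"bad library_type {self.library_type!r}")
        if self.joint is not None:
            j = np.asarray(self.joint, dtype=float)
            if j.shape != (2, 2, 2) or (j < 0).any() or abs(j.sum() - 1.0) > 1e-9:
                raise SimulationError("joint must be a (2,2,2) distribution summing to 1")
            self.joint = j
        else:
            for p in self.editing_marginals:
                if not 0.0 <= p <= 1.0:
                    raise SimulationError("editing marginals must lie in [0, 1]")

    def state_distribution(self) -> np.ndarray:
        """Joint distribution over the 8 editing states, shape (2,2,2)."""
        if self.joint is not None:
            return self.joint
        p_sg, p_qr, p_in = self.editing_marginals
        j = np.empty((2, 2, 2))
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    j[a, b, c] = (
                        (p_sg if a else 1 - p_sg)
                        * (p_qr if b else 1 - p_qr)
                        * (p_in if c else 1 - p_in)
                    )
        return j

    def splice_probability(self, qr_edited, intron_edited):
        """P(spliced | editing state) = logistic(l0 - l1*qr - l2*in4)."""
        z = (
            self.splice_logit_base
            - self.splice_penalty_qr * np.asarray(qr_edited, dtype=float)
            - self.splice_penalty_intron * np.asarray(intron_edited, dtype=float)
        )
        return 1.0 / (1.0 + np.exp(-z))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        if d["joint"] is not None:
            d["joint"] = np.asarray(d["joint"]).ravel().tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("joint") is not None:
            d["joint"] = np.asarray(d["joint"], dtype=float).reshape(2, 2, 2)
        if "editing_marginals" in d and d["editing_marginals"] is not None:
            d["editing_marginals"] = tuple(d["editing_marginals"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample (JSON round-trippable)."""

    sample_id: str
    seed: int | None
    depth: int
    pre_mrna_rates: dict[str, float]  # realized over all molecules
    mrna_rates: dict[str, float]  # realized over spliced molecules
    sequenced_g_truth: dict[str, int]  # edited-molecule count among sequenced reads
    spliced_fraction: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TruthRecord":
        return cls(**json.loads(s))


@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: str

    def fastq(self) -> str:
        return f"@{self.name}\n{self.sequence}\n+\n{self.quality}\n"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def expected_pool_rates(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Closed-form per-pool editing rates by enumeration of the 8 states.

    Returns ``{"pre_mrna": {role: rate}, "mrna": {...}, "spliced_fraction": f}``
    where the mRNA rates condition on splicing under the logistic selection
    model.  Used for design and for consistency checks against simulation.
    """
    joint = config.state_distribution()
    out: dict[str, dict[str, float]] = {"pre_mrna": {}, "mrna": {}}
    sp = np.empty((2, 2, 2))
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                sp[a, b, c] = config.splice_probability(b, c)
    w_spliced = joint * sp
    total_spliced = w_spliced.sum()
    idx = {"S/G": 0, "Q/R": 1, "intron+4": 2}
    for role, ax in idx.items():
        sel = [slice(None)] * 3
        sel[ax] = 1
        out["pre_mrna"][role] = float(joint[tuple(sel)].sum())
        out["mrna"][role] = float(w_spliced[tuple(sel)].sum() / total_spliced)
    out["spliced_fraction"] = float(total_spliced)  # type: ignore[assignment]
    return out


def simulate_molecules(
    config: SimulationConfig, n: int, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` molecules: editing-state vectors and spliced flags.

    Returns ``(edits, spliced)`` where ``edits`` is a boolean ``(n, 3)`` array
    in :data:`SITE_ROLES` order and ``spliced`` a boolean ``(n,)`` array.
    """
    if n <= 0:
        raise SimulationError("molecule count must be positive")
    rng = _as_rng(seed if seed is not None else config.seed)
    joint = config.state_distribution()
    states = rng.choice(8, size=n, p=joint.ravel())
    edits = np.stack(
        [(states >> 2) & 1, (states >> 1) & 1, states & 1], axis=1
    ).astype(bool)
    p_spliced = config.splice_probability(edits[:, 1], edits[:, 2])
    spliced = rng.random(n) < p_spliced
    return edits, spliced


def _phred_mean(config: SimulationConfig) -> float:
    if config.phred_mean is not None:
        return config.phred_mean
    if config.error_rate <= 0:
        return 40.0
    return -10.0 * math.log10(config.error_rate)


def _mutate(seq_arr: np.ndarray, quals: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Apply substitution errors coupled to the quality scores.

    Per-base error probability is proportional to ``10**(-q/10)``, rescaled so
    the mean over all emitted bases equals ``error_rate`` exactly.
    """
    if error_rate <= 0:
        return seq_arr
    perr = np.power(10.0, -quals / 10.0)
    scale = error_rate / perr.mean()
    hit = rng.random(seq_arr.shape) < np.minimum(perr * scale, 1.0)
    n_hit = int(hit.sum())
    if n_hit:
        # replace with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=n_hit)
        codes = np.searchsorted(_BASES, seq_arr[hit])
        seq_arr[hit] = _BASES[(codes + shift) % 4]
    return seq_arr


def emit_library(
    molecules: tuple[np.ndarray, np.ndarray],
    reference: AmpliconReference,
    barcodes: BarcodePair,
    config: SimulationConfig,
    seed=None,
    sample_id: str = "sample",
) -> tuple[list[FastqRead], TruthRecord]:
    """Sequence one sample: sample molecules from the configured pool and emit reads.

    Each read is ``i5 + amplicon(+errors) + i7`` with a Phred+33 quality
    string over the full read.  A depth draw of zero yields an empty,
    warning-flagged sample (empty read list), not a failure.
    """
    edits, spliced = molecules
    role_offsets = {role: reference.site(role)[0] for role in SITE_ROLES}
    if config.library_type == "mrna":
        pool = np.flatnonzero(spliced)
    elif config.library_type == "pre_mrna":
        pool = np.flatnonzero(~spliced)
    else:
        pool = np.arange(len(spliced))
    rng = _as_rng(seed if seed is not None else config.seed)
    depth = int(rng.negative_binomial(
        n=config.depth_dispersion,
        p=config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
    ))
    pre_rates = {r: float(edits[:, i].mean()) for i, r in enumerate(SITE_ROLES)}
    m_rates = {
        r: (float(edits[spliced, i].mean()) if spliced.any() else float("nan"))
        for i, r in enumerate(SITE_ROLES)
    }
    if depth == 0 or len(pool) == 0:
        truth = TruthRecord(
            sample_id=sample_id,
            seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
            depth=0,
            pre_mrna_rates=pre_rates,
            mrna_rates=m_rates,
            sequenced_g_truth={r: 0 for r in SITE_ROLES},
            spliced_fraction=float(spliced.mean()),
        )
        return [], truth

    chosen = pool[rng.integers(0, len(pool), size=depth)]
    read_edits = edits[chosen]  # (depth, 3)

    insert = np.frombuffer(reference.sequence.encode(), dtype="S1")
    full = np.concatenate(
        [
            np.frombuffer(barcodes.i5.encode(), dtype="S1"),
            insert,
            np.frombuffer(barcodes.i7.encode(), dtype="S1"),
        ]
    )
    reads_arr = np.tile(full, (depth, 1))
    for i, role in enumerate(SITE_ROLES):
        col = 8 + role_offsets[role]
        reads_arr[read_edits[:, i], col] = b"G"

    qmean = _phred_mean(config)
    quals = np.clip(
        np.rint(rng.normal(qmean, config.phred_sd, size=reads_arr.shape)), 2, 41
    ).astype(np.int64)
    reads_arr = _mutate(reads_arr, quals, config.error_rate, rng)
    qual_chars = (quals + 33).astype(np.uint8)

    reads = [
        FastqRead(
            name=f"{sample_id}:{i}",
            sequence=reads_arr[i].tobytes().decode(),
            quality=qual_chars[i].tobytes().decode(),
        )
        for i in range(depth)
    ]
    truth = TruthRecord(
        sample_id=sample_id,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        depth=depth,
        pre_mrna_rates=pre_rates,
        mrna_rates=m_rates,
        sequenced_g_truth={
            r: int(read_edits[:, i].sum()) for i, r in enumerate(SITE_ROLES)
        },
        spliced_fraction=float(spliced.mean()),
    )
    return reads, truth


def simulate_sample(
    reference: AmpliconReference,
    barcodes: BarcodePair,
    config: SimulationConfig,
    seed=None,
    sample_id: str = "sample",
    n_molecules: int = 50_000,
) -> tuple[list[FastqRead], TruthRecord]:
    """Convenience: molecules + library for one sample with a single seed."""
    rng = _as_rng(seed if seed is not None else config.seed)
    molecules = simulate_molecules(config, n_molecules, rng)
    return emit_library(molecules, reference, barcodes, config, rng, sample_id)


def simulate_study(
    reference: AmpliconReference,
    sheet: SampleSheet,
    configs: dict[str, SimulationConfig] | SimulationConfig,
    seed: int = 0,
    n_molecules: int = 50_000,
    shuffle: bool = True,
) -> tuple[list[FastqRead], dict[str, TruthRecord]]:
    """Simulate a pooled multiplexed library for every sample in the sheet.

    ``configs`` is either one config for all samples or a mapping
    ``sample_id -> SimulationConfig``.  Returns the pooled (optionally
    shuffled) read list plus per-sample truth records.
    """
    rng = np.random.default_rng(seed)
    all_reads: list[FastqRead] = []
    truths: dict[str, TruthRecord] = {}
    for meta, bc in sheet:
        cfg = configs[meta.sample_id] if isinstance(configs, dict) else configs
        reads, truth = simulate_sample(
            reference, bc, cfg, rng, sample_id=meta.sample_id, n_molecules=n_molecules
        )
        all_reads.extend(reads)
        truths[meta.sample_id] = truth
    if shuffle:
        order = rng.permutation(len(all_reads))
        all_reads = [all_reads[i] for i in order]
    return all_reads, truths


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    """Write reads to FASTQ; gzip-compressed when the path ends in .gz."""
    path = str(path)
    op = gzip.open if path.endswith(".gz") else open
    with op(path, "wt") as fh:
        for r in reads:
            fh.write(r.fastq())


def simulate_site_counts(
    true_rate: float, depth: int, error_rate: float, seed=None
):
    """Draw per-site base counts under the generator's substitution model.

    The base read out at an editable adenosine is G with probability
    ``p*(1-e) + (1-p)*e/3``, A with ``(1-p)*(1-e) + p*e/3`` and C or T with
    ``e/3`` each.  Returns a :class:`~ampliedit.quantify.SiteCounts`.  This is
    the counts-level shortcut for estimator studies at full study depth; the
    read-level path exercises the identical error model.
    """
    from .quantify import SiteCounts

    if not 0.0 <= true_rate <= 1.0:
        raise SimulationError("true_rate must lie in [0, 1]")
    rng = _as_rng(seed)
    e = error_rate
    p = true_rate
    probs = [
        (1 - p) * (1 - e) + p * e / 3.0,  # A
        e / 3.0,  # C
        p * (1 - e) + (1 - p) * e / 3.0,  # G
        e / 3.0,  # T
    ]
    a, c, g, t = rng.multinomial(depth, probs)
    return SiteCounts(role="Q/R", a=int(a), c=int(c), g=int(g), t=int(t), n=0)


def simulate_qpcr(
    expression: dict[str, float],
    noise_sd: float = 0.0,
    reference_ct: float = 20.0,
    seed=None,
):
    """Simulate a qPCR Ct table for the dCt method.

    For each sample, ``Ct_target - Ct_ref = -log2(relative expression)`` plus
    independent Gaussian noise of sd ``noise_sd`` on each Ct value.  Returns a
    pandas DataFrame with columns sample_id, ct_target, ct_reference.
    """
    import pandas as pd

    rng = _as_rng(seed)
    rows = []
    for sid, expr in expression.items():
        if not expr > 0:
            raise SimulationError(f"sample {sid}: expression must be positive")
        ct_ref = reference_ct + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        ct_tgt = (
            reference_ct
            - math.log2(expr)
            + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        )
        rows.append({"sample_id": sid, "ct_target": ct_tgt, "ct_reference": ct_ref})
    return pd.DataFrame(rows)


def simulate_sanger_peaks(
    true_rate: float, noise_sd: float = 0.0, seed=None
) -> tuple[float, float]:
    """Simulate a Sanger chromatogram peak pair (A, G) at an edited site.

    Peak heights are the true base fractions plus truncated Gaussian noise, so
    the expected ``G/(A+G)`` ratio equals the true editing rate at small
    noise.  Peak-ratio quantification is noisier than counting reads,
    especially at low rates.
    """
    if not 0.0 <= true_rate <= 1.0:
        raise SimulationError("true_rate must lie in [0, 1]")
    rng = _as_rng(seed)
    peak_g = true_rate + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
    peak_a = (1.0 - true_rate) + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
    return (max(peak_a, 0.0), max(peak_g, 0.0))


def random_sample_sheet(
    n_samples: int,
    seed=None,
    min_pair_distance: int = 4,
    tissues: Sequence[str] | None = None,
    timepoints: Sequence[str] = ("P0", "P21", "P120"),
    replicates: int = 3,
) -> SampleSheet:
    """Generate a dual-barcode sample sheet with well-separated barcode pairs.

    Pairs are drawn uniformly and accepted only if their combined Hamming
    distance to every accepted pair is at least ``min_pair_distance``.
    Samples are laid out tissue-major over timepoints and replicates.
    """
    rng = _as_rng(seed)
    pairs: list[BarcodePair] = []
    while len(pairs) < n_samples:
        cand = BarcodePair(
            "".join(rng.choice(list("ACGT"), 8)), "".join(rng.choice(list("ACGT"), 8))
        )
        if all(combined_distance(cand, p) >= min_pair_distance for p in pairs):
            pairs.append(cand)
    if tissues is None:
        per_tissue = len(timepoints) * replicates
        n_tissues = math.ceil(n_samples / per_tissue)
        tissues = [f"tissue{i + 1:02d}" for i in range(n_tissues)]
    entries = []
    i = 0
    for tissue in tissues:
        for tp in timepoints:
            for rep in range(1, replicates + 1):
                if i >= n_samples:
                    break
                entries.append(
                    (SampleMeta(f"s{i + 1:03d}", tissue, tp, rep), pairs[i])
                )
                i += 1
    return SampleSheet(entries[:n_samples])
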