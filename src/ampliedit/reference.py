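"""Amplicon reference model: sequences, genomic anchoring and editing-site catalogs.

An :class:`AmpliconReference` ties a short PCR amplicon sequence (given on the
transcript strand) to genomic coordinates through a single anchor, and carries
a catalog of positions of interest: editable adenosines (A-to-I editing sites,
read out as A->G by the sequencer) and non-editable control positions used to
measure the background error floor.

Coordinates are 0-based half-open internally; every reported genomic
coordinate is 1-based, genome-browser style.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

VALID_BASES = set("ACGTN")
VALID_REGIONS = ("exonic", "intronic")
TIMEPOINT_ORDER = {"P0": 0, "P21": 1, "P120": 2}


class ReferenceError(ValueError):
    """Raised when an amplicon reference or site catalog fails validation."""


@dataclass(frozen=True)
class GenomicSite:
    """A single genomic position of interest on the transcript strand.

    ``ref_base`` is the reference base on the *transcript* strand; for an
    editable site it must be ``A`` (editing is defined on the transcript).
    ``role`` is a free label such as ``"Q/R"``, ``"S/G"``, ``"intron+4"`` or
    ``"control_1"``; roles must be unique within one catalog.
    """

    chrom: str
    position: int  # 1-based
    strand: str
    ref_base: str
    role: str
    region: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ReferenceError(f"site {self.role!r}: position must be positive")
        if self.strand not in ("+", "-"):
            raise ReferenceError(f"site {self.role!r}: strand must be '+' or '-'")
        if self.ref_base not in VALID_BASES:
            raise ReferenceError(f"site {self.role!r}: bad ref_base {self.ref_base!r}")
        if self.region not in VALID_REGIONS:
            raise ReferenceError(f"site {self.role!r}: bad region {self.region!r}")

    @property
    def editable(self) -> bool:
        """True for catalog entries that mark an editable adenosine."""
        return not self.role.startswith("control") and self.ref_base == "A"


@dataclass
class SampleMeta:
    """Identity of one biological sample: tissue, developmental timepoint, replicate."""

    sample_id: str
    tissue: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ReferenceError(f"sample {self.sample_id}: replicate must be >= 1")

    @property
    def group(self) -> tuple[str, str]:
        return (self.tissue, self.timepoint)


@dataclass(frozen=True)
class BarcodePair:
    """Dual 8-nt sample indices flanking the insert (i5 at 5', i7 at 3')."""

    i5: str
    i7: str

    def __post_init__(self) -> None:
        for name, bc in (("i5", self.i5), ("i7", self.i7)):
            if len(bc) != 8 or set(bc) - set("ACGT"):
                raise ReferenceError(f"{name} barcode {bc!r}: must be 8 nt over ACGT")


@dataclass
class AmpliconReference:
    """A validated amplicon with genomic anchoring and a site catalog.

    ``sites`` maps 0-based amplicon offsets to :class:`GenomicSite` entries.
    Offset 0 of the sequence corresponds to ``anchor_pos`` on ``anchor_chrom``;
    on the ``+`` strand genomic positions increase with offset, on ``-`` they
    decrease.
    """

    name: str
    sequence: str
    anchor_chrom: str
    anchor_pos: int
    strand: str
    sites: list[tuple[int, GenomicSite]] = field(default_factory=list)
    primer_fwd: str = ""
    primer_rev: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence or set(self.sequence) - VALID_BASES:
            raise ReferenceError("amplicon sequence must be non-empty over ACGTN")
        if self.strand not in ("+", "-"):
            raise ReferenceError("strand must be '+' or '-'")
        roles = [s.role for _, s in self.sites]
        if len(roles) != len(set(roles)):
            raise ReferenceError("duplicate role labels in site catalog")
        for off, site in self.sites:
            if not 0 <= off < len(self.sequence):
                raise ReferenceError(
                    f"site {site.role!r}: offset {off} outside [0, {len(self.sequence)})"
                )
            if self.sequence[off] != site.ref_base:
                raise ReferenceError(
                    f"site {site.role!r}: reference base mismatch at offset {off} "
                    f"(sequence has {self.sequence[off]}, catalog says {site.ref_base})"
                )
            got = self.offset_to_genomic(off)
            if got != (site.chrom, site.position):
                raise ReferenceError(
                    f"site {site.role!r}: genomic anchor inconsistency "
                    f"(offset {off} maps to {got}, catalog says "
                    f"({site.chrom}, {site.position}))"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_to_genomic(self, offset: int) -> tuple[str, int]:
        """Map a 0-based amplicon offset to (chrom, 1-based genomic position)."""
        if not 0 <= offset < len(self.sequence):
            raise ReferenceError(f"offset {offset} outside [0, {len(self.sequence)})")
        if self.strand == "+":
            return (self.anchor_chrom, self.anchor_pos + offset)
        return (self.anchor_chrom, self.anchor_pos - offset)

    def genomic_to_offset(self, chrom: str, position: int) -> int:
        """Inverse of :meth:`offset_to_genomic`."""
        if chrom != self.anchor_chrom:
            raise ReferenceError(f"chromosome {chrom!r} != anchor {self.anchor_chrom!r}")
        off = position - self.anchor_pos if self.strand == "+" else self.anchor_pos - position
        if not 0 <= off < len(self.sequence):
            raise ReferenceError(f"position {chrom}:{position} outside the amplicon")
        return off

    def site(self, role: str) -> tuple[int, GenomicSite]:
        for off, s in self.sites:
            if s.role == role:
                return off, s
        raise KeyError(role)

    @property
    def editable_sites(self) -> list[tuple[int, GenomicSite]]:
        return [(o, s) for o, s in self.sites if s.editable]

    @property
    def control_sites(self) -> list[tuple[int, GenomicSite]]:
        return [(o, s) for o, s in self.sites if not s.editable]


def build_amplicon_reference(fasta_record, site_catalog: dict) -> AmpliconReference:
    """Build and validate an :class:`AmpliconReference`.

    Parameters
    ----------
    fasta_record
        A Bio.SeqRecord (or any object with ``id`` and ``seq``) holding the
        amplicon sequence on the transcript strand.
    site_catalog
        Mapping with keys ``name`` (optional, defaults to the record id),
        ``anchor_chrom``, ``anchor_pos``, ``strand``, optional ``primer_fwd``
        / ``primer_rev``, and ``sites``: a list of dicts each carrying
        ``role``, ``ref_base``, ``region`` and either a 0-based ``offset`` or
        a 1-based ``genomic_pos``.
    """
    seq = str(fasta_record.seq).upper()
    strand = site_catalog["strand"]
    anchor_chrom = site_catalog["anchor_chrom"]
    anchor_pos = int(site_catalog["anchor_pos"])
    sites: list[tuple[int, GenomicSite]] = []
    for entry in site_catalog.get("sites", []):
        if "offset" in entry:
            off = int(entry["offset"])
            if strand == "+":
                pos = anchor_pos + off
            else:
                pos = anchor_pos - off
        elif "genomic_pos" in entry:
            pos = int(entry["genomic_pos"])
            off = pos - anchor_pos if strand == "+" else anchor_pos - pos
        else:
            raise ReferenceError(
                f"site {entry.get('role')!r}: need 'offset' or 'genomic_pos'"
            )
        sites.append(
            (
                off,
                GenomicSite(
                    chrom=anchor_chrom,
                    position=pos,
                    strand=strand,
                    ref_base=entry["ref_base"].upper(),
                    role=entry["role"],
                    region=entry["region"],
                ),
            )
        )
    return AmpliconReference(
        name=site_catalog.get("name", getattr(fasta_record, "id", "amplicon")),
        sequence=seq,
        anchor_chrom=anchor_chrom,
        anchor_pos=anchor_pos,
        strand=strand,
        sites=sites,
        primer_fwd=site_catalog.get("primer_fwd", ""),
        primer_rev=site_catalog.get("primer_rev", ""),
    )


def load_reference(fasta_path: str | Path, catalog_path: str | Path) -> AmpliconReference:
    """Load an amplicon reference from a FASTA file plus a JSON site catalog."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    with open(catalog_path) as fh:
        catalog = json.load(fh)
    return build_amplicon_reference(record, catalog)


def flnb_synthetic_reference() -> AmpliconReference:
    """The bundled synthetic Flnb-like amplicon fixture.

    A synthetic 100-nt sequence (not the true mm10 sequence) that preserves
    the genomic geometry of the murine Flnb editing region: the Q/R codon
    adenosine at chr14:7,936,048, the S/G adenosine 7 nt upstream at
    chr14:7,936,041, the intronic +4 adenosine at chr14:7,936,053, and the
    donor 9-mer context CAG|gtgagg across the exon 41 junction.  Three
    non-editable adenosines are cataloged as error-floor controls.
    """
    data = resources.files("ampliedit").joinpath("data")
    with resources.as_file(data.joinpath("flnb_synthetic.fa")) as fa, resources.as_file(
        data.joinpath("flnb_synthetic.json")
    ) as js:
        return load_reference(fa, js)


class SampleSheet:
    """Dual-barcode sample sheet: sample metadata paired with i5/i7 indices."""

    def __init__(self, entries: Iterable[tuple[SampleMeta, BarcodePair]]):
        self.entries: list[tuple[SampleMeta, BarcodePair]] = list(entries)
        ids = [m.sample_id for m, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ReferenceError("duplicate sample_id in sample sheet")
        keys = [(m.tissue, m.timepoint, m.replicate) for m, _ in self.entries]
        if len(keys) != len(set(keys)):
            raise ReferenceError("duplicate (tissue, timepoint, replicate) in sample sheet")
        pairs = [(b.i5, b.i7) for _, b in self.entries]
        if len(pairs) != len(set(pairs)):
            raise ReferenceError("duplicate (i5, i7) barcode pair in sample sheet")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def meta(self, sample_id: str) -> SampleMeta:
        for m, _ in self.entries:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m, _ in self.entries]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        """Read a TSV with columns sample_id, tissue, timepoint, replicate, i5, i7."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "tissue", "timepoint", "replicate", "i5", "i7"}
        missing = required - set(df.columns)
        if missing:
            raise ReferenceError(f"sample sheet missing columns: {sorted(missing)}")
        entries = [
            (
                SampleMeta(r.sample_id, r.tissue, r.timepoint, int(r.replicate)),
                BarcodePair(r.i5.upper(), r.i7.upper()),
            )
            for r in df.itertuples()
        ]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            {
                "sample_id": m.sample_id,
                "tissue": m.tissue,
                "timepoint": m.timepoint,
                "replicate": m.replicate,
                "i5": b.i5,
                "i7": b.i7,
            }
            for m, b in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def combined_distance(a: BarcodePair, b: BarcodePair) -> int:
    """Combined Hamming distance over both 8-nt indices (16 positions)."""
    return sum(x != y for x, y in zip(a.i5, b.i5)) + sum(
        x != y for x, y in zip(a.i7, b.i7)
    )
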