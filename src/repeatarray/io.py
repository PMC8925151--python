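"""Reading and structuring minisatellite alleles.

A minisatellite allele is an ordered array of fixed-length nucleotide repeat
units (84 nt by default, each encoding one C2H2 zinc finger).  This module
reads allele FASTA files together with a sample table, partitions each allele
into repeat units, translates units into zinc fingers, excises the
hypervariable DNA-contact codons ("masking") and validates the C2H2 anchor
residues.

Coordinates in all user-facing structures are 1-based and closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ConfigError, MetadataError, PartitionError

logger = logging.getLogger(__name__)

#: Default repeat-unit length in nucleotides (one zinc finger per unit).
DEFAULT_UNIT_LENGTH = 84

#: Amino-acid positions (1-based within the 28-residue unit) of the DNA-contact
#: residues, i.e. alpha-helix positions -1, +3 and +6.
DEFAULT_CONTACT_POSITIONS = (13, 16, 19)

#: 1-based amino-acid offsets of the C2H2 anchor residues (Cys, Cys, His, His)
#: in the reference repeat unit used by this package.
DEFAULT_ANCHOR_OFFSETS = (4, 9, 20, 24)

_ANCHOR_RESIDUES = ("C", "C", "H", "H")

VALID_HEMISPHERES = ("NH", "SH")


@dataclass(frozen=True)
class MaskSpec:
    """Which codons to excise before masked comparisons.

    ``contact_positions`` are 1-based amino-acid indices within a repeat unit;
    position k covers nucleotides 3k-2 .. 3k (1-based, closed).  The default
    (13, 16, 19) removes the three hypervariable DNA-contact codons, so an
    84-nt unit masks to 75 nt.
    """

    contact_positions: tuple[int, ...] = DEFAULT_CONTACT_POSITIONS

    def __post_init__(self) -> None:
        pos = self.contact_positions
        if list(pos) != sorted(set(pos)):
            raise ConfigError("mask positions must be strictly increasing")
        if pos and pos[0] < 1:
            raise ConfigError("mask positions are 1-based (must be >= 1)")

    def nt_ranges(self) -> list[tuple[int, int]]:
        """1-based closed nucleotide ranges covered by the masked codons."""
        return [(3 * k - 2, 3 * k) for k in self.contact_positions]

    def masked_nt_indices(self, unit_length: int) -> list[int]:
        """0-based nucleotide indices removed from a unit of ``unit_length``."""
        if self.contact_positions and 3 * max(self.contact_positions) > unit_length:
            raise ConfigError(
                f"mask position {max(self.contact_positions)} outside a "
                f"{unit_length}-nt unit"
            )
        idx = []
        for lo, hi in self.nt_ranges():
            idx.extend(range(lo - 1, hi))
        return idx

    def apply(self, seq: str) -> str:
        """Return ``seq`` with the masked codons excised, order preserved."""
        drop = set(self.masked_nt_indices(len(seq)))
        return "".join(c for i, c in enumerate(seq) if i not in drop)


DEFAULT_MASK = MaskSpec()


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat unit of a minisatellite array.

    ``index`` is the 1-based position within the array; ``masked_seq`` is the
    unit with the hypervariable contact codons excised.
    """

    seq: str
    index: int
    masked_seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def compared_seq(self, masked: bool) -> str:
        return self.masked_seq if masked else self.seq


@dataclass(frozen=True)
class ZincFinger:
    """Translation of one repeat unit into a 28-residue C2H2 zinc finger.

    ``contact_code`` concatenates the residues at the DNA-contact positions
    (e.g. "DSK"); it is None when any contact codon is ambiguous.  ``valid``
    is False when the translation contains a stop codon or an ambiguous
    (N-containing) codon; ``reason`` says why.
    """

    aa: str
    contact_code: str | None
    valid: bool
    unit_index: int
    reason: str | None = None


@dataclass
class MinisatelliteAllele:
    """An ordered repeat array attributed to an individual and population."""

    allele_id: str
    individual_id: str
    population: str
    hemisphere: str
    units: list[RepeatUnit]
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if not self.units:
            raise PartitionError(f"allele {self.allele_id}: empty repeat array")
        lengths = {len(u) for u in self.units}
        if len(lengths) != 1:
            raise PartitionError(
                f"allele {self.allele_id}: units of unequal length {lengths}"
            )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_length(self) -> int:
        return len(self.units[0])

    @property
    def array_seq(self) -> str:
        """The repeat-array nucleotide sequence (flanks excluded)."""
        return "".join(u.seq for u in self.units)

    def unit_seqs(self, masked: bool = False) -> tuple[str, ...]:
        return tuple(u.compared_seq(masked) for u in self.units)

    def zincfingers(self, mask: MaskSpec = DEFAULT_MASK) -> list[ZincFinger]:
        return [translate_unit(u, mask=mask) for u in self.units]


def partition_allele(
    seq: str,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    mask: MaskSpec = DEFAULT_MASK,
) -> list[RepeatUnit]:
    """Cut an array sequence into consecutive non-overlapping repeat units.

    Units are returned 5'->3' with 1-based indices.  Raises
    :class:`PartitionError` if the length is not a multiple of
    ``unit_length``.
    """
    seq = seq.upper()
    if unit_length < 1:
        raise ConfigError("unit_length must be >= 1")
    if len(seq) == 0 or len(seq) % unit_length != 0:
        raise PartitionError(
            f"sequence length {len(seq)} is not a positive multiple of "
            f"unit length {unit_length}"
        )
    units = []
    for i in range(len(seq) // unit_length):
        s = seq[i * unit_length : (i + 1) * unit_length]
        units.append(RepeatUnit(seq=s, index=i + 1, masked_seq=mask.apply(s)))
    return units


def translate_unit(
    unit: RepeatUnit,
    mask: MaskSpec = DEFAULT_MASK,
    frame_offset: int = 0,
) -> ZincFinger:
    """Translate a repeat unit (frame 1 by default) into a zinc finger.

    A stop codon or an N-containing codon marks the finger invalid (with a
    reason) rather than raising.  The contact code is extracted whenever all
    contact codons are unambiguous, even for invalid fingers.
    """
    nt = unit.seq[frame_offset:]
    if len(nt) % 3 != 0:
        raise PartitionError(
            f"unit {unit.index}: length {len(nt)} not divisible by 3"
        )
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    ambiguous = any("N" in c for c in codons)
    aa = str(Seq(nt).translate())
    has_stop = "*" in aa
    reason = None
    if has_stop:
        reason = "stop"
    elif ambiguous:
        reason = "ambiguous"
    code = None
    positions = mask.contact_positions
    if all(p <= len(codons) for p in positions) and not any(
        "N" in codons[p - 1] for p in positions
    ):
        code = "".join(aa[p - 1] for p in positions)
        if "*" in code:
            code = None
    return ZincFinger(
        aa=aa,
        contact_code=code,
        valid=not (has_stop or ambiguous),
        unit_index=unit.index,
        reason=reason,
    )


def mask_unit(unit: RepeatUnit, mask: MaskSpec = DEFAULT_MASK) -> str:
    """Return the unit sequence with the masked codons excised."""
    return mask.apply(unit.seq)


def validate_znf(
    zf: ZincFinger,
    anchor_offsets: Sequence[int] = DEFAULT_ANCHOR_OFFSETS,
) -> bool:
    """Check the C2H2 anchor residues (Cys, Cys, His, His) and absence of stops.

    ``anchor_offsets`` are 1-based amino-acid positions expected to carry, in
    order, C, C, H, H.  This anchor check is the package's structural validity
    test for a zinc finger.
    """
    if len(anchor_offsets) != 4:
        raise ConfigError("exactly four anchor offsets (C, C, H, H) required")
    if "*" in zf.aa:
        return False
    if any(p < 1 or p > len(zf.aa) for p in anchor_offsets):
        raise ConfigError("anchor offset outside the translated unit")
    return all(
        zf.aa[p - 1] == want for p, want in zip(anchor_offsets, _ANCHOR_RESIDUES)
    )


def read_sample_table(samples_path: str | Path) -> pd.DataFrame:
    """Read the TSV mapping allele -> individual -> population -> hemisphere."""
    # keep_default_na: "NA" is the North Atlantic population, not missing data
    df = pd.read_csv(
        samples_path, sep="\t", dtype=str, comment="#",
        keep_default_na=False, na_values=[],
    )
    required = ["allele_id", "individual_id", "population", "hemisphere"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MetadataError(f"sample table missing columns: {missing}")
    bad_hem = set(df["hemisphere"]) - set(VALID_HEMISPHERES)
    if bad_hem:
        raise MetadataError(f"unknown hemisphere labels: {sorted(bad_hem)}")
    if df["allele_id"].duplicated().any():
        dups = df.loc[df["allele_id"].duplicated(), "allele_id"].tolist()
        raise MetadataError(f"duplicate allele_id rows: {dups}")
    return df


def read_alleles(
    fasta_path: str | Path,
    samples_path: str | Path,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    flank5_len: int = 0,
    flank3_len: int = 0,
    mask: MaskSpec = DEFAULT_MASK,
) -> list[MinisatelliteAllele]:
    """Read allele sequences and metadata into :class:`MinisatelliteAllele`.

    Each FASTA record is trimmed of the declared 5'/3' flanks and partitioned
    into ``unit_length`` repeat units.  Record order is preserved.  A record
    absent from the sample table raises :class:`MetadataError`; a trimmed
    length that is not a multiple of the unit length raises
    :class:`PartitionError` naming the record.
    """
    table = read_sample_table(samples_path).set_index("allele_id")
    alleles = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in table.index:
            raise MetadataError(f"record {rec.id!r} absent from sample table")
        row = table.loc[rec.id]
        seq = str(rec.seq).upper()
        end = len(seq) - flank3_len if flank3_len else len(seq)
        core = seq[flank5_len:end]
        try:
            units = partition_allele(core, unit_length=unit_length, mask=mask)
        except PartitionError as e:
            raise PartitionError(f"record {rec.id!r}: {e}") from e
        alleles.append(
            MinisatelliteAllele(
                allele_id=rec.id,
                individual_id=row["individual_id"],
                population=row["population"],
                hemisphere=row["hemisphere"],
                units=units,
                flank5=seq[:flank5_len],
                flank3=seq[end:],
            )
        )
    if not alleles:
        raise MetadataError(f"no FASTA records found in {fasta_path}")
    logger.info("read %d alleles from %s", len(alleles), fasta_path)
    return alleles


def write_unit_table(
    alleles: Iterable[MinisatelliteAllele],
    path: str | Path,
    mask: MaskSpec = DEFAULT_MASK,
    header_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """Emit the per-unit TSV (allele, unit index, sequence, translation)."""
    rows = []
    for a in alleles:
        for u, zf in zip(a.units, a.zincfingers(mask)):
            rows.append(
                {
                    "allele_id": a.allele_id,
                    "unit_index": u.index,
                    "unit_seq": u.seq,
                    "aa": zf.aa,
                    "contact_code": zf.contact_code or "NA",
                    "valid": validate_znf(zf) and zf.valid,
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df
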