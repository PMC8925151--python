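"""Zinc-finger catalogues, allele-variant naming and core-motif comparison.

A *ZnF type* is a distinct 28-residue amino-acid sequence observed across the
repeat units of the sample; types seen in more than one individual are
"common", the rest "unique".  Whole arrays are collapsed into *allele
variants* (identity at the protein level by default) and named
``<hemisphere><total ZnFs>_<letter>``, counting the proximal zinc knuckle in
the total.  The *core motif* is the DNA-contact-code fingerprint of the array
fingers most important for DNA binding (positions 3-6 by default); pairs of
core motifs classify as symmetric / partial / asymmetric binding predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError
from .io import DEFAULT_MASK, MaskSpec, MinisatelliteAllele, ZincFinger

logger = logging.getLogger(__name__)

DEFAULT_CORE_WINDOW = (3, 6)
DEFAULT_KNUCKLE_COUNT = 1


@dataclass
class ZnFType:
    """One distinct zinc-finger amino-acid sequence and its carriers."""

    type_id: str
    aa: str
    contact_code: str | None
    carrier_individuals: frozenset[str]
    occurrence_count: int

    @property
    def status(self) -> str:
        return "common" if len(self.carrier_individuals) > 1 else "unique"


@dataclass
class AlleleVariant:
    """A named allele variant: one distinct (protein-level) repeat array."""

    variant_id: str
    hemisphere: str
    total_znf_count: int
    member_alleles: frozenset[str]
    carrier_individuals: frozenset[str]
    array_signature: tuple[str, ...]
    contact_codes: tuple[str, ...]

    @property
    def n_array_units(self) -> int:
        return len(self.array_signature)


@dataclass(frozen=True)
class CoreMotif:
    """Contact codes of a 1-based closed window of array zinc fingers."""

    window: tuple[int, int]
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if hi - lo + 1 != len(self.codes):
            raise ConfigError("core-motif window span != number of codes")


@dataclass(frozen=True)
class MotifComparison:
    """Per-position agreement of two equally sized core motifs."""

    category: str  # symmetric | partial | asymmetric
    matches: tuple[bool, ...]

    @property
    def n_match(self) -> int:
        return sum(self.matches)

    @property
    def n_positions(self) -> int:
        return len(self.matches)


def build_catalog(
    zincfingers: Iterable[tuple[ZincFinger, str]],
) -> list[ZnFType]:
    """Group valid zinc fingers into types by full amino-acid sequence.

    Input is (finger, individual_id) pairs; only valid fingers should be
    supplied.  Types are ordered by descending occurrence count, then by
    amino-acid sequence, and given ids ZF01, ZF02, ...  An empty input yields
    an empty catalogue with a warning.
    """
    by_aa: dict[str, dict] = {}
    for zf, ind in zincfingers:
        entry = by_aa.setdefault(
            zf.aa, {"carriers": set(), "count": 0, "code": zf.contact_code}
        )
        entry["carriers"].add(ind)
        entry["count"] += 1
        if entry["code"] is None:
            entry["code"] = zf.contact_code
    if not by_aa:
        logger.warning("empty zinc-finger input: empty catalogue")
        return []
    ordered = sorted(by_aa.items(), key=lambda kv: (-kv[1]["count"], kv[0]))
    width = max(2, len(str(len(ordered))))
    return [
        ZnFType(
            type_id=f"ZF{i + 1:0{width}d}",
            aa=aa,
            contact_code=info["code"],
            carrier_individuals=frozenset(info["carriers"]),
            occurrence_count=info["count"],
        )
        for i, (aa, info) in enumerate(ordered)
    ]


def validate_and_collect(
    alleles: Sequence[MinisatelliteAllele],
    mask: MaskSpec = DEFAULT_MASK,
    anchor_offsets: Sequence[int] | None = None,
) -> list[tuple[ZincFinger, str]]:
    """Translate every unit and keep only structurally valid zinc fingers.

    Validity = clean translation (no stop, no ambiguity) plus the C2H2
    anchor check; invalid fingers are counted in a log line.
    """
    from .io import DEFAULT_ANCHOR_OFFSETS, validate_znf

    offsets = tuple(anchor_offsets or DEFAULT_ANCHOR_OFFSETS)
    kept, dropped = [], 0
    for a in alleles:
        for zf in a.zincfingers(mask):
            if zf.valid and validate_znf(zf, offsets):
                kept.append((zf, a.individual_id))
            else:
                dropped += 1
    if dropped:
        logger.info("dropped %d invalid zinc fingers", dropped)
    return kept


def _letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA ... (spreadsheet-column style)."""
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def name_alleles(
    alleles: Sequence[MinisatelliteAllele],
    knuckle_count: int = DEFAULT_KNUCKLE_COUNT,
    mask: MaskSpec = DEFAULT_MASK,
    nucleotide_level: bool = False,
) -> list[AlleleVariant]:
    """Collapse alleles into variants and assign deterministic names.

    Variant identity is the ordered tuple of per-unit amino-acid sequences
    (``nucleotide_level=True`` splits finer, on nucleotide sequences).  The
    name is ``<HEM><total>_<letter>`` where total counts array units plus the
    proximal zinc knuckle(s), and letters are assigned within each
    (hemisphere, total) group by descending number of carrier individuals,
    ties broken lexicographically on the array signature.
    """
    groups: dict[tuple, dict] = {}
    for a in alleles:
        fingers = a.zincfingers(mask)
        sig = a.unit_seqs() if nucleotide_level else tuple(z.aa for z in fingers)
        key = (a.hemisphere, sig)
        g = groups.setdefault(
            key,
            {
                "alleles": set(),
                "individuals": set(),
                "codes": tuple(z.contact_code or "???" for z in fingers),
            },
        )
        g["alleles"].add(a.allele_id)
        g["individuals"].add(a.individual_id)

    variants: list[AlleleVariant] = []
    # letter groups: same hemisphere and same total finger count
    by_name_group: dict[tuple[str, int], list[tuple]] = {}
    for (hem, sig), g in groups.items():
        total = len(sig) + knuckle_count
        by_name_group.setdefault((hem, total), []).append((sig, g))
    for (hem, total), members in sorted(by_name_group.items()):
        members.sort(key=lambda m: (-len(m[1]["individuals"]), m[0]))
        for i, (sig, g) in enumerate(members):
            variants.append(
                AlleleVariant(
                    variant_id=f"{hem}{total}_{_letters(i)}",
                    hemisphere=hem,
                    total_znf_count=total,
                    member_alleles=frozenset(g["alleles"]),
                    carrier_individuals=frozenset(g["individuals"]),
                    array_signature=sig,
                    contact_codes=g["codes"],
                )
            )
    return variants


def core_motif(
    variant: AlleleVariant,
    window: tuple[int, int] = DEFAULT_CORE_WINDOW,
) -> CoreMotif:
    """Extract the contact-code fingerprint of array positions ``window``.

    The window is 1-based and closed on the array (the knuckle is excluded
    from the numbering).
    """
    lo, hi = window
    if lo < 1 or hi > variant.n_array_units or lo > hi:
        raise ConfigError(
            f"core-motif window {window} outside array of "
            f"{variant.n_array_units} units ({variant.variant_id})"
        )
    return CoreMotif(window=(lo, hi), codes=variant.contact_codes[lo - 1 : hi])


def classify_pair(m1: CoreMotif, m2: CoreMotif) -> MotifComparison:
    """Classify a pair of core motifs as symmetric / partial / asymmetric.

    Symmetric: contact codes identical at every window position (predicting
    fully symmetric binding of the two variants' target motifs).  Asymmetric:
    different at every position.  Partial: anything in between.  Per-position
    matches are carried so users can apply their own threshold.
    """
    if len(m1.codes) != len(m2.codes):
        raise ConfigError("core motifs span different window sizes")
    matches = tuple(c1 == c2 for c1, c2 in zip(m1.codes, m2.codes))
    if all(matches):
        category = "symmetric"
    elif not any(matches):
        category = "asymmetric"
    else:
        category = "partial"
    return MotifComparison(category=category, matches=matches)


def write_catalog(
    catalog: Sequence[ZnFType], path: str | Path, header_lines: Sequence[str] = ()
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "type_id": [t.type_id for t in catalog],
            "aa": [t.aa for t in catalog],
            "contact_code": [t.contact_code or "NA" for t in catalog],
            "n_individuals": [len(t.carrier_individuals) for t in catalog],
            "status": [t.status for t in catalog],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df


def write_variants(
    variants: Sequence[AlleleVariant],
    path: str | Path,
    catalog: Sequence[ZnFType] | None = None,
    header_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """Variants TSV; the signature column uses catalogue type ids if given."""
    aa_to_id = {t.aa: t.type_id for t in catalog} if catalog else {}
    rows = []
    for v in variants:
        sig = "-".join(aa_to_id.get(aa, aa) for aa in v.array_signature)
        rows.append(
            {
                "variant_id": v.variant_id,
                "hemisphere": v.hemisphere,
                "total_znfs": v.total_znf_count,
                "signature": sig,
                "n_alleles": len(v.member_alleles),
                "n_individuals": len(v.carrier_individuals),
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df


def write_motif_report(
    variants: Sequence[AlleleVariant],
    path: str | Path,
    window: tuple[int, int] = DEFAULT_CORE_WINDOW,
    header_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """All-pairs core-motif comparison with per-position match counts."""
    eligible = [v for v in variants if v.n_array_units >= window[1]]
    skipped = [v.variant_id for v in variants if v.n_array_units < window[1]]
    if skipped:
        logger.warning("arrays shorter than core window skipped: %s", skipped)
    rows = []
    for i, v1 in enumerate(eligible):
        for v2 in eligible[i + 1 :]:
            cmp = classify_pair(core_motif(v1, window), core_motif(v2, window))
            rows.append(
                {
                    "variant_1": v1.variant_id,
                    "variant_2": v2.variant_id,
                    "n_match": cmp.n_match,
                    "n_positions": cmp.n_positions,
                    "category": cmp.category,
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df
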