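"""Weighted edit distances between minisatellite repeat arrays.

The distance between two repeat arrays is the minimum total cost over all
monotone alignments of the units of one array to the units of the other:

* aligning unit ``a_i`` to ``b_j`` costs ``w_mut`` per mismatching nucleotide
  (the unit Hamming distance);
* deleting or inserting a unit costs ``w_indel``, reduced to ``w_slippage``
  when the unit is an exact copy of one of its neighbours in its *own* array
  (replication slippage duplicates or deletes a copy of an adjacent repeat,
  so such events are cheaper than the gain or loss of a novel unit).

Comparisons can run on full units or on units with the hypervariable
DNA-contact codons excised ("masked"); slippage eligibility is decided on the
same compared region.  Default weights are w_mut=1, w_indel=3.5,
w_slippage=1.75.  ``N`` bases mismatch everything, including another ``N``.

:func:`array_edit_distance` is a dynamic program; :func:`brute_force_distance`
enumerates every monotone alignment independently and exists purely to verify
the dynamic program on small instances.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, LengthError
from .io import MinisatelliteAllele, RepeatUnit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatDistanceParams:
    """Cost weights and masking switch for the array edit distance."""

    w_mut: float = 1.0
    w_indel: float = 3.5
    w_slippage: float = 1.75
    masked: bool = True

    def __post_init__(self) -> None:
        if min(self.w_mut, self.w_indel, self.w_slippage) < 0:
            raise ConfigError("distance weights must be non-negative")
        if self.w_slippage > self.w_indel:
            warnings.warn(
                "w_slippage > w_indel: slippage events cost more than novel "
                "indels, which inverts the intended model",
                stacklevel=2,
            )

    def scaled(self, c: float) -> "RepeatDistanceParams":
        return RepeatDistanceParams(
            self.w_mut * c, self.w_indel * c, self.w_slippage * c, self.masked
        )


DEFAULT_PARAMS = RepeatDistanceParams()


def _seq_of(u, masked: bool) -> str:
    if isinstance(u, RepeatUnit):
        return u.compared_seq(masked)
    return str(u)


def unit_hamming(u, v, masked: bool = False) -> int:
    """Mismatch count between two repeat units; N mismatches everything."""
    s, t = _seq_of(u, masked), _seq_of(v, masked)
    if len(s) != len(t):
        raise LengthError(f"units of unequal length: {len(s)} vs {len(t)}")
    return sum(a != b or a == "N" or b == "N" for a, b in zip(s, t))


def _units_identical(s: str, t: str) -> bool:
    # N is unknown, hence never certainly identical (conservative policy)
    return s == t and "N" not in s


def _gap_costs(seqs: Sequence[str], p: RepeatDistanceParams) -> list[float]:
    """Per-unit indel cost: w_slippage iff the unit equals a neighbour.

    Neighbour context comes from the original array, never from a partially
    consumed alignment, so costs are alignment-order independent.
    """
    n = len(seqs)
    costs = []
    for i, s in enumerate(seqs):
        slip = (i > 0 and _units_identical(s, seqs[i - 1])) or (
            i < n - 1 and _units_identical(s, seqs[i + 1])
        )
        costs.append(p.w_slippage if slip else p.w_indel)
    return costs


def _compared_seqs(a, masked: bool) -> list[str]:
    units = a.units if isinstance(a, MinisatelliteAllele) else a
    return [_seq_of(u, masked) for u in units]


def _check_lengths(sa: Sequence[str], sb: Sequence[str]) -> None:
    lens = {len(s) for s in sa} | {len(s) for s in sb}
    if len(lens) > 1:
        raise LengthError(f"mixed compared unit lengths: {sorted(lens)}")


def array_edit_distance(a, b, p: RepeatDistanceParams = DEFAULT_PARAMS) -> float:
    """Minimum-cost monotone alignment distance between two repeat arrays.

    ``a`` and ``b`` are :class:`MinisatelliteAllele` objects or sequences of
    units/strings.  An empty array is allowed: the distance is the pure indel
    cost of the other array.
    """
    sa, sb = _compared_seqs(a, p.masked), _compared_seqs(b, p.masked)
    _check_lengths(sa, sb)
    if not sa or not sb:
        logger.warning("empty repeat array in distance computation")
    del_cost = _gap_costs(sa, p)
    ins_cost = _gap_costs(sb, p)
    n, m = len(sa), len(sb)
    prev = np.empty(m + 1)
    prev[0] = 0.0
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] + ins_cost[j - 1]
    cur = np.empty(m + 1)
    for i in range(1, n + 1):
        cur[0] = prev[0] + del_cost[i - 1]
        ai = sa[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + p.w_mut * unit_hamming(ai, sb[j - 1]),
                prev[j] + del_cost[i - 1],
                cur[j - 1] + ins_cost[j - 1],
            )
        prev, cur = cur, prev
    return float(prev[m])


def array_edit_alignment(
    a, b, p: RepeatDistanceParams = DEFAULT_PARAMS
) -> tuple[float, list[tuple[str, int | None, int | None]]]:
    """Distance plus one optimal alignment for diagnostics.

    Operations are ``("match", i, j)``, ``("delete", i, None)`` and
    ``("insert", None, j)`` with 1-based unit indices.  Ties are broken
    preferring match over deletion over insertion; the traceback carries no
    semantic weight beyond illustrating one optimal path.
    """
    sa, sb = _compared_seqs(a, p.masked), _compared_seqs(b, p.masked)
    _check_lengths(sa, sb)
    del_cost = _gap_costs(sa, p)
    ins_cost = _gap_costs(sb, p)
    n, m = len(sa), len(sb)
    D = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        D[i, 0] = D[i - 1, 0] + del_cost[i - 1]
    for j in range(1, m + 1):
        D[0, j] = D[0, j - 1] + ins_cost[j - 1]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + p.w_mut * unit_hamming(sa[i - 1], sb[j - 1]),
                D[i - 1, j] + del_cost[i - 1],
                D[i, j - 1] + ins_cost[j - 1],
            )
    ops: list[tuple[str, int | None, int | None]] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and abs(
                D[i, j]
                - (D[i - 1, j - 1] + p.w_mut * unit_hamming(sa[i - 1], sb[j - 1]))
            )
            < eps
        ):
            ops.append(("match", i, j))
            i, j = i - 1, j - 1
        elif i > 0 and abs(D[i, j] - (D[i - 1, j] + del_cost[i - 1])) < eps:
            ops.append(("delete", i, None))
            i -= 1
        else:
            ops.append(("insert", None, j))
            j -= 1
    ops.reverse()
    return float(D[n, m]), ops


def brute_force_distance(
    a, b, p: RepeatDistanceParams = DEFAULT_PARAMS, max_units: int = 4
) -> float:
    """Exhaustive-enumeration oracle for :func:`array_edit_distance`.

    Enumerates every monotone alignment (every choice of matched index pairs
    increasing in both coordinates), scores each literally from the cost
    rules, and returns the minimum.  Deliberately shares no code with the
    dynamic program.  Refuses arrays longer than ``max_units``.
    """
    sa, sb = _compared_seqs(a, p.masked), _compared_seqs(b, p.masked)
    _check_lengths(sa, sb)
    n, m = len(sa), len(sb)
    if n > max_units or m > max_units:
        raise ConfigError(
            f"brute-force oracle limited to {max_units} units (got {n}, {m})"
        )

    def plain_gap(seqs, i):
        # re-derive slippage eligibility from scratch (no shared helper state)
        s = seqs[i]
        if "N" not in s and (
            (i > 0 and seqs[i - 1] == s) or (i + 1 < len(seqs) and seqs[i + 1] == s)
        ):
            return p.w_slippage
        return p.w_indel

    _mm_cache: dict[tuple[str, str], int] = {}

    def mismatches(s, t):
        key = (s, t)
        if key not in _mm_cache:
            _mm_cache[key] = sum(
                1 for x, y in zip(s, t) if x != y or "N" in (x, y)
            )
        return _mm_cache[key]

    best = float("inf")
    for k in range(min(n, m) + 1):
        for ai in itertools.combinations(range(n), k):
            for bj in itertools.combinations(range(m), k):
                cost = sum(
                    p.w_mut * mismatches(sa[i], sb[j]) for i, j in zip(ai, bj)
                )
                cost += sum(plain_gap(sa, i) for i in range(n) if i not in ai)
                cost += sum(plain_gap(sb, j) for j in range(m) if j not in bj)
                best = min(best, cost)
    return best


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray
    #: carrier multiplicity per label when built with dedupe=True
    weights: dict[str, int] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise LengthError("matrix shape does not match label count")
        if not np.allclose(v, v.T, atol=1e-9):
            raise LengthError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise LengthError("distance matrix diagonal not zero")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_phylip(
        self, path: str | Path, tab: bool = False, header_lines: Sequence[str] = ()
    ) -> None:
        """Square PHYLIP matrix, relaxed names up to 32 chars, 6 decimals."""
        sep = "\t" if tab else "  "
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                name = lab[:32].ljust(10)
                fh.write(name + sep + sep.join(f"{x:.6f}" for x in row) + "\n")

    def write_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        """Long-format ``id1 id2 distance`` TSV (upper triangle)."""
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("id1\tid2\tdistance\n")
            for i, li in enumerate(self.labels):
                for j in range(i + 1, len(self.labels)):
                    fh.write(f"{li}\t{self.labels[j]}\t{self.values[i, j]:.6f}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP matrix written by :meth:`DistanceMatrix.write_phylip`."""
    labels, rows = [], []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    n = int(lines[0].split()[0])
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels=labels, values=np.array(rows))


def distance_matrix(
    alleles: Sequence,
    p: RepeatDistanceParams = DEFAULT_PARAMS,
    dedupe: bool = False,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All pairwise array edit distances.

    ``alleles`` are :class:`MinisatelliteAllele` objects (labelled by
    ``allele_id``) or plain unit-sequence lists (labelled by ``labels`` or
    position).  With ``dedupe=True``, alleles identical on the compared
    region collapse to one representative each; multiplicities are kept in
    ``weights``.
    """
    if len(alleles) < 2:
        raise LengthError("need at least 2 alleles for a distance matrix")
    if labels is None:
        labels = [
            a.allele_id if isinstance(a, MinisatelliteAllele) else f"a{i + 1}"
            for i, a in enumerate(alleles)
        ]
    seqs = [tuple(_compared_seqs(a, p.masked)) for a in alleles]
    _check_lengths([s for ss in seqs for s in ss], [])
    items = list(zip(labels, seqs, alleles))
    weights = None
    if dedupe:
        seen: dict[tuple, list] = {}
        for lab, sig, a in items:
            seen.setdefault(sig, []).append((lab, a))
        items = [(mem[0][0], sig, mem[0][1]) for sig, mem in seen.items()]
        weights = {
            mem[0][0]: len(mem) for mem in seen.values()
        }
        logger.info("dedupe: %d alleles -> %d representatives", len(alleles), len(items))
    n = len(items)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = array_edit_distance(items[i][2], items[j][2], p)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=[it[0] for it in items], values=vals, weights=weights)
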