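"""Repeat-pool diversity and population differentiation.

Following the repeat-stacking approach, every repeat unit of every allele in
a population is treated as one haploid sequence in that population's *pool*
(identical units kept with multiplicity).  On such pools this module
computes the segregating-site count S, the Watterson estimator
theta_W = S / a1 (a1 the harmonic number of the pool size), the average
pairwise nucleotide diversity pi per site with its standard error (Nei 1987
variance), and between-pool differentiation: Nei's Gst = (Ht - Hs)/Ht and
Jost's D = ((Ht - Hs)/(1 - Hs)) * k/(k - 1), with Hs/Ht either uncorrected
or with the Nei & Chesser (1983) sample-size corrections (haploid form,
harmonic-mean pool size), which permit small negative estimates in
undifferentiated samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LengthError, PoolError
from .io import MinisatelliteAllele

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class RepeatPool:
    """A multiset of aligned repeat-unit sequences from one population."""

    population: str
    units: list[str]
    masked: bool = False

    def __post_init__(self) -> None:
        if not self.units:
            raise PoolError(f"empty repeat pool for {self.population}")
        if len({len(u) for u in self.units}) != 1:
            raise LengthError(f"pool {self.population}: unequal unit lengths")

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def L(self) -> int:
        return len(self.units[0])

    def counts(self) -> np.ndarray:
        """Per-site base counts, shape (L, 4) in A,C,G,T order; N dropped."""
        enc = np.frombuffer(
            "".join(self.units).encode(), dtype=np.uint8
        ).reshape(self.n, self.L)
        out = np.zeros((self.L, 4), dtype=np.int64)
        for bi, b in enumerate(_BASES):
            out[:, bi] = (enc == ord(b)).sum(axis=0)
        return out


@dataclass
class DiversityStats:
    population: str
    n: int
    L: int
    S: int
    theta_locus: float
    theta_site: float
    pi: float
    pi_se: float
    masked: bool


@dataclass
class DifferentiationStats:
    pop_pair: tuple[str, ...]
    Hs: float
    Ht: float
    Gst: float
    Dj: float
    masked: bool
    corrected: bool


def stack_pool(
    alleles: Sequence[MinisatelliteAllele],
    population: str,
    masked: bool = False,
    per_variant: bool = False,
) -> RepeatPool:
    """Stack the repeat units of a population's alleles into one pool.

    ``per_variant=True`` collapses alleles identical over the compared region
    to a single representative before pooling (the alternative reading of
    "stacking non-unique alleles"); the default keeps every allele.
    """
    members = [a for a in alleles if a.population == population]
    if not members:
        raise PoolError(f"no alleles for population {population!r}")
    arrays = [a.unit_seqs(masked) for a in members]
    if per_variant:
        seen = dict.fromkeys(arrays)  # insertion-ordered dedupe
        arrays = list(seen)
    units = [u for arr in arrays for u in arr]
    return RepeatPool(population=population, units=units, masked=masked)


def segregating_sites(pool: RepeatPool) -> int:
    """Number of columns with at least two observed (non-N) states."""
    if pool.n < 2:
        raise PoolError("segregating sites need n >= 2")
    c = pool.counts()
    return int(((c > 0).sum(axis=1) >= 2).sum())


def harmonic_number(n: int) -> float:
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta(S: int, n: int, L: int) -> tuple[float, float]:
    """Watterson estimator; returns (per-locus, per-site) values."""
    if n < 2:
        raise PoolError("Watterson theta needs n >= 2")
    a1 = harmonic_number(n)
    theta = S / a1
    return theta, theta / L


def nucleotide_diversity(pool: RepeatPool) -> tuple[float, float]:
    """Average pairwise nucleotide diversity per site, with standard error.

    pi = sum over pairs of per-pair mismatch counts (on sites where both
    members are non-N) divided by C(n,2)*L.  The SE is the square root of
    Nei's (1987) variance of the estimate,
    V = pi*(n+1)/(3*(n-1)*L) + 2*(n^2+n+3)*pi^2 / (9*n*(n-1)).
    """
    n, L = pool.n, pool.L
    if n < 2:
        raise PoolError("nucleotide diversity needs n >= 2")
    c = pool.counts()
    valid = c.sum(axis=1)  # non-N observations per site
    # mismatching pairs per site among non-N observations
    pairs_mismatch = (valid * (valid - 1) - (c * (c - 1)).sum(axis=1)) / 2.0
    total_pairs = n * (n - 1) / 2.0
    pi = float(pairs_mismatch.sum() / (total_pairs * L))
    var = pi * (n + 1) / (3.0 * (n - 1) * L) + 2.0 * (n * n + n + 3) * pi * pi / (
        9.0 * n * (n - 1)
    )
    return pi, float(np.sqrt(var))


def diversity_stats(pool: RepeatPool) -> DiversityStats:
    """All per-pool diversity summaries in one record."""
    S = segregating_sites(pool)
    th_locus, th_site = watterson_theta(S, pool.n, pool.L)
    pi, se = nucleotide_diversity(pool)
    return DiversityStats(
        population=pool.population,
        n=pool.n,
        L=pool.L,
        S=S,
        theta_locus=th_locus,
        theta_site=th_site,
        pi=pi,
        pi_se=se,
        masked=pool.masked,
    )


def _hs_ht(pools: Sequence[RepeatPool], corrected: bool) -> tuple[float, float]:
    """Hs and Ht averaged over all compared sites.

    Unweighted population means; with ``corrected`` the Nei & Chesser (1983)
    haploid corrections with per-site harmonic-mean sample size are applied.
    Sites where some population has no valid (non-N) observation are dropped
    from the averages (with a log line): fewer than two populations leave
    differentiation undefined at that site.
    """
    L = pools[0].L
    k = len(pools)
    counts = [p.counts() for p in pools]
    ns = np.stack([c.sum(axis=1) for c in counts])  # (k, L) valid n per site
    usable = (ns > 0).all(axis=0)
    if not usable.all():
        logger.info("dropping %d sites with a data-less population", int((~usable).sum()))
    if not usable.any():
        raise PoolError("no site has data in every population")
    freqs = np.stack(
        [c / np.maximum(n, 1)[:, None] for c, n in zip(counts, ns)]
    )  # (k, L, 4)
    homo = (freqs**2).sum(axis=2)  # (k, L) sum p^2 per pop per site
    hs_raw = (1.0 - homo).mean(axis=0)  # uncorrected Hs per site
    pbar = freqs.mean(axis=0)  # unweighted mean frequencies, (L, 4)
    ht_raw = 1.0 - (pbar**2).sum(axis=1)
    if corrected:
        n_harm = k / (1.0 / np.maximum(ns, 1)).sum(axis=0)  # per-site
        with np.errstate(divide="ignore", invalid="ignore"):
            hs = n_harm / (n_harm - 1.0) * hs_raw
        hs = np.where(n_harm > 1, hs, hs_raw)
        ht = ht_raw + hs / (n_harm * k)
    else:
        hs, ht = hs_raw, ht_raw
    return float(hs[usable].mean()), float(ht[usable].mean())


def differentiation(
    pools: Sequence[RepeatPool], corrected: bool = True
) -> list[DifferentiationStats]:
    """Gst and Jost's D for every pool pair plus the overall (k-pool) value.

    The overall record (pop_pair listing every population) is appended last
    when more than two pools are supplied.
    """
    if len(pools) < 2:
        raise PoolError("differentiation needs >= 2 pools")
    if len({p.L for p in pools}) != 1:
        raise LengthError("pools compared at different lengths")
    if len({p.masked for p in pools}) != 1:
        raise LengthError("pools mix masked and unmasked comparisons")
    results = []
    subsets: list[tuple[RepeatPool, ...]] = list(itertools.combinations(pools, 2))
    if len(pools) > 2:
        subsets.append(tuple(pools))
    for group in subsets:
        k = len(group)
        hs, ht = _hs_ht(group, corrected)
        gst = (ht - hs) / ht if ht > 0 else 0.0
        dj = (ht - hs) / (1.0 - hs) * k / (k - 1.0) if hs < 1.0 else 0.0
        results.append(
            DifferentiationStats(
                pop_pair=tuple(p.population for p in group),
                Hs=hs,
                Ht=ht,
                Gst=gst,
                Dj=dj,
                masked=group[0].masked,
                corrected=corrected,
            )
        )
    return results


def write_diversity_table(
    stats: Sequence[DiversityStats], path: str | Path, header_lines=()
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "population": s.population,
                "n": s.n,
                "L": s.L,
                "S": s.S,
                "theta_locus": round(s.theta_locus, 6),
                "theta_site": round(s.theta_site, 6),
                "pi": round(s.pi, 6),
                "pi_se": round(s.pi_se, 6),
                "masked": s.masked,
            }
            for s in stats
        ]
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df


def write_differentiation_table(
    stats: Sequence[DifferentiationStats], path: str | Path, header_lines=()
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "pops": "|".join(s.pop_pair),
                "Hs": round(s.Hs, 6),
                "Ht": round(s.Ht, 6),
                "Gst": round(s.Gst, 6),
                "JostD": round(s.Dj, 6),
                "masked": s.masked,
                "corrected": s.corrected,
            }
            for s in stats
        ]
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df
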