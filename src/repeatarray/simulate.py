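"""Forward-time simulation of minisatellite (zinc-finger array) evolution.

The generative model is a haploid Wright-Fisher pool of repeat arrays per
population, evolving along a fixed two-hemisphere population tree
``((ANV, ANIV), (NA, NP))``: an ancestral pool is burnt in, splits into the
two hemisphere lineages which diverge for ``t2`` generations, each of which
splits into two populations diverging a further ``t1`` generations
(``t2 >> t1`` gives strong between- and weak within-hemisphere structure).

Per generation each nucleotide mutates with probability ``mu`` — multiplied
by ``hv_multiplier`` inside the three hypervariable DNA-contact codons — and
each repeat unit duplicates in place (slippage: the copy is inserted adjacent
to its template) with ``dup_rate`` or is deleted with ``del_rate``, subject
to array-size guards.  Unequal crossover between homologues is *not*
modelled.  Two alleles per sampled individual are drawn from the terminal
pools.  All randomness flows from one seeded generator; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from .errors import ConfigError
from .io import (
    DEFAULT_CONTACT_POSITIONS,
    DEFAULT_UNIT_LENGTH,
    MaskSpec,
    MinisatelliteAllele,
    partition_allele,
)

logger = logging.getLogger(__name__)

#: Synthetic 84-nt consensus repeat unit used as the simulation ancestor.
#: It is a constructed stand-in for a baleen-whale first-array zinc finger:
#: in frame 1 it translates to a 28-residue C2H2 finger with Cys anchors at
#: positions 4 and 9, His anchors at 20 and 24, and DNA-contact residues
#: D, S, K at positions 13, 16, 19 (codons GAT, AGC, AAA).
ANCESTRAL_UNIT_NT = (
    "ACCGGAGAGTGTGGCAGAGGTTTTTGCTCATGGAGTGATCAGTCCAGCAATCTGAAACATCAACGTACTCACACAGGGGAAAAG"
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: population -> hemisphere for the default four-population design
DEFAULT_POPULATIONS = (("ANV", "SH"), ("ANIV", "SH"), ("NA", "NH"), ("NP", "NH"))


def ancestral_unit(seed: int | None = None, unit_length: int = DEFAULT_UNIT_LENGTH) -> str:
    """The ancestral repeat unit: the shipped consensus, or a random one.

    With a ``seed``, a random in-frame unit is generated instead (codons
    drawn uniformly, stop codons resampled) with the four C2H2 anchor codons
    forced, so the translated finger always validates.
    """
    if seed is None:
        if unit_length != DEFAULT_UNIT_LENGTH:
            raise ConfigError("the shipped consensus unit is 84 nt; pass a seed")
        return ANCESTRAL_UNIT_NT
    if unit_length % 3:
        raise ConfigError("unit_length must be a codon multiple")
    rng = np.random.default_rng(seed)
    n_codons = unit_length // 3
    codons = []
    for _ in range(n_codons):
        c = "".join(chr(b) for b in rng.choice(_BASES, size=3))
        while c in _STOPS:
            c = "".join(chr(b) for b in rng.choice(_BASES, size=3))
        codons.append(c)
    anchors = {4: "TGT", 9: "TGC", 20: "CAT", 24: "CAC"}
    for pos, codon in anchors.items():
        if pos <= n_codons:
            codons[pos - 1] = codon
    return "".join(codons)


@dataclass
class SimScenario:
    """Parameters of one simulation run (defaults = the study conditions)."""

    seed: int = 0
    unit_length: int = DEFAULT_UNIT_LENGTH
    ancestral_units: int = 9
    #: point-mutation probability per nucleotide per generation
    mu: float = 5e-6
    #: rate multiplier inside the three hypervariable contact codons
    hv_multiplier: float = 10.0
    #: slippage duplication / deletion probability per unit per generation
    dup_rate: float = 1e-4
    del_rate: float = 1e-4
    #: haploid Wright-Fisher pool size per population lineage
    pool_size: int = 100
    #: generations: ancestral burn-in, terminal branches, hemisphere branches
    burn_in: int = 600
    t1: int = 50
    t2: int = 1000
    #: diploid individuals sampled per terminal population
    n_per_pop: int = 25
    min_units: int = 4
    max_units: int = 14
    populations: tuple[tuple[str, str], ...] = DEFAULT_POPULATIONS
    contact_positions: tuple[int, ...] = DEFAULT_CONTACT_POSITIONS

    def __post_init__(self) -> None:
        if min(self.mu, self.dup_rate, self.del_rate) < 0:
            raise ConfigError("rates must be non-negative")
        if self.min_units < 1 or self.max_units < self.min_units:
            raise ConfigError("need 1 <= min_units <= max_units")
        if not (self.min_units <= self.ancestral_units <= self.max_units):
            raise ConfigError("ancestral_units outside [min_units, max_units]")
        if len(self.populations) != 4:
            raise ConfigError("the population tree is ((P1,P2),(P3,P4)): 4 labels")

    @property
    def hv_sites(self) -> tuple[int, ...]:
        """0-based hypervariable nucleotide offsets within a unit."""
        return tuple(
            MaskSpec(self.contact_positions).masked_nt_indices(self.unit_length)
        )

    def expected_theta_site(self) -> dict[str, float]:
        """Neutral equilibrium 2*N*mu expectations per site class."""
        return {
            "slow": 2 * self.pool_size * self.mu,
            "hypervariable": 2 * self.pool_size * self.mu * self.hv_multiplier,
        }

    def expected_unit_divergence(self) -> dict[str, float]:
        """Expected pairwise mismatch fraction between pool units per class.

        Repeat units are founded as identical copies of the ancestor, so a
        random unit pair has diverged for roughly the whole simulated span
        (within-array paralogy dominates stacked-pool diversity, as it does
        in real minisatellite pools).  The observable mismatch fraction
        applies the Jukes-Cantor four-state saturation correction to the
        expected substitution load d = 2 * span * mu * rate-multiplier.
        """
        span = self.burn_in + self.t2 + self.t1
        out = {}
        for name, r in (("slow", 1.0), ("hypervariable", self.hv_multiplier)):
            d = 2.0 * span * self.mu * r
            out[name] = 0.75 * (1.0 - float(np.exp(-4.0 * d / 3.0)))
        return out


@dataclass
class SimResult:
    scenario: SimScenario
    alleles: list[MinisatelliteAllele]
    #: (generation, lineage, event type, detail) tuples, in draw order
    events: list[tuple[int, str, str, str]]
    rejected: dict[str, int]

    @property
    def truth(self) -> dict:
        return {
            "scenario": asdict(self.scenario),
            "expected_theta_site": self.scenario.expected_theta_site(),
            "expected_unit_divergence": self.scenario.expected_unit_divergence(),
            "n_events": len(self.events),
            "rejected": dict(self.rejected),
        }


class _Pool:
    """Mutable Wright-Fisher pool of repeat arrays (tuples of unit strings)."""

    def __init__(self, alleles: list[tuple[str, ...]], label: str):
        self.alleles = alleles
        self.label = label

    def copy(self, label: str) -> "_Pool":
        return _Pool(list(self.alleles), label)


def _mutate_unit(unit: str, site: int, rng: np.random.Generator) -> str:
    old = unit[site]
    choices = [b for b in "ACGT" if b != old]
    return unit[:site] + choices[rng.integers(3)] + unit[site + 1 :]


def _evolve(
    pool: _Pool,
    gens: int,
    s: SimScenario,
    rng: np.random.Generator,
    events: list,
    rejected: dict[str, int],
    gen_offset: int,
) -> None:
    hv = np.array(s.hv_sites)
    slow = np.array([i for i in range(s.unit_length) if i not in set(s.hv_sites)])
    n_hv, n_slow = len(hv), len(slow)
    N = s.pool_size
    for g in range(gens):
        gen = gen_offset + g
        # Wright-Fisher resampling
        parents = rng.integers(0, N, N)
        pool.alleles = [pool.alleles[p] for p in parents]
        counts = np.array([len(a) for a in pool.alleles])
        total_units = int(counts.sum())
        lam = (
            s.mu * total_units * n_slow,
            s.mu * s.hv_multiplier * total_units * n_hv,
            s.dup_rate * total_units,
            s.del_rate * total_units,
        )
        n_ev = rng.poisson(lam)
        if not n_ev.any():
            continue
        for kind, count in zip(("mut_slow", "mut_hv", "dup", "del"), n_ev):
            for _ in range(count):
                counts = np.array([len(a) for a in pool.alleles])
                cum = np.cumsum(counts)
                u = int(rng.integers(cum[-1]))
                ai = int(np.searchsorted(cum, u, side="right"))
                ui = u - (cum[ai - 1] if ai else 0)
                allele = list(pool.alleles[ai])
                if kind in ("mut_slow", "mut_hv"):
                    sites = slow if kind == "mut_slow" else hv
                    site = int(sites[rng.integers(len(sites))])
                    allele[ui] = _mutate_unit(allele[ui], site, rng)
                    events.append((gen, pool.label, kind, f"unit{ui + 1}:nt{site + 1}"))
                elif kind == "dup":
                    if len(allele) >= s.max_units:
                        rejected["dup"] += 1
                        continue
                    allele.insert(ui + 1, allele[ui])
                    events.append((gen, pool.label, "dup", f"unit{ui + 1}"))
                else:
                    if len(allele) <= s.min_units:
                        rejected["del"] += 1
                        continue
                    del allele[ui]
                    events.append((gen, pool.label, "del", f"unit{ui + 1}"))
                pool.alleles[ai] = tuple(allele)


def simulate(s: SimScenario) -> SimResult:
    """Run the scenario and return sampled alleles with the truth record."""
    rng = np.random.default_rng(s.seed)
    anc = ancestral_unit(None) if s.unit_length == DEFAULT_UNIT_LENGTH else ancestral_unit(
        int(rng.integers(2**31)), s.unit_length
    )
    events: list[tuple[int, str, str, str]] = []
    rejected = {"dup": 0, "del": 0}
    root = _Pool([tuple([anc] * s.ancestral_units)] * s.pool_size, "root")
    _evolve(root, s.burn_in, s, rng, events, rejected, 0)
    t0 = s.burn_in
    hemis = {}
    pops = {}
    (p1, h1), (p2, h2), (p3, h3), (p4, h4) = s.populations
    for hem, members in ((h1, (p1, p2)), (h3, (p3, p4))):
        hp = root.copy(hem)
        _evolve(hp, s.t2, s, rng, events, rejected, t0)
        hemis[hem] = hp
        for pop in members:
            pp = hp.copy(pop)
            _evolve(pp, s.t1, s, rng, events, rejected, t0 + s.t2)
            pops[pop] = pp

    mask = MaskSpec(s.contact_positions)
    alleles: list[MinisatelliteAllele] = []
    hem_of = dict(s.populations)
    for pop, _hem in s.populations:
        pool = pops[pop]
        n_draw = 2 * s.n_per_pop
        idx = rng.choice(
            s.pool_size, size=n_draw, replace=n_draw > s.pool_size
        )
        for i in range(s.n_per_pop):
            ind = f"{pop}_i{i + 1:03d}"
            for tag, j in (("a", idx[2 * i]), ("b", idx[2 * i + 1])):
                seq = "".join(pool.alleles[int(j)])
                alleles.append(
                    MinisatelliteAllele(
                        allele_id=f"{ind}_{tag}",
                        individual_id=ind,
                        population=pop,
                        hemisphere=hem_of[pop],
                        units=partition_allele(seq, s.unit_length, mask=mask),
                    )
                )
    logger.info(
        "simulated %d alleles, %d events (%d rejected)",
        len(alleles),
        len(events),
        sum(rejected.values()),
    )
    return SimResult(scenario=s, alleles=alleles, events=events, rejected=rejected)


def write_outputs(
    result: SimResult, outdir: str | Path, prefix: str = "sim"
) -> dict[str, Path]:
    """Write FASTA + sample TSV (the dialects the reader consumes) + truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{prefix}_alleles.fasta"
    samples = outdir / f"{prefix}_samples.tsv"
    truth = outdir / f"{prefix}_truth.txt"
    with open(fasta, "w") as fh:
        for a in result.alleles:
            fh.write(f">{a.allele_id}\n")
            seq = a.array_seq
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(samples, "w") as fh:
        fh.write(f"# seed={result.scenario.seed}\n")
        fh.write("allele_id\tindividual_id\tpopulation\themisphere\n")
        for a in result.alleles:
            fh.write(f"{a.allele_id}\t{a.individual_id}\t{a.population}\t{a.hemisphere}\n")
    with open(truth, "w") as fh:
        fh.write(f"# seed={result.scenario.seed}\n")
        for key, val in result.truth.items():
            if key != "n_events":
                fh.write(f"# {key}: {val}\n")
        fh.write("generation\tlineage\tevent\tdetail\n")
        for gen, lin, kind, detail in result.events:
            fh.write(f"{gen}\t{lin}\t{kind}\t{detail}\n")
    return {"fasta": fasta, "samples": samples, "truth": truth}
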