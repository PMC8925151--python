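# Methods

This note documents the models and numerical choices behind `repeatarray`:
what each statistic assumes, what the simulator does and does not emulate,
and the decisions taken where the design was genuinely open.

## Repeat units, zinc fingers and masking

An allele is an ordered array of fixed-length repeat units (default 84 nt),
partitioned 5'→3' after optional flank trimming; a trimmed length that is
not a multiple of the unit length is an error, never silently padded.
Units are translated in frame 1 (the frame offset is configurable; the
amplicon's phase is an input property, not something the package infers).
A translated unit is a valid zinc finger when it has no stop codon, no
N-containing codon, and carries the C2H2 anchor residues C, C, H, H at the
configured offsets (defaults 4, 9, 20, 24, taken from the package's
reference unit — see below).  This anchor check is a deliberate, transparent
stand-in for profile-HMM bit-score filtering: it accepts exactly the
fingers whose structural skeleton is intact and is trivially reproducible.

The *mask* excises the codons for the DNA-contact residues at unit amino
acids 13, 16, 19 (alpha-helix −1, +3, +6), i.e. nucleotides 37–39, 46–48,
55–57, leaving 75 nt of an 84-nt unit.  These positions are under
diversifying selection in PRDM9 arrays; masked comparisons measure the
conserved backbone.  Whether alpha-helix +2 should also be masked is
genuinely unsettled in the literature; the default masks only (−1, +3, +6),
and the positions are a configuration list.

All user-facing coordinates are 1-based and closed.  `N` bases are allowed
in input and treated conservatively: an `N` mismatches everything
(including another `N`) in distances, is excluded from diversity counts,
and disqualifies a unit from slippage identity.

### The reference unit

`repeatarray.simulate.ANCESTRAL_UNIT_NT` is a **synthetic** consensus: an
84-nt in-frame unit constructed to have the conserved baleen-whale first
zinc finger's properties — intact C2H2 anchors and the DSK contact triplet
(codons GAT, AGC, AAA at positions 13/16/19).  It is a constructed
stand-in, not a sequence extracted from any genome, and is used as the
simulation ancestor and test fixture only; nothing in the analysis path
depends on it.

## The slippage-aware array edit distance

The distance between two unit arrays is the minimum total cost over all
monotone alignments (matched index pairs strictly increasing in both
coordinates).  Matching units costs `w_mut` per mismatching nucleotide on
the compared (masked or unmasked) region; an unmatched unit costs `w_indel`
unless it is an exact copy of one of its neighbours in its own array, in
which case it costs `w_slippage` — replication slippage inserts or deletes
copies of adjacent repeats, so such events are evidence-cheaper than the
gain of a novel unit.  Defaults `w_mut = 1`, `w_indel = 3.5`,
`w_slippage = 1.75`.

Open points resolved here, chosen for determinism and testability:

* **Slippage eligibility** is "identical to the unit immediately before or
  after it in its *original* array, on the compared region".  Using the
  original array (not the partially consumed alignment) makes gap costs
  independent of alignment order, which is what makes an exhaustive
  enumeration oracle well defined.
* **Masking consistency**: slippage identity is tested on the same region
  used for substitution costs, keeping one comparison space per setting.
  A consequence, verified exhaustively, is that masked distances never
  exceed unmasked ones.
* **Unit Hamming counts are unnormalised** (cost per mismatching
  nucleotide, not per fraction of unit), so `w_mut` has units of cost per
  base.
* **No triangle inequality** is claimed: context-dependent gap costs can
  violate it.  Downstream NJ does not require metricity.
* The dynamic program reports the minimum cost; a traceback is available
  for diagnostics with ties broken match > deletion > insertion, and
  carries no semantic weight.

`brute_force_distance` enumerates every monotone alignment and applies the
cost rules literally, sharing no code with the dynamic program; the test
suite sweeps all array pairs up to 4 units over a 3-unit alphabet in both
mask settings and requires exact agreement.

## Trees

`nj_tree` implements classic Saitou–Nei neighbor joining and BIONJ.  BIONJ
follows the published agglomerative recurrences: distances and variance
estimates (initialised to the distances) are reduced with the mixing weight
λ = 1/2 + Σₖ(V_jk − V_ik) / (2(r−2)V_ij), clamped to [0, 1]; when V_ij = 0
(identical rows), λ = 1/2, which reduces BIONJ to classic NJ.  Ties in the
Q criterion (within 10⁻¹⁰) are broken on the lexicographically smallest
pair of cluster labels, so runs are reproducible across platforms rather
than hostage to floating-point association order.  Negative branch-length
estimates are clamped to zero; the pre-clamp value is logged and kept on
the result object (values within 10⁻⁹ of zero are treated as float noise
and zeroed silently).  Rooting inserts a degree-2 root part-way along the
outgroup's pendant branch (fraction configurable, default midpoint), which
preserves all leaf-to-leaf path lengths.

Correctness anchors: exact three-point solutions on 3 taxa; exact recovery
of additive matrices (topology and branch lengths); Robinson–Foulds 0
against the generating topology on random additive matrices of 5–12 taxa;
and agreement with two independent implementations (scikit-bio's NJ, and
the R `ape::bionj` oracle run through Rscript).

## Repeat-pool statistics

Following the repeat-stacking approach, every repeat unit of every allele
of a population is one haploid sequence in the population's pool, identical
units retained with multiplicity (`per_variant=True` collapses identical
whole alleles first — the alternative reading of "stacking non-unique
alleles"; both are exposed because the distinction matters for real data).

* **S** — columns with ≥ 2 observed non-N states.
* **Watterson θ** — S/a₁ with a₁ = Σ₁ⁿ⁻¹ 1/i, reported per locus and per
  site (the per-site value divides by the compared length L, 84 or 75).
* **π** — mean pairwise mismatch fraction, computed from per-site base
  counts; pairs with an N at a site do not contribute a mismatch there but
  the denominator stays C(n,2)·L (conservative).  The reported `pi_se` is
  the square root of Nei's (1987) variance of π̂,
  V = π(n+1)/(3(n−1)L) + 2(n²+n+3)π² / (9n(n−1)).
  Note that at minisatellite-pool sample sizes this SE is of the same order
  as π itself — pool members share a single genealogy, so the estimate is
  genuinely that uncertain.  A published table printing "± 0.0001" at
  similar n and π is numerically consistent with quoting V rather than
  √V; this package reports the SE and leaves the interpretation of other
  reports to the reader.
* **Gst / Jost's D** — per-site allele frequencies per population, with
  unweighted population means.  With `corrected=True` (default) the
  Nei & Chesser (1983) haploid corrections are used: ñ is the per-site
  harmonic mean of per-population valid counts, Hs = ñ/(ñ−1)·(1 − mean Σp²),
  Ht = 1 − Σp̄² + Hs/(ñk).  The corrections allow small negative Gst/D in
  undifferentiated samples, which is the behaviour real studies report.
  Site values are averaged over all compared sites; a site where some
  population has only N observations is dropped from the averages (logged),
  since differentiation is undefined there.  Gst = (Ht−Hs)/Ht and
  D = ((Ht−Hs)/(1−Hs))·k/(k−1) are computed from the averaged Hs, Ht, per
  population pair and once overall.

No hypothesis tests (and hence no multiple-testing correction) are attached
to these statistics.

## The simulator

`SimScenario` describes a forward-time model chosen to generate exactly the
data structure the analysis assumes, with known ground truth:

* One haploid Wright–Fisher pool of `pool_size` repeat arrays per
  population lineage; discrete generations; per-generation event counts are
  Poisson draws, events placed uniformly (rates are small enough that
  multiple hits per unit per generation are negligible).
* Point mutation at `mu` per nt per generation, multiplied by
  `hv_multiplier` (default 10) inside the three contact codons; mutations
  change to one of the three other bases uniformly.
* Slippage duplication (`dup_rate` per unit per generation) inserts a copy
  adjacent to its template — precisely the event the `w_slippage` gap cost
  models; deletion (`del_rate`) removes a unit.  Arrays are kept within
  [`min_units`, `max_units`] by rejecting violating events (counted in the
  truth record).
* The population tree is fixed: ancestral burn-in, split into two
  hemisphere lineages evolving `t2` generations, each splitting into two
  populations evolving a further `t1` generations; two alleles per sampled
  individual are drawn from the terminal pools.
* One seeded generator drives every draw; a fixed seed yields byte-identical
  FASTA/TSV/truth files.

**Defaults and why.**  `pool_size=100`, `mu=5e-6`, `hv_multiplier=10`,
`dup_rate=del_rate=1e-4`, `burn_in=600`, `t1=50`, `t2=1000` (= 20·t1),
`ancestral_units=9` (the most prevalent Antarctic array length),
`n_per_pop=25` diploid individuals.  Two properties drove the rate and time
choices.  First, stacked-pool diversity is dominated by *within-array
paralogy*: units are founded as identical copies, so a random unit pair has
diverged for roughly the whole simulated span (1650 generations), exactly
as in real minisatellite pools.  `mu=5e-6` puts masked unit divergence at
2·1650·μ ≈ 0.014 per site — the order observed in baleen-whale PRDM9
pools — while keeping the 10× contact codons in the near-linear regime
(Jukes–Cantor saturation < 10%), so the masking fold of π stays near its
small-mutation expectation (75 + 9·10)/75 = 2.2 (computed per locus, i.e.
as the ratio of mean pairwise differences; the per-site ratio with its
unequal denominators 84 vs 75 would be 165/84 ≈ 1.96).  Second, `t2` must
comfortably exceed the hemisphere pools' time to common ancestry (~2N
generations with a long tail); with `t2=1000` incomplete lineage sorting is
negligible and hemisphere samples are genealogically monophyletic in ~99%
of replicates, which is what the tree-recovery check measures.

**What the simulator does not emulate.**  Unequal crossing-over between
homologues (the other major minisatellite mechanism) is not modelled — it
complicates ground truth and the analysis never estimates it; gene
conversion, selection on binding sites, hotspot erosion, overlapping
generations and migration are likewise absent.  Consequently, passing the
synthetic-recovery checks demonstrates that the pipeline recovers structure
generated by point mutation, slippage and drift along a clean population
tree; it does not validate behaviour under recombinational shuffling of
arrays, nor the demographic realism of any particular species.

## Problem sizes used in the checks

The exhaustive oracle sweep covers all array pairs of length 0–4 over a
3-unit alphabet in both mask settings (14 762 pairs).  Tree consistency
uses 100 random additive matrices of 5–12 taxa, alternating NJ and BIONJ.
Synthetic recovery runs 100 replicates of the default scenario (hemisphere
clade recovery on deduplicated variant representatives, masking fold of π
pooled over replicates) plus 200 panmictic replicates (burn-in only,
split-time zero) for the Gst null.  These sizes give the rates and means
stable second decimals while keeping a full run in the low minutes on one
core.

## Known limitations

* Variant naming letters (A, B, …) are ordered by carrier count then
  signature; published naming conventions are not fully specified, so
  letters need not coincide with any particular study's labels.
* The core-motif symmetric/partial/asymmetric rule is a declared
  three-way threshold on contact-code matches; binding prediction proper
  (SVM or PWM models) is out of scope, and per-position match counts are
  always emitted so users can re-threshold.
* The array edit distance treats the unit as the atom; nucleotide-level
  alignment across unit boundaries, ancestral-state reconstruction and
  unequal-crossover inference are out of scope.
* PHYLIP output uses relaxed names (≤ 32 characters); tools enforcing
  strict 10-character names need the TSV long format instead.
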