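# Methods

## Scope and model

`pcbdechlor` analyzes anaerobic microbial reductive dechlorination of
polychlorinated biphenyl (PCB) mixtures at the congener level. The
underlying chemistry is simple and discrete: a biphenyl carries 1–10
chlorines at ring positions 2–6 and 2′–6′ (carbon 1/1′ holds the
inter-ring bond and is never substituted), and organohalide-respiring
bacteria remove one chlorine at a time from one ring. Everything in the
package is built on four layers:

1. **Congener space.** A ring substitution pattern is a subset of
   {2,…,6}, canonical under the ring's mirror symmetry (2↔6, 3↔5, 4
   fixed); 20 canonical patterns exist, including the bare ring. A
   congener is an unordered pair of patterns with at least one
   chlorine; there are exactly 209 (20·21/2 − 1). Names follow the
   per-ring shorthand of the dechlorination literature
   (`2345-245-CB`), with the more-chlorinated ring written first and
   ties broken by the numerically smaller position string — a
   convention recovered from the printed names themselves
   (`24-25-CB`, `235-245-CB`, `236-24-CB`) and enforced as the single
   naming authority. Systematic (BZ) congener numbers are deliberately
   not used. Chlorine sites are classed ortho/meta/para (positions
   2,6 / 3,5 / 4) and unflanked / singly / doubly flanked by counting
   chlorinated neighbors among ring positions 2–6 only, so ortho
   chlorines can never be doubly flanked.

2. **Process rule sets.** A dechlorination "process" is encoded as a
   list of ring-local rules (substrate pattern, removed position); the
   product pattern is derived, never stored. Built-ins:

   * **H** — flanked para and doubly flanked meta removal:
     34→3, 234→24, 245→25, 2345→235, 2345→245.
   * **N** — flanked meta removal: 234→24, 235→25, 236→26, 245→24,
     2345→245, 2345→234.
   * **T** — doubly flanked meta of 2345 rings only: 2345→245.
   * **CG1** — the novel enrichment-culture pattern: doubly flanked
     meta (234→24, 2345→245) at full weight, plus partial para
     (2345→235) and partial ortho (234→34) at weight 0.2.

   The default mode is *strict* (evidenced transformations only),
   because structural predicates over-generate: a generic
   "flanked para" rule would also permit 234→23, which is never
   observed. A *generic* mode is provided for Process N (remove any
   meta chlorine with a chlorinated neighbor); on the five evidenced
   rings it reproduces the strict list exactly, and it is the way to
   explore substrates like 2356 rings that the strict list does not
   cover. The 0.2 weight on CG1's partial rules is a configurable
   stand-in for a qualitative "partially": no quantity is published.

3. **Pathway graphs.** The closure of a congener under a rule set is a
   DAG (every edge removes one chlorine), enumerated breadth-first.
   Two rules yielding the same product are kept as parallel labeled
   edges — they are distinct kinetic channels — but nodes are unique.
   Graphs are bounded by the sub-multisets of the start's chlorines
   (≤2¹⁰ nodes, in practice ≤209), so no depth cap is needed by
   default; one exists for user-supplied rule sets.

4. **Profiles.** The quantitative unit is mole percent of total PCBs.
   Weight-percent quantitation converts by mol%ᵢ ∝ wᵢ/MWᵢ with
   MW = 154.21 + 34.44·n g/mol (biphenyl plus H→Cl increments; the
   increment is 35.45 − 1.008 rounded, tested to 0.1 g/mol). Profiles
   must sum to 100 ± 0.5 (published table columns drift by rounding)
   and are renormalized only on explicit request. Homolog-level
   profiles (keys `tri` … `nona`) are accepted wherever only mass
   balance matters — homolog distributions, mean chlorines per
   biphenyl, chlorine release — because published endpoint tables are
   often homolog-only; structure-aware operations reject them.
   Chlorine release is (Δ mean chlorines) × total concentration in µM,
   reported as nmol/mL (the units coincide), and depends only on
   homolog marginals. Growth yield is cells grown per mole of chlorine
   released.

## Classification

Published studies attribute a culture's pattern to a process by expert
inspection of which congeners were lost and which products appeared.
The package formalizes this as an explained-fraction score, an
invention of the package rather than a published statistic, and every
verdict therefore ships with per-congener witness paths so the ranking
can be audited against the narrative reasoning it imitates:

* a decreased congener is *explained* by process P if ≥1 rule of P
  applies to it;
* an increased congener is *explained* if it is reachable under P
  (multi-step; the search depth is automatically capped by the
  chlorine-count difference) from some decreased congener;
* fractions are weighted by |Δ mol%| (`mole` weighting) or by counts
  (`unit` weighting, for published loss/gain lists), combined by their
  unweighted mean (harmonic and gain-only alternatives are available),
  and ranked descending with alphabetical tie-breaks.

Losses and gains come either from explicit lists or from a
before/after profile pair thresholded at |Δ| ≥ 2 mol%, the screening
convention of the source tables; the threshold is configurable. An
empty loss set returns an explicit "no classification" result. The
score does not penalize over-generation (a process predicting products
that did not appear), which matches how the patterns are diagnosed in
the field but means that a rule set whose transformations are a subset
of another's (T ⊂ H, and largely ⊂ CG1) can tie with it on data it
generated; ties are flagged, never hidden. Mixed-process deconvolution
is out of scope.

## Kinetics

Forward simulation treats each rule application as a first-order
reaction: dx/dt = Qx over the closed congener set, with off-diagonal
Q[j,i] the summed rates of edges i→j and diagonal entries minus the
outgoing total, so columns sum to zero and total moles are conserved
exactly — matching the observation that total PCB moles stay constant
through dechlorination. The system is solved with the matrix
exponential (the state space is ≤209, so this is exact and cheap)
rather than stochastically. Time is in months, the natural unit of the
3- and 6-month incubation endpoints. No rate constants are published;
the default is 1.0 per month for every rule, with rule weights (0.2
for CG1's partial channels) as multipliers, and per-rule, per-tag and
per-congener-context overrides available. Consequently simulated
*extents* at 3 months are not calibrated to the published endpoint
homolog table and no such fit is claimed; only qualitative endpoint
behavior (which products accumulate, which substrates persist) is
meaningful. Numerical guards: negative rates are rejected; round-off
negatives from the exponential map (~1e-16) are clipped to zero;
conservation is tested to 1e-6 and the two-state closed form
x(t) = x₀e^(−kt) to 1e-9.

## Synthetic data

The generator emulates the measured inputs of a sediment-free
dechlorination experiment; it is first-class, tested code, not a
fixture.

* **Mixtures.** Homolog marginals are fixed, by construction, to the
  control distribution of the weathered commercial mixture (tri 0.07,
  tetra 0.21, penta 9.63, hexa 47.75, hepta 36.26, octa 5.51, nona
  0.57 mol%; mean 6.39 chlorines per biphenyl) at 81 µM total PCBs.
  Within each homolog the named dominant congeners (hepta: 2345-245,
  2345-236, 2356-234, 2345-234; hexa: 245-245, 236-245, 234-245,
  234-236, 2345-25) split 70% of the homolog's mass evenly — chosen
  once to match the reported ~72 mol% share of the four dominant
  hexa-CBs — and the remainder is allocated by a seeded Dirichlet(1)
  draw over the homolog's other congeners. The true congener-level
  composition of the commercial mixture is external knowledge and is
  deliberately not imported; nothing downstream depends on it.
* **Replicates.** Measurement noise is applied after simulation (the
  replicate-SD semantics of endpoint tables), not to rates. Each
  homolog draws one zero-mean Gaussian with the published replicate SD
  (tri 0.47 … nona 0.01 mol%), allocated over its detected congeners
  proportionally to abundance, then profiles are clipped at zero and
  renormalized to 100. The proportional allocation keeps the homolog
  sum at exactly the requested SD before renormalization; the
  renormalization itself couples homologs slightly, so measured SDs
  sit within a factor of ~2 of the targets for the major homologs
  (verified by simulation in the tests) and somewhat above target for
  trace homologs (octa, nona), which inherit cross-talk from the large
  ones.
* **Growth.** Paired (chlorine removed, cell count) observations at a
  configurable yield (default 3.30×10¹⁴ cells per mole of chlorine,
  the reported average) with optional fractional Gaussian noise;
  noiseless generation followed by the yield formula recovers the
  input exactly.

What passing synthetic tests do *not* show: the generator has no
chromatographic error structure (co-elution, detector nonlinearity,
calibration bias), no congener-specific bioavailability, no lag
phases, and within-homolog composition is a modeling choice — so
recovery rates measured here bound performance on idealized, not real,
data.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (NumPy
`default_rng`); identical seeds give identical outputs. The
process-recovery experiment uses 100 seeds: per seed, a fresh mixture,
a 3-month Process-N simulation of the full (~196-state) network,
triplicate noisy replicates averaged as in the endpoint table, and
classification against {H, N, T, CG1} at the 2 mol% threshold with
mole weighting; the whole experiment runs in a few seconds. The
success criterion (N ranked first, no tie) is met in 100/100 seeds
under these defaults.

## Known limitations

* Only the four processes evidenced here are built in; the other
  literature patterns (M, Q, H′, P, LP) are not specified by this
  source and must be supplied as user rule-set files.
* Whether the 2345→245 step observed alongside Process H activity
  belongs to H proper or a co-occurring T-like activity is not
  resolvable from pattern data; the classifier reports the ranking
  (including "could be a combination" cases like H vs H+T) and leaves
  interpretation to the user.
* Strict-mode N cannot explain products requiring 2356-ring attack
  (e.g. a 2356-24-CB gain); generic mode can, and is flagged as
  exploratory in its rule tags.
* The kinetic layer is linear and growth-free: no Monod coupling,
  no substrate inhibition, no partitioning between phases.
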