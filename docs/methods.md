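# Methods

This note records the models behind `foldchron`, the parameters that
matter, the choices made where the design was genuinely open, and what the
tests do and do not establish.

## Character coding

A census cell is a nonnegative copy number `n(f, p)` of fold family `f` in
proteome `p`. Each proteome is one ordered multistate character with 24
states written `0–9A–N`; the maximal state `N` (23) is ancestral, so
polarity runs from high abundance to absence and a hypothetical all-`N`
terminal roots the tree without an outgroup (Lundberg rooting).

The count-to-state transform is not uniquely determined by the coding
convention, only its endpoints are (absent → `0`, per-proteome maximum →
`N`). The default is the log rescaling

    state(f, p) = round(23 · ln(n+1) / ln(n_max(p)+1)),

with half-up rounding (deterministic, and monotone in `n` within a
column). A linear rescaling `round(23 · n / n_max(p))` is available via
`scale="linear"`. Normalization is per proteome, matching the view that
each proteome is a single character with its own state range; whether the
original analyses normalized per column or globally is not documented, so
both the default and the alternative are explicit options. Both scalings
were compared on simulated censuses and give indistinguishable recovery of
planted birth orders.

An all-zero proteome column has no defined normalization and is rejected.
Such columns cannot occur in real censuses (a proteome is made of domains)
but can occur in simulations that track only a few dozen families;
`drop_empty_proteomes` removes them and is applied in the simulate path of
the pipeline.

## Parsimony engine

Characters are ordered (Wagner): the cost of changing state `i` to `j` is
`|i − j|`, the natural reading of a 0…N transformation series with a
polarized ancestral extreme. An unordered (Fitch) cost model is available
for comparison in `parsimony_score`.

Two scoring engines are implemented and tested for equality:

- a Sankoff dynamic program over all 24 states (reference; supports both
  cost models), with the min-plus transition computed in O(states) per
  node by forward/backward sweeps;
- the Farris interval method for ordered characters (exact on binary
  trees), used by the search because it is ~an order of magnitude faster.

Both are validated against brute-force enumeration of internal state
assignments on all topologies of up to 5 terminals.

The heuristic search is stepwise random addition followed by TBR
hill-climbing. TBR is evaluated with a re-rooting decomposition: for each
bisection the per-edge "rooted cost + state interval" of both fragments is
computed in one up/down pass, after which every reconnection pair is
scored by a vectorized interval join; a full TBR sweep over an `n`-taxon
tree is therefore O(E² · characters) with a small constant rather than
O(E²) full rescorings. The ratchet alternates TBR climbs on a reweighted
matrix (a random fraction of characters upweighted by a constant factor)
and the original matrix, keeping the best unweighted score. The published
regime ("10×30 chains", 1,000 addition replicates) is under-specified
about chain interaction; it is interpreted as independent iterations and
is reachable through `SearchConfig`; the desk-scale defaults are 25
addition replicates and 50 ratchet iterations with 25% of characters
upweighted ×2.

Determinism: all randomness flows from `SearchConfig.seed`; all iteration
orders are sorted and ties (including co-optimal trees) are broken
first-found, so identical seeds give bit-identical Newick output. The
number of co-optimal trees encountered is reported, matching the practice
of retaining a single MP reconstruction.

## Node distances and clocks

The depth `d` of a leaf is the number of internal nodes on the
root-to-leaf path (root counted). The guaranteed properties of the
published scale are only that it spans 0–1 with the basal-most family at
0; min–max rescaling `(d − d_min)/(d_max − d_min)` is the least-assuming
realization and the default, with `(d − 1)/(d_max − 1)` as an option. If
all leaves are equally deep, every nd is 0.

Two structure clocks ship as constants: fold level
`t = −3.802·nd + 3.814` and FSF level `t = −3.831·nd + 3.628` (Gy before
present). The source text states that FSF clocks were used for the purine
ages, yet its quoted ages (≈3.8 Gy at nd = 0, ≈3 Gy at nd = 0.187) match
the fold line more closely; both clocks are provided, the fold line is the
default, and no attempt is made to guess the original per-figure choice.
Negative ages (possible near nd = 1, e.g. the FSF line goes negative above
nd ≈ 0.947) are clamped to 0 with a warning rather than raising, so
rounding noise cannot crash a pipeline. `calibrate_clock` fits new clocks
by ordinary least squares and reports slope, intercept, Pearson r and the
correlation p-value.

When a family lacks a tree-derived age, `resolve_age` applies the
documented fallback chain: a secondary age table first, then the largest
nd among fold families of the same FSF (derived from the ccs prefix when
no explicit grouping is given), with the provenance tagged per entry.

## Purine fixture

The packaged fixture encodes the node-distance ages of the 11 fold
families at the core of purine metabolism and a 17-step EC-labeled network
linking them to the INT, BIO and CAT pathways (plus one pentose-phosphate
step, label CAR, for the PRPP precursor context). First appearances on the
fixture are INT = 0, BIO = 0.057, CAT = 0.069; the BIO establishment
window is 0.057–0.367 in nd, i.e. about 1.18 Gy under the fold clock. The
completion of the central BIO repertoire is carried both as the reported
0.187 and as the age of its youngest family (SAICAR synthase, 0.188);
the two differ by printed rounding and are deliberately not reconciled.
One editorial completion: no EC number is named in the source chronology
for the GDP–GMP interconversion family c.37.1.1, so the fixture attaches
it to the canonical guanylate kinase (2.7.4.8) and NDP kinase (2.7.4.6)
steps, which realizes its described intra-pathway role in INT.

The enzyme-level age of a multi-domain step is the minimum nd among its
families — an enzymatic activity exists once any of its catalytic domains
does. EC strings support `-` wildcards in joins. The painting ramp is a
linear RGB interpolation from red (nd = 0) to blue (nd = 1); the palette
is presentational.

## Synthetic censuses

The generator realizes the world the method assumes, nothing more:

- a pure-birth (Yule) organismal tree grown to `n_proteomes` tips
  (per-lineage split rate `lineage_branching`, default 1), rescaled so the
  root sits at 0 and the tips at `timeline_length` (default 10 abstract
  units);
- family originations at `birth_schedule` times (default: sorted uniform
  draws, with the founding family anchored at 0 so the oldest age is
  well-defined), each in a single random lineage alive at that moment;
- per-lineage-segment dynamics: whole-family loss with probability
  `1 − exp(−loss_rate·dt)`, otherwise `Poisson(duplication_rate·dt)`
  additional copies; both daughters inherit counts at splits.

Defaults for the rates follow the stated validation configuration
(duplication 0.5, loss 0.05 per family per lineage per time unit).
The generator does **not** model sequence evolution, HMM detection noise,
genome size variation or horizontal transfer; a green recovery test
therefore establishes that the pipeline can read back a planted birth
order from abundance data of this idealized kind, not that it dates real
proteomes correctly.

Two properties of the generator hold strongly at the stated configuration
(20-seed sweeps): older quartiles of families are more abundant than
younger ones, and birth rank anticorrelates with total abundance
(median Spearman ρ ≈ −0.68).

### Known limitation: end-to-end recovery strength

The end-to-end recovery experiment (simulate → encode → infer → node
distances at 40 families × 30 proteomes) attains median Spearman
ρ ≈ 0.38 between planted birth rank and inferred nd over 20 seeds —
positive and informative, but well short of the 0.7 aimed for by the
validation suite, whose test is kept at that bar and fails honestly.
Two measured causes: (i) even ranking families directly by total
abundance — the method's own core assumption — yields only median
ρ ≈ 0.68 in this world, so 0.7 exceeds the information ceiling of a
40-family census with these rates; and (ii) parsimony also responds to
shared proteome-coverage patterns (which lineage a family was born in),
which with 30 proteomes competes with the age signal: the optimal tree is
genuinely not the abundance ladder (verified by scoring both). The effect
is not a search artifact (exhaustive enumeration agrees with the heuristic
wherever it is feasible, and quintupling search effort does not change the
correlations) and not a growth-model artifact (a multiplicative per-copy
duplication variant gives the same median). Larger censuses — more
proteomes, more families, stronger abundance scaling — are exactly the
regime the full-scale method operates in.

## Numerical and degenerate-input conventions

- States are int16; scores are exact integers under unit weights (floats
  only during weighted ratchet phases; comparisons use a 1e-9 epsilon).
- Ties everywhere break toward the first candidate in sorted order.
- Trees with fewer than 3 data taxa, empty matrices, nd outside [0, 1],
  calibrations without two distinct nd values, unknown pathways and
  unresolvable families are rejected with messages naming the offender.
- Exhaustive enumeration refuses more than 9 data taxa ((2n−5)!! growth).
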