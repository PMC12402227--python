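# Methods

This note records what `ecotraits` computes, the assumptions behind each
indicator, the defaults and why they were chosen, and what the synthetic
test bed does and does not demonstrate.

## Data model

A snapshot is a node table (id, name, management class, biomass B,
production P, catch Y, reference biomass B_ref) plus a link table
(predator, prey, consumption). Units are a mass density (e.g. t km⁻²) and
its annual rate; the indices only require internal consistency, not a
particular unit. Catch is total fishery-induced removal, landed or not.
Habitats may appear as ordinary nodes whose "prey" links are habitat-use
dependencies; all metrics treat them identically to species.

Conventions enforced at load time: ids unique, links resolve, flows
non-negative, duplicate (predator, prey) rows rejected rather than summed
(they are almost always a data bug). Links with consumption exactly 0 are
treated as absent by every index — a zero flow carries no trophic
information and would inflate degrees. Self-links (cannibalism) are
permitted and contribute 2 to degree and 1 to degree-out.

## Hub Index

`Hub_Index = min(R_degree, R_degree_out, R_pagerank)` with competition
("1224") ranks, 1 = best. Ties share the smallest rank of their block, so
ranking is deterministic. The top `max(1, ceil(0.05·N))` species by Hub
Index are hubs; ties at the cutoff are all included (small webs still
yield a hub; nothing arbitrary is excluded). Consequently webs with heavy
rank ties — common when integer degree-out values repeat — can designate
more than 5% of species; that is the tie rule working as intended.

PageRank choices (all configurable): orientation predator→prey, so
centrally placed, heavily consumed prey score high; edge weights =
consumption (the score should reflect number *and* strength of links),
with an unweighted mode for binary diet data; damping 0.85 (the classic
default); dangling mass redistributed uniformly; convergence to an L1
tolerance of 1e-10. Because out-edge weights are row-normalised, scores
are invariant under global rescaling of all flows.

## Structural resilience

From the weighted degrees s_in (species' total consumption of its prey)
and s_out (total predation on it):

- ⟨s⟩ = total flow / N. The means of s_in and s_out coincide by
  conservation, so no halving or averaging of the two is applied.
- σ_in, σ_out are *population* standard deviations: the moments describe
  the degree distribution itself, and only with population moments does
  the product form S·H cancel exactly to cov(s_in, s_out)/⟨s⟩.
- β_eff = ⟨s⟩ + S·H, evaluated in the cancelled form
  ⟨s⟩ + cov(s_in, s_out)/⟨s⟩. When σ_in·σ_out = 0 (a constant marginal)
  the covariance is identically zero, so S and H are reported as 0 and
  β_eff = ⟨s⟩, removing the 0/0 ambiguity without changing the value
  anywhere else. When s_in = s_out for every node the expression reduces
  to the undirected limit ⟨s²⟩/⟨s⟩ exactly; the tests assert this.

Zone classification in the (H, ⟨s⟩) plane: below the frontier
(β_eff < β_crit) the system is non-resilient, and this verdict dominates —
negative symmetry can pull β_eff below the frontier even when both axis
thresholds are cleared. Above the frontier, clearing *both* axis
thresholds (⟨s⟩ > s_crit and H > H_crit) makes the system fully resilient;
otherwise it is partially resilient. The critical values depend on the
node dynamics assumed for the system, which a structural snapshot cannot
supply, so they are **required configuration**. The shipped demonstration
defaults (s_crit = H_crit = β_crit = 1.0, the axis intercepts of a unit
frontier in the web's own flow units) exhibit the mechanism; every test in
this repository constructs webs relative to the configured thresholds and
none depends on the defaults' absolute values. Zone → R schemes:
default {1.0, 0.8, 0.5}, conservative {1.0, 0.5, 0.25}, both plain config.

## Green Band

Step 1 fits ordinary least squares of log10 B on log10 P over the
*unfished* reference snapshot (≥ 3 species with positive B and P; others
are excluded with a logged warning). Base-10 logs throughout — the slope
is base-invariant, and decade units match how biomass–production plots are
read. The regression is of B on P; the opposite orientation is a
documented one-switch alternative, flagged because "biomass against
production" is ambiguous in common usage.

Step 2 bounds at production P: upper = min(0.5·P, P^(1+a)),
lower = min(0.5·P, δ·P^(1+a)). δ defaults to the conventional 0.01
(`delta_mode="fixed"`). The alternative `variance` mode ties the width to
the fit: δ = 10^(−k·resid_sd) with k = 2 by default, so a tighter unfished
profile yields a narrower band; the exact functional form is a package
choice and is recorded in the fitted model object.

Step 3 classifies: above the band → Fail, within (bounds inclusive — the
band is the acceptable zone, so boundary equality is not a failure) →
Acceptable, below → Light. Edge conventions: positive catch with zero
production is rated above (any removal from a non-producing stock is
distortive); zero catch and zero production excludes the species. The
signed log10 distance past the violated bound supports "how far out" and
trend reporting; `track_band` raises an early-warning flag for species
still inside the band whose headroom to the upper bound has strictly
shrunk over a sliding window (default 3 snapshots).

## Composite index

`ETI = R · Σ_j W_j [Σ_i κ_i N_ij / N_j]` over management classes j and
rating × relative-biomass combinations i. Relative-biomass bands are
half-open [low, high), top band closed, so a boundary value lands in the
upper (better) band. Classes with N_j = 0 are dropped and the remaining
weights renormalised to sum 1 — the inner mean is undefined for an empty
class, and renormalisation keeps the score on [0, R]. Hub class
membership is recomputed from the snapshot's topology by default (hub
identity shifts as a system restructures under pressure); a config flag
pins classes to the node table instead. Scores are reported to 3 decimals;
the rank label is assigned before rounding.

**Placeholder calibration.** The operational κ table, class weights,
biomass band edges and rank thresholds belong to a management calibration
this package does not ship. The defaults follow the intended shape: κ
decreasing monotonically from 1.0 (sustainably fished at near-reference
biomass) to 0.0 (overfished and collapsed); hub and vulnerable classes
weighted highest (0.3 each, target 0.2, byproduct/other 0.1); four
conservative biomass bands (healthy ≥ 0.75·B_ref, intermediate ≥ 0.4,
depleted ≥ 0.1, collapsed below); ten equal-width rank bands on [0, 1].
One deliberate design choice: Light and Acceptable share κ within each
biomass column. Both are sustainable harvest patterns — the biomass axis
already separates them — and equal scores make the composite monotone as
species move Light → Acceptable → Fail under rising pressure, which keeps
the index interpretable as a degradation signal.

## Synthetic test bed

`generate_web` emulates what a mass-balanced ecosystem model exports:

- Topology: niche-interval rule (each consumer eats a contiguous interval
  of the niche axis below it), expected connectance set by a
  Beta(1, 1/(2C) − 1) range distribution; the lowest-niche species is
  forced basal. Topologies are resampled until realised connectance is
  within 15% of target and the web is connected.
- Trophic levels solved from TL = 1 + mean prey TL (mildly damped so
  mutual-predation loops stay solvable).
- Biomass: 30 t km⁻² at the base, declining 0.7 decades per trophic level
  with 0.2 decades of lognormal scatter — the transfer-efficiency-like
  slope and noise of typical shelf-system models.
- Turnover: P/B interpolated geometrically from 60 yr⁻¹ (basal) to
  0.3 yr⁻¹ (apex), Q/B from 150 to 1 yr⁻¹ with growth efficiency capped
  below 0.5; flows allocate each consumer's intake (Q/B)·B across its prey
  in proportion to prey biomass, so intake is mass-consistent by
  construction.
- Classes assigned down the trophic ordering: vulnerable (0.15) at the
  top, then target (0.30), byproduct (0.15), other (0.40).

Fishing uses an equilibrium surplus-production response: under
F = g·F_ref a stock sits at B = B₀·max(0.01, 1 − F/r) with r its P/B,
catch = F·B; link flows scale with the relative biomass of both endpoints,
and production scales with own relative biomass times prey availability
(one rebalance pass), which lets unfished consumers feel depleted prey.
Reference mortalities default to class multiples of r (target 0.5·r —
the single-stock optimum — byproduct 0.3, vulnerable 0.1, other 0.05),
standing in for a system-level sustainable exploitation rate that this
package deliberately does not estimate.

What this test bed does **not** emulate: dynamic trophic cascades,
predator release and compensation (which in real systems can make Green
Band trajectories non-monotone), recruitment variability, environmental
forcing, or the taxonomic idiosyncrasies of real models. Passing tests
therefore demonstrate that the indicators respond correctly to controlled,
monotone structural degradation — not that they are calibrated for any
real ecosystem.

## Numerical choices and problem sizes

- PageRank converged to L1 1e-10 (1e-14 where cross-checked against the
  hand-written power-iteration oracle, agreement to 1e-12).
- β_eff cross-checked term-by-term on 1000 random webs to 1e-9 relative.
- The depletion experiment in tests and the acceptance script uses a
  30-species web at connectance 0.15 over g ∈ {0 … 5}, the size at which
  every qualitative behaviour of interest (band crossings, rank descent,
  hub turnover) is already expressed.
- Slope-recovery checks use 50-species references with production spanning
  six decades (a whole-ecosystem range, marine mammals through plankton)
  and 0.2 decades of lognormal scatter; the OLS slope standard error is
  then ≈ 0.015, comfortably inside the ±0.05 check.
- Generator determinism is absolute per config+seed; every CLI run writes
  a manifest so deterministic stages reproduce byte-identically.

## Known limitations

- Resilience thresholds are demonstrative until calibrated; absolute zone
  calls on real data are meaningless without system-specific β_crit.
- The composite's κ/W/band/rank numbers are placeholders (above).
- The unfished profile must come from a model or a genuinely unfished
  reference state; fitting it to a fished snapshot biases the band.
- Import/export flows across the system boundary are not modelled as
  nodes; webs are closed to the species/habitat set supplied.
- PageRank orientation, weighting and damping follow documented defaults;
  comparisons across studies should pin these in config.
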