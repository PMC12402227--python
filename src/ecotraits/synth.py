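"""Synthetic mass-balanced food webs and fishing-depletion scenarios.

The generator emulates the kind of snapshot an Ecopath-style mass-balance
model exports: a niche-model topology (each consumer eats a contiguous
interval of the niche axis below it), biomass declining with trophic
level, production/biomass and consumption/biomass ratios falling from
fast-turnover basal groups to slow apex predators, and consumption flows
allocated by prey biomass so that each consumer's total intake equals
(Q/B) x B exactly.  Everything is deterministic per seed.

Fishing scenarios apply an equilibrium surplus-production (Schaefer)
response rather than dynamic simulation: under fishing mortality
F = g * F_ref a stock equilibrates at B = B0 * max(eps, 1 - F/r), catch is
F * B, and production and flows shrink with the biomasses on both ends of
each link.  A one-pass prey-availability rebalance passes indirect effects
to unfished consumers.  This closed-form, monotone depletion is enough to
exercise every indicator across the full range from pristine to collapsed;
it is not an ecosystem model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .foodweb import FoodWeb, Link, Species, WebSeries

#: Residual biomass floor: a stock fished past F = r keeps 1% of B0,
#: mimicking a highly depleted but not extinct group.
BIOMASS_FLOOR = 0.01

#: Reference fishing mortality as a multiple of a species' intrinsic rate
#: (its P/B), by management class.  Target species are fished near the
#: single-stock optimum F = r/2; others take incidental mortality.
DEFAULT_F_MULTIPLIER = {
    "target": 0.5,
    "byproduct": 0.3,
    "vulnerable": 0.1,
    "other": 0.05,
    "hub": 0.05,
}

#: Fishing-pressure ladder, as multiples g of the reference mortality.
DEFAULT_G_SCHEDULE = (
    0.0, 0.02, 0.05, 0.1, 0.2, 0.5, 0.65, 1.0, 1.5, 2.0, 5.0, 10.0, 20.0,
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic reference (unfished) web.

    ``pb_range``/``qb_range`` give (slowest, fastest) per-year turnover
    ratios, interpolated geometrically from the highest trophic level down
    to the basal/first consumer level.  ``biomass_slope`` is the log10
    decline of biomass per trophic level; ``noise_sd`` adds lognormal
    scatter (log10 units) around that trend.  ``class_fractions`` allocate
    management classes down the trophic ordering (hub membership is
    recomputed by the topology module, not assigned here).
    """

    n_species: int = 30
    connectance: float = 0.15
    seed: int = 0
    pb_range: tuple[float, float] = (0.3, 60.0)
    qb_range: tuple[float, float] = (1.0, 150.0)
    basal_biomass: float = 30.0
    biomass_slope: float = 0.7
    noise_sd: float = 0.2
    class_fractions: dict = field(
        default_factory=lambda: {
            "vulnerable": 0.15,
            "target": 0.30,
            "byproduct": 0.15,
            "other": 0.40,
        }
    )

    def __post_init__(self) -> None:
        if self.n_species < 5:
            raise ValidationError(f"n_species must be >= 5, got {self.n_species}")
        if not 0.02 < self.connectance < 0.4:
            raise ValidationError(
                f"connectance must lie in (0.02, 0.4), got {self.connectance}"
            )
        for name in ("pb_range", "qb_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValidationError(f"{name} must be positive with lo <= hi")
        if self.basal_biomass <= 0 or self.biomass_slope <= 0:
            raise ValidationError("basal_biomass and biomass_slope must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        total = sum(self.class_fractions.values())
        if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
            raise ValidationError(f"class_fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class ScenarioConfig:
    """A fishing-pressure scenario over a reference web.

    ``f_ref`` maps species id to the reference fishing mortality (yr^-1)
    that the multiplier g scales — the stand-in for a system-level
    sustainable exploitation rate, which this package does not estimate.
    ``r`` maps species id to the intrinsic rate governing the equilibrium
    depletion response.  Build both from a web with
    :func:`default_scenario`.
    """

    f_ref: dict[str, float]
    g_schedule: tuple[float, ...] = DEFAULT_G_SCHEDULE
    r: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.g_schedule):
            raise ValidationError("g multipliers must be >= 0")
        if any(f < 0 for f in self.f_ref.values()):
            raise ValidationError("reference fishing mortalities must be >= 0")
        if any(v <= 0 for v in self.r.values()):
            raise ValidationError("intrinsic rates must be positive")


def default_scenario(
    web: FoodWeb,
    g_schedule: tuple[float, ...] = DEFAULT_G_SCHEDULE,
    multipliers: dict[str, float] | None = None,
) -> ScenarioConfig:
    """Scenario with per-species r = P/B and class-based F_ref = m * r."""
    multipliers = multipliers or DEFAULT_F_MULTIPLIER
    r = {}
    f_ref = {}
    for sp in web.species:
        if sp.biomass <= 0 or sp.production <= 0:
            continue
        rate = sp.production / sp.biomass
        r[sp.id] = rate
        f_ref[sp.id] = multipliers.get(sp.species_class, 0.0) * rate
    return ScenarioConfig(f_ref=f_ref, g_schedule=tuple(g_schedule), r=r)


# ---------------------------------------------------------------------------
# Reference-web generation


def _niche_topology(config: SynthConfig, rng: np.random.Generator) -> list[set[int]]:
    """Prey sets per species under the niche-interval rule.

    Each species gets a niche value in (0, 1); consumers eat every species
    whose value falls in a contiguous interval centred below their own.
    The lowest-niche species is forced basal.  Expected connectance matches
    the target via the Beta(1, 1/(2C) - 1) range distribution.
    """
    n = config.n_species
    niche = np.sort(rng.uniform(0.0, 1.0, n))
    beta_shape = 1.0 / (2.0 * config.connectance) - 1.0
    ranges = niche * rng.beta(1.0, beta_shape, n)
    ranges[0] = 0.0  # guarantee a basal species
    prey: list[set[int]] = []
    for i in range(n):
        if ranges[i] == 0.0:
            prey.append(set())
            continue
        centre = rng.uniform(ranges[i] / 2.0, niche[i])
        lo, hi = centre - ranges[i] / 2.0, centre + ranges[i] / 2.0
        eaten = {j for j in range(n) if lo <= niche[j] <= hi}
        if not (eaten - {i}):  # no external prey: eat the nearest lower species
            below = [j for j in range(n) if j != i and niche[j] < niche[i]]
            if below:
                eaten.add(max(below, key=lambda j: niche[j]))
            else:
                eaten = set()
        prey.append(eaten)
    return prey


def _is_connected(prey: list[set[int]], n: int) -> bool:
    adjacency = [set() for _ in range(n)]
    for i, eaten in enumerate(prey):
        for j in eaten:
            adjacency[i].add(j)
            adjacency[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def _trophic_levels(prey: list[set[int]]) -> np.ndarray:
    """TL = 1 for basal, else 1 + mean prey TL (solved linearly)."""
    n = len(prey)
    A = np.zeros((n, n))
    for i, eaten in enumerate(prey):
        if eaten:
            for j in eaten:
                A[i, j] = 1.0 / len(eaten)
    # mild damping keeps loop-heavy diets (mutual predation) solvable;
    # clip guards against runaway levels in pathological cycles
    tl = np.linalg.solve(np.eye(n) - 0.999 * A, np.ones(n))
    return np.clip(tl, 1.0, 10.0)


def _log_interp(level: float, lo_level: float, hi_level: float, fast: float, slow: float) -> float:
    """Geometric interpolation from `fast` at lo_level to `slow` at hi_level."""
    if hi_level <= lo_level:
        return fast
    frac = np.clip((level - lo_level) / (hi_level - lo_level), 0.0, 1.0)
    return float(10.0 ** (np.log10(fast) + frac * (np.log10(slow) - np.log10(fast))))


def _assign_classes(order: np.ndarray, config: SynthConfig) -> list[str]:
    """Allocate classes down the trophic ordering: vulnerable at the top,
    then target, byproduct, other."""
    n = len(order)
    fractions = config.class_fractions
    sequence = ["vulnerable", "target", "byproduct", "other"]
    counts = {c: int(round(fractions.get(c, 0.0) * n)) for c in sequence}
    counts["other"] = n - sum(counts[c] for c in sequence[:-1])
    classes = [""] * n
    pos = 0
    for cls in sequence:
        for _ in range(max(counts[cls], 0)):
            if pos < n:
                classes[order[pos]] = cls
                pos += 1
    for i in range(n):
        if not classes[i]:
            classes[i] = "other"
    return classes


def generate_web(config: SynthConfig, max_tries: int = 500) -> FoodWeb:
    """Generate a connected, mass-consistent reference web.

    Topology is resampled until the realised connectance lies within 15% of
    the target and the web is (weakly) connected, so the generator fails
    only for genuinely infeasible configurations.  Output is identical for
    identical configs (the seed drives every draw).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    prey = None
    for _ in range(max_tries):
        candidate = _niche_topology(config, rng)
        n_links = sum(len(p) for p in candidate)
        realised = n_links / n**2
        if (
            abs(realised - config.connectance) <= 0.15 * config.connectance
            and _is_connected(candidate, n)
            and n_links > 0
        ):
            prey = candidate
            break
    if prey is None:
        raise ValidationError(
            f"could not realise connectance {config.connectance} on "
            f"{n} species after {max_tries} tries"
        )
    tl = _trophic_levels(prey)
    tl_max = max(float(tl.max()), 2.0)

    noise = rng.normal(0.0, config.noise_sd, n)
    biomass = config.basal_biomass * 10.0 ** (
        -config.biomass_slope * (tl - 1.0) + noise
    )
    pb = np.array(
        [
            _log_interp(t, 1.0, tl_max, config.pb_range[1], config.pb_range[0])
            for t in tl
        ]
    )
    qb = np.zeros(n)
    consumer_levels = [tl[i] for i in range(n) if prey[i]]
    lo_cons = min(consumer_levels) if consumer_levels else 2.0
    for i in range(n):
        if prey[i]:
            qb[i] = _log_interp(tl[i], lo_cons, tl_max, config.qb_range[1], config.qb_range[0])
            qb[i] = max(qb[i], 2.0 * pb[i])  # growth efficiency < 0.5
    production = pb * biomass
    consumption = qb * biomass

    ids = [f"sp{i:03d}" for i in range(n)]
    order = np.argsort(-tl, kind="stable")
    classes = _assign_classes(order, config)
    species = [
        Species(
            id=ids[i],
            name=f"group {i}",
            species_class=classes[i],
            biomass=float(biomass[i]),
            production=float(production[i]),
            catch=0.0,
            reference_biomass=float(biomass[i]),
        )
        for i in range(n)
    ]
    links = []
    for i in range(n):
        if not prey[i]:
            continue
        prey_idx = sorted(prey[i])
        prey_biomass = biomass[prey_idx]
        shares = prey_biomass / prey_biomass.sum()
        for j, share in zip(prey_idx, shares):
            links.append(Link(ids[i], ids[j], float(consumption[i] * share)))
    meta = pd.DataFrame(
        {"trophic_level": tl, "pb": pb, "qb": qb}, index=pd.Index(ids, name="id")
    )
    return FoodWeb(species=species, links=links, timestamp=0.0, node_metadata=meta)


# ---------------------------------------------------------------------------
# Fishing scenarios


def apply_fishing(web: FoodWeb, g: float, scenario: ScenarioConfig) -> FoodWeb:
    """Equilibrium snapshot of the reference web under pressure g * F_ref.

    Per fished species: F = g * f_ref, B = B0 * max(eps, 1 - F/r) and
    catch = F * B.  Each link's flow scales with the relative biomass of
    both its endpoints; production scales with the species' own relative
    biomass times its prey availability (the one-pass rebalance that lets
    unfished consumers feel depleted prey).  g = 0 returns the reference
    state with zero catch.
    """
    if g < 0:
        raise ValidationError(f"g must be >= 0, got {g}")
    relb = {}
    for sp in web.species:
        F = g * scenario.f_ref.get(sp.id, 0.0)
        if F <= 0:
            relb[sp.id] = 1.0
            continue
        r = scenario.r.get(sp.id)
        if r is None:
            r = sp.production / sp.biomass if sp.biomass > 0 else None
        if r is None or r <= 0:
            relb[sp.id] = 1.0
            continue
        relb[sp.id] = max(BIOMASS_FLOOR, 1.0 - F / r)

    inflow0: dict[str, float] = {sp.id: 0.0 for sp in web.species}
    inflow_scaled: dict[str, float] = {sp.id: 0.0 for sp in web.species}
    for link in web.active_links():
        inflow0[link.predator] += link.consumption
        inflow_scaled[link.predator] += link.consumption * relb[link.prey]
    availability = {
        sp.id: (inflow_scaled[sp.id] / inflow0[sp.id]) if inflow0[sp.id] > 0 else 1.0
        for sp in web.species
    }

    species = []
    for sp in web.species:
        F = g * scenario.f_ref.get(sp.id, 0.0)
        b_new = sp.biomass * relb[sp.id]
        species.append(
            Species(
                id=sp.id,
                name=sp.name,
                species_class=sp.species_class,
                biomass=b_new,
                production=sp.production * relb[sp.id] * availability[sp.id],
                catch=F * b_new,
                reference_biomass=sp.reference_biomass,
            )
        )
    links = [
        Link(
            link.predator,
            link.prey,
            link.consumption * relb[link.predator] * relb[link.prey],
        )
        for link in web.links
    ]
    meta = None if web.node_metadata is None else web.node_metadata.copy()
    return FoodWeb(species=species, links=links, timestamp=g, node_metadata=meta)


def depletion_sweep(
    config: SynthConfig, scenario: ScenarioConfig | None = None
) -> WebSeries:
    """One snapshot per g in the scenario schedule over a fresh reference.

    With the default schedule the first snapshot (g = 0) is the unfished
    reference itself.  Snapshot timestamps carry the g multipliers when the
    schedule strictly increases, else the schedule index.
    """
    reference = generate_web(config)
    scenario = scenario or default_scenario(reference)
    if not scenario.g_schedule:
        raise ValidationError("g_schedule must not be empty")
    gs = scenario.g_schedule
    increasing = all(b > a for a, b in zip(gs, gs[1:]))
    snapshots = []
    for idx, g in enumerate(gs):
        snap = apply_fishing(reference, g, scenario)
        snap.timestamp = g if increasing else float(idx)
        snapshots.append(snap)
    return WebSeries(snapshots)
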