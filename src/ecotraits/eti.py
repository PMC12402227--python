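"""The Ecosystem Traits Index (ETI).

The ETI folds three complementary views of an ecosystem — topology (hub
species), structural resilience (the scalar R) and distortive fishing
pressure (Green Band status crossed with relative biomass) — into a single
score on [0, 1]::

    ETI = R * sum_j W_j [ sum_i kappa_i * N_ij / N_j ]

where j runs over management classes (vulnerable, hub, target, byproduct,
other), i over Green Band x relative-biomass combinations, ``N_ij`` counts
the class-j species in combination i, ``kappa_i`` in [0, 1] scores how
healthy combination i is, and the class weights ``W_j`` sum to 1.  R
multiplies the compositional term because losing structural resilience
amplifies every other risk.  The score maps onto ten qualitative ranks,
from close-to-pristine down to collapsed.

The default combination scores, class weights, biomass bands and rank
thresholds shipped here are PLACEHOLDER values following the intended
shape — kappa decreasing from 1.0 (sustainably fished, near-reference
biomass) to 0.0 (overfished and collapsed), hub and vulnerable classes
weighted highest, ten equal-width rank bands.  Replace them with an
operational calibration before management use; every number is plain
configuration (YAML/JSON) for exactly that reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import greenband as gb
from . import hub as hubmod
from . import resilience as res
from .errors import ConfigError, ValidationError
from .foodweb import SPECIES_CLASSES, FoodWeb, WebSeries

RATINGS = ("Light", "Acceptable", "Fail")

#: Placeholder relative-biomass bands (B/B_ref), half-open [low, high),
#: top band unbounded; intentionally conservative.
DEFAULT_RELB_BANDS = (
    ("collapsed", 0.0, 0.1),
    ("depleted", 0.1, 0.4),
    ("intermediate", 0.4, 0.75),
    ("healthy", 0.75, math.inf),
)

#: Placeholder combination scores kappa[(rating, relb band)].  Light and
#: Acceptable share a score — both are sustainable harvest patterns, the
#: biomass axis differentiates them — while Fail is penalised throughout.
DEFAULT_KAPPA = {
    ("Light", "healthy"): 1.0,
    ("Light", "intermediate"): 0.7,
    ("Light", "depleted"): 0.35,
    ("Light", "collapsed"): 0.1,
    ("Acceptable", "healthy"): 1.0,
    ("Acceptable", "intermediate"): 0.7,
    ("Acceptable", "depleted"): 0.35,
    ("Acceptable", "collapsed"): 0.1,
    ("Fail", "healthy"): 0.5,
    ("Fail", "intermediate"): 0.3,
    ("Fail", "depleted"): 0.1,
    ("Fail", "collapsed"): 0.0,
}

#: Placeholder class weights; hub and vulnerable species weigh most because
#: their loss disproportionately degrades structure.
DEFAULT_WEIGHTS = {
    "vulnerable": 0.3,
    "hub": 0.3,
    "target": 0.2,
    "byproduct": 0.1,
    "other": 0.1,
}

#: Ten qualitative ranks partitioning [0, 1]; (lower threshold, label, colour).
DEFAULT_RANK_BANDS = (
    (0.9, "Close to pristine", "#1a9850"),
    (0.8, "High integrity", "#66bd63"),
    (0.7, "Good integrity", "#a6d96a"),
    (0.6, "Medium integrity", "#d9ef8b"),
    (0.5, "Low integrity", "#fee08b"),
    (0.4, "Structure eroding", "#fdae61"),
    (0.3, "Shocks possible", "#f46d43"),
    (0.2, "Shocks likely", "#d73027"),
    (0.1, "Collapse likely", "#a50026"),
    (0.0, "Collapsed", "#67001f"),
)


@dataclass
class ETIConfig:
    """Everything the composite index needs, schema-validated.

    Sections map one-to-one onto the YAML/JSON config document: relative-
    biomass bands, kappa combination scores, class weights, rank bands,
    resilience thresholds/scheme, hub designation and Green Band options.
    """

    relb_bands: tuple = DEFAULT_RELB_BANDS
    kappa: dict = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    rank_bands: tuple = DEFAULT_RANK_BANDS
    resilience: res.ResilienceThresholds = field(
        default_factory=res.ResilienceThresholds
    )
    hub_percentile: float = hubmod.DEFAULT_HUB_PERCENTILE
    pagerank_damping: float = hubmod.DEFAULT_DAMPING
    delta_mode: str = "fixed"
    delta_k: float = 2.0
    recompute_hub: bool = True

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        bands = list(self.relb_bands)
        if not bands:
            raise ConfigError("relb_bands: at least one band required")
        low0 = bands[0][1]
        if low0 != 0.0:
            raise ConfigError("relb_bands: first band must start at 0")
        for (n1, _, h1), (n2, l2, _) in zip(bands, bands[1:]):
            if h1 != l2:
                raise ConfigError(
                    f"relb_bands: bands {n1!r} and {n2!r} are not contiguous"
                )
        band_names = [b[0] for b in bands]
        if len(set(band_names)) != len(band_names):
            raise ConfigError("relb_bands: duplicate band names")
        for rating in RATINGS:
            for name in band_names:
                key = (rating, name)
                if key not in self.kappa:
                    raise ConfigError(f"kappa: missing combination {key}")
                if not 0.0 <= self.kappa[key] <= 1.0:
                    raise ConfigError(
                        f"kappa: value for {key} must lie in [0, 1], got "
                        f"{self.kappa[key]}"
                    )
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("weights: class weights must be >= 0")
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigError(f"weights: must sum to 1, got {total}")
        unknown = set(self.weights) - set(SPECIES_CLASSES)
        if unknown:
            raise ConfigError(f"weights: unknown species classes {sorted(unknown)}")
        ranks = list(self.rank_bands)
        lows = [r[0] for r in ranks]
        if lows != sorted(lows, reverse=True) or len(set(lows)) != len(lows):
            raise ConfigError("rank_bands: thresholds must strictly decrease")
        if lows[-1] != 0.0:
            raise ConfigError("rank_bands: lowest band must start at 0")
        if any(not 0 <= lo < 1 for lo in lows):
            raise ConfigError("rank_bands: thresholds must lie in [0, 1)")
        if not 0 < self.hub_percentile <= 1:
            raise ConfigError("hub_percentile must lie in (0, 1]")

    @property
    def relb_band_names(self) -> list[str]:
        return [b[0] for b in self.relb_bands]

    @property
    def combinations(self) -> list[tuple[str, str]]:
        """All (rating, relb band) combinations i, in display order."""
        return [(r, b) for r in RATINGS for b in self.relb_band_names]

    @property
    def rank_labels(self) -> list[str]:
        return [r[1] for r in self.rank_bands]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "relb_bands": [
                {"name": n, "low": lo, "high": None if math.isinf(hi) else hi}
                for n, lo, hi in self.relb_bands
            ],
            "kappa": {
                rating: {
                    band: self.kappa[(rating, band)] for band in self.relb_band_names
                }
                for rating in RATINGS
            },
            "weights": dict(self.weights),
            "rank_bands": [
                {"low": lo, "label": label, "colour": colour}
                for lo, label, colour in self.rank_bands
            ],
            "resilience": {
                "s_crit": self.resilience.s_crit,
                "h_crit": self.resilience.h_crit,
                "beta_crit": self.resilience.beta_crit,
                "scheme": dict(self.resilience.scheme),
            },
            "hub": {
                "percentile": self.hub_percentile,
                "pagerank_damping": self.pagerank_damping,
                "recompute": self.recompute_hub,
            },
            "greenband": {"delta_mode": self.delta_mode, "k": self.delta_k},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ETIConfig":
        for section in ("relb_bands", "kappa", "weights", "rank_bands"):
            if section not in payload:
                raise ConfigError(f"config is missing section {section!r}")
        try:
            relb = tuple(
                (
                    str(b["name"]),
                    float(b["low"]),
                    math.inf if b.get("high") is None else float(b["high"]),
                )
                for b in payload["relb_bands"]
            )
            kappa = {
                (str(rating), str(band)): float(value)
                for rating, per_band in payload["kappa"].items()
                for band, value in per_band.items()
            }
            weights = {str(k): float(v) for k, v in payload["weights"].items()}
            rank_bands = tuple(
                (float(r["low"]), str(r["label"]), str(r.get("colour", "")))
                for r in payload["rank_bands"]
            )
        except (KeyError, TypeError, ValueError) as err:
            raise ConfigError(f"malformed config section: {err}") from err
        res_cfg = payload.get("resilience", {})
        thresholds = res.ResilienceThresholds(
            s_crit=float(res_cfg.get("s_crit", 1.0)),
            h_crit=float(res_cfg.get("h_crit", 1.0)),
            beta_crit=float(res_cfg.get("beta_crit", 1.0)),
            scheme=dict(res_cfg.get("scheme", res.DEFAULT_SCHEME)),
        )
        hub_cfg = payload.get("hub", {})
        gb_cfg = payload.get("greenband", {})
        return cls(
            relb_bands=relb,
            kappa=kappa,
            weights=weights,
            rank_bands=rank_bands,
            resilience=thresholds,
            hub_percentile=float(hub_cfg.get("percentile", hubmod.DEFAULT_HUB_PERCENTILE)),
            pagerank_damping=float(hub_cfg.get("pagerank_damping", hubmod.DEFAULT_DAMPING)),
            recompute_hub=bool(hub_cfg.get("recompute", True)),
            delta_mode=str(gb_cfg.get("delta_mode", "fixed")),
            delta_k=float(gb_cfg.get("k", 2.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ETIConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigError("config document must be a mapping")
        return cls.from_dict(payload)


@dataclass
class ETIResult:
    """One snapshot's composite score and its ingredients."""

    N: pd.DataFrame  # counts, combinations x classes
    N_j: pd.Series  # per-class totals
    score: float
    R: float
    zone: str
    rank_label: str
    timestamp: object | None = None


def relb_category(biomass: float, reference_biomass: float, config: ETIConfig) -> str:
    """Relative-biomass band of B/B_ref; interior boundaries belong to the
    upper band (half-open rule), the top band is closed above."""
    if reference_biomass <= 0:
        raise ValidationError(
            f"relative biomass needs reference_biomass > 0, got {reference_biomass}"
        )
    ratio = biomass / reference_biomass
    for name, low, high in config.relb_bands:
        if low <= ratio < high:
            return name
    return config.relb_bands[-1][0]  # top band closed


def tabulate(
    statuses: pd.DataFrame,
    web: FoodWeb,
    config: ETIConfig,
    hub_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Count species per (Green Band rating x relative-biomass band)
    combination and management class: the N_ij matrix.

    ``hub_ids`` (normally the hub module's designation for this snapshot)
    overrides the static class column, because hub identity shifts as the
    ecosystem restructures; pass None to pin classes to the node table.
    Species absent from ``statuses`` (excluded by the Green Band step) are
    skipped.
    """
    index = pd.MultiIndex.from_tuples(config.combinations, names=["rating", "relb"])
    counts = pd.DataFrame(0, index=index, columns=list(SPECIES_CLASSES))
    for sp in web.species:
        if sp.id not in statuses.index:
            continue
        rating = statuses.loc[sp.id, "rating"]
        band = relb_category(sp.biomass, sp.reference_biomass, config)
        cls = "hub" if (hub_ids is not None and sp.id in hub_ids) else sp.species_class
        counts.loc[(rating, band), cls] += 1
    return counts


def eti_score(
    N: pd.DataFrame,
    config: ETIConfig,
    R: float,
    zone: str = "",
    timestamp=None,
) -> ETIResult:
    """Evaluate the composite score from a tabulation and a resilience
    scalar.

    Classes with no species are dropped and the remaining weights
    renormalised to sum 1, keeping the score on [0, R].
    """
    N_j = N.sum(axis=0)
    occupied = [c for c in N.columns if N_j[c] > 0]
    if not occupied:
        raise ValidationError("cannot score an ETI with every class empty")
    total_w = sum(config.weights.get(c, 0.0) for c in occupied)
    if total_w <= 0:
        raise ConfigError(
            f"all occupied classes {occupied} carry zero weight; cannot renormalise"
        )
    kappa = pd.Series(
        {comb: config.kappa[comb] for comb in config.combinations}
    ).reindex(N.index)
    inner = {c: float((kappa * N[c]).sum() / N_j[c]) for c in occupied}
    score = R * sum(config.weights.get(c, 0.0) / total_w * inner[c] for c in occupied)
    return ETIResult(
        N=N,
        N_j=N_j,
        score=score,
        R=R,
        zone=zone,
        rank_label=eti_rank(score, config),
        timestamp=timestamp,
    )


def eti_rank(score: float, config: ETIConfig) -> str:
    """Label of the rank band containing the score (bands half-open from
    below, the top band closed at 1)."""
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"ETI score must lie in [0, 1], got {score}")
    for low, label, _ in config.rank_bands:
        if score >= low:
            return label
    return config.rank_bands[-1][1]


def assess_snapshot(
    web: FoodWeb, model: gb.GreenBandModel, config: ETIConfig
) -> ETIResult:
    """Full per-snapshot pipeline: hub set, resilience, Green Band,
    tabulation, score and rank."""
    hub_ids: set[str] | None = None
    if config.recompute_hub:
        scores = hubmod.hub_index(
            web, damping=config.pagerank_damping, percentile=config.hub_percentile
        )
        hub_ids = hubmod.hub_species(scores, percentile=config.hub_percentile)
    state = res.assess(web, config.resilience)
    statuses = gb.classify_species(web, model)
    counts = tabulate(statuses, web, config, hub_ids=hub_ids)
    return eti_score(
        counts, config, R=state.R, zone=state.zone, timestamp=web.timestamp
    )


def eti_timeseries(
    series: WebSeries, reference: FoodWeb, config: ETIConfig | None = None
) -> list[ETIResult]:
    """Score every snapshot against one reference (unfished) profile.

    The Green Band model is fitted once on the reference; hub sets, R and
    statuses are recomputed per snapshot.  Per-snapshot failures carry the
    snapshot's timestamp.
    """
    config = config or ETIConfig()
    model = gb.fit_unfished_profile(reference, delta_mode=config.delta_mode, k=config.delta_k)
    results = []
    for web in series:
        try:
            results.append(assess_snapshot(web, model, config))
        except Exception as err:
            raise type(err)(f"snapshot {web.timestamp!r}: {err}") from err
    return results


def timeseries_frame(results: list[ETIResult]) -> pd.DataFrame:
    """Tabular view of a scored series (score reported to 3 decimals;
    ranks were assigned before rounding)."""
    return pd.DataFrame(
        {
            "timestamp": [r.timestamp for r in results],
            "score": [round(r.score, 3) for r in results],
            "rank_label": [r.rank_label for r in results],
            "R": [r.R for r in results],
            "zone": [r.zone for r in results],
        }
    )
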