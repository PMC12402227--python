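"""Food-web snapshots: data model, CSV/JSON I/O and validation.

A :class:`FoodWeb` is one snapshot in time of a directed, weighted trophic
network.  Nodes are species, functional groups or habitats; a link
``(predator, prey, consumption)`` records the annual consumption flow from
prey to predator (habitat "prey" links express habitat-use dependency).
A :class:`WebSeries` is an ordered sequence of snapshots over a shared
species universe, used for tracking indicators through time.

Tables are exchanged as plain CSV: a node table with columns
``id,name,class,biomass,production,catch,reference_biomass`` and a link
table with columns ``predator,prey,consumption``.  Unknown node columns are
preserved as metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateNetworkError,
    ReferentialError,
    SchemaError,
    ValidationError,
)

#: Management classes used to weight species in the composite index.
SPECIES_CLASSES = ("vulnerable", "hub", "target", "byproduct", "other")

NODE_COLUMNS = (
    "id",
    "name",
    "class",
    "biomass",
    "production",
    "catch",
    "reference_biomass",
)
LINK_COLUMNS = ("predator", "prey", "consumption")


@dataclass(frozen=True)
class Species:
    """One node of the web: a species, functional group or habitat.

    ``biomass`` and ``reference_biomass`` are mass densities (e.g. t km^-2);
    ``production`` and ``catch`` are mass-density rates (t km^-2 yr^-1).
    ``catch`` is total fishery-induced mortality, landed or not.
    ``reference_biomass`` is the unfished/baseline biomass used for
    relative-biomass scoring and must be positive when that scoring is
    requested.
    """

    id: str
    name: str = ""
    species_class: str = "other"
    biomass: float = 0.0
    production: float = 0.0
    catch: float = 0.0
    reference_biomass: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("species id must be a non-empty string")
        if self.species_class not in SPECIES_CLASSES:
            raise ValidationError(
                f"species {self.id!r}: unknown class {self.species_class!r}; "
                f"expected one of {SPECIES_CLASSES}"
            )
        for attr in ("biomass", "production", "catch", "reference_biomass"):
            value = getattr(self, attr)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"species {self.id!r}: {attr} must be finite and >= 0, got {value}"
                )

    @property
    def relative_biomass(self) -> float:
        """B / B_ref; requires a positive reference biomass."""
        if self.reference_biomass <= 0:
            raise ValidationError(
                f"species {self.id!r}: relative biomass requested but "
                f"reference_biomass is {self.reference_biomass}"
            )
        return self.biomass / self.reference_biomass


@dataclass(frozen=True)
class Link:
    """Directed consumption flow: ``predator`` eats ``prey`` at rate
    ``consumption`` (mass-density yr^-1).  Self-links model cannibalism."""

    predator: str
    prey: str
    consumption: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.consumption) or self.consumption < 0:
            raise ValidationError(
                f"link ({self.predator!r}, {self.prey!r}): consumption must be "
                f"finite and >= 0, got {self.consumption}"
            )


@dataclass
class FoodWeb:
    """A validated snapshot of a weighted food web.

    Parameters
    ----------
    species
        Node list; ids must be unique.
    links
        Consumption links; both endpoints must resolve to species and the
        same (predator, prey) pair may appear at most once.
    timestamp
        Optional label for the snapshot (e.g. a year).
    node_metadata
        Extra node-table columns preserved on load, indexed by species id.
    """

    species: list[Species]
    links: list[Link]
    timestamp: object | None = None
    node_metadata: pd.DataFrame | None = None
    _by_id: dict[str, Species] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [sp.id for sp in self.species]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate species ids: {sorted(dupes)}")
        self._by_id = {sp.id: sp for sp in self.species}
        known = set(self._by_id)
        dangling = sorted(
            {l.predator for l in self.links if l.predator not in known}
            | {l.prey for l in self.links if l.prey not in known}
        )
        if dangling:
            raise ReferentialError(
                f"links reference unknown species ids: {dangling}"
            )
        pairs = [(l.predator, l.prey) for l in self.links]
        dup_pairs = {p for p in pairs if pairs.count(p) > 1}
        if dup_pairs:
            raise ValidationError(
                "duplicate (predator, prey) links (flows are never silently "
                f"summed): {sorted(dup_pairs)}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [sp.id for sp in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def __getitem__(self, species_id: str) -> Species:
        try:
            return self._by_id[species_id]
        except KeyError:
            raise KeyError(f"unknown species id {species_id!r}") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._by_id

    def active_links(self) -> list[Link]:
        """Links carrying positive flow.

        A recorded flow of exactly zero carries no trophic information and is
        treated as absent by every index (binary and weighted alike).
        """
        return [l for l in self.links if l.consumption > 0]

    def require_links(self) -> None:
        if self.n_species < 2 or not self.active_links():
            raise DegenerateNetworkError(
                "index computation needs at least 2 species and 1 link with "
                f"positive flow (got {self.n_species} species, "
                f"{len(self.active_links())} active links)"
            )

    # -- tabular views -----------------------------------------------------

    def node_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "id": [sp.id for sp in self.species],
                "name": [sp.name for sp in self.species],
                "class": [sp.species_class for sp in self.species],
                "biomass": [sp.biomass for sp in self.species],
                "production": [sp.production for sp in self.species],
                "catch": [sp.catch for sp in self.species],
                "reference_biomass": [sp.reference_biomass for sp in self.species],
            }
        )
        return frame

    def link_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predator": [l.predator for l in self.links],
                "prey": [l.prey for l in self.links],
                "consumption": [l.consumption for l in self.links],
            }
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        payload = {
            "timestamp": self.timestamp,
            "species": [
                {
                    "id": sp.id,
                    "name": sp.name,
                    "class": sp.species_class,
                    "biomass": sp.biomass,
                    "production": sp.production,
                    "catch": sp.catch,
                    "reference_biomass": sp.reference_biomass,
                }
                for sp in self.species
            ],
            "links": [
                {"predator": l.predator, "prey": l.prey, "consumption": l.consumption}
                for l in self.links
            ],
        }
        if self.node_metadata is not None:
            payload["node_metadata"] = self.node_metadata.reset_index().to_dict(
                orient="list"
            )
        return payload

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FoodWeb":
        meta = None
        if payload.get("node_metadata"):
            meta = pd.DataFrame(payload["node_metadata"]).set_index("id")
        return cls(
            species=[
                Species(
                    id=str(row["id"]),
                    name=str(row.get("name", "")),
                    species_class=str(row.get("class", "other")),
                    biomass=float(row.get("biomass", 0.0)),
                    production=float(row.get("production", 0.0)),
                    catch=float(row.get("catch", 0.0)),
                    reference_biomass=float(row.get("reference_biomass", 0.0)),
                )
                for row in payload["species"]
            ],
            links=[
                Link(str(row["predator"]), str(row["prey"]), float(row["consumption"]))
                for row in payload["links"]
            ],
            timestamp=payload.get("timestamp"),
            node_metadata=meta,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FoodWeb":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class WebSeries:
    """Ordered snapshots sharing one species universe.

    Timestamps must be strictly increasing; every snapshot must carry the
    same species ids (a species absent from the system is represented with
    biomass zero rather than dropped).
    """

    snapshots: list[FoodWeb]

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValidationError("a WebSeries needs at least one snapshot")
        stamps = [w.timestamp for w in self.snapshots]
        if any(t is None for t in stamps):
            raise ValidationError("every snapshot in a series needs a timestamp")
        if any(not b > a for a, b in zip(stamps, stamps[1:])):
            raise ValidationError(f"timestamps must be strictly increasing: {stamps}")
        universe = set(self.snapshots[0].ids)
        for web in self.snapshots[1:]:
            if set(web.ids) != universe:
                raise ValidationError(
                    "all snapshots must share one species universe; snapshot "
                    f"{web.timestamp!r} differs"
                )

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    @property
    def timestamps(self) -> list:
        return [w.timestamp for w in self.snapshots]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"snapshots": [w.to_dict() for w in self.snapshots]}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WebSeries":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([FoodWeb.from_dict(d) for d in payload["snapshots"]])


# ---------------------------------------------------------------------------
# Table I/O


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def load_foodweb(node_table, link_table, timestamp=None) -> FoodWeb:
    """Read a snapshot from CSV node and link tables.

    Unknown node columns are kept in ``FoodWeb.node_metadata``.  Duplicate
    (predator, prey) rows, dangling ids and negative quantities all raise.
    """
    nodes = pd.read_csv(node_table, dtype={"id": str, "name": str, "class": str})
    links = pd.read_csv(link_table, dtype={"predator": str, "prey": str})
    return foodweb_from_frames(nodes, links, timestamp=timestamp)


def foodweb_from_frames(
    nodes: pd.DataFrame, links: pd.DataFrame, timestamp=None
) -> FoodWeb:
    """Build a validated :class:`FoodWeb` from in-memory node/link tables."""
    _require_columns(nodes, NODE_COLUMNS, "node")
    _require_columns(links, LINK_COLUMNS, "link")
    if nodes["id"].duplicated().any():
        raise ValidationError(
            f"duplicate ids in node table: "
            f"{sorted(nodes.loc[nodes['id'].duplicated(), 'id'])}"
        )
    extra = [c for c in nodes.columns if c not in NODE_COLUMNS]
    meta = nodes.set_index("id")[extra].copy() if extra else None
    species = [
        Species(
            id=str(row.id),
            name="" if pd.isna(row.name_) else str(row.name_),
            species_class=str(row.class_),
            biomass=float(row.biomass),
            production=float(row.production),
            catch=float(row.catch),
            reference_biomass=float(row.reference_biomass),
        )
        for row in nodes.rename(columns={"name": "name_", "class": "class_"}).itertuples()
    ]
    link_objs = [
        Link(str(row.predator), str(row.prey), float(row.consumption))
        for row in links.itertuples()
    ]
    return FoodWeb(species=species, links=link_objs, timestamp=timestamp, node_metadata=meta)


def save_foodweb(web: FoodWeb, node_table, link_table) -> None:
    """Write a snapshot back to CSV node and link tables (round-trips)."""
    frame = web.node_frame()
    if web.node_metadata is not None:
        frame = frame.merge(web.node_metadata.reset_index(), on="id", how="left")
    frame.to_csv(node_table, index=False)
    web.link_frame().to_csv(link_table, index=False)


# ---------------------------------------------------------------------------
# Matrix views


def binary_adjacency(web: FoodWeb) -> pd.DataFrame:
    """Predator x prey incidence: True where a positive flow exists.

    Presence/absence diet data is all the topology metrics need, so this is
    the common substrate for degree-based indices.  Zero-flow links are
    dropped.
    """
    ids = web.ids
    adj = pd.DataFrame(False, index=ids, columns=ids, dtype=bool)
    for link in web.active_links():
        adj.loc[link.predator, link.prey] = True
    adj.index.name = "predator"
    adj.columns.name = "prey"
    return adj


def consumption_matrix(web: FoodWeb) -> pd.DataFrame:
    """Predator x prey flow matrix; absent links are zero.

    The matrix total equals total system consumption.
    """
    ids = web.ids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for link in web.active_links():
        mat.loc[link.predator, link.prey] = link.consumption
    mat.index.name = "predator"
    mat.columns.name = "prey"
    return mat
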