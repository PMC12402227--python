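"""Structural resilience of a weighted food web.

Following the universal resilience framework of Gao and co-workers, the
response of a networked system to perturbation is summarised by a single
effective state computed from the weighted-degree distribution::

    beta_eff = <s> + S * H
             = <s> + (<s_in s_out> - <s_in><s_out>) / (sigma_in sigma_out)
                   * (sigma_in sigma_out) / <s>

where ``s_in`` (a species' total consumption of its prey) and ``s_out``
(total predation on it) are the weighted in/out degrees, ``<s>`` is the
network density (mean weighted degree), ``H`` the flow heterogeneity and
``S`` the in/out symmetry.  Moments use population (not sample) standard
deviations so the product form cancels exactly.

A system's position in the (H, <s>) plane relative to the resilience
frontier classifies it: above both axis thresholds it is fully resilient;
below the frontier (beta_eff < beta_crit) it is non-resilient; in between
it is partially resilient.  Each zone maps to a scalar R used by the
composite index — 1.0 / 0.8 / 0.5 by default, with a more precautionary
1.0 / 0.5 / 0.25 alternative.

The critical thresholds depend on the node dynamics assumed, which a
structural snapshot cannot supply, so they are configuration: the shipped
defaults (all 1.0 in the web's flow units) demonstrate the mechanism and
must be calibrated to the system under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateNetworkError
from .foodweb import FoodWeb, WebSeries, consumption_matrix

ZONES = ("resilient", "partially_resilient", "non_resilient")

#: Zone -> R scalar, default scheme.
DEFAULT_SCHEME = {"resilient": 1.0, "partially_resilient": 0.8, "non_resilient": 0.5}
#: More precautionary alternative.
CONSERVATIVE_SCHEME = {"resilient": 1.0, "partially_resilient": 0.5, "non_resilient": 0.25}


@dataclass(frozen=True)
class ResilienceThresholds:
    """Critical values bounding the resilient region.

    ``s_crit`` and ``h_crit`` are the axis intercepts of the resilience
    frontier in the (H, <s>) plane; ``beta_crit`` is the frontier itself.
    All share the web's flow units.  The scheme maps each zone to its
    scalar R.
    """

    s_crit: float = 1.0
    h_crit: float = 1.0
    beta_crit: float = 1.0
    scheme: dict = field(default_factory=lambda: dict(DEFAULT_SCHEME))

    def __post_init__(self) -> None:
        for attr in ("s_crit", "h_crit", "beta_crit"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"{attr} must be positive, got {getattr(self, attr)}")
        missing = [z for z in ZONES if z not in self.scheme]
        if missing:
            raise ConfigError(f"resilience scheme is missing zone(s): {missing}")
        r_res, r_part, r_non = (self.scheme[z] for z in ZONES)
        if not r_res > r_part > r_non > 0:
            raise ConfigError(
                "scheme values must strictly decrease with worsening zone, got "
                f"{self.scheme}"
            )
        # The frontier must not cut through the fully-resilient corner:
        # sitting exactly at both axis thresholds may not fall below it.
        if self.s_crit + self.h_crit < self.beta_crit:
            raise ConfigError(
                "inconsistent thresholds: a point at (s_crit, h_crit) would lie "
                "below beta_crit"
            )


@dataclass
class ResilienceState:
    """Weighted-degree summary of one snapshot.

    ``beta_eff = mean_s + S * H`` holds exactly; ``zone`` and ``R`` are
    filled in by :func:`classify_zone` / :func:`resilience_scalar`.
    """

    s_in: pd.Series
    s_out: pd.Series
    mean_s: float
    S: float
    H: float
    beta_eff: float
    zone: str | None = None
    R: float | None = None
    timestamp: object | None = None


def weighted_degrees(web: FoodWeb) -> tuple[pd.Series, pd.Series]:
    """Per-species weighted degrees (s_in, s_out).

    ``s_in`` sums a species' consumption of its prey; ``s_out`` sums
    predation upon it.  Totals balance: every flow leaves one node and
    enters another.
    """
    mat = consumption_matrix(web)
    total = float(mat.to_numpy().sum())
    if total <= 0:
        raise DegenerateNetworkError("all flows are zero; weighted degrees undefined")
    s_in = mat.sum(axis=1).rename("s_in")  # predator rows: consumption of prey
    s_out = mat.sum(axis=0).rename("s_out")  # prey columns: predation pressure
    return s_in, s_out


def beta_eff(web: FoodWeb) -> ResilienceState:
    """Compute (<s>, S, H, beta_eff) for one snapshot; zone and R unset.

    ``<s>`` is total flow / N (the mean of s_in, which equals the mean of
    s_out by conservation).  When either marginal has zero spread the
    covariance is identically zero, so S*H is taken as 0 rather than
    evaluating the 0/0 ratio.
    """
    if web.n_species < 2:
        raise DegenerateNetworkError("beta_eff needs at least 2 species")
    s_in, s_out = weighted_degrees(web)
    a = s_in.to_numpy(dtype=float)
    b = s_out.to_numpy(dtype=float)
    mean_s = float(a.mean())
    cov = float((a * b).mean() - a.mean() * b.mean())
    sigma_in = float(a.std())  # population std: distributional moments
    sigma_out = float(b.std())
    if sigma_in * sigma_out > 0:
        S = cov / (sigma_in * sigma_out)
        H = sigma_in * sigma_out / mean_s
        beta = mean_s + cov / mean_s
    else:
        S, H = 0.0, 0.0
        beta = mean_s
    return ResilienceState(
        s_in=s_in,
        s_out=s_out,
        mean_s=mean_s,
        S=S,
        H=H,
        beta_eff=beta,
        timestamp=web.timestamp,
    )


def classify_zone(state: ResilienceState, thresholds: ResilienceThresholds) -> str:
    """Place a state in the resilience plane.

    Non-resilient when beta_eff has dropped below the frontier; fully
    resilient when both network density and heterogeneity clear their axis
    thresholds (and the frontier); partially resilient otherwise.
    """
    if state.beta_eff < thresholds.beta_crit:
        return "non_resilient"
    if state.mean_s > thresholds.s_crit and state.H > thresholds.h_crit:
        return "resilient"
    return "partially_resilient"


def resilience_scalar(zone: str, scheme: dict | None = None) -> float:
    """Scalar R for a zone under the given scheme (default 1.0/0.8/0.5)."""
    scheme = DEFAULT_SCHEME if scheme is None else scheme
    try:
        return float(scheme[zone])
    except KeyError:
        raise ConfigError(f"zone {zone!r} absent from scheme {scheme}") from None


def assess(web: FoodWeb, thresholds: ResilienceThresholds | None = None) -> ResilienceState:
    """beta_eff + zone + R in one call."""
    thresholds = thresholds or ResilienceThresholds()
    state = beta_eff(web)
    state.zone = classify_zone(state, thresholds)
    state.R = resilience_scalar(state.zone, thresholds.scheme)
    return state


def resilience_trajectory(
    series: WebSeries, thresholds: ResilienceThresholds | None = None
) -> list[ResilienceState]:
    """One classified state per snapshot, ordered in time.

    Per-snapshot failures are re-raised with the timestamp attached so a
    long series pinpoints its bad snapshot.
    """
    thresholds = thresholds or ResilienceThresholds()
    states = []
    for web in series:
        try:
            states.append(assess(web, thresholds))
        except DegenerateNetworkError as err:
            raise DegenerateNetworkError(
                f"snapshot {web.timestamp!r}: {err}"
            ) from err
    return states


def trajectory_frame(states: list[ResilienceState]) -> pd.DataFrame:
    """Tabular view of a trajectory for CSV output and plotting."""
    return pd.DataFrame(
        {
            "timestamp": [s.timestamp for s in states],
            "mean_s": [s.mean_s for s in states],
            "S": [s.S for s in states],
            "H": [s.H for s in states],
            "beta_eff": [s.beta_eff for s in states],
            "zone": [s.zone for s in states],
            "R": [s.R for s in states],
        }
    )
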