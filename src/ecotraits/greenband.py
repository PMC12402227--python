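"""Green Band: the acceptable envelope of catch given production.

An unfished ecosystem sustains a characteristic mortality profile that is
summarised by the log-log regression of biomass on production across its
species.  The fitted slope ``a`` defines, on a plot of catch Y against
production P, a band of exploitation rates aligned with that natural
profile::

    upper bound:  min(0.5 P, P^(1+a))
    lower bound:  min(0.5 P, delta * P^(1+a))

with ``delta`` a band-width scalar, typically about 0.01, optionally tied
to the regression's residual spread.  Species above the band are being
structurally overfished (rating Fail), species within it are harvested in
line with the natural system (Acceptable), and species below it have scope
for more exploitation (Light).  Tracking species against the band through
time gives an early warning: a species still inside the band whose distance
to the upper bound keeps shrinking is heading for trouble.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .foodweb import FoodWeb, WebSeries

log = logging.getLogger(__name__)

#: Band-width scalar used when delta_mode="fixed".
DEFAULT_DELTA = 0.01
#: status -> qualitative rating.
RATING_OF_STATUS = {"below": "Light", "within": "Acceptable", "above": "Fail"}


@dataclass(frozen=True)
class GreenBandModel:
    """Fitted unfished biomass-production profile.

    ``a`` is the slope of log10(biomass) on log10(production); ``delta``
    scales the lower bound of the band.  ``resid_sd`` is the population
    standard deviation of the regression residuals (log10 units); in
    ``variance`` mode delta is derived from it as ``10**(-k * resid_sd)``.
    """

    a: float
    intercept: float
    resid_sd: float
    delta: float = DEFAULT_DELTA
    delta_mode: str = "fixed"
    k: float = 2.0
    n_points: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValidationError(f"delta must lie in (0, 1), got {self.delta}")


def fit_unfished_profile(
    reference: FoodWeb,
    delta_mode: str = "fixed",
    k: float = 2.0,
) -> GreenBandModel:
    """OLS of log10(biomass) on log10(production) over the reference web.

    Species with non-positive biomass or production carry no information in
    log space; they are excluded with a logged warning.  At least 3 usable
    points are required.

    Parameters
    ----------
    delta_mode
        ``"fixed"`` uses delta = 0.01; ``"variance"`` derives the band
        width from the residual spread as ``10**(-k * resid_sd)``.
    """
    if delta_mode not in ("fixed", "variance"):
        raise ValidationError(f"delta_mode must be 'fixed' or 'variance', got {delta_mode!r}")
    usable = [sp for sp in reference.species if sp.biomass > 0 and sp.production > 0]
    dropped = [sp.id for sp in reference.species if sp not in usable]
    if dropped:
        log.warning(
            "green-band fit: excluding %d species with non-positive biomass "
            "or production: %s",
            len(dropped),
            dropped,
        )
    if len(usable) < 3:
        raise ValidationError(
            f"green-band fit needs >= 3 species with positive biomass and "
            f"production, got {len(usable)}"
        )
    log_p = np.log10([sp.production for sp in usable])
    log_b = np.log10([sp.biomass for sp in usable])
    if np.ptp(log_p) == 0:
        raise ValidationError("zero variance in log-production; slope undefined")
    fit = stats.linregress(log_p, log_b)
    resid = log_b - (fit.intercept + fit.slope * log_p)
    resid_sd = float(np.std(resid))
    if delta_mode == "fixed":
        delta = DEFAULT_DELTA
    else:
        delta = min(10.0 ** (-k * resid_sd), 1.0 - 1e-12)
        delta = max(delta, 1e-12)
    return GreenBandModel(
        a=float(fit.slope),
        intercept=float(fit.intercept),
        resid_sd=resid_sd,
        delta=delta,
        delta_mode=delta_mode,
        k=k,
        n_points=len(usable),
        source=str(reference.timestamp) if reference.timestamp is not None else "",
    )


def band_bounds(P, model: GreenBandModel):
    """(upper, lower) catch bounds at production P.

    upper = min(0.5 P, P^(1+a)), lower = min(0.5 P, delta P^(1+a));
    lower <= upper always since delta < 1.  Accepts scalars or arrays.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise ValidationError("band bounds require production > 0")
    envelope = P ** (1.0 + model.a)
    upper = np.minimum(0.5 * P, envelope)
    lower = np.minimum(0.5 * P, model.delta * envelope)
    if upper.ndim == 0:
        return float(upper), float(lower)
    return upper, lower


def classify_species(web: FoodWeb, model: GreenBandModel) -> pd.DataFrame:
    """Per-species Green Band status for one snapshot.

    Returns a frame indexed by species id with columns ``P`` (production),
    ``Y`` (catch), ``lower``, ``upper``, ``status`` (below/within/above,
    bounds inclusive), ``rating`` (Light/Acceptable/Fail) and ``distance``
    — the signed log10 distance past the nearest violated bound, positive
    above the band, negative below, 0 within.

    Zero-production species with positive catch are rated ``above`` by
    convention (any catch from a non-producing stock is distortive); species
    with neither production nor catch are excluded.  Both cases are logged.
    """
    rows = []
    for sp in web.species:
        if sp.production <= 0:
            if sp.catch > 0:
                log.warning(
                    "species %s has catch %.3g with no production; rated above",
                    sp.id,
                    sp.catch,
                )
                rows.append((sp.id, sp.production, sp.catch, np.nan, np.nan, "above"))
            else:
                log.warning("species %s has no production and no catch; excluded", sp.id)
            continue
        upper, lower = band_bounds(sp.production, model)
        if sp.catch > upper:
            status = "above"
        elif sp.catch < lower:
            status = "below"
        else:
            status = "within"
        rows.append((sp.id, sp.production, sp.catch, lower, upper, status))
    frame = pd.DataFrame(
        rows, columns=["id", "P", "Y", "lower", "upper", "status"]
    ).set_index("id")
    frame["rating"] = frame["status"].map(RATING_OF_STATUS)
    with np.errstate(divide="ignore"):
        above = np.log10(frame["Y"] / frame["upper"])
        below = np.log10(frame["Y"] / frame["lower"])
    frame["distance"] = np.where(
        frame["status"] == "above",
        above,
        np.where(frame["status"] == "below", below, 0.0),
    )
    # catch with zero production: infinitely far above any finite bound
    frame.loc[frame["upper"].isna(), "distance"] = np.inf
    return frame


def track_band(
    series: WebSeries, model: GreenBandModel, window: int = 3
) -> pd.DataFrame:
    """Status per species per snapshot, with an early-warning flag.

    ``warning`` is True at a snapshot when the species sits within the band
    and its log-distance to the upper bound has strictly decreased over the
    last ``window`` snapshots (``window`` values, ``window - 1`` decreases).
    """
    if window < 2:
        raise ValidationError(f"window must be >= 2, got {window}")
    if len(series) < 2:
        raise ValidationError("tracking needs at least 2 snapshots")
    if window > len(series):
        raise ValidationError(
            f"window {window} exceeds series length {len(series)}"
        )
    frames = []
    for web in series:
        frame = classify_species(web, model).reset_index()
        frame.insert(0, "timestamp", web.timestamp)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    # headroom below the upper bound, in log10 units; positive inside the band
    with np.errstate(divide="ignore"):
        out["headroom"] = np.log10(out["upper"] / out["Y"])
    out["warning"] = False
    for sp_id, group in out.groupby("id", sort=False):
        group = group.sort_values("timestamp")
        head = group["headroom"].to_numpy()
        within = (group["status"] == "within").to_numpy()
        for t in range(window - 1, len(group)):
            recent = head[t - window + 1 : t + 1]
            if within[t] and np.all(np.isfinite(recent)) and np.all(np.diff(recent) < 0):
                out.loc[group.index[t], "warning"] = True
    return out
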