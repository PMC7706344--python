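"""Crop growth rate between stem elongation (GS31) and anthesis (GS65).

CGR is the change in a trait (destructive AGB in t/ha, or a LiDAR biomass
index) divided by the number of days in the window, per plot. Because
genotypes reach anthesis on different calendar dates while scans happen on
common dates, trait values are linearly interpolated between sampling
events to each genotype's GS31/GS65 dates; a value is taken directly from a
sampling event when the date coincides. No extrapolation is performed:
plots whose event window does not bracket the phenology dates are excluded
with a logged reason.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .errors import DateRangeError, PhenologyError, ValidationError

__all__ = ["interpolate_trait", "compute_cgr", "cgr_table", "read_phenology"]

log = logging.getLogger(__name__)


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


def interpolate_trait(series, target_date) -> float:
    """Piecewise-linear interpolation of a (date, value) series.

    ``series`` is an iterable of (date, value) pairs (dates as ISO strings,
    ``date`` or ``Timestamp``). The target must lie within the sampled
    window — :class:`DateRangeError` otherwise — and an exact event date
    returns that event's value exactly.
    """
    pairs = sorted((_as_date(d), float(v)) for d, v in series)
    if len(pairs) < 2:
        raise ValidationError("interpolation needs at least 2 sampling events")
    dates = [p[0] for p in pairs]
    values = [p[1] for p in pairs]
    t = _as_date(target_date)
    if not (dates[0] <= t <= dates[-1]):
        raise DateRangeError(
            f"target {t.isoformat()} outside sampled window "
            f"[{dates[0].isoformat()}, {dates[-1].isoformat()}]"
        )
    days = np.array([(d - dates[0]).days for d in dates], dtype=float)
    return float(np.interp((t - dates[0]).days, days, values))


def compute_cgr(value_start, value_end, date_start, date_end) -> float:
    """Growth rate: (value_end − value_start) / days between the dates."""
    d0, d1 = _as_date(date_start), _as_date(date_end)
    n_days = (d1 - d0).days
    if n_days <= 0:
        raise ValidationError(f"non-positive duration: {d0} → {d1}")
    return (float(value_end) - float(value_start)) / n_days


def cgr_table(
    traits: pd.DataFrame,
    phenology: pd.DataFrame,
    trait: str,
) -> pd.DataFrame:
    """Per-plot CGR of one trait over each genotype's GS31→GS65 window.

    ``traits`` is a long table with columns plot_id, genotype, date, trait,
    value; ``phenology`` maps genotype → gs31, gs65 dates. Plots whose
    sampling events do not bracket the phenology window are excluded and
    logged. Missing phenology raises :class:`PhenologyError` naming every
    affected genotype.
    """
    sub = traits[traits["trait"] == trait]
    if sub.empty:
        raise ValidationError(f"no rows for trait {trait!r}")
    phen = phenology.set_index("genotype") if "genotype" in phenology.columns else phenology
    missing = set(sub["genotype"]) - set(phen.index)
    if missing:
        raise PhenologyError(missing)

    out = []
    for (plot_id, genotype), grp in sub.groupby(["plot_id", "genotype"], sort=True):
        series = list(zip(grp["date"], grp["value"]))
        g31 = _as_date(phen.loc[genotype, "gs31"])
        g65 = _as_date(phen.loc[genotype, "gs65"])
        try:
            v31 = interpolate_trait(series, g31)
            v65 = interpolate_trait(series, g65)
        except (DateRangeError, ValidationError) as exc:
            log.warning("excluding plot %s (%s): %s", plot_id, genotype, exc)
            continue
        out.append(
            {
                "plot_id": plot_id,
                "genotype": genotype,
                "value": compute_cgr(v31, v65, g31, g65),
                "n_days": (g65 - g31).days,
            }
        )
    return pd.DataFrame(out, columns=["plot_id", "genotype", "value", "n_days"])


def read_phenology(path) -> pd.DataFrame:
    """Read a genotype → (gs31, gs65) table, validating date order."""
    df = pd.read_csv(path, comment="#")
    for col in ("genotype", "gs31", "gs65"):
        if col not in df.columns:
            raise ValidationError(f"phenology table lacks column {col!r}")
    bad = [
        r.genotype
        for r in df.itertuples()
        if _as_date(r.gs31) >= _as_date(r.gs65)
    ]
    if bad:
        raise ValidationError(f"GS31 not before GS65 for: {', '.join(map(str, bad))}")
    return df
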