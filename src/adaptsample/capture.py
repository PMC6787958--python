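"""Capture-probability accounting and priority-weight updates.

The quantity tracked per species x site is ``p*`` (*p(capture)*): the
probability of at least one acoustic detection so far, given presence
(Otis et al. capture framework).  From an hourly vocalization probability
``p_v`` the per-minute detection probability is obtained by treating the
hour as a homogeneous availability process,

    p_min = 1 - (1 - p_v)**(1/60),

so that sampling all 60 minutes of an hour recovers ``p_v`` exactly and
within-hour effort matters.  A day's detection probability under a
schedule is the complement product over its 1-min samples, and ``p*``
accumulates across days as ``1 - (1 - p*)(1 - p*_d)`` — detections are
assumed independent across minutes, hours, and days.

Priority weights shrink linearly as a species approaches its capture
threshold ``p*_max`` (default 0.95): ``raw = w0 * max(0, 1 - p*/p*_max)``,
renormalized site-wise to sum to one; a species at or past threshold gets
weight zero, and a site where every species is satisfied is released (all
weights zero).

An optional relaxed mode supports thresholds above one, reinterpreting
the stop metric as the expected number of capture days, ``sum_d p*_d``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CaptureState",
    "per_minute_pv",
    "daily_capture_prob",
    "update_cumulative",
    "initial_weights",
    "update_weights",
]


@dataclass
class CaptureState:
    """Per species x site capture bookkeeping."""

    species_code: str
    site_id: str
    p_star: float = 0.0
    weight: float = 0.0
    p_star_max: float = 0.95
    achieved_date: dt.date | None = None

    @property
    def achieved(self) -> bool:
        return self.achieved_date is not None


def per_minute_pv(p_v):
    """Per-minute detection probability from an hourly p_v (vectorized).

    ``1 - (1 - p_v)**(1/60)``; lies in [0, p_v].
    """
    p_v = np.asarray(p_v, dtype=float)
    if (p_v < 0).any() or (p_v > 1).any():
        raise ValueError("p_v must lie in [0, 1]")
    return 1.0 - (1.0 - p_v) ** (1.0 / 60.0)


def daily_capture_prob(
    hour_counts, pv_hours, minute_scaling: bool = True
):
    """Probability of >= 1 detection in one day under a sampling schedule.

    Parameters
    ----------
    hour_counts
        Length-24 integer array: 1-min samples scheduled in each hour.
    pv_hours
        Hourly p_v for the species at this site-date; shape (..., 24)
        (leading axes broadcast, e.g. species x sites).
    minute_scaling
        If True (default), each sampled minute detects independently with
        :func:`per_minute_pv`; if False, any sampled hour contributes its
        full hourly p_v once, regardless of how many minutes it received.
    """
    counts = np.asarray(hour_counts)
    pv = np.asarray(pv_hours, dtype=float)
    if counts.shape[-1] != 24 or pv.shape[-1] != 24:
        raise ValueError("hour_counts and pv_hours must have trailing axis 24")
    if np.isnan(pv).any():
        raise ValueError("pv_hours contains missing values")
    if minute_scaling:
        # (1 - p_min)**m = (1 - p_v)**(m/60); exact collapse at m = 60.
        certain = pv >= 1.0
        log_miss = np.log1p(-np.where(certain, 0.0, pv)) * (counts / 60.0)
        miss = np.where(certain, (counts == 0).astype(float), np.exp(log_miss))
    else:
        miss = np.where(counts > 0, 1.0 - pv, 1.0)
    return 1.0 - np.prod(miss, axis=-1)


def update_cumulative(p_star_prev, p_star_d):
    """Fold one day's detection probability into cumulative p*."""
    prev = np.asarray(p_star_prev, dtype=float)
    day = np.asarray(p_star_d, dtype=float)
    for name, a in (("p_star_prev", prev), ("p_star_d", day)):
        if (a < 0).any() or (a > 1).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    return 1.0 - (1.0 - prev) * (1.0 - day)


def initial_weights(species: list[str]) -> dict[str, float]:
    """Equal initial priority weights, 1/K per species."""
    if not species:
        raise ValueError("species list must not be empty")
    if len(set(species)) != len(species):
        raise ValueError("species codes must be unique")
    w = 1.0 / len(species)
    return {s: w for s in species}


def update_weights(
    p_star, initial, p_star_max, metric=None
) -> np.ndarray:
    """Updated site-wise priority weights after a day of accounting.

    All arrays share the shape (K,) for one site (or (K, R) across sites;
    normalization is over axis 0).  ``metric`` defaults to ``p_star``; pass
    the expected-capture-days sum instead under the relaxed thresholds
    above one.

    raw_k = initial_k * max(0, 1 - metric_k / p_star_max_k), then
    site-wise renormalized to sum to 1; if every raw weight at a site is
    zero the site is released (all weights stay 0).
    """
    p_star = np.asarray(p_star, dtype=float)
    initial = np.asarray(initial, dtype=float)
    thr = np.asarray(p_star_max, dtype=float)
    m = p_star if metric is None else np.asarray(metric, dtype=float)
    if (initial < 0).any():
        raise ValueError("initial weights must be >= 0")
    raw = initial * np.clip(1.0 - m / thr, 0.0, None)
    total = raw.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, raw / np.where(total > 0, total, 1.0), 0.0)
    return out
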