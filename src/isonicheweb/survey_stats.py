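"""Benthic-survey reductions: point-intercept cover, rugosity, site contrasts.

A transect records the benthic component under each of its intercept points
(the line-point count design: one point every 10 cm along a 10-m line gives
100 points) and the length of a chain moulded over the reef surface between
the transect's endpoints. Percent cover is the share of points per
component; the rugosity index is chain length over linear length (1 = flat).
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import SurveyTransect
from .errors import InsufficientDataError

__all__ = [
    "percent_cover",
    "rugosity",
    "compare_sites",
    "cover_summary",
    "macroalgae_cover",
    "MACROALGAE_COMPONENTS",
    "CoverSummary",
    "SiteComparison",
]

#: Erect fleshy and calcareous algal groups counted as "macroalgae"
#: (algal turf is deliberately excluded from the aggregate).
MACROALGAE_COMPONENTS = frozenset(
    {
        "fleshy_brown",
        "fleshy_red",
        "fleshy_green",
        "calcareous_green",
        "calcareous_red",
    }
)


def percent_cover(
    transect: SurveyTransect, components: Sequence[str] | None = None
) -> dict[str, float]:
    """Percent of intercept points per benthic component.

    When ``components`` is given, those labels are always present in the
    output (0 when unobserved) and any label outside the list is aggregated
    under ``"other"``; otherwise observed labels are reported verbatim.
    """
    counts = Counter(transect.point_components)
    total = len(transect.point_components)
    if components is None:
        return {comp: 100.0 * c / total for comp, c in counts.items()}
    out = {comp: 100.0 * counts.get(comp, 0) / total for comp in components}
    other = sum(c for comp, c in counts.items() if comp not in components)
    out["other"] = 100.0 * other / total
    return out


def rugosity(transect: SurveyTransect) -> float:
    """Rugosity index: chain length / linear length (>= 1 by validation)."""
    return transect.chain_length / transect.linear_length


@dataclass(frozen=True)
class SiteComparison:
    mean_a: float
    ci_a: tuple[float, float]
    mean_b: float
    ci_b: tuple[float, float]
    t: float
    df: int
    p: float


def _mean_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    mean = float(values.mean())
    n = len(values)
    se = float(values.std(ddof=1)) / math.sqrt(n)
    half = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)) * se
    return mean, (mean - half, mean + half)


def compare_sites(
    values_a: Sequence[float], values_b: Sequence[float]
) -> SiteComparison:
    """Pooled-variance Student's t between two sites' per-transect values.

    Returns per-site mean ± 95% t-interval plus (t, df, p) with
    df = nA + nB − 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 transects per site")
    mean_a, ci_a = _mean_ci(a)
    mean_b, ci_b = _mean_ci(b)
    df = len(a) + len(b) - 2
    s2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = mean_a - mean_b
    if s2 == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / math.sqrt(s2 * (1.0 / len(a) + 1.0 / len(b)))
        p = 2.0 * float(stats.t.sf(abs(t), df=df))
    return SiteComparison(mean_a=mean_a, ci_a=ci_a, mean_b=mean_b, ci_b=ci_b, t=t, df=df, p=p)


@dataclass(frozen=True)
class CoverSummary:
    site: str
    component: str
    per_transect: tuple[float, ...]
    mean: float
    ci_low: float
    ci_high: float


def cover_summary(
    transects: Iterable[SurveyTransect], components: Sequence[str]
) -> list[CoverSummary]:
    """Per-site, per-component mean percent cover with 95% t-intervals."""
    by_site: dict[str, list[SurveyTransect]] = {}
    for t in transects:
        by_site.setdefault(t.site, []).append(t)
    labels = list(components) + ["other"]
    out: list[CoverSummary] = []
    for site, group in by_site.items():
        covers = [percent_cover(t, components) for t in group]
        for comp in labels:
            vals = np.asarray([c[comp] for c in covers])
            if len(vals) < 2:
                mean, ci = float(vals.mean()), (float(vals.mean()), float(vals.mean()))
            else:
                mean, ci = _mean_ci(vals)
            out.append(
                CoverSummary(
                    site=site,
                    component=comp,
                    per_transect=tuple(float(v) for v in vals),
                    mean=mean,
                    ci_low=ci[0],
                    ci_high=ci[1],
                )
            )
    return out


def macroalgae_cover(
    transect: SurveyTransect, macroalgae: frozenset[str] = MACROALGAE_COMPONENTS
) -> float:
    """Total percent cover of erect fleshy + calcareous macroalgae (turf excluded)."""
    cover = percent_cover(transect)
    return sum(v for comp, v in cover.items() if comp in macroalgae)
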