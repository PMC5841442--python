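"""Scaled (saturating) trophic-position estimation from δ15N.

Classical additive TP estimators assume a constant per-step δ15N enrichment.
Meta-analysis of paired diet–consumer measurements shows the enrichment
narrows as dietary δ15N rises, so consumer δ15N saturates toward a limit
δ15N_lim. With a linear discrimination model Δδ15N = β0 + β1·δ15N_diet
(β1 < 0), the saturating limit and the per-step approach rate are

    δ15N_lim = −β0 / β1
    k        = −log((β0 − δ15N_lim) / (−δ15N_lim))

and the trophic position of a consumer relative to a baseline organism of
known trophic level ``TP_base`` is

    TP = [log(δ15N_lim − δ15N_base) − log(δ15N_lim − δ15N_TP)] / k + TP_base.

The ratio structure makes TP invariant to the log base, provided ``k`` and
the TP equation use the same base; this package uses natural logs. The
defaults β0 = 5.924, β1 = −0.271 give δ15N_lim ≈ 21.86‰ and k ≈ 0.3161.

Cross-site comparison utilities (per-species Student's t tests and Pearson
correlations over shared taxa) live here too, since the headline question —
does food-chain length differ between a coral-dominated and a degraded
reef? — is answered with them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import IsotopeSample, Role
from .errors import (
    BaselineError,
    DomainError,
    InsufficientDataError,
    SaturationError,
)

__all__ = [
    "ScalingParams",
    "TrophicPositionEstimate",
    "delta_from_ratio",
    "ratio_from_delta",
    "scaling_constants",
    "trophic_position",
    "estimate_species_tp",
    "per_replicate_tp",
    "compare_species_between_sites",
    "cross_site_correlation",
]


def delta_from_ratio(r_sample: float, r_std: float) -> float:
    """δX in ‰ from raw isotope ratios: 1000·(R_sample − R_std)/R_std."""
    if np.any(np.asarray(r_std) <= 0):
        raise DomainError("standard ratio must be positive")
    return 1000.0 * (r_sample - r_std) / r_std


def ratio_from_delta(delta: float, r_std: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if np.any(np.asarray(r_std) <= 0):
        raise DomainError("standard ratio must be positive")
    return r_std * (1.0 + delta / 1000.0)


@dataclass(frozen=True)
class ScalingParams:
    """Constants of the scaled TP framework.

    ``beta0`` (‰) and ``beta1`` (‰ per ‰, < 0) describe how per-step
    enrichment declines with dietary δ15N; ``d15n_lim`` and ``k`` are derived.
    """

    beta0: float
    beta1: float
    tp_base: float
    d15n_lim: float
    k: float


def scaling_constants(
    beta0: float = 5.924, beta1: float = -0.271, tp_base: float = 2.0
) -> ScalingParams:
    """Derive δ15N_lim = −β0/β1 and k = −ln((β0 − lim)/(−lim)).

    Raises :class:`DomainError` for β1 ≥ 0 (no saturating limit) and for the
    degenerate boundary β0 = δ15N_lim (k would need log 0).
    """
    if beta1 >= 0:
        raise DomainError("beta1 must be negative: the enrichment must narrow with d15N")
    d15n_lim = -beta0 / beta1
    ratio = (beta0 - d15n_lim) / (-d15n_lim)
    if ratio <= 0:
        raise DomainError(
            f"degenerate scaling: (beta0 - lim)/(-lim) = {ratio} is not positive"
        )
    k = -math.log(ratio)
    if k <= 0:
        raise DomainError(f"derived approach rate k = {k} is not positive")
    return ScalingParams(beta0=beta0, beta1=beta1, tp_base=tp_base, d15n_lim=d15n_lim, k=k)


DEFAULT_SCALING = scaling_constants()


def trophic_position(
    d15n_consumer: float | np.ndarray,
    d15n_base: float,
    params: ScalingParams = DEFAULT_SCALING,
) -> float | np.ndarray:
    """Scaled trophic position of a consumer δ15N against a baseline δ15N.

    Both values must lie strictly below the saturating limit; at or above it
    the framework is undefined and :class:`SaturationError` is raised.
    Accepts scalars or arrays for ``d15n_consumer``.
    """
    lim = params.d15n_lim
    consumer = np.asarray(d15n_consumer, dtype=float)
    if np.any(consumer >= lim) or d15n_base >= lim:
        raise SaturationError(
            f"d15N at or above the saturating limit {lim:.4f}‰: TP undefined"
        )
    tp = (np.log(lim - d15n_base) - np.log(lim - consumer)) / params.k + params.tp_base
    if np.ndim(d15n_consumer) == 0:
        return float(tp)
    return tp


@dataclass(frozen=True)
class TrophicPositionEstimate:
    taxon: str
    site: str
    tp_mean: float
    ci_low: float
    ci_high: float
    n: int
    d15n_base_used: float

    def __post_init__(self) -> None:
        if self.tp_mean < 1:
            raise DomainError(f"{self.taxon!r}: TP {self.tp_mean} below 1")
        if not self.ci_low <= self.ci_high:
            raise DomainError(f"{self.taxon!r}: CI bounds out of order")


def _t_interval(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    n = len(values)
    mean = float(values.mean())
    if n < 2:
        return (mean, mean)
    se = float(values.std(ddof=1)) / math.sqrt(n)
    half = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1) * se
    return (mean - half, mean + half)


def _baseline_d15n(
    samples: Sequence[IsotopeSample], baseline_taxon: str, site: str
) -> float:
    vals = [
        s.d15N
        for s in samples
        if s.site == site and s.taxon == baseline_taxon and s.role is Role.CONSUMER
    ]
    if not vals:
        raise BaselineError(f"baseline taxon {baseline_taxon!r} has no replicates at {site!r}")
    return float(np.mean(vals))


def per_replicate_tp(
    samples: Sequence[IsotopeSample],
    baseline_taxon: str,
    site: str,
    params: ScalingParams = DEFAULT_SCALING,
) -> pd.DataFrame:
    """Per-replicate TPs of all consumers at one site (columns taxon, site, tp)."""
    base = _baseline_d15n(samples, baseline_taxon, site)
    rows = [
        (s.taxon, site, trophic_position(s.d15N, base, params))
        for s in samples
        if s.site == site and s.role is Role.CONSUMER
    ]
    return pd.DataFrame(rows, columns=["taxon", "site", "tp"])


def estimate_species_tp(
    samples: Sequence[IsotopeSample],
    baseline_taxon: str,
    site: str,
    params: ScalingParams = DEFAULT_SCALING,
) -> list[TrophicPositionEstimate]:
    """Per-taxon TP estimates at one site.

    The baseline δ15N is the mean over the baseline taxon's replicates at
    this site. Each other taxon's TP is computed per replicate and
    summarized as mean with a 95% t-interval. The baseline taxon itself is
    anchored by construction: its TP_mean is TP_base exactly (evaluated at
    the baseline mean), with a CI from its per-replicate spread.
    """
    base = _baseline_d15n(samples, baseline_taxon, site)
    groups: dict[str, list[float]] = {}
    for s in samples:
        if s.site == site and s.role is Role.CONSUMER:
            groups.setdefault(s.taxon, []).append(s.d15N)
    estimates = []
    for taxon, d15n in groups.items():
        tps = np.asarray([trophic_position(v, base, params) for v in d15n])
        ci = _t_interval(tps)
        mean = params.tp_base if taxon == baseline_taxon else float(tps.mean())
        estimates.append(
            TrophicPositionEstimate(
                taxon=taxon,
                site=site,
                tp_mean=mean,
                ci_low=min(ci[0], mean),
                ci_high=max(ci[1], mean),
                n=len(d15n),
                d15n_base_used=base,
            )
        )
    return estimates


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sample pooled-variance Student's t; degenerate zero-variance cases
    resolve to t = 0, p = 1 (equal means) or t = ±inf, p = 0 (shifted means)."""
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = float(a.mean() - b.mean())
    if s2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df=df))
    return t, df, p


def compare_species_between_sites(
    samples: Sequence[IsotopeSample],
    metric: Literal["TP", "d13C", "d15N"],
    sites: tuple[str, str] | None = None,
    baseline_taxon: str | None = None,
    params: ScalingParams = DEFAULT_SCALING,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-taxon two-sample pooled t tests between the two sites.

    ``metric`` selects per-replicate TP (needs ``baseline_taxon``), δ13C, or
    δ15N. Taxa present at only one site, or with fewer than 2 replicates at
    either site, are excluded and reported in the returned warning list.
    Returns (table, warnings); table columns: taxon, mean_a, mean_b, t, df,
    p, significant (at ``alpha``, uncorrected).
    """
    all_sites = list(dict.fromkeys(s.site for s in samples))
    if sites is None:
        if len(all_sites) != 2:
            raise InsufficientDataError(
                f"expected exactly 2 sites, found {all_sites}; pass sites= explicitly"
            )
        sites = (all_sites[0], all_sites[1])
    site_a, site_b = sites

    if metric == "TP":
        if baseline_taxon is None:
            raise DomainError("metric 'TP' requires baseline_taxon")
        frames = [
            per_replicate_tp(samples, baseline_taxon, site, params)
            .rename(columns={"tp": "value"})
            for site in sites
        ]
        values = pd.concat(frames, ignore_index=True)
    else:
        col = {"d13C": "d13C", "d15N": "d15N"}[metric]
        rows = [
            (s.taxon, s.site, getattr(s, col))
            for s in samples
            if s.role is Role.CONSUMER and s.site in sites
        ]
        values = pd.DataFrame(rows, columns=["taxon", "site", "value"])

    warnings: list[str] = []
    records = []
    for taxon in values["taxon"].unique():
        a = values.query("taxon == @taxon and site == @site_a")["value"].to_numpy(float)
        b = values.query("taxon == @taxon and site == @site_b")["value"].to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            warnings.append(f"{taxon}: present at only one site; excluded")
            continue
        if len(a) < 2 or len(b) < 2:
            warnings.append(f"{taxon}: fewer than 2 replicates at a site; excluded")
            continue
        t, df, p = _pooled_t(a, b)
        records.append((taxon, float(a.mean()), float(b.mean()), t, df, p, p < alpha))
    table = pd.DataFrame(
        records, columns=["taxon", "mean_a", "mean_b", "t", "df", "p", "significant"]
    )
    return table, warnings


def cross_site_correlation(
    values_a: Sequence[float], values_b: Sequence[float]
) -> float:
    """Pearson r over taxa present at both sites (paired by position)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("paired value vectors must have equal length")
    if len(a) < 3:
        raise InsufficientDataError("need >= 3 paired taxa for a correlation")
    if a.std() == 0 or b.std() == 0:
        raise DomainError("zero variance on one axis: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def paired_taxon_values(
    estimates_a: Iterable[TrophicPositionEstimate],
    estimates_b: Iterable[TrophicPositionEstimate],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align two per-site estimate collections on shared taxa."""
    by_a = {e.taxon: e.tp_mean for e in estimates_a}
    by_b = {e.taxon: e.tp_mean for e in estimates_b}
    shared = [t for t in by_a if t in by_b]
    return (
        np.asarray([by_a[t] for t in shared]),
        np.asarray([by_b[t] for t in shared]),
        shared,
    )
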