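"""Domain types and tabular I/O for two-site stable-isotope food-web studies.

The study design this package serves: basal carbon sources (algae, epiphytes,
particulate organic matter) and a shared set of consumer species are sampled
at two sites, each specimen measured for δ13C (vs VPDB) and δ15N (vs
atmospheric N2), both in per mil (‰). Consumers carry a literature-derived
trophic category (herbivore / omnivore / carnivore); sources do not. Benthic
condition at each site is recorded with point-intercept transects and
chain-rugosity measurements.

CSV schemas
-----------
Samples:    ``sample_id,site,taxon,role,trophic_category,d13C,d15N``
            (isotopes serialized with 4 decimal places; round-trip lossless
            at that precision).
Transects:  a points file ``site,transect_id,point_index,component`` plus a
            chains file ``site,transect_id,chain_length,linear_length``.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParseError,
    SchemaError,
    ValidationError,
)

SAMPLE_COLUMNS = ("sample_id", "site", "taxon", "role", "trophic_category", "d13C", "d15N")
ISOTOPE_DECIMALS = 4


class Role(str, enum.Enum):
    SOURCE = "source"
    CONSUMER = "consumer"


class TrophicCategory(str, enum.Enum):
    HERBIVORE = "herbivore"
    OMNIVORE = "omnivore"
    CARNIVORE = "carnivore"
    NONE = "none"


CONSUMER_CATEGORIES = (
    TrophicCategory.HERBIVORE,
    TrophicCategory.OMNIVORE,
    TrophicCategory.CARNIVORE,
)


@dataclass(frozen=True)
class IsotopeSample:
    """One measured specimen.

    ``trophic_category`` is ``none`` exactly when ``role`` is ``source``;
    (site, taxon) pairs identify replicate groups.
    """

    sample_id: str
    site: str
    taxon: str
    role: Role
    trophic_category: TrophicCategory
    d13C: float
    d15N: float

    def __post_init__(self) -> None:
        role = Role(self.role)
        cat = TrophicCategory(self.trophic_category)
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "trophic_category", cat)
        if not (math.isfinite(self.d13C) and math.isfinite(self.d15N)):
            raise ValidationError(
                f"sample {self.sample_id!r}: non-finite isotope value "
                f"(d13C={self.d13C}, d15N={self.d15N})"
            )
        if (role is Role.SOURCE) != (cat is TrophicCategory.NONE):
            raise ValidationError(
                f"sample {self.sample_id!r}: trophic_category must be 'none' "
                f"iff role is 'source' (got role={role.value}, "
                f"category={cat.value})"
            )


@dataclass(frozen=True)
class TrophicEnrichmentFactor:
    """Mean ± SD isotopic shift per trophic step, per isotope, in ‰."""

    mean_c: float
    sd_c: float
    mean_n: float
    sd_n: float

    def __post_init__(self) -> None:
        if self.sd_c < 0 or self.sd_n < 0:
            raise ValidationError("TEF SDs must be >= 0")


#: Post's (2002) widely used discrimination factors: δ13C 0.40 ± 1.30‰,
#: δ15N 3.40 ± 1.00‰ per trophic step.
POST_TEF = TrophicEnrichmentFactor(mean_c=0.40, sd_c=1.30, mean_n=3.40, sd_n=1.00)


@dataclass(frozen=True)
class SourceSpec:
    """A basal carbon source summarized as per-isotope mean and SD (‰).

    SDs follow the sample convention (n−1 denominator). ``n`` records how
    many samples were pooled, when known.
    """

    name: str
    mean_c: float
    sd_c: float
    mean_n: float
    sd_n: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sd_c < 0 or self.sd_n < 0:
            raise ValidationError(f"source {self.name!r}: SDs must be >= 0")


@dataclass(frozen=True)
class SurveyTransect:
    """One benthic transect: point-intercept components plus chain/linear lengths (m)."""

    site: str
    transect_id: str
    point_components: tuple[str, ...]
    chain_length: float
    linear_length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "point_components", tuple(self.point_components))
        if len(self.point_components) == 0:
            raise ValidationError(f"transect {self.transect_id!r}: no intercept points")
        if not (self.chain_length >= self.linear_length > 0):
            raise ValidationError(
                f"transect {self.transect_id!r}: need chain_length >= linear_length > 0 "
                f"(got chain={self.chain_length}, linear={self.linear_length})"
            )


@dataclass
class StudyDataset:
    """A full two-site study: samples, transects, baseline anchor, category map."""

    samples: list[IsotopeSample]
    transects: list[SurveyTransect] = field(default_factory=list)
    baseline_taxon: str = ""
    category_map: dict[str, TrophicCategory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.site, None)
        return list(seen)

    def validate(self) -> None:
        if self.baseline_taxon:
            for site in self.sites():
                if not any(
                    s.taxon == self.baseline_taxon and s.role is Role.CONSUMER and s.site == site
                    for s in self.samples
                ):
                    raise ValidationError(
                        f"baseline taxon {self.baseline_taxon!r} absent among consumers "
                        f"at site {site!r}"
                    )
        if self.category_map:
            for s in self.samples:
                if s.role is Role.CONSUMER and s.taxon not in self.category_map:
                    raise ValidationError(f"consumer taxon {s.taxon!r} has no trophic category")


# ---------------------------------------------------------------------------
# Tabular I/O


def samples_to_frame(samples: Iterable[IsotopeSample]) -> pd.DataFrame:
    rows = [
        (s.sample_id, s.site, s.taxon, s.role.value, s.trophic_category.value, s.d13C, s.d15N)
        for s in samples
    ]
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def read_samples(path: str | Path) -> list[IsotopeSample]:
    """Read a sample CSV, validating every row.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ParseError` with the row index for non-numeric isotope values.
    Row order is preserved.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    samples: list[IsotopeSample] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        values = {}
        for col in ("d13C", "d15N"):
            raw = getattr(row, col)
            try:
                values[col] = float(raw)
            except ValueError:
                raise ParseError(f"{path}: row {i}: non-numeric {col} value {raw!r}") from None
        samples.append(
            IsotopeSample(
                sample_id=row.sample_id,
                site=row.site,
                taxon=row.taxon,
                role=Role(row.role),
                trophic_category=TrophicCategory(row.trophic_category),
                d13C=values["d13C"],
                d15N=values["d15N"],
            )
        )
    return samples


def write_samples(samples: Iterable[IsotopeSample], path: str | Path) -> None:
    """Write samples as CSV in the documented column order.

    Isotope values are serialized with 4 decimal places, so write → read →
    write is byte-stable and read-back is lossless at that precision.
    """
    frame = samples_to_frame(samples)
    fmt = f"%.{ISOTOPE_DECIMALS}f"
    frame["d13C"] = frame["d13C"].map(lambda v: fmt % v)
    frame["d15N"] = frame["d15N"].map(lambda v: fmt % v)
    frame.to_csv(path, index=False)


def read_transects(points_path: str | Path, chains_path: str | Path) -> list[SurveyTransect]:
    """Assemble transects from a points file and a chains file (schemas above)."""
    pts = pd.read_csv(points_path, dtype=str, keep_default_na=False)
    for col in ("site", "transect_id", "point_index", "component"):
        if col not in pts.columns:
            raise SchemaError(f"{points_path}: missing required column(s): {col}")
    chains = pd.read_csv(chains_path)
    for col in ("site", "transect_id", "chain_length", "linear_length"):
        if col not in chains.columns:
            raise SchemaError(f"{chains_path}: missing required column(s): {col}")
    pts["point_index"] = pts["point_index"].astype(int)
    transects: list[SurveyTransect] = []
    chain_lookup = {
        (str(r.site), str(r.transect_id)): (float(r.chain_length), float(r.linear_length))
        for r in chains.itertuples(index=False)
    }
    for (site, tid), group in pts.groupby(["site", "transect_id"], sort=False):
        if (site, tid) not in chain_lookup:
            raise ValidationError(f"transect {tid!r} at {site!r}: no chain record")
        chain, linear = chain_lookup[(site, tid)]
        comps = tuple(group.sort_values("point_index")["component"])
        transects.append(
            SurveyTransect(
                site=site, transect_id=tid, point_components=comps,
                chain_length=chain, linear_length=linear,
            )
        )
    return transects


def write_transects(
    transects: Iterable[SurveyTransect], points_path: str | Path, chains_path: str | Path
) -> None:
    point_rows = []
    chain_rows = []
    for t in transects:
        chain_rows.append((t.site, t.transect_id, t.chain_length, t.linear_length))
        for i, comp in enumerate(t.point_components):
            point_rows.append((t.site, t.transect_id, i, comp))
    pd.DataFrame(point_rows, columns=["site", "transect_id", "point_index", "component"]).to_csv(
        points_path, index=False
    )
    pd.DataFrame(
        chain_rows, columns=["site", "transect_id", "chain_length", "linear_length"]
    ).to_csv(chains_path, index=False)


# ---------------------------------------------------------------------------
# Source pooling


def pool_sources(
    samples: Iterable[IsotopeSample],
    grouping: Mapping[str, str],
    sd_override: Mapping[str, tuple[float, float]] | None = None,
) -> list[SourceSpec]:
    """Pool source samples into labelled source groups.

    ``grouping`` maps taxon → pooled-source label (e.g. both ``turf`` and
    ``epiphytes`` → ``"turf+epiphytes"``). Means and SDs are computed over
    all member samples pooled together — not as means of per-taxon means —
    with the sample (n−1) SD convention. A group with fewer than 2 samples
    has no defined SD and raises unless ``sd_override[label]`` supplies
    ``(sd_c, sd_n)``.
    """
    sd_override = sd_override or {}
    members: dict[str, list[IsotopeSample]] = {}
    for s in samples:
        if s.taxon in grouping:
            if s.role is not Role.SOURCE:
                raise ValidationError(
                    f"taxon {s.taxon!r} is grouped as a source but sample "
                    f"{s.sample_id!r} has role {s.role.value!r}"
                )
            members.setdefault(grouping[s.taxon], []).append(s)
    specs: list[SourceSpec] = []
    for label, group in members.items():
        c = np.array([s.d13C for s in group], dtype=float)
        n15 = np.array([s.d15N for s in group], dtype=float)
        if len(group) < 2:
            if label not in sd_override:
                raise InsufficientDataError(
                    f"source group {label!r} has {len(group)} sample(s): SD undefined "
                    "(supply an explicit sd_override)"
                )
            sd_c, sd_n = sd_override[label]
        else:
            sd_c = float(np.std(c, ddof=1))
            sd_n = float(np.std(n15, ddof=1))
        specs.append(
            SourceSpec(
                name=label,
                mean_c=float(c.mean()),
                sd_c=sd_c,
                mean_n=float(n15.mean()),
                sd_n=sd_n,
                n=len(group),
            )
        )
    return specs
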