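"""Citation statistics, property/flavor profiling, and dose summaries.

Implements the ethnobotanical frequency-of-citation index (FC, the number of
prescriptions containing a material; RFC = FC / N with N the total number of
prescriptions), the RFC >= 0.1 frequent-material filter, categorical
breakdowns of the catalog metadata (TCM property, flavor, flavor-property
pairs, traditional effect, family, plant part), and per-material dose
summaries (mean, sample SD, quartiles) behind the survey's box plots.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .io_model import (
    Dataset,
    FLAVOR_ENUM,
    MaterialRecord,
    PROPERTY_BUCKETS,
    TransactionSet,
)

BREAKDOWN_KEYS = ("property", "flavor", "flavor_property", "effect", "family", "part")


@dataclass(frozen=True)
class MaterialFrequency:
    material_id: str
    fc: int
    rfc: float       # exact FC / N
    rfc_2dp: float   # rounded to 2 decimals, as printed in survey tables


@dataclass(frozen=True)
class DoseSummary:
    """Five-number summary plus mean/SD of a material's daily doses (g)."""

    n: int
    mean: float
    sd: float
    min: float
    q1: float
    q2: float
    q3: float
    max: float
    sd_undefined: bool = False  # True when n == 1 (sd reported as 0)


@dataclass(frozen=True)
class Breakdown:
    key: str
    count: int
    percent: int
    denominator: int


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# property / flavor parsing

_INTENSITY = re.compile(r"^(mild|mildly|slightly|highly|very)\s+", re.IGNORECASE)


def _strip_intensity(token: str) -> str:
    return _INTENSITY.sub("", token.strip())


def bucket_property(property_raw: str) -> str:
    """Map a raw property/flavor string to one of the five property buckets.

    The property phrase precedes the first ";". Intensity prefixes collapse
    into the base bucket: "Mild warm" -> warm, "Highly hot" -> hot,
    "Mild cold" -> cold.
    """
    head = property_raw.split(";", 1)[0]
    token = _strip_intensity(head).strip().strip(".").lower()
    if token not in PROPERTY_BUCKETS:
        raise ParseError(f"unrecognized property phrase {head.strip()!r}")
    return token


def parse_flavors(property_raw: str) -> frozenset[str]:
    """Extract the set of flavors from a raw property/flavor string.

    The flavor phrase follows the first ";". Flavors are separated by commas
    and/or "and"; intensity prefixes are dropped ("mild bitter" -> bitter).
    """
    parts = property_raw.split(";", 1)
    if len(parts) < 2 or not parts[1].strip():
        raise ParseError(f"no flavor phrase in {property_raw!r}")
    tail = parts[1].strip().rstrip(".")
    tokens = re.split(r",|\band\b", tail)
    flavors = set()
    for tok in tokens:
        tok = _strip_intensity(tok).strip().lower()
        if not tok:
            continue
        if tok not in FLAVOR_ENUM:
            raise ParseError(f"unrecognized flavor token {tok!r} in {property_raw!r}")
        flavors.add(tok)
    if not flavors:
        raise ParseError(f"empty flavor list in {property_raw!r}")
    return frozenset(flavors)


# ---------------------------------------------------------------------------
# citation frequencies

def citation_frequencies(ts: TransactionSet) -> list[MaterialFrequency]:
    """FC and RFC for every item of the universe.

    Counting is presence-based: a material counts once per prescription that
    contains it, so RFC is always in [0, 1]. Output is sorted by FC
    descending, ties by material id.
    """
    if ts.N == 0:
        raise ValidationError("RFC undefined for an empty transaction set (N = 0)")
    counts = {item: 0 for item in ts.universe}
    for t in ts.transactions:
        for item in t:
            counts[item] += 1
    freqs = [
        MaterialFrequency(
            material_id=item,
            fc=c,
            rfc=c / ts.N,
            rfc_2dp=round(c / ts.N, 2),
        )
        for item, c in counts.items()
    ]
    freqs.sort(key=lambda f: (-f.fc, f.material_id))
    return freqs


def select_frequent(
    freqs: Iterable[MaterialFrequency], threshold: float = 0.1
) -> list[MaterialFrequency]:
    """Keep materials with RFC >= threshold (inclusive, on the exact RFC)."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return [f for f in freqs if f.rfc >= threshold]


# ---------------------------------------------------------------------------
# categorical breakdowns

def _effect_dedup(materials: Sequence[MaterialRecord]) -> list[MaterialRecord]:
    """Drop later records sharing a scientific name (species-level dedup)."""
    seen: set[str] = set()
    out = []
    for m in materials:
        key = m.scientific_name or m.material_id
        if key in seen:
            continue
        seen.add(key)
        out.append(m)
    return out


def breakdowns(
    materials: Sequence[MaterialRecord],
    key: str,
    dedup_species: bool = False,
) -> list[Breakdown]:
    """Categorical composition of a material list.

    The denominator is the number of materials passed in. A material
    contributes once to *each* flavor it carries, so flavor percentages may
    sum above 100; ``flavor_property`` counts a material under every
    (flavor, property) pair. Percentages are rounded to the nearest integer,
    ties away from zero.

    ``dedup_species`` counts records sharing a scientific name once per
    category (the denominator is unchanged); relevant when a catalog lists
    two trade forms of one species.
    """
    if key not in BREAKDOWN_KEYS:
        raise ValueError(f"key must be one of {BREAKDOWN_KEYS}, got {key!r}")
    if not materials:
        raise ValidationError("breakdowns over an empty material list")
    denominator = len(materials)
    pool = _effect_dedup(materials) if dedup_species else list(materials)

    counts: dict[str, int] = {}

    def _add(label: str) -> None:
        counts[label] = counts.get(label, 0) + 1

    for m in pool:
        if key == "property":
            if m.property_bucket:
                _add(m.property_bucket)
        elif key == "flavor":
            for fl in m.flavors:
                _add(fl)
        elif key == "flavor_property":
            if m.property_bucket:
                for fl in m.flavors:
                    _add(f"{fl}-{m.property_bucket}")
        elif key == "effect":
            if m.effect_category:
                _add(m.effect_category)
        elif key == "family":
            if m.family:
                _add(m.family)
        elif key == "part":
            if m.part_used:
                _add(m.part_used)

    out = [
        Breakdown(
            key=label,
            count=c,
            percent=_round_half_away(100.0 * c / denominator),
            denominator=denominator,
        )
        for label, c in counts.items()
    ]
    out.sort(key=lambda b: (-b.count, b.key))
    return out


# ---------------------------------------------------------------------------
# dose summaries

def dose_summary(dataset: Dataset, material_id: str) -> DoseSummary:
    """Mean, sample SD (n-1 denominator) and quartiles of a material's doses.

    Quartiles use linear interpolation between order statistics (the
    convention of standard box plots). A single observation yields a
    degenerate summary with sd reported as 0 and ``sd_undefined=True``.
    """
    doses = [
        dose
        for p in dataset.prescriptions
        for m, dose in p.items
        if m == material_id
    ]
    if not doses:
        raise ValidationError(f"material {material_id!r} has no dosed occurrences")
    arr = np.asarray(doses, dtype=float)
    n = arr.size
    q1, q2, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    if n == 1:
        sd, undef = 0.0, True
    else:
        sd, undef = float(np.std(arr, ddof=1)), False
    return DoseSummary(
        n=n,
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(arr.min()),
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        max=float(arr.max()),
        sd_undefined=undef,
    )


def dose_summaries(dataset: Dataset) -> dict[str, DoseSummary]:
    """Dose summary for every material occurring in the prescriptions."""
    used = sorted({m for p in dataset.prescriptions for m, _ in p.items})
    return {mid: dose_summary(dataset, mid) for mid in used}
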