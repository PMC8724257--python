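"""Data model and delimited-text I/O for material catalogs and prescriptions.

The catalog mirrors the survey's material table: one row per medicinal
material with its pharmacopeia metadata (TCM property/flavor string,
traditional-effect category, daily-dose range in grams, pharmacology tags).
Prescriptions are stored long-format: one row per (prescription, material)
with the daily dose in grams. All files are comma-separated UTF-8 with a
header row; semicolons separate values *within* a multi-valued cell, which
matches the pharmacopeia's own punctuation ("Warm; sweet and pungent").
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical five-way TCM property (nature) classification.
PROPERTY_BUCKETS = ("cold", "cool", "neutral", "warm", "hot")
#: Canonical five-way TCM flavor classification.
FLAVOR_ENUM = ("sweet", "pungent", "bitter", "sour", "bland")

CATALOG_COLUMNS = [
    "material_id", "scientific_name", "family", "local_name", "part_used",
    "property_raw", "effect_category", "dose_min_g", "dose_max_g",
    "pharm_tags", "rfc_printed",
]
PRESCRIPTION_COLUMNS = [
    "prescription_id", "pharmacy_id", "region", "material_id", "dose_g",
]


@dataclass(frozen=True)
class MaterialRecord:
    """One catalog entry for a medicinal material.

    ``property_bucket`` and ``flavors`` are derived from ``property_raw``
    at load time; ``flagged`` marks records whose property string could not
    be parsed in lenient mode.
    """

    material_id: str
    scientific_name: str = ""
    family: str = ""
    local_name: str = ""
    part_used: str = ""
    property_raw: str = ""
    property_bucket: str | None = None
    flavors: frozenset[str] = frozenset()
    effect_category: str = ""
    dose_min_g: float | None = None
    dose_max_g: float | None = None
    pharm_tags: frozenset[str] = frozenset()
    rfc_printed: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.property_bucket is not None and self.property_bucket not in PROPERTY_BUCKETS:
            raise ValidationError(
                f"{self.material_id}: property_bucket {self.property_bucket!r} "
                f"not one of {PROPERTY_BUCKETS}"
            )
        if self.dose_min_g is not None and self.dose_max_g is not None:
            if not (0 < self.dose_min_g <= self.dose_max_g):
                raise ValidationError(
                    f"{self.material_id}: dose range must satisfy "
                    f"0 < min <= max, got [{self.dose_min_g}, {self.dose_max_g}]"
                )


@dataclass(frozen=True)
class Prescription:
    """A prescription: a set of materials with daily doses in grams."""

    prescription_id: str
    pharmacy_id: str = ""
    region_code: str = ""
    items: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.items]
        if len(ids) != len(set(ids)):
            raise ValidationError(
                f"{self.prescription_id}: duplicate material within prescription"
            )
        for m, dose in self.items:
            if dose <= 0:
                raise ValidationError(
                    f"{self.prescription_id}: dose for {m} must be > 0, got {dose}"
                )

    @property
    def material_ids(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.items)


@dataclass(frozen=True)
class Dataset:
    """A catalog plus the prescriptions that reference it."""

    catalog: tuple[MaterialRecord, ...]
    prescriptions: tuple[Prescription, ...]

    @property
    def N(self) -> int:
        return len(self.prescriptions)

    def validate(self, strict: bool = True) -> None:
        known = {m.material_id for m in self.catalog}
        for p in self.prescriptions:
            unknown = p.material_ids - known
            if unknown and strict:
                raise ValidationError(
                    f"{p.prescription_id}: unknown material id(s) {sorted(unknown)}"
                )


@dataclass(frozen=True)
class TransactionSet:
    """Binary incidence view: each prescription reduced to its item set."""

    universe: tuple[str, ...]
    transactions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for i, t in enumerate(self.transactions):
            if not t <= uni:
                raise ValidationError(
                    f"transaction {i} contains items outside the universe: "
                    f"{sorted(t - uni)}"
                )

    @property
    def N(self) -> int:
        return len(self.transactions)


# ---------------------------------------------------------------------------
# readers


def _parse_multivalue(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return frozenset()
    return frozenset(s.strip() for s in str(cell).split(";") if s.strip())


def load_catalog(path: str | Path, strict: bool = True) -> tuple[MaterialRecord, ...]:
    """Read a material catalog from a delimited UTF-8 file.

    Derives ``property_bucket`` and ``flavors`` from the raw property/flavor
    string. In strict mode an unparseable property string raises
    :class:`ParseError`; in lenient mode the record is kept with the derived
    fields unset and ``flagged=True``.
    """
    from .descriptive_stats import bucket_property, parse_flavors

    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = {"material_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"catalog missing required column(s): {sorted(missing)}")

    seen: set[str] = set()
    records: list[MaterialRecord] = []
    for _, row in df.iterrows():
        mid = str(row["material_id"]).strip()
        if mid in seen:
            raise ValidationError(f"duplicate material_id {mid!r} in catalog")
        seen.add(mid)

        raw = row.get("property_raw")
        raw = "" if pd.isna(raw) else str(raw)
        bucket: str | None = None
        flavors: frozenset[str] = frozenset()
        flagged = False
        if raw:
            try:
                bucket = bucket_property(raw)
                flavors = parse_flavors(raw)
            except ParseError:
                if strict:
                    raise
                flagged = True

        def _num(col: str) -> float | None:
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        records.append(MaterialRecord(
            material_id=mid,
            scientific_name=str(row.get("scientific_name", "") or ""),
            family=str(row.get("family", "") or ""),
            local_name=str(row.get("local_name", "") or ""),
            part_used=str(row.get("part_used", "") or ""),
            property_raw=raw,
            property_bucket=bucket,
            flavors=flavors,
            effect_category=str(row.get("effect_category", "") or ""),
            dose_min_g=_num("dose_min_g"),
            dose_max_g=_num("dose_max_g"),
            pharm_tags=_parse_multivalue(row.get("pharm_tags")),
            rfc_printed=_num("rfc_printed"),
            flagged=flagged,
        ))
    return tuple(records)


def load_prescriptions(
    path: str | Path,
    catalog: Sequence[MaterialRecord],
    strict: bool = True,
) -> tuple[Prescription, ...]:
    """Read long-format prescription rows and group them by prescription id.

    Grouping preserves file order. Duplicate (prescription, material) rows
    collapse to a single item keeping the first dose (a warning is logged):
    citation counting is presence-based, so a material never counts twice
    within one prescription.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = {"prescription_id", "material_id", "dose_g"} - set(df.columns)
    if missing:
        raise ValidationError(f"prescriptions missing column(s): {sorted(missing)}")

    known = {m.material_id for m in catalog}
    order: list[str] = []
    groups: dict[str, dict[str, float]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        pid = str(row["prescription_id"]).strip()
        mid = str(row["material_id"]).strip()
        if mid not in known and strict:
            raise ValidationError(f"{pid}: unknown material id {mid!r}")
        dose = float(row["dose_g"])
        if dose <= 0:
            raise ValidationError(f"{pid}: dose for {mid} must be > 0, got {dose}")
        if pid not in groups:
            order.append(pid)
            groups[pid] = {}
            meta[pid] = (
                str(row.get("pharmacy_id", "") or ""),
                str(row.get("region", "") or ""),
            )
        if mid in groups[pid]:
            logger.warning(
                "duplicate row (%s, %s): keeping first dose %.3g g", pid, mid,
                groups[pid][mid],
            )
            continue
        groups[pid][mid] = dose

    return tuple(
        Prescription(
            prescription_id=pid,
            pharmacy_id=meta[pid][0],
            region_code=meta[pid][1],
            items=tuple(groups[pid].items()),
        )
        for pid in order
    )


def load_dataset(
    catalog_path: str | Path,
    prescriptions_path: str | Path,
    strict: bool = True,
) -> Dataset:
    catalog = load_catalog(catalog_path, strict=strict)
    prescriptions = load_prescriptions(prescriptions_path, catalog, strict=strict)
    ds = Dataset(catalog=catalog, prescriptions=prescriptions)
    ds.validate(strict=strict)
    return ds


def to_transactions(dataset: Dataset) -> TransactionSet:
    """Reduce each prescription to its set of material ids.

    The universe is the catalog order, extended (in first-seen order) by any
    prescription items missing from the catalog so that lenient-mode data
    still mines.
    """
    universe = [m.material_id for m in dataset.catalog]
    seen = set(universe)
    for p in dataset.prescriptions:
        for m, _ in p.items:
            if m not in seen:
                seen.add(m)
                universe.append(m)
    return TransactionSet(
        universe=tuple(universe),
        transactions=tuple(p.material_ids for p in dataset.prescriptions),
    )


# ---------------------------------------------------------------------------
# writers


def _catalog_frame(records: Iterable[MaterialRecord]) -> pd.DataFrame:
    rows = []
    for m in records:
        rows.append({
            "material_id": m.material_id,
            "scientific_name": m.scientific_name,
            "family": m.family,
            "local_name": m.local_name,
            "part_used": m.part_used,
            "property_raw": m.property_raw,
            "effect_category": m.effect_category,
            "dose_min_g": m.dose_min_g,
            "dose_max_g": m.dose_max_g,
            "pharm_tags": ";".join(sorted(m.pharm_tags)),
            "rfc_printed": m.rfc_printed,
        })
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_tables(results: Mapping[str, object], out_dir: str | Path) -> dict[str, Path]:
    """Write a collection of results as delimited UTF-8 tables.

    ``results`` maps a result kind to the object to serialize. Recognized
    kinds and their deterministic file names:

    - ``"catalog"`` (materials)            -> catalog.csv
    - ``"frequencies"`` (MaterialFrequency) -> material_frequencies.csv
    - ``"breakdown_<key>"`` (Breakdown)     -> breakdown_<key>.csv
    - ``"dose_summaries"`` (DoseSummary map)-> dose_summaries.csv
    - ``"itemsets"`` (ItemsetSupport)       -> frequent_itemsets.csv
    - ``"rules"`` (AssociationRule)         -> rules.csv
    - ``"transactions"`` (TransactionSet)   -> transactions.csv
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    written: dict[str, Path] = {}

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, encoding="utf-8")
        written[name] = path

    for kind, obj in results.items():
        if kind == "catalog":
            _emit("catalog.csv", _catalog_frame(obj))
        elif kind == "frequencies":
            _emit("material_frequencies.csv", pd.DataFrame(
                [{"material_id": f.material_id, "FC": f.fc,
                  "RFC": repr(f.rfc), "RFC_2dp": f"{f.rfc_2dp:.2f}"} for f in obj],
            ))
        elif kind.startswith("breakdown_"):
            _emit(f"{kind}.csv", pd.DataFrame(
                [{"category": b.key, "count": b.count, "percent": b.percent}
                 for b in obj],
            ))
        elif kind == "dose_summaries":
            _emit("dose_summaries.csv", pd.DataFrame(
                [{"material_id": mid, "n": s.n, "min": s.min, "q1": s.q1,
                  "q2": s.q2, "q3": s.q3, "max": s.max, "mean": s.mean,
                  "sd": s.sd} for mid, s in obj.items()],
            ))
        elif kind == "itemsets":
            _emit("frequent_itemsets.csv", pd.DataFrame(
                [{"itemset": "+".join(s.items), "size": len(s.items),
                  "count": s.count, "fraction": repr(s.fraction)} for s in obj],
            ))
        elif kind == "rules":
            _emit("rules.csv", pd.DataFrame(
                [{"antecedent": "+".join(r.antecedent),
                  "consequent": "+".join(r.consequent),
                  "support_count": r.support_count,
                  "support_fraction": repr(r.support_fraction),
                  "confidence": repr(r.confidence)} for r in obj],
            ))
        elif kind == "transactions":
            _emit("transactions.csv", pd.DataFrame(
                [{"transaction_id": f"T{i + 1:03d}",
                  "items": "+".join(sorted(t, key=obj.universe.index))}
                 for i, t in enumerate(obj.transactions)],
            ))
        else:
            raise ValueError(f"unknown result kind {kind!r}")
    return written


def write_prescriptions(
    prescriptions: Iterable[Prescription], path: str | Path
) -> Path:
    """Write prescriptions in the long input format (one row per item)."""
    path = Path(path)
    rows = [
        {"prescription_id": p.prescription_id, "pharmacy_id": p.pharmacy_id,
         "region": p.region_code, "material_id": m, "dose_g": repr(dose)}
        for p in prescriptions
        for m, dose in p.items
    ]
    pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS).to_csv(
        path, index=False, encoding="utf-8"
    )
    return path


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    """Read back a material_frequencies.csv exactly as written.

    ``RFC`` round-trips exactly because it is serialized with ``repr``.
    """
    df = pd.read_csv(path, dtype={"material_id": str}, float_precision="round_trip")
    df["FC"] = df["FC"].astype(int)
    df["RFC"] = df["RFC"].astype(float)
    return df
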