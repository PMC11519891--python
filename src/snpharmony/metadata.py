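"""Schemaless sample/breed/dataset metadata with GeoJSON export.

Sample descriptions rarely follow a common schema, so beyond a minimal
required attribute set (breed, country, original ID, chip, optional GPS
and breed purpose) every record carries an open ``extra`` map that is
preserved verbatim through storage round trips.  The store is a single
JSON document file — a desk-scale stand-in for a document database,
keeping the schemaless model without a server.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

PURPOSES = {"dairy", "meat", "wool", "mixed"}

# Minimal ISO 3166-1 name -> alpha-2 table covering common small-ruminant
# study countries; alpha-2 input passes through.  Display names are kept
# alongside the code.
COUNTRY_ALPHA2 = {
    "albania": "AL", "algeria": "DZ", "argentina": "AR", "austria": "AT",
    "brazil": "BR", "china": "CN", "croatia": "HR", "egypt": "EG",
    "ethiopia": "ET", "france": "FR", "germany": "DE", "greece": "GR",
    "hungary": "HU", "india": "IN", "iran": "IR", "ireland": "IE",
    "italy": "IT", "kenya": "KE", "morocco": "MA", "namibia": "NA",
    "netherlands": "NL", "norway": "NO", "poland": "PL", "portugal": "PT",
    "romania": "RO", "serbia": "RS", "spain": "ES", "sweden": "SE",
    "switzerland": "CH", "turkey": "TR", "united kingdom": "GB",
    "uruguay": "UY", "united states": "US",
}


def normalize_country(value: str) -> str:
    """ISO 3166-1 alpha-2 code for a country name (or code passthrough)."""
    text = value.strip()
    if len(text) == 2 and text.isalpha():
        return text.upper()
    code = COUNTRY_ALPHA2.get(text.lower())
    if code is None:
        raise ValueError(f"unknown country {value!r}; supply an ISO alpha-2 code")
    return code


@dataclass
class SampleRecord:
    smarter_id: str
    original_id: str
    country: str
    breed: str
    breed_code: str
    species: str  # sheep | goat
    chip_name: str
    dataset: str = ""
    purpose: str | None = None
    location: tuple[float, float] | None = None  # (longitude, latitude)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in ("sheep", "goat"):
            raise ValueError(f"species must be sheep or goat, got {self.species!r}")
        if self.purpose is not None and self.purpose not in PURPOSES:
            raise ValueError(f"purpose must be one of {sorted(PURPOSES)}")
        if self.location is not None:
            lon, lat = self.location
            if not (-180 <= lon <= 180 and -90 <= lat <= 90):
                raise ValueError(f"bad coordinates {self.location}")
            self.location = (float(lon), float(lat))


@dataclass
class BreedRecord:
    name: str
    code: str
    species: str
    aliases: dict = field(default_factory=dict)  # dataset -> name used there


@dataclass
class DatasetRecord:
    name: str
    source: str  # foreground | background
    chip_name: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("foreground", "background"):
            raise ValueError("source must be foreground or background")


class MetadataStore:
    """In-memory metadata collection persisted as one JSON file."""

    def __init__(self) -> None:
        self.samples: dict[str, SampleRecord] = {}
        self.breeds: dict[tuple[str, str], BreedRecord] = {}
        self.datasets: dict[str, DatasetRecord] = {}

    # -- mutation ---------------------------------------------------------

    def add_sample(self, record: SampleRecord) -> None:
        existing = self.samples.get(record.smarter_id)
        if existing is not None and existing != record:
            same_animal = (existing.dataset == record.dataset and
                           existing.original_id == record.original_id)
            if not same_animal:
                raise ValueError(
                    f"smarter_id {record.smarter_id} already present "
                    "with different content")
            # same (dataset, original ID): a metadata update, not a clash
        self.samples[record.smarter_id] = record

    def add_breed(self, record: BreedRecord) -> None:
        key = (record.code, record.species)
        existing = self.breeds.get(key)
        if existing is None:
            self.breeds[key] = record
        else:
            existing.aliases.update(record.aliases)

    def add_dataset(self, record: DatasetRecord) -> None:
        existing = self.datasets.get(record.name)
        if existing is not None and existing != record:
            raise ValueError(f"dataset {record.name} already present "
                             "with different content")
        self.datasets[record.name] = record

    # -- queries ----------------------------------------------------------

    def query_samples(self, filters: dict | None = None) -> list[SampleRecord]:
        """Filter samples: conjunctive across fields, disjunctive within a
        field's value list; unknown fields match nothing (warned).
        Results are ordered by smarter_id."""
        records = sorted(self.samples.values(), key=lambda r: r.smarter_id)
        if not filters:
            return records
        schema = {f for f in SampleRecord.__dataclass_fields__ if f != "extra"}
        out = records
        for fld, wanted in filters.items():
            values = wanted if isinstance(wanted, (list, tuple, set)) else [wanted]
            values = set(values)
            if fld in schema:
                out = [r for r in out if getattr(r, fld) in values]
            else:
                matched = [r for r in out
                           if fld in r.extra and r.extra[fld] in values]
                if not matched and not any(fld in r.extra for r in records):
                    warnings.warn(f"unknown filter field {fld!r} matches nothing",
                                  stacklevel=2)
                out = matched
        return out

    def gps_coverage(self, samples=None) -> dict[tuple[str, str], float]:
        """Fraction of samples with GPS per (species, dataset source)
        stratum; strata with no samples are omitted."""
        samples = list(samples) if samples is not None else \
            list(self.samples.values())
        strata: dict[tuple[str, str], list[int]] = {}
        for record in samples:
            ds = self.datasets.get(record.dataset)
            source = ds.source if ds else "unknown"
            key = (record.species, source)
            located, total = strata.setdefault(key, [0, 0])
            strata[key][1] += 1
            if record.location is not None:
                strata[key][0] += 1
        return {key: located / total
                for key, (located, total) in sorted(strata.items())}

    def check_integrity(self, dataset) -> tuple[list, list]:
        """Cross-check against a merged genotype dataset: returns
        (samples missing from the store, store IDs absent from the
        genotype file).  Genotype sample keys use smarter_id as IID."""
        geno_ids = {s.iid for s in dataset.samples}
        missing_meta = sorted(geno_ids - set(self.samples))
        missing_geno = sorted(set(self.samples) - geno_ids)
        return missing_meta, missing_geno

    # -- export -----------------------------------------------------------

    def export_geojson(self, samples=None) -> tuple[dict, int]:
        """GeoJSON FeatureCollection of located samples (coordinates in
        (longitude, latitude) order); returns the collection and the
        number of samples excluded for lacking coordinates."""
        samples = list(samples) if samples is not None else \
            self.query_samples()
        features, excluded = [], 0
        for record in samples:
            if record.location is None:
                excluded += 1
                continue
            lon, lat = record.location
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": {
                    "smarter_id": record.smarter_id,
                    "breed": record.breed,
                    "country": record.country,
                    "chip_name": record.chip_name,
                },
            })
        if excluded:
            logger.info("export_geojson: %d samples without coordinates "
                        "excluded", excluded)
        return {"type": "FeatureCollection", "features": features}, excluded

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "samples": [asdict(r) for r in
                        sorted(self.samples.values(),
                               key=lambda r: r.smarter_id)],
            "breeds": [asdict(r) for r in
                       sorted(self.breeds.values(),
                              key=lambda r: (r.code, r.species))],
            "datasets": [asdict(r) for r in
                         sorted(self.datasets.values(), key=lambda r: r.name)],
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "MetadataStore":
        doc = json.loads(Path(path).read_text())
        store = cls()
        for rec in doc.get("samples", []):
            if rec.get("location") is not None:
                rec["location"] = tuple(rec["location"])
            store.add_sample(SampleRecord(**rec))
        for rec in doc.get("breeds", []):
            store.add_breed(BreedRecord(**rec))
        for rec in doc.get("datasets", []):
            store.add_dataset(DatasetRecord(**rec))
        return store


def read_sample_metadata(path) -> list[dict]:
    """Read a sample metadata TSV: required columns original_id, breed,
    breed_code, country, species, chip_name; optional purpose, latitude,
    longitude; any further columns land in ``extra``."""
    import csv

    required = {"original_id", "breed", "breed_code", "country", "species",
                "chip_name"}
    optional = {"purpose", "latitude", "longitude"}
    rows = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for raw in reader:
            row = {k: (v or "").strip() for k, v in raw.items()}
            location = None
            if row.get("latitude") and row.get("longitude"):
                location = (float(row["longitude"]), float(row["latitude"]))
            rows.append({
                "original_id": row["original_id"],
                "breed": row["breed"],
                "breed_code": row["breed_code"].upper(),
                "country": normalize_country(row["country"]),
                "country_name": row["country"],
                "species": row["species"],
                "chip_name": row["chip_name"],
                "purpose": row.get("purpose") or None,
                "location": location,
                "extra": {k: v for k, v in row.items()
                          if k not in required | optional and v},
            })
    return rows
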