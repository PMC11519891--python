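"""Reproducible, idempotent import pipeline.

A plain-text import manifest (YAML) lists ordered steps — chip manifest
imports, dataset imports, metadata imports, merge, dedupe — with their
parameters.  Each executed step is recorded in a state file together with
a digest of its parameters and input files; re-running the pipeline skips
every step whose digest is unchanged, so repeating the same command has
no side effects and appending one step re-executes only that step.  All
outputs are written deterministically (sorted keys, no timestamps): the
same inputs always produce byte-identical genotype files and metadata
store.

Output layout under the working directory::

    registry.jsonl      variant registry
    metadata.json       sample/breed/dataset metadata store
    idstate.json        stable-ID assignment state
    processed/<ds>.*    per-dataset TOP-coded PLINK binary + report
    final/<name>.*      merged PLINK binary, IBS report
    RELEASE.json        machine-readable release stamp (semantic version)
    .import_state.json  step completion markers
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .convert import convert_dataset, infer_coding, write_conversion_report
from .dataset import GenotypeDataset
from .errors import SnpHarmonyError
from .importers import import_affymetrix_annotation, import_illumina_manifest
from .io.affymetrix import read_affymetrix_calls
from .io.illumina import read_illumina_report
from .io.plink import read_plink_binary, read_plink_text, write_plink_binary
from .merge import IdState, assign_smarter_ids, find_duplicates, merge_datasets
from .metadata import (
    DatasetRecord,
    MetadataStore,
    SampleRecord,
    read_sample_metadata,
)
from .registry import Registry
from .strand import Coding

logger = logging.getLogger(__name__)

STATE_FILE = ".import_state.json"


class StepError(SnpHarmonyError):
    def __init__(self, step: str, message: str):
        super().__init__(f"step {step!r}: {message}")
        self.step = step


@dataclass
class ImportManifest:
    species: str
    assembly: str
    steps: list[dict]

    @classmethod
    def load(cls, path) -> "ImportManifest":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict) or "steps" not in doc:
            raise SnpHarmonyError(f"{path}: not an import manifest")
        steps = doc["steps"]
        names = [s.get("name") for s in steps]
        if None in names or len(set(names)) != len(names):
            raise SnpHarmonyError(f"{path}: every step needs a unique name")
        return cls(species=doc.get("species", "sheep"),
                   assembly=doc.get("assembly", ""), steps=steps)


@dataclass
class RunResult:
    executed: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _step_digest(step: dict, base: Path) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(step, sort_keys=True).encode())
    for input_path in _step_inputs(step, base):
        if not input_path.exists():
            raise FileNotFoundError(input_path)
        h.update(input_path.name.encode())
        h.update(_digest_file(input_path).encode())
    return h.hexdigest()


def _step_inputs(step: dict, base: Path) -> list[Path]:
    kind = step.get("kind")
    paths: list[Path] = []
    if kind == "import-manifest":
        paths.append(base / step["file"])
    elif kind == "import-dataset":
        fmt = step.get("format", "bed")
        prefix = base / step["file"]
        if fmt == "ped":
            paths += [prefix.with_suffix(".ped"), prefix.with_suffix(".map")]
        elif fmt == "bed":
            paths += [prefix.with_suffix(ext) for ext in (".bed", ".bim", ".fam")]
        else:
            paths.append(base / step["file"])
        if step.get("metadata"):
            paths.append(base / step["metadata"])
    elif kind == "import-metadata":
        paths.append(base / step["file"])
    return paths


def run_import(manifest_path, workdir) -> RunResult:
    """Execute an import manifest; idempotent per step."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = ImportManifest.load(manifest_path)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    (workdir / "processed").mkdir(exist_ok=True)
    (workdir / "final").mkdir(exist_ok=True)

    state_path = workdir / STATE_FILE
    state = (json.loads(state_path.read_text())
             if state_path.exists() else {"steps": {}})
    result = RunResult()

    for step in manifest.steps:
        name = step["name"]
        try:
            digest = _step_digest(step, base)
        except FileNotFoundError as exc:
            raise StepError(name, f"missing input file {exc.args[0]}") from exc
        if state["steps"].get(name) == digest:
            logger.info("step %s: up to date, skipping", name)
            result.skipped.append(name)
            continue
        logger.info("step %s: executing (%s)", name, step.get("kind"))
        try:
            _execute(step, manifest, base, workdir)
        except Exception as exc:
            raise StepError(name, str(exc)) from exc
        state["steps"][name] = digest
        state_path.write_text(json.dumps(state, sort_keys=True, indent=1) + "\n")
        result.executed.append(name)

    (workdir / "RELEASE.json").write_text(json.dumps(
        {"schema": 1, "species": manifest.species, "version": __version__},
        sort_keys=True) + "\n")
    return result


def _registry(workdir: Path, species: str) -> Registry:
    path = workdir / "registry.jsonl"
    return Registry.load(path) if path.exists() else Registry(species=species)


def _store(workdir: Path) -> MetadataStore:
    path = workdir / "metadata.json"
    return MetadataStore.load(path) if path.exists() else MetadataStore()


def _execute(step: dict, manifest: ImportManifest, base: Path,
             workdir: Path) -> None:
    kind = step.get("kind")
    if kind == "import-manifest":
        registry = _registry(workdir, manifest.species)
        fmt = step.get("format", "illumina")
        importer = {"illumina": import_illumina_manifest,
                    "affymetrix": import_affymetrix_annotation}.get(fmt)
        if importer is None:
            raise SnpHarmonyError(f"unknown manifest format {fmt!r}")
        report = importer(registry, base / step["file"], step["chip"],
                          step.get("assembly", manifest.assembly))
        logger.info("imported %d/%d records (%d flagged) for chip %s",
                    report.n_imported, report.n_records, report.n_flagged,
                    report.chip_name)
        registry.save(workdir / "registry.jsonl")
    elif kind == "import-dataset":
        _import_dataset(step, manifest, base, workdir)
    elif kind == "import-metadata":
        _import_metadata(step, manifest, base, workdir,
                         with_ids=False)
    elif kind == "merge":
        registry = _registry(workdir, manifest.species)
        datasets = [read_plink_binary(workdir / "processed" / ds,
                                      coding=Coding.ILLUMINA_TOP,
                                      assembly=manifest.assembly,
                                      chip_name=step.get("chip"))
                    for ds in step["datasets"]]
        for ds_name, ds in zip(step["datasets"], datasets):
            ds.source = ds_name
            ds.chip_name = _processed_chip(workdir, ds_name)
        merged = merge_datasets(datasets, registry)
        write_plink_binary(merged, workdir / "final" / step.get("out", "merged"))
    elif kind == "dedupe":
        target = workdir / "final" / step.get("dataset", "merged")
        merged = read_plink_binary(target, coding=Coding.ILLUMINA_TOP,
                                   assembly=manifest.assembly)
        report = find_duplicates(merged,
                                 threshold=step.get("threshold", 0.95),
                                 mode=step.get("mode", "all"))
        report.write_tsv(workdir / "final" /
                         step.get("report", "ibs_report.tsv"))
    else:
        raise SnpHarmonyError(f"unknown step kind {kind!r}")


def _processed_chip(workdir: Path, ds_name: str) -> str | None:
    meta = workdir / "processed" / f"{ds_name}.json"
    if meta.exists():
        return json.loads(meta.read_text()).get("chip_name")
    return None


def _import_dataset(step: dict, manifest: ImportManifest, base: Path,
                    workdir: Path) -> None:
    fmt = step.get("format", "bed")
    assembly = step.get("assembly", manifest.assembly)
    chip = step.get("chip")
    prefix = base / step["file"]
    if fmt == "ped":
        dataset = read_plink_text(prefix.with_suffix(".ped"),
                                  prefix.with_suffix(".map"),
                                  assembly=assembly, chip_name=chip)
    elif fmt == "bed":
        dataset = read_plink_binary(prefix, assembly=assembly, chip_name=chip)
    elif fmt == "report":
        dataset = read_illumina_report(base / step["file"], assembly=assembly)
        dataset.chip_name = chip or dataset.chip_name
    elif fmt == "affymetrix-calls":
        dataset = read_affymetrix_calls(base / step["file"], chip_name=chip,
                                        assembly=assembly)
    else:
        raise SnpHarmonyError(f"unknown dataset format {fmt!r}")
    dataset.source = step["name"]

    registry = _registry(workdir, manifest.species)
    coding = step.get("coding", "infer")
    if coding == "infer":
        inference = infer_coding(dataset, registry)
        if inference.coding is None:
            raise SnpHarmonyError(
                "coding inference tied between "
                f"{[c.value for c in inference.ties]}; set an explicit "
                "'coding' in the step")
        dataset.coding = inference.coding
        logger.info("inferred coding %s (concordance %.4f)",
                    inference.coding.value,
                    inference.concordance[inference.coding])
    else:
        dataset.coding = Coding(coding)

    converted, report = convert_dataset(dataset, registry)
    out_prefix = workdir / "processed" / step["name"]

    if step.get("metadata"):
        converted = _import_metadata(step, manifest, base, workdir,
                                     dataset=converted)
    write_plink_binary(converted, out_prefix)
    write_conversion_report(report, out_prefix.with_suffix(".conversion.tsv"))
    (out_prefix.with_suffix(".json")).write_text(json.dumps(
        {"chip_name": converted.chip_name, "assembly": converted.assembly,
         "coding": converted.coding.value}, sort_keys=True) + "\n")


def _import_metadata(step: dict, manifest: ImportManifest, base: Path,
                     workdir: Path, dataset: GenotypeDataset | None = None,
                     with_ids: bool = True):
    """Register samples in the metadata store, assigning stable IDs, and
    (when a genotype dataset is passed) rename its samples to
    breed-code/stable-ID keys."""
    rows = read_sample_metadata(base / step.get("metadata", step.get("file")))
    dataset_name = step["name"]
    for row in rows:
        row["dataset"] = dataset_name

    store = _store(workdir)
    store.add_dataset(DatasetRecord(
        name=dataset_name, source=step.get("source", "background"),
        chip_name=step.get("chip", ""), citation=step.get("citation", "")))

    id_state_path = workdir / "idstate.json"
    state = IdState.load(id_state_path) if id_state_path.exists() else IdState()
    ids, state = assign_smarter_ids(rows, manifest.species, state)
    state.save(id_state_path)

    by_original = {}
    for row, sid in zip(rows, ids):
        record = SampleRecord(
            smarter_id=str(sid), original_id=row["original_id"],
            country=row["country"], breed=row["breed"],
            breed_code=row["breed_code"], species=row["species"],
            chip_name=row["chip_name"], dataset=dataset_name,
            purpose=row["purpose"], location=row["location"],
            extra=row["extra"])
        store.add_sample(record)
        by_original[row["original_id"]] = record
    store.save(workdir / "metadata.json")

    if dataset is None:
        return None
    renamed = dataset.copy()
    new_samples = []
    for sample in dataset.samples:
        record = by_original.get(sample.iid)
        if record is None:
            raise SnpHarmonyError(
                f"sample {sample.iid} has no metadata row in dataset "
                f"{dataset_name}")
        new_samples.append(type(sample)(
            fid=record.breed_code, iid=record.smarter_id,
            father=sample.father, mother=sample.mother, sex=sample.sex,
            phenotype=sample.phenotype))
    renamed.samples = new_samples
    return renamed
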