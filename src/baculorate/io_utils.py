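"""Readers and writers for the tabular and sequence formats used.

TSV is the canonical dialect (CSV accepted on read); frequencies are stored
internally as proportions and converted from percents only at the I/O
boundary.  Every numeric output file can be accompanied by a JSON sidecar
recording parameters, seed and package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .model_core import ExperimentDesign, SimulationParams
from .selection_spectrum import RegionAnnotation
from .variant_filter import VARIANT_COLUMNS, DetectionConfig, validate_records

__all__ = [
    "RunConfig",
    "read_variant_table",
    "write_variant_table",
    "read_coverage",
    "write_coverage",
    "read_reference_and_annotation",
    "write_reference_and_annotation",
    "write_sidecar",
    "load_run_config",
]

_ANNOTATION_COLUMNS = ["name", "start", "end", "category", "strand", "frame"]


@dataclass
class RunConfig:
    """Bundle of parameters driving one pipeline run."""

    params: SimulationParams
    design: ExperimentDesign
    detection: DetectionConfig
    seed: int = 0
    log_level: str = "INFO"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_variant_table(path, percent: bool = False) -> pd.DataFrame:
    """Read a variant TSV/CSV into a validated records DataFrame.

    With ``percent=True`` the frequency column is interpreted as percent
    and converted to a proportion.
    """
    path = Path(path)
    records = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in VARIANT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if percent:
        records["frequency"] = records["frequency"] / 100.0
    return validate_records(records)


def write_variant_table(records: pd.DataFrame, path) -> None:
    path = Path(path)
    records.to_csv(path, sep=_sep_for(path), index=False)


def read_coverage(path) -> dict[str, np.ndarray]:
    """Read a long coverage table (lineage, position, depth) into arrays."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("lineage", "position", "depth"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return {
        lin: grp.sort_values("position")["depth"].to_numpy(dtype=float)
        for lin, grp in df.groupby("lineage")
    }


def write_coverage(coverage: dict[str, np.ndarray], path) -> None:
    frames = [
        pd.DataFrame(
            {"lineage": lin, "position": np.arange(1, len(depth) + 1), "depth": depth}
        )
        for lin, depth in coverage.items()
    ]
    pd.concat(frames).to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


def read_reference_and_annotation(fasta_path, annotation_path) -> RegionAnnotation:
    """Load a FASTA reference and an interval table into an annotation.

    The annotation is a TSV/CSV with columns name, start, end, category,
    strand, frame (1-based closed intervals).  Bounds and CDS length
    divisibility are validated by :class:`RegionAnnotation`.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one sequence, got {len(records)}")
    reference = str(records[0].seq).upper()
    annotation_path = Path(annotation_path)
    table = pd.read_csv(annotation_path, sep=_sep_for(annotation_path))
    missing = [c for c in _ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{annotation_path}: missing columns {missing}")
    intervals = tuple(
        (int(r.start), int(r.end), str(r.category), str(r.strand), int(r.frame))
        for r in table.itertuples()
    )
    return RegionAnnotation(reference=reference, intervals=intervals)


def write_reference_and_annotation(
    annotation: RegionAnnotation, fasta_path, annotation_path, name: str = "reference"
) -> None:
    SeqIO.write(
        [SeqRecord(Seq(annotation.reference), id=name, description="")],
        str(fasta_path),
        "fasta",
    )
    rows = [
        {"name": f"iv{k}", "start": s, "end": e, "category": c, "strand": st, "frame": fr}
        for k, (s, e, c, st, fr) in enumerate(annotation.intervals)
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(
        Path(annotation_path), sep=_sep_for(Path(annotation_path)), index=False
    )


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_sidecar(path, seed: int | None = None, **metadata) -> None:
    """Write a JSON provenance sidecar next to an output file."""
    payload = {"tool": "baculorate", "version": __version__, "seed": seed}
    payload.update({k: _jsonable(v) for k, v in metadata.items()})
    Path(str(path) + ".meta.json").write_text(json.dumps(payload, indent=2))


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration.

    Recognized top-level keys: ``params``, ``design``, ``detection``,
    ``seed``, ``log_level``; unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"params", "design", "detection", "seed", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(
        params=SimulationParams(**raw.get("params", {})),
        design=ExperimentDesign(**raw.get("design", {})),
        detection=DetectionConfig(**raw.get("detection", {})),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
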