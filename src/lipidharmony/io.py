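"""Readers/writers for the tabular dialect, the run manifest, and the pipeline driver.

The canonical on-disk form of a measurement table is a pair of CSVs: a data
file (``feature`` column, then one column per injection) and a sidecar
metadata file (one row per injection: sample, role, method, batch,
dilution_fraction, replicate).  Missing values are empty cells, distinct
from 0.  Lipid names are canonicalized through the shorthand parser on read;
unparseable names ride along as opaque features and are excluded from
composition-dependent stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .harmonize import ConsensusValues, median_fold_align, reference_normalize, summarize_reference
from .isotopes import deisotope
from .metrics import cross_method_cov, fold_from_average
from .nomenclature import LipidSpecies, format_shorthand, parse_shorthand
from .qc import QCThresholds, apply_qc
from .quantify import InternalStandardMap, to_concentration
from .tables import ConcentrationTable, MeasurementTable, SchemaError

__all__ = [
    "read_measurements",
    "write_measurements",
    "species_index_for",
    "RunManifest",
    "run_pipeline",
]


def read_measurements(data_path: str, metadata_path: str) -> MeasurementTable:
    """Read the measurement CSV dialect; validates cross-references and roles."""
    data = pd.read_csv(data_path)
    if "feature" not in data.columns:
        raise SchemaError(f"{data_path}: first column must be named 'feature'")
    data = data.set_index("feature")
    for col in data.columns:
        bad = data[col].apply(
            lambda v: not (pd.isna(v) or isinstance(v, (int, float)))
        )
        if bad.any():
            raise SchemaError(
                f"{data_path}: non-numeric cells in column {col!r}, rows "
                f"{list(data.index[bad])}"
            )
    meta = pd.read_csv(metadata_path).set_index("injection")
    only_data = set(data.columns) - set(meta.index)
    only_meta = set(meta.index) - set(data.columns)
    if only_data or only_meta:
        raise SchemaError(
            f"injections without metadata: {sorted(only_data)}; "
            f"metadata without data: {sorted(only_meta)}"
        )
    return MeasurementTable(data.astype(float), meta)


def write_measurements(table: MeasurementTable, data_path: str, metadata_path: str) -> None:
    table.intensities.to_csv(data_path, index_label="feature")
    table.injections.to_csv(metadata_path, index_label="injection")


def species_index_for(features) -> dict[str, LipidSpecies]:
    """Parse every parseable feature name; opaque features are skipped."""
    index = {}
    for feature in features:
        try:
            index[feature] = parse_shorthand(feature)
        except Exception:
            continue
    return index


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Append-only record of the stages a run applied."""

    seed: int | None = None
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **params) -> None:
        self.stages.append(
            {"stage": stage, "params": params, "time": time.strftime("%Y-%m-%dT%H:%M:%S")}
        )

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "seed": self.seed, "stages": self.stages},
                fh, indent=2,
            )


def run_pipeline(config: dict, out_dir: str, seed: int | None = None) -> RunManifest:
    """Execute deisotope → quantify → qc → normalize → (align) → report.

    ``config`` (typically loaded from YAML) names, per method, the data and
    metadata CSVs, plus the IS map, thresholds, the reference sample, and an
    optional consensus CSV.  Every stage's output is written under
    ``out_dir``; the manifest records stages, parameters, and input digests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed)

    methods = config["methods"]  # {label: {"data": path, "metadata": path}}
    if config.get("normalize", True):
        # fail fast, before any computation, if normalization has no reference
        for method, paths in methods.items():
            meta = pd.read_csv(paths["metadata"])
            if not (meta["role"] == "reference").any():
                raise SchemaError(
                    f"normalize requested but method {method!r} has no "
                    f"role=reference injections"
                )
    is_map = InternalStandardMap.from_yaml(config["is_map"])
    thresholds = QCThresholds(**config.get("qc_thresholds", {}))
    consensus = (
        ConsensusValues.from_csv(config["consensus"]) if config.get("consensus") else None
    )

    conc_tables: dict[str, ConcentrationTable] = {}
    normalized: dict[str, ConcentrationTable] = {}
    for method, paths in methods.items():
        table = read_measurements(paths["data"], paths["metadata"])
        manifest.record(
            "read", method=method,
            data=_digest(paths["data"]), metadata=_digest(paths["metadata"]),
        )
        index = species_index_for(table.features)
        if config.get("deisotope", True):
            table = deisotope(table, index)
            manifest.record("deisotope", method=method,
                            clamped=list(table.clamped_features))
        conc = to_concentration(
            table, index, is_map,
            plasma_volume_ul=config.get("plasma_volume_ul", 10.0), method=method,
        )
        report = apply_qc(table, index, is_map, thresholds)
        report.to_csv(out / f"qc_{method}.csv")
        survivors = report.survivors
        (out / f"qc_{method}_survivors.txt").write_text("\n".join(survivors) + "\n")
        manifest.record("qc", method=method, survivors=len(survivors))
        conc = conc.with_values(conc.values.loc[survivors])
        conc.values.to_csv(out / f"concentrations_{method}.csv", index_label="lipid")
        conc_tables[method] = conc

        if config.get("normalize", True):
            summary = summarize_reference(conc, policy=config.get("reference_policy", "mean"))
            norm, dropped = reference_normalize(conc, summary, consensus)
            norm.values.to_csv(out / f"normalized_{method}.csv", index_label="lipid")
            manifest.record("normalize", method=method, dropped=len(dropped),
                            state=norm.state)
            normalized[method] = norm

    if config.get("align", False) and len(conc_tables) >= 2:
        aligned = median_fold_align(conc_tables, rescale=config.get("rescale", "ratio"))
        for method, table in aligned.items():
            table.values.to_csv(out / f"aligned_{method}.csv", index_label="lipid")
        manifest.record("align", methods=list(aligned), rescale=config.get("rescale", "ratio"))

    if len(conc_tables) >= 2:
        compare = normalized if normalized else conc_tables
        common = set.intersection(*(set(t.lipids) for t in compare.values()))
        trimmed = {m: t.with_values(t.values.loc[sorted(common)]) for m, t in compare.items()}
        cov_series = cross_method_cov(trimmed)
        folds = fold_from_average(trimmed)
        pd.DataFrame({"cross_method_cov": cov_series}).join(folds).to_csv(
            out / "method_comparison.csv", index_label="lipid"
        )
        manifest.record("report", lipids=len(common))

    manifest.write(out / "manifest.json")
    return manifest
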