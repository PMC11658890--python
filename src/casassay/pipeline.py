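"""End-to-end runs: configuration, logging, sample sheets, artifact writing.

A run is described by a :class:`RunConfig` (plain YAML on disk; CLI flags
override).  ``run_pam_pipeline`` executes extraction through consensus
calling for a depletion experiment; ``run_kinetics_pipeline`` fits every
condition of a long-format time-course table and evaluates requested
fold-changes.  Each run directory receives the resolved config, a log with
input checksums, all tables (TSV) and a machine-readable JSON report.
Reports contain no timestamps, so identical configs produce identical
reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .depletion import (
    DEFAULT_CONFIDENCE,
    DEFAULT_INCLUSION_FRACTION,
    DEFAULT_PSEUDOCOUNT,
    PamDepletionModel,
)
from .kinetics import ExponentialKineticsModel, TimeCourse, fold_change
from .library import PamLibrarySpec, default_library_spec


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    track: str  # "pam" | "kinetics"
    output_dir: Path
    # pam track
    sample_sheet: Path | None = None
    confidence: float = DEFAULT_CONFIDENCE
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    inclusion_fraction: float = DEFAULT_INCLUSION_FRACTION
    threshold_method: str = "gaussian"
    weight_by_depletion: bool = False
    library: dict[str, Any] | None = None  # PamLibrarySpec fields; default design if None
    # kinetics track
    timecourse: Path | None = None
    assay: str = "cleavage_fraction"
    time_unit: str = "minute"
    fit_mode: str | None = None  # "pooled" | "per_replicate" | None (assay default)
    fold_changes: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw["output_dir"] = Path(raw["output_dir"])
        for key in ("sample_sheet", "timecourse"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        if "fold_changes" in raw:
            raw["fold_changes"] = [tuple(fc) for fc in raw["fold_changes"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if v is not None
        }
        data["fold_changes"] = [list(fc) for fc in self.fold_changes]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def library_spec(self) -> PamLibrarySpec:
        if self.library is None:
            return default_library_spec()
        return PamLibrarySpec(**self.library)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = [f"casassay {__version__}"]

    def add(self, message: str) -> None:
        self.lines.append(message)

    def checksum(self, path: Path) -> None:
        self.add(f"input {path} sha256={_sha256(path)}")

    def write(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def read_sample_sheet(path: str | Path) -> list[tuple[str, str, Path]]:
    """TSV with columns sample_id, role, path (paths relative to the sheet)."""
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "role", "path"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    base = Path(path).parent
    out = []
    for row in sheet.itertuples(index=False):
        p = Path(row.path)
        out.append((str(row.sample_id), str(row.role), p if p.is_absolute() else base / p))
    return out


def run_pam_pipeline(config: RunConfig) -> dict:
    """Depletion track: extract -> normalize -> log2FC -> threshold ->
    significant -> logo -> consensus; writes all artifacts and returns the
    report dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    if config.sample_sheet is None:
        raise ValueError("pam track requires a sample_sheet")
    samples = read_sample_sheet(config.sample_sheet)
    log.checksum(Path(config.sample_sheet))
    for _, _, p in samples:
        log.checksum(p)

    library = config.library_spec()
    model = PamDepletionModel.from_fastq(samples, library, pseudocount=config.pseudocount)
    for sid, table in model.tables.items():
        table.to_frame().to_csv(out / f"counts_{sid}.tsv", sep="\t", index=False)
        log.add(
            f"sample {sid} role={table.sample_role} total={table.total_reads} "
            f"matched={table.matched_reads}"
        )
    results = model.fit(
        confidence=config.confidence,
        threshold_method=config.threshold_method,
        inclusion_fraction=config.inclusion_fraction,
        weight_by_depletion=config.weight_by_depletion,
    )
    artifacts = {}
    for sid, res in results.per_sample.items():
        dep_path = out / f"depletion_{sid}.tsv"
        res.table.reset_index().to_csv(dep_path, sep="\t", index=False)
        logo_path = out / f"logo_{sid}.tsv"
        res.logo.to_frame().to_csv(logo_path, sep="\t", index=False)
        # names are relative to the run directory so reports are hash-stable
        artifacts[sid] = {"depletion": dep_path.name, "logo": logo_path.name}
    log.add(f"threshold {results.threshold:.6f} at confidence {config.confidence}")

    report = {
        "tool": "casassay",
        "version": __version__,
        "track": "pam",
        "parameters": {
            "confidence": config.confidence,
            "pseudocount": config.pseudocount,
            "inclusion_fraction": config.inclusion_fraction,
            "threshold_method": config.threshold_method,
        },
        "results": results.as_dict(),
        "artifacts": artifacts,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    log.write()
    return report


def read_timecourses(
    path: str | Path, assay: str, time_unit: str
) -> dict[str, TimeCourse]:
    """Long-format TSV (condition, replicate, time, value [, blank]) into
    per-condition :class:`TimeCourse` objects."""
    data = pd.read_csv(path, sep="\t")
    required = {"condition", "replicate", "time", "value"}
    if not required <= set(data.columns):
        raise ValueError(f"timecourse table must have columns {sorted(required)}")
    courses = {}
    for cond, grp in data.groupby("condition", sort=False):
        blank = None
        if "blank" in grp.columns and grp["blank"].notna().any():
            blank = float(grp["blank"].dropna().mean())
        courses[str(cond)] = TimeCourse(
            condition=str(cond),
            time_unit=time_unit,  # type: ignore[arg-type]
            observations=grp[["replicate", "time", "value"]].reset_index(drop=True),
            assay=assay,  # type: ignore[arg-type]
            blank_mean=blank,
        )
    return courses


def run_kinetics_pipeline(config: RunConfig) -> dict:
    """Kinetics track: per-condition exponential fits, replicate aggregates,
    and requested fold-changes; writes JSON + TSV artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    if config.timecourse is None:
        raise ValueError("kinetics track requires a timecourse table")
    log.checksum(Path(config.timecourse))
    courses = read_timecourses(config.timecourse, config.assay, config.time_unit)

    per_replicate = {"pooled": False, "per_replicate": True}.get(config.fit_mode)
    fits = {}
    rows = []
    for cond, course in courses.items():
        res = ExponentialKineticsModel(course).fit(per_replicate=per_replicate)
        fits[cond] = res
        agg = res.aggregate
        rows.append(
            {
                "condition": cond,
                "k_obs": "nd" if agg.nd else agg.mean_k,
                "sd_k_obs": agg.sd_k,
                "n": agg.n,
                "ymax": res.ymax,
                "nd": agg.nd,
            }
        )
        log.add(f"condition {cond}: {'nd' if agg.nd else f'k_obs={agg.mean_k:.6g}'}")

    report: dict[str, Any] = {
        "tool": "casassay",
        "version": __version__,
        "track": "kinetics",
        "parameters": {
            "assay": config.assay,
            "time_unit": config.time_unit,
            "fit_mode": config.fit_mode or "assay default",
        },
        "conditions": {cond: res.as_dict() for cond, res in fits.items()},
    }
    if config.fold_changes:
        folds = {}
        for num, den in config.fold_changes:
            for name in (num, den):
                if name not in fits:
                    raise ValueError(f"unknown condition {name!r} in fold-change request")
            folds[f"{num}/{den}"] = fold_change(fits[num].aggregate, fits[den].aggregate)
        report["fold_changes"] = folds

    pd.DataFrame(rows).to_csv(out / "fits.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    log.write()
    return report
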