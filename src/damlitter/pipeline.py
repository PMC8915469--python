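"""One-command orchestration of the full convergence analysis.

Stages communicate through on-disk artifacts (presence TSV, distance CSV,
heterogeneity CSV, Newick trees, coordinate CSVs, area CSVs) so each is
independently inspectable, plus a machine-readable JSON report collecting
the configuration, software version, input checksum and every p-value and
area. Everything downstream of the input file is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .records import (
    IsolationRecord,
    SampleMeta,
    TimePoint,
    ValidationError,
    encode_presence,
    read_records,
)
from .distance import phi_distance_matrix
from .stats import (
    MATRIX_FILTERS,
    compare_to_birth,
    ranksum_exact,
    within_family_heterogeneity,
)
from .cluster import complete_linkage, to_newick
from .ordination import classical_mds_2d, group_areas

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A stage failed; the message names the stage and offending unit."""


#: Time points whose polygon areas are compared against birth.
AREA_COMPARISONS: tuple[str, ...] = ("T30", "T60")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input: str
    output_dir: str
    matrix_filters: Sequence[str] = ("all", "rectal_only")
    transform: str = "half_one_minus_phi"
    constant_policy: str = "neutral"
    holm_adjust: bool = False
    include_dams: bool = True
    overwrite: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = [f for f in self.matrix_filters if f not in MATRIX_FILTERS]
        if bad:
            raise ValidationError(f"unknown matrix_filter preset(s): {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ranksum_json(res) -> dict:
    return {"W": res.statistic_W, "n_a": res.n_a, "n_b": res.n_b,
            "p": res.p_two_sided, "method": res.method}


def analyze(
    samples: Sequence[SampleMeta],
    records: Sequence[IsolationRecord],
    config: RunConfig,
    out_dir: Path | None = None,
) -> dict:
    """Run the analysis stages on in-memory data; optionally write artifacts.

    Returns the report dict: per matrix filter, the heterogeneity table,
    the three birth comparisons, per-family dendrogram Newick strings, and
    the polygon-area table with its T0-vs-T30/T60 rank-sum tests.
    """
    matrix = encode_presence(records, samples)
    dist = phi_distance_matrix(matrix, constant_policy=config.constant_policy,
                               transform=config.transform)
    if out_dir is not None:
        matrix.to_tsv(out_dir / "presence.tsv")
        dist.to_csv(out_dir / "distances.csv")

    families = sorted({s.family_id for s in samples})
    report: dict = {"filters": {}}
    for preset in config.matrix_filters:
        allowed = MATRIX_FILTERS[preset]
        fdir = out_dir / preset if out_dir is not None else None
        if fdir is not None:
            fdir.mkdir(parents=True, exist_ok=True)

        try:
            het = within_family_heterogeneity(
                dist, samples, matrix_filter=preset,
                include_dams=config.include_dams)
            births = compare_to_birth(het, holm=config.holm_adjust)
        except Exception as exc:
            raise PipelineError(f"heterogeneity stage failed ({preset}): {exc}")

        newicks: dict[str, str] = {}
        area_frames = []
        for fam in families:
            ids = [
                s.sample_id for s in samples
                if s.family_id == fam
                and (allowed is None or s.matrix in allowed)
                and (config.include_dams or s.subject_role.value != "dam")
            ]
            fam_samples = [s for s in samples if s.sample_id in set(ids)]
            if len(ids) >= 2:
                try:
                    tree = complete_linkage(dist.subset(ids))
                    newicks[fam] = to_newick(tree)
                except Exception as exc:
                    raise PipelineError(
                        f"clustering stage failed ({preset}, family {fam}): {exc}")
            if len(ids) >= 3:
                try:
                    ordn = classical_mds_2d(dist.subset(ids))
                    areas = group_areas(ordn, fam_samples)
                    areas["goodness"] = ordn.goodness
                    area_frames.append(areas)
                    if fdir is not None:
                        ordn.to_csv(fdir / f"coords_{fam}.csv")
                except Exception as exc:
                    raise PipelineError(
                        f"ordination stage failed ({preset}, family {fam}): {exc}")

        area_table = (pd.concat(area_frames, ignore_index=True)
                      if area_frames else pd.DataFrame(
                          columns=["family_id", "time_point", "n_points", "area"]))
        area_tests: dict[str, dict] = {}
        t0_areas = area_table.loc[
            area_table["time_point"] == "T0", "area"].to_numpy()
        for tp in AREA_COMPARISONS:
            vals = area_table.loc[
                area_table["time_point"] == tp, "area"].to_numpy()
            if len(t0_areas) >= 2 and len(vals) >= 2:
                area_tests[tp] = _ranksum_json(ranksum_exact(vals, t0_areas))
            else:
                area_tests[tp] = {"testable": False}

        if fdir is not None:
            het.to_csv(fdir / "heterogeneity.csv", index=False)
            area_table.to_csv(fdir / "areas.csv", index=False)
            for fam, nwk in newicks.items():
                (fdir / f"dendrogram_{fam}.nwk").write_text(nwk + "\n")
            (fdir / "birth_tests.json").write_text(json.dumps(
                {tp: (_ranksum_json(c.result) if c.testable
                      else {"testable": False})
                 for tp, c in births.items()}, indent=2) + "\n")
            (fdir / "area_tests.json").write_text(
                json.dumps(area_tests, indent=2) + "\n")

        report["filters"][preset] = {
            "heterogeneity": het.to_dict(orient="records"),
            "birth_comparisons": {
                tp: (_ranksum_json(c.result) if c.testable
                     else {"testable": False})
                for tp, c in births.items()},
            "dendrograms": newicks,
            "areas": area_table.to_dict(orient="records"),
            "area_comparisons": area_tests,
        }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute records -> presence -> distance -> statistics -> artifacts.

    Writes all stage outputs under ``config.output_dir`` and returns the
    report dict (also written as ``report.json``)."""
    in_path = Path(config.input)
    if not in_path.exists():
        raise ValidationError(f"input file not found: {in_path}")
    out_dir = Path(config.output_dir)
    report_path = out_dir / "report.json"
    if report_path.exists() and not config.overwrite:
        raise ValidationError(
            f"{report_path} exists; pass overwrite to replace it")
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        samples, records = read_records(in_path)
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc

    report = analyze(samples, records, config, out_dir=out_dir)
    report = {
        "config": asdict(config) | {"matrix_filters": list(config.matrix_filters)},
        "version": __version__,
        "input_sha256": _sha256(in_path),
        "n_samples": len(samples),
        "n_records": len(records),
        "generated_at": datetime.now(timezone.utc).isoformat(),
        **report,
    }
    report_path.write_text(json.dumps(report, indent=2) + "\n")
    return report
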