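"""Configuration-driven orchestration.

A YAML config names condition blocks (topology + replica trajectories +
selections), the metrics to compute, network parameters and pharmacology
datasets; ``run`` executes the stages in dependency order (io → metrics
→ network, pharmacology independent), isolates failures to their
condition block, and writes deterministic CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__, io, metrics, network, pharm

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "load_config", "run"]


class ConditionConfig(BaseModel):
    label: str
    topology: Path
    replicas: list[list[Path]]
    bw_map: Optional[Path] = None
    selections: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _files_exist(self) -> "ConditionConfig":
        missing = [
            str(p)
            for p in [self.topology, self.bw_map, *(f for rep in self.replicas for f in rep)]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise ValueError(f"condition {self.label!r}: missing files {missing}")
        return self


class MetricRequest(BaseModel):
    kind: Literal["rmsd", "rmsf", "contacts", "hbonds", "dihedral"]
    condition: str
    selection: str = "name CA"
    selection_b: Optional[str] = None
    fit_selection: Optional[str] = None
    cutoff: float = 4.5
    atoms: Optional[list[int]] = None
    allow_overlap: bool = False


class NetworkRequest(BaseModel):
    conditions: list[str]
    ca_selection: str = "name CA"
    contact_selection: Optional[str] = None  # default: heavy-atom self-contacts
    fit_selection: Optional[str] = None
    persistency_threshold: float = 75.0
    contact_cutoff: float = 4.5
    exclude_consecutive: bool = True
    corr_floor: float = 1e-6
    communities: bool = False
    compare: Optional[list[str]] = None

    @field_validator("compare")
    @classmethod
    def _two_labels(cls, v):
        if v is not None and len(v) != 2:
            raise ValueError("network.compare needs exactly two condition labels")
        return v


class PharmacologyRequest(BaseModel):
    label: str
    path: Path
    fits: list[Literal["logistic3", "allosterism"]] = Field(default_factory=lambda: ["logistic3"])
    agonist: Optional[str] = None

    @model_validator(mode="after")
    def _exists(self) -> "PharmacologyRequest":
        if not Path(self.path).exists():
            raise ValueError(f"pharmacology dataset {self.label!r}: {self.path} missing")
        return self


class PipelineConfig(BaseModel):
    output_dir: Path
    seed: int = 0
    conditions: list[ConditionConfig] = Field(default_factory=list)
    metrics: list[MetricRequest] = Field(default_factory=list)
    network: Optional[NetworkRequest] = None
    pharmacology: list[PharmacologyRequest] = Field(default_factory=list)

    @model_validator(mode="after")
    def _labels(self) -> "PipelineConfig":
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            raise ValueError("condition labels must be unique")
        known = set(labels)
        for m in self.metrics:
            if m.condition not in known:
                raise ValueError(f"metric references unknown condition {m.condition!r}")
        if self.network:
            for lab in self.network.conditions + (self.network.compare or []):
                if lab not in known:
                    raise ValueError(f"network references unknown condition {lab!r}")
        return self


@dataclass
class RunReport:
    """Output bundle of one pipeline run, traceable to its config."""

    config_hash: str
    seed: int
    version: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def provenance(self) -> dict:
        return dict(config_hash=self.config_hash, seed=self.seed, version=self.version)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _load_condition(cond: ConditionConfig) -> tuple[io.Topology, list[io.Trajectory]]:
    top = io.read_topology(cond.topology, bw_map=cond.bw_map)
    trajs = [
        io.read_trajectory(files, top, replica=r) for r, files in enumerate(cond.replicas)
    ]
    return top, trajs


def _run_metric(
    req: MetricRequest, top: io.Topology, trajs: list[io.Trajectory]
) -> tuple[pd.DataFrame, dict]:
    sel = io.select(top, req.selection)
    fit = io.select(top, req.fit_selection) if req.fit_selection else None
    if req.kind == "rmsd":
        reference = trajs[0].coordinates[0]
        series = [metrics.rmsd(t, reference, sel, fit) for t in trajs]
        frames = []
        for s in series:
            frames.append(pd.DataFrame(dict(replica=s.replica, frame=np.arange(len(s.values)), rmsd=s.values)))
        summary = {"rmsd": metrics.rmsd_summary(series)}
        return pd.concat(frames, ignore_index=True), summary
    if req.kind == "rmsf":
        prof = metrics.rmsf(trajs, sel, fit)
        return (
            pd.DataFrame(dict(resid=prof.resids, rmsf=prof.values)),
            {"mean_rmsf": float(prof.values.mean())},
        )
    if req.kind == "contacts":
        sel_b = io.select(top, req.selection_b) if req.selection_b else sel
        table = metrics.contact_persistency(
            trajs, sel, sel_b, cutoff=req.cutoff,
            allow_overlap=req.allow_overlap or req.selection_b in (None, req.selection),
        )
        return table.table.assign(
            replica_persistency=table.table["replica_persistency"].map(
                lambda xs: ";".join(f"{x:.3f}" for x in xs)
            )
        ), {"n_pairs": len(table.table)}
    if req.kind == "dihedral":
        if not req.atoms or len(req.atoms) != 4:
            raise ValueError("dihedral metric needs exactly four atom ids")
        rows = []
        for t in trajs:
            s = metrics.dihedral(t, req.atoms)
            rows.append(pd.DataFrame(dict(replica=t.replica, frame=np.arange(t.n_frames), angle=s.values)))
        merged = pd.concat(rows, ignore_index=True)
        rot = metrics.rotamer_distribution(merged["angle"].to_numpy())
        return merged, {"g_minus": rot.g_minus, "trans": rot.trans, "g_plus": rot.g_plus}
    raise ValueError(f"hbond metrics need explicit donor/acceptor lists; "
                     f"use the library interface for kind {req.kind!r}")


def run(config: PipelineConfig) -> RunReport:
    """Execute the configured stages and write outputs under output_dir."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=_config_hash(config), seed=config.seed, version=__version__)

    loaded: dict[str, tuple[io.Topology, list[io.Trajectory]]] = {}
    for cond in config.conditions:
        t0 = time.perf_counter()
        try:
            loaded[cond.label] = _load_condition(cond)
        except Exception as exc:
            report.errors[f"io/{cond.label}"] = str(exc)
            logger.error("condition %s failed to load: %s", cond.label, exc)
        report.timings[f"io/{cond.label}"] = time.perf_counter() - t0

    for k, req in enumerate(config.metrics):
        key = f"metrics/{k}_{req.kind}_{req.condition}"
        if req.condition not in loaded:
            report.errors[key] = "condition failed to load"
            continue
        t0 = time.perf_counter()
        try:
            table, summary = _run_metric(req, *loaded[req.condition])
            report.tables[key] = table
            report.summaries[key] = summary
        except Exception as exc:
            report.errors[key] = str(exc)
            logger.error("%s failed: %s", key, exc)
        report.timings[key] = time.perf_counter() - t0

    if config.network:
        nets: dict[str, network.DynamicalNetwork] = {}
        req = config.network
        params = network.NetworkBuildParams(
            contact_cutoff=req.contact_cutoff,
            persistency_threshold=req.persistency_threshold,
            exclude_consecutive=req.exclude_consecutive,
            corr_floor=req.corr_floor,
        )
        for label in req.conditions:
            key = f"network/{label}"
            if label not in loaded:
                report.errors[key] = "condition failed to load"
                continue
            t0 = time.perf_counter()
            try:
                top, trajs = loaded[label]
                ca = io.select(top, req.ca_selection)
                fit = io.select(top, req.fit_selection) if req.fit_selection else None
                contact_sel = io.select(top, req.contact_selection) if req.contact_selection else ca
                corr = network.correlation_matrix(trajs, ca, fit)
                contacts = metrics.contact_persistency(
                    trajs, contact_sel, contact_sel, cutoff=req.contact_cutoff, allow_overlap=True
                )
                net = network.build_network(corr, contacts, params, condition=label)
                nets[label] = net
                report.tables[key] = net.edge_list()
                report.summaries[key] = dict(n_nodes=len(net.nodes), n_edges=net.n_edges)
                if req.communities:
                    part = network.detect_communities(net)
                    report.tables[f"network/{label}_communities"] = pd.DataFrame(
                        sorted(part.labels.items()), columns=["resid", "community"]
                    )
                    report.summaries[key]["modularity"] = part.modularity
            except Exception as exc:
                report.errors[key] = str(exc)
                logger.error("%s failed: %s", key, exc)
            report.timings[key] = time.perf_counter() - t0
        if req.compare and all(lab in nets for lab in req.compare):
            a, b = req.compare
            report.tables[f"network/compare_{a}_vs_{b}"] = network.compare_networks(
                nets[a], nets[b]
            )

    for preq in config.pharmacology:
        key = f"pharm/{preq.label}"
        t0 = time.perf_counter()
        try:
            dataset = io.read_dose_response(preq.path)
            if "logistic3" in preq.fits:
                fits = pharm.fit_logistic3(dataset)
                report.tables[f"{key}_logistic"] = pd.DataFrame(
                    [
                        dict(
                            group="/".join(str(g) for g in f.group),
                            pec50=f.pec50,
                            sem=f.pec50_sem,
                            summary=f.summary(),
                        )
                        for f in fits
                    ]
                )
            if "allosterism" in preq.fits:
                fit = pharm.fit_operational_allosterism(dataset, agonist=preq.agonist)
                report.summaries[f"{key}_allosterism"] = dict(
                    logab=fit.logab, logab_se=fit.logab_se, summary=fit.summary()
                )
        except Exception as exc:
            report.errors[key] = str(exc)
            logger.error("%s failed: %s", key, exc)
        report.timings[key] = time.perf_counter() - t0

    _write_report(report, out_dir)
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    for key, table in report.tables.items():
        path = out_dir / (key.replace("/", "__") + ".csv")
        table.to_csv(path, index=False, float_format="%.6g")
    payload = dict(
        provenance=report.provenance(),
        summaries=report.summaries,
        errors=report.errors,
        timings={k: round(v, 4) for k, v in report.timings.items()},
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
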