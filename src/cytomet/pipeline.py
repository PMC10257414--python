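"""End-to-end orchestration: simulate/load → debarcode → gate → per-compartment
clustering + index association → MET scoring → survival statistics, with a JSON
run manifest recording parameters, seeds, and a conservative cell-count ledger.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (TSNEParams, associate_index, embed_tsne, estimate_k,
                      pool_and_downsample, som_metacluster)
from .debarcode import BarcodeScheme, assign_barcodes, split_by_sample
from .events import EventMatrix, arcsinh_transform, concatenate, normalize_to_max
from .fcs import read_fcs, write_fcs
from .gate import GateConfig, compartment_counts, gate_events, gating_report
from .panel import MET_MARKERS, MarkerPanel, tnbc_panel
from .scores import ki67_lnr_index, met_score_cells, met_score_patient
from .simulate import CohortConfig, generate_cohort, generate_survival
from .stats import km_estimate, logrank, spearman, stratify

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Everything one run needs: inputs (or a simulation request), stage
    parameters, and the global seed."""

    out_dir: Path = Path("run")
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fcs_dir: Path | None = None
    clinical_csv: Path | None = None
    panel_yaml: Path | None = None
    barcode_yaml: Path | None = None
    sep_threshold: float = 0.3
    gate: GateConfig = field(default_factory=GateConfig)
    cofactor: float = 5.0
    compartments: tuple[str, ...] = ("cancer", "stromal")
    min_cells: int = 100
    tsne: TSNEParams | None = None        # None -> desk-scale profile from seed
    k_range: tuple[int, int] = (2, 8)
    tsne_subsample: int | None = 1_500    # cells used for k estimation
    som_grid: tuple[int, int] = (10, 10)
    hazard_coupling: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key in ("out_dir", "fcs_dir", "clinical_csv", "panel_yaml", "barcode_yaml"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig.from_dict(kwargs["cohort"])
        if "gate" in kwargs:
            g = kwargs["gate"]
            kwargs["gate"] = GateConfig(
                thresholds=g.get("thresholds", None) or GateConfig().thresholds,
                dna_window=tuple(g.get("dna_window", GateConfig().dna_window)),
            )
        if "tsne" in kwargs and kwargs["tsne"] is not None:
            kwargs["tsne"] = TSNEParams(**kwargs["tsne"])
        for key in ("compartments", "k_range", "som_grid"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.simulate:
            for key in ("fcs_dir", "clinical_csv"):
                p = getattr(self, key)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"validation failed: {key} missing or does not exist")
            if self.fcs_dir is not None and not any(Path(self.fcs_dir).glob("*.fcs")):
                raise PipelineError(f"validation failed: no .fcs files in {self.fcs_dir}")


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain; returns the run directory.

    Stage failures raise :class:`PipelineError` naming the stage; outputs of
    completed stages are retained on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def _stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                try:
                    return fn(*a, **kw)
                except Exception as exc:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return wrapped
        return deco

    # -- inputs --------------------------------------------------------------
    @_stage("input")
    def _input():
        if config.simulate:
            cohort = generate_cohort(config.cohort, out_dir=out / "input")
            return cohort.events, cohort.clinical, cohort.scheme, cohort.panel
        panel = tnbc_panel() if config.panel_yaml is None else MarkerPanel.from_file(config.panel_yaml)
        clinical = pd.read_csv(config.clinical_csv)
        files = sorted(Path(config.fcs_dir).glob("*.fcs"))
        events = {f.stem: read_fcs(f, panel) for f in files}
        if config.barcode_yaml is not None:
            scheme = BarcodeScheme.from_file(config.barcode_yaml)
        else:
            from .debarcode import default_scheme
            scheme = default_scheme(sorted(events), k=config.cohort.barcode_k,
                                    channels=panel.channels_of("barcode"))
        return events, clinical, scheme, panel

    events_by_file, clinical, scheme, panel = _input()

    # -- debarcode: pool the acquisition, assign, split ----------------------
    @_stage("debarcode")
    def _debarcode():
        pooled_raw = concatenate(list(events_by_file.values()))
        pooled = arcsinh_transform(pooled_raw, config.cofactor)
        calls = assign_barcodes(pooled, scheme, config.sep_threshold)
        samples = split_by_sample(pooled, calls)
        report = calls.report()
        _write_tsv(report, out / "debarcode_report.tsv")
        manifest["stages"]["debarcode"] = {
            "cells_in": int(pooled.n_cells),
            "assigned": int(calls.n_assigned),
            "unassigned": int(pooled.n_cells - calls.n_assigned),
            "sep_threshold": config.sep_threshold,
        }
        return samples

    samples = _debarcode()

    # -- gate ----------------------------------------------------------------
    @_stage("gate")
    def _gate():
        per_comp: dict[str, dict[str, EventMatrix]] = {c: {} for c in config.compartments}
        tallies = []
        ledger = {}
        for pid, em in samples.items():
            labels = gate_events(em, config.gate)
            rep = gating_report(labels)
            rep.insert(0, "sample", pid)
            tallies.append(rep)
            ledger[pid] = {
                "cells": int(em.n_cells),
                "live_singlets": int(labels.live_singlet.sum()),
            }
            for comp in config.compartments:
                rows = np.flatnonzero(labels.labels == comp)
                if rows.size:
                    sub = em.subset(rows)
                    sub.sample_id = pid
                    per_comp[comp][pid] = sub
        _write_tsv(pd.concat(tallies, ignore_index=True), out / "gating_report.tsv")
        manifest["stages"]["gate"] = ledger
        return per_comp

    per_comp = _gate()

    # -- cluster + index association per compartment -------------------------
    @_stage("cluster")
    def _cluster():
        results = {}
        tsne_params = config.tsne or TSNEParams.desk_scale(config.seed)
        for comp, comp_samples in per_comp.items():
            if len(comp_samples) < 2:
                log.warning("compartment %s has <2 samples; skipping clustering", comp)
                continue
            pooled = pool_and_downsample(comp_samples, config.min_cells, config.seed)
            sub = pooled
            if config.tsne_subsample and pooled.n_cells > config.tsne_subsample:
                rng = np.random.default_rng(config.seed)
                keep = rng.choice(pooled.n_cells, config.tsne_subsample, replace=False)
                from .cluster import PooledMatrix
                sub = PooledMatrix(pooled.values[keep], pooled.marker_names,
                                   pooled.patient_ids[keep], pooled.source_rows[keep],
                                   pooled.downsample_n)
            emb = embed_tsne(sub, tsne_params)
            k = estimate_k(emb, config.k_range, seed=config.seed)
            assign = som_metacluster(pooled, config.som_grid, k, seed=config.seed)
            assign = associate_index(assign, clinical)

            cdir = out / f"cluster_{comp}"
            _write_tsv(assign.to_frame(), cdir / "assignment.tsv")
            prof = assign.profiles.copy()
            prof["n"] = assign.counts
            prof["ki67_lnr_index"] = assign.index
            _write_tsv(prof.reset_index(), cdir / "profiles.tsv")
            emb_df = pd.DataFrame(emb.coords, columns=["tsne1", "tsne2"])
            emb_df["patient_id"] = sub.patient_ids
            _write_tsv(emb_df, cdir / "embedding.tsv")
            manifest["stages"].setdefault("cluster", {})[comp] = {
                "downsample_n": pooled.downsample_n,
                "n_pooled": int(pooled.n_cells),
                "k": int(k),
                "index_max_cluster": assign.index_extremes[0],
                "index_min_cluster": assign.index_extremes[1],
                "tsne": vars(tsne_params) | {"perplexity_requested": tsne_params.perplexity},
            }
            results[comp] = (pooled, assign)
        return results

    cluster_results = _cluster()

    # -- scores --------------------------------------------------------------
    @_stage("score")
    def _score():
        cancer = per_comp.get("cancer", {})
        if not cancer:
            log.warning("no cancer cells gated; skipping MET scoring")
            return None
        pooled_cancer = concatenate(list(cancer.values()))
        norm = normalize_to_max(pooled_cancer, list(MET_MARKERS))
        met_cells = met_score_cells(norm)
        met_pat = met_score_patient(met_cells, norm.sample_id)
        idx = ki67_lnr_index(clinical).set_index("patient_id")
        table = pd.DataFrame({"met": met_pat}).join(idx, how="inner")
        rho, p = spearman(table["met"], table["index"])
        _write_tsv(table.reset_index(), out / "met_scores.tsv")
        manifest["stages"]["score"] = {
            "n_cancer_cells": int(norm.n_cells),
            "n_patients": int(len(table)),
            "spearman_met_vs_index": {"rho": rho, "p": p},
        }
        return table

    met_table = _score()

    # -- survival ------------------------------------------------------------
    @_stage("survive")
    def _survive():
        if {"time", "event"}.issubset(clinical.columns):
            surv = clinical
        else:
            surv = generate_survival(clinical, config.hazard_coupling, config.seed)
        idx = ki67_lnr_index(surv)
        groups = stratify(idx["index"].to_numpy())
        times = surv["time"].to_numpy(float)
        ev = surv["event"].to_numpy(int)
        km_frames = []
        for g in ("high", "low"):
            m = groups == g
            if m.sum() == 0:
                continue
            km = km_estimate(times[m], ev[m])
            km.insert(0, "group", g)
            km_frames.append(km)
        chi2, p = logrank(times, ev, groups)
        _write_tsv(pd.concat(km_frames, ignore_index=True), out / "km_curves.tsv")
        summary = {"logrank_chi2": chi2, "logrank_p": p,
                   "n_high": int((groups == "high").sum()),
                   "n_low": int((groups == "low").sum())}
        (out / "survival_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["survive"] = summary
        surv.to_csv(out / "survival.csv", index=False)
        return summary

    _survive()

    manifest["outputs"] = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
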