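"""End-to-end pipeline: configuration, per-subject runs and cohort runs.

A :class:`PipelineConfig` fixes every analysis choice (montage, bands,
epoch scheme, filter and metric options, community seed).  For each
subject the pipeline preprocesses the recording, computes the power
spectrum summaries, the per-band PLI matrices and the graph / MST /
community metrics for the whole-head and frontotemporal node sets, and
returns tidy long-format tables.  A cohort run joins the per-subject
network features with clinical covariates and executes the statistical
stage.  Every output carries a config hash so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import community_metrics
from .connectivity import band_pli
from .graph import build_graph, network_metrics
from .montage import BANDS, FRONTOTEMPORAL, MONTAGE_25
from .mst import kruskal_mst, tree_metrics
from .preprocess import BandSpec, EEGRecording, average_reference, make_epochs
from .spectral import spectral_table
from .stats import SubjectRecord, cohort_report


@dataclass
class PipelineConfig:
    montage: tuple[str, ...] = MONTAGE_25
    bands: dict = field(default_factory=lambda: dict(BANDS))
    fs: float = 500.0
    epoch_length_s: float = 10.0
    total_s: float = 90.0
    broadband: tuple[float, float] = (0.1, 45.0)
    trim_s: float = 0.5
    cc_norm: str | None = None
    community_seed: int = 0
    node_sets: dict = field(default_factory=lambda: {
        "whole": list(MONTAGE_25),
        "frontotemporal": list(FRONTOTEMPORAL),
    })

    def __post_init__(self) -> None:
        for name, nodes in self.node_sets.items():
            unknown = [n for n in nodes if n not in self.montage]
            if unknown:
                raise ValueError(f"node set {name!r} references labels outside "
                                 f"the montage: {unknown!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["montage"] = list(d["montage"])
        d["broadband"] = list(d["broadband"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "montage" in d:
            d["montage"] = tuple(d["montage"])
        if "broadband" in d:
            d["broadband"] = tuple(d["broadband"])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_subject(config: PipelineConfig, rec: EEGRecording) -> dict[str, pd.DataFrame]:
    """Run the full per-subject analysis.

    Returns ``spectral`` (one row per band), ``pli_edges`` (long edge
    list per band) and ``metrics`` (one row per band x node_set x
    metric) tables, each tagged with the config hash.
    """
    rec = average_reference(rec)
    spect = spectral_table(rec, config.bands)

    bands = [BandSpec(n, lo, hi) for n, (lo, hi) in config.bands.items()]
    epoched = make_epochs(rec, config.epoch_length_s, config.total_s,
                          bands=bands, broadband=config.broadband)

    edge_rows, metric_rows = [], []
    for band_name, ep in epoched.items():
        cm = band_pli(ep, trim_s=config.trim_s)
        n = len(cm.labels)
        for i in range(n):
            for j in range(i + 1, n):
                edge_rows.append({
                    "subject_id": rec.subject_id, "band": band_name,
                    "node_i": cm.labels[i], "node_j": cm.labels[j],
                    "pli": cm.pli[i, j],
                })
        for set_name, nodes in config.node_sets.items():
            g = build_graph(cm, nodes, tag=set_name)
            wm = network_metrics(cm, nodes, tag=set_name, cc_norm=config.cc_norm)
            tm = tree_metrics(kruskal_mst(g), band=band_name, node_set=set_name,
                              subject_id=rec.subject_id)
            com = community_metrics(g, seed=config.community_seed,
                                    band=band_name, subject_id=rec.subject_id)
            values = {
                "mean_pli": wm.mean_pli, "cc": wm.cc, "pl": wm.pl,
                "mst_diameter": float(tm.diameter),
                "mst_diameter_norm": tm.diameter_norm,
                "mst_leaf_fraction": tm.leaf_fraction,
                "mst_bc_max": tm.bc_max,
                "mst_tree_hierarchy": tm.tree_hierarchy,
                "mst_kappa": tm.kappa,
                "modularity_q": com.q,
                "mean_pc": com.mean_pc,
                "n_modules": float(com.n_modules),
            }
            for metric, value in values.items():
                metric_rows.append({
                    "subject_id": rec.subject_id, "band": band_name,
                    "node_set": set_name, "metric": metric, "value": value,
                })

    out = {
        "spectral": spect,
        "pli_edges": pd.DataFrame(edge_rows),
        "metrics": pd.DataFrame(metric_rows),
    }
    for frame in out.values():
        frame.attrs["config_hash"] = config.hash
        frame.attrs["plinet_version"] = __version__
    return out


def features_wide(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long metrics table to one row per subject.

    Columns are named ``<metric>_<band>_<node_set>`` (e.g.
    ``mean_pli_theta_frontotemporal``).
    """
    wide = metrics.assign(
        feature=metrics["metric"] + "_" + metrics["band"] + "_" + metrics["node_set"]
    ).pivot_table(index="subject_id", columns="feature", values="value")
    wide.columns.name = None
    return wide.reset_index()


def run_cohort(
    config: PipelineConfig,
    subjects: list[tuple[EEGRecording, SubjectRecord]],
    stat_metrics: list[str] | None = None,
    regression_candidates: list[str] | None = None,
) -> dict:
    """Per-subject pipeline over a cohort plus the statistical stage.

    Returns the joined subject x feature table, the long metrics table
    and the :func:`plinet.stats.cohort_report` results.  The default
    statistical focus follows the study design: frontotemporal theta
    metrics are always tested, and the regression candidates span the
    frontotemporal network features of every band plus the clinical
    covariates.
    """
    metric_frames, records = [], []
    for rec, record in subjects:
        res = run_subject(config, rec)
        metric_frames.append(res["metrics"])
        records.append(record.to_row())
    metrics = pd.concat(metric_frames, ignore_index=True)
    wide = features_wide(metrics)
    clinical = pd.DataFrame(records)
    table = clinical.merge(wide, on="subject_id", how="left")

    if stat_metrics is None:
        stat_metrics = [
            f"{m}_theta_frontotemporal"
            for m in ("mean_pli", "cc", "pl", "mst_diameter")
        ]
    if regression_candidates is None:
        network = [
            f"{m}_{b}_frontotemporal"
            for b in config.bands
            for m in ("mean_pli", "cc", "pl", "mst_diameter")
        ]
        clinical_cands = [
            "age", "duration", "age_of_onset", "febrile_history",
            "family_history", "status_epilepticus", "aura", "generalized",
            "postictal_confusion", "seizure_duration_min", "n_asm",
        ]
        regression_candidates = [c for c in network + clinical_cands
                                 if c in table.columns]
    report = cohort_report(table, stat_metrics,
                           regression_candidates=regression_candidates)
    return {"table": table, "metrics": metrics, **report,
            "config_hash": config.hash}


def write_cohort_results(outdir: str | Path, results: dict,
                         config: PipelineConfig) -> Path:
    """Write cohort tables, regression report and a provenance log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["table"].to_csv(outdir / "subject_table.csv", index=False,
                            float_format="%.8f")
    results["metrics"].to_csv(outdir / "metrics_long.csv", index=False,
                              float_format="%.8f")
    results["group_tests"].to_csv(outdir / "group_tests.csv", index=False,
                                  float_format="%.8f")
    results["correlations"].to_csv(outdir / "correlations.csv", index=False,
                                   float_format="%.8f")
    reg = results["regression"]
    (outdir / "regression.json").write_text(json.dumps({
        "selected": reg.selected, "beta": reg.beta, "p_values": reg.p_values,
        "n_obs": reg.n_obs, "steps": reg.steps,
    }, indent=1))
    (outdir / "run_log.json").write_text(json.dumps({
        "config_hash": config.hash, "plinet_version": __version__,
        "config": config.to_dict(),
    }, indent=1))
    return outdir
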