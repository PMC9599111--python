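"""End-to-end orchestration: simulate/load -> ERSP -> PLV -> threshold ->
network -> node classes -> group comparison.

A single :class:`PipelineConfig` drives every stage; all randomness is
derived from one master seed (named sub-streams for data generation and
permutation testing), so a rerun with the same config reproduces every
table bit-identically.  Outputs are tidy CSV/TSV tables, Pajek NET
graphs, and a JSON manifest with the config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import AtlasSpec, default_atlas
from .bands import DEFAULT_BANDS, BandSpec
from .connectivity import PLVMatrix, ThresholdSpec, compute_threshold, group_plv
from .network import BrainNetwork, build_network, node_table, write_pajek
from .simulate import Coupling, GroundTruth, ParadigmSpec, TrialDataset, generate_dataset
from .spectral import ERSPResult, group_ersp
from .stats import compare_groups

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "summarize"]

DEFAULT_PAIRS = (("M-AIG", "CG"), ("F-AIG", "CG"), ("M-AIG", "F-AIG"))


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML-serialisable."""

    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    truth: GroundTruth = field(default_factory=GroundTruth)
    dataset_path: str | None = None  # real/pre-generated data; overrides simulation
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    n_perm: int = 10_000
    alpha: float = 0.05
    top_frac: float = 0.2
    seed: int = 0
    decim: int = 1
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "paradigm": {
                "baseline_window": list(self.paradigm.baseline_window),
                "cue_window": list(self.paradigm.cue_window),
                "task_window": list(self.paradigm.task_window),
                "rest_lead": self.paradigm.rest_lead,
                "sampling_rate": self.paradigm.sampling_rate,
                "group_sizes": dict(self.paradigm.group_sizes),
            },
            "truth": {
                "ersp_gain": {
                    f"{roi}|{band}|{group}": g
                    for (roi, band, group), g in sorted(self.truth.ersp_gain.items())
                },
                "coupling": [
                    [c.roi_i, c.roi_j, c.band, c.group, c.kappa] for c in self.truth.coupling
                ],
                "noise_level": self.truth.noise_level,
                "freq_jitter": self.truth.freq_jitter,
            },
            "dataset_path": self.dataset_path,
            "bands": [[b.name, b.lo, b.hi] for b in self.bands],
            "pairs": [list(p) for p in self.pairs],
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "top_frac": self.top_frac,
            "seed": self.seed,
            "decim": self.decim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        paradigm = ParadigmSpec(
            baseline_window=tuple(d["paradigm"]["baseline_window"]),
            cue_window=tuple(d["paradigm"]["cue_window"]),
            task_window=tuple(d["paradigm"]["task_window"]),
            rest_lead=float(d["paradigm"]["rest_lead"]),
            sampling_rate=float(d["paradigm"]["sampling_rate"]),
            group_sizes={k: int(v) for k, v in d["paradigm"]["group_sizes"].items()},
        ) if "paradigm" in d else ParadigmSpec()
        tr = d.get("truth", {})
        truth = GroundTruth(
            ersp_gain={
                tuple(k.split("|")): float(v) for k, v in tr.get("ersp_gain", {}).items()
            },
            coupling=tuple(
                Coupling(i, j, b, g, float(k)) for i, j, b, g, k in tr.get("coupling", [])
            ),
            noise_level=float(tr.get("noise_level", 0.3)),
            freq_jitter=float(tr.get("freq_jitter", 0.5)),
        )
        bands = tuple(
            BandSpec(name, float(lo), float(hi)) for name, lo, hi in d.get("bands", [])
        ) or DEFAULT_BANDS
        return cls(
            paradigm=paradigm,
            truth=truth,
            dataset_path=d.get("dataset_path"),
            bands=bands,
            pairs=tuple(tuple(p) for p in d.get("pairs", DEFAULT_PAIRS)),
            n_perm=int(d.get("n_perm", 10_000)),
            alpha=float(d.get("alpha", 0.05)),
            top_frac=float(d.get("top_frac", 0.2)),
            seed=int(d.get("seed", 0)),
            decim=int(d.get("decim", 1)),
            out_dir=d.get("out_dir"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    dataset: TrialDataset
    ersp: ERSPResult
    plv: dict[tuple[str, str], PLVMatrix]  # (band, group) ->
    thresholds: dict[str, ThresholdSpec]  # band ->
    networks: dict[tuple[str, str], BrainNetwork]  # (band, group) ->
    nodes: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict


def _sub_seed(master: int, name: str) -> int:
    """Named deterministic sub-seed, kept below 2**31."""
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Run every stage and (optionally) write all outputs to ``cfg.out_dir``."""
    if cfg.dataset_path:
        from .io import read_dataset

        ds = read_dataset(cfg.dataset_path)
    else:
        ds = generate_dataset(
            cfg.paradigm,
            default_atlas(),
            cfg.truth,
            seed=_sub_seed(cfg.seed, "simulate"),
            bands=cfg.bands,
        )

    ersp = group_ersp(ds, bands=cfg.bands, decim=cfg.decim)

    plv: dict[tuple[str, str], PLVMatrix] = {}
    thresholds: dict[str, ThresholdSpec] = {}
    networks: dict[tuple[str, str], BrainNetwork] = {}
    node_frames = []
    groups = tuple(ds.paradigm.group_sizes)
    for band in cfg.bands:
        per_group = group_plv(ds, band, decim=max(cfg.decim, 1))
        for g in groups:
            plv[(band.name, g)] = per_group[g]
        thresholds[band.name] = compute_threshold(
            per_group["M-AIG"], per_group["F-AIG"], per_group["CG"]
        )
        for g in groups:
            net = build_network(per_group[g], thresholds[band.name], ds.atlas)
            networks[(band.name, g)] = net
            node_frames.append(node_table(net, ersp.ersp(band.name, g), cfg.top_frac))
    nodes = pd.concat(node_frames, ignore_index=True)

    trial_activation = {
        (band.name, g): ersp.trial_activation(band.name, ds.trial_indices(g))
        for band in cfg.bands
        for g in groups
    }
    comparisons = compare_groups(
        trial_activation,
        ds.atlas,
        pairs=cfg.pairs,
        n_perm=cfg.n_perm,
        alpha=cfg.alpha,
        seed=_sub_seed(cfg.seed, "stats"),
    )

    manifest = {
        "oscinet_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "sub_seeds": {name: _sub_seed(cfg.seed, name) for name in ("simulate", "stats")},
        "n_trials": int(ds.n_trials),
        "thresholds": {
            b: {"threshold": t.threshold, "component_means": t.component_means}
            for b, t in thresholds.items()
        },
    }
    bundle = ResultsBundle(
        config=cfg,
        dataset=ds,
        ersp=ersp,
        plv=plv,
        thresholds=thresholds,
        networks=networks,
        nodes=nodes,
        comparisons=comparisons,
        manifest=manifest,
    )
    if cfg.out_dir:
        _write_bundle(bundle, Path(cfg.out_dir))
    return bundle


def _write_bundle(bundle: ResultsBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle.ersp.table.to_csv(out / "ersp.csv", index=False)
    bundle.nodes.to_csv(out / "nodes.csv", index=False)
    bundle.comparisons.to_csv(out / "comparisons.csv", index=False)
    edges = []
    for (band, group), net in bundle.networks.items():
        write_pajek(net, out / f"network_{band}_{group}.net")
        for u, v, w in net.graph.edges(data="weight"):
            edges.append((u, v, band, group, w))
    pd.DataFrame(edges, columns=["roi_i", "roi_j", "band", "group", "plv"]).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    for (band, group), m in bundle.plv.items():
        pd.DataFrame(
            m.values, index=bundle.dataset.atlas.roi_labels, columns=bundle.dataset.atlas.roi_labels
        ).to_csv(out / f"plv_{band}_{group}.csv")
    with open(out / "manifest.json", "w") as f:
        json.dump(bundle.manifest, f, indent=2, sort_keys=True)
    summarize(bundle).to_csv(out / "summary.csv", index=False)


def summarize(bundle: ResultsBundle) -> pd.DataFrame:
    """Per-network report: class counts, threshold, edges, significant ROIs.

    Class counts always sum to 130 per network.  Significant-ROI counts
    are per (band, pair) from the comparison table and attached to the
    first group of the pair.
    """
    from .network import NODE_CLASSES

    rows = []
    for (band, group), net in bundle.networks.items():
        sub = bundle.nodes[(bundle.nodes.band == band) & (bundle.nodes.group == group)]
        counts = sub.node_class.value_counts().to_dict()
        row = {
            "band": band,
            "group": group,
            "threshold": bundle.thresholds[band].threshold,
            "mean_plv": bundle.plv[(band, group)].mean_plv,
            "n_edges": net.n_edges,
        }
        for cls in NODE_CLASSES:
            row[f"n_{cls}"] = int(counts.get(cls, 0))
        comp = bundle.comparisons
        sig = comp[(comp.band == band) & comp.pair.str.startswith(f"{group}:") & comp.significant]
        row["n_significant_vs_other"] = int(len(sig))
        rows.append(row)
    return pd.DataFrame(rows)
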