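"""End-to-end orchestration: clean -> PLS -> network -> ensemble (plus
behavior / photometry / tracing stages when inputs are present), with a
seeded run manifest sufficient to rerun identically."""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import data as dio
from . import ensemble as ens
from . import network as net
from . import pls as pls_mod
from . import stats as st
from . import synth

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with a stable CRC of
    the stage name, reduced below 2**31."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    counts_path: str | None = None
    regions_path: str | None = None
    sessions_path: str | None = None
    conditions: tuple = dio.SOCIAL_CONDITIONS
    threshold_frac: float = 0.10
    n_perm: int = 500
    n_boot: int = 500
    run_ensemble: bool = True
    zone: tuple = (30.0, 30.0, 50.0, 50.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        cfg = cls(**raw)
        for attr in ("counts_path", "regions_path", "sessions_path"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        return cfg


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "parameters": {
            "threshold_frac": config.threshold_frac,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "conditions": list(config.conditions),
        },
    }

    # ---- load or simulate -------------------------------------------------
    if config.counts_path is not None:
        manifest["inputs"]["counts"] = _checksum(config.counts_path)
        ds = dio.load_activity(config.counts_path, config.regions_path)
    else:
        spec = synth.default_activity_spec(stage_seed(config.seed, "simulate"))
        ds, _ = synth.make_activity(spec)
        dio.save_activity(ds, out / "synthetic_counts.csv")
    manifest["stages"]["load"] = {
        "n_subjects": len(ds.subjects), "n_regions": len(ds.region_ids)
    }

    # ---- clean ------------------------------------------------------------
    try:
        ds_clean, report = dio.remove_outliers(ds)
        report.to_frame().to_csv(out / "outliers.tsv", sep="\t", index=False)
        ds_imp = dio.impute_condition_mean(ds_clean)
        per_subject, per_condition = dio.condition_totals(ds_imp)
        per_condition.to_csv(out / "condition_totals.csv")
        manifest["stages"]["clean"] = {"n_outliers_removed": report.n_removed}
    except Exception as e:
        raise RuntimeError(f"stage 'clean' failed: {e}") from e

    # ---- headline behavioral-style statistics on totals --------------------
    try:
        social = [c for c in config.conditions if (ds_imp.conditions == c).any()]
        groups = [
            per_subject.loc[per_subject["condition"] == c, "total"].to_numpy()
            for c in social
        ]
        stats_out = {}
        if len(groups) >= 2:
            stats_out["anova_totals"] = st.anova_oneway(groups).to_record()
        if {"HBT_ingroup", "HBT_outgroup"} <= set(social):
            a = per_subject.loc[per_subject["condition"] == "HBT_ingroup", "total"]
            b = per_subject.loc[per_subject["condition"] == "HBT_outgroup", "total"]
            stats_out["ttest_ingroup_vs_outgroup"] = st.ttest_two_sample(
                a, b
            ).to_record()
        with open(out / "totals_stats.json", "w") as f:
            json.dump(stats_out, f, indent=2)
        manifest["stages"]["totals_stats"] = list(stats_out)
    except Exception as e:
        raise RuntimeError(f"stage 'totals_stats' failed: {e}") from e

    # ---- task PLS ---------------------------------------------------------
    try:
        res = pls_mod.run_task_pls(
            ds_imp, social, n_perm=config.n_perm, n_boot=config.n_boot,
            seed=stage_seed(config.seed, "pls"),
        )
        with open(out / "pls.json", "w") as f:
            json.dump(res.to_records(), f, indent=2)
        table = pd.concat(
            {
                "salience": res.region_saliences["LV1"],
                "bootstrap_ratio": res.bootstrap_ratios["LV1"],
            },
            axis=1,
        )
        table.to_csv(out / "pls_saliences.tsv", sep="\t")
        manifest["stages"]["pls"] = {
            "lv1_p": float(res.permutation_p[0]),
            "n_reliable_lv1": sum(
                len(v) for v in pls_mod.reliable_regions(res, 1).values()
            ),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'pls' failed: {e}") from e

    # ---- networks per HBT condition ----------------------------------------
    try:
        net_summary = {}
        for cond in ("HBT_ingroup", "HBT_outgroup"):
            if not (ds_imp.conditions == cond).any():
                continue
            r, n = net.correlation_matrix(ds_imp, cond)
            network = net.threshold_network(
                r, config.threshold_frac, n, condition=cond
            )
            cent = net.centrality(network)
            hubs = net.identify_hubs(cent)
            comm = net.louvain_communities(
                network, seed=stage_seed(config.seed, f"louvain_{cond}")
            )
            net.export_edge_list(network, out / f"network_{cond}.tsv")
            cent.assign(community=pd.Series(comm)).to_csv(
                out / f"centrality_{cond}.tsv", sep="\t"
            )
            net_summary[cond] = {
                "n_edges": network.graph.number_of_edges(),
                "hubs": hubs,
            }
        manifest["stages"]["network"] = net_summary
    except Exception as e:
        raise RuntimeError(f"stage 'network' failed: {e}") from e

    # ---- ensemble ----------------------------------------------------------
    if config.run_ensemble:
        try:
            grid = ens.default_config_grid(stage_seed(config.seed, "ensemble"))
            tally = ens.run_ensemble(ds_imp, grid)
            tally.to_frame().to_csv(out / "ensemble_tally.tsv", sep="\t")
            top = tally.ratios["ingroup_only"].idxmax()
            manifest["stages"]["ensemble"] = {
                "n_configs": tally.n_configs,
                "top_ingroup_only_region": top,
                "top_ingroup_only_pct": float(tally.ratios.loc[top, "ingroup_only"]),
            }
        except Exception as e:
            raise RuntimeError(f"stage 'ensemble' failed: {e}") from e

    # ---- behavior (when session records are present) ------------------------
    if config.sessions_path is not None:
        try:
            records = bhv.load_sessions(config.sessions_path)
            openers = bhv.classify_openers(records)
            curves = bhv.opening_curves(records)
            curves.to_csv(out / "opening_curves.csv", index=False)
            mat = (
                records.pivot(index="rat_id", columns="day", values="opened_by_rat")
                .astype(float)
            )
            q = st.cochran_q(mat.to_numpy())
            lat = records.pivot(index="rat_id", columns="day", values="latency_s")
            fr = st.friedman(lat.to_numpy())
            manifest["stages"]["behavior"] = {
                "n_openers": int(openers.sum()),
                "cochran_q": q.to_record(),
                "friedman": fr.to_record(),
            }
        except Exception as e:
            raise RuntimeError(f"stage 'behavior' failed: {e}") from e

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    logger.info("pipeline complete; manifest at %s", out / "manifest.json")
    return manifest


def report(out_dir) -> str:
    """Plain-text summary of whatever stage outputs exist in *out_dir*."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("no manifest.json; run the pipeline first")
    with open(manifest_path) as f:
        manifest = json.load(f)
    lines = [
        "fosmap run report",
        "=================",
        f"seed: {manifest['seed']}",
        "",
    ]
    stages = manifest.get("stages", {})
    for name in ("load", "clean", "totals_stats", "pls", "network", "ensemble",
                 "behavior"):
        if name not in stages:
            lines.append(f"[{name}] not run")
            continue
        lines.append(f"[{name}] {json.dumps(stages[name], default=str)}")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
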