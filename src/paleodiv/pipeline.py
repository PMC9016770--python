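"""Study-shaped orchestration: clade detection, per-clade model fits across
families, and a unified comparison report.

The cross-framework table compares the best model of each trait-free family
(null/time/env/episodic/DD) by AIC and Akaike weight; Mk/stochastic-mapping
and SSE results are reported in separate sections and never merged into that
table (their likelihoods condition on different data).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bd, dd, episodic, mk, spectral, sse
from .env import read_env_csv
from .phylo import Phylogeny, parse_newick
from .selection import ModelRow, akaike_table

log = logging.getLogger("paleodiv")

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    tree: str
    traits: str | None = None
    env: dict = field(default_factory=dict)      # name -> csv path
    f: float = 0.92
    clades: str | None = None                    # clades.json path or None (auto)
    families: tuple = ("time", "env", "episodic", "dd", "mk", "sse")
    seed: int = 0
    out: str = "results/analysis"
    max_shifts: int = 2
    grid_step: float = 0.5
    n_maps: int = 200
    sse_specs: tuple | None = None               # labels subset; None = all 36
    sse_d: int = 2

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self):
        if not Path(self.tree).exists():
            raise FileNotFoundError(self.tree)
        if not (0 < self.f <= 1):
            raise ValueError("f must be in (0, 1]")
        needs_traits = {"mk", "sse"} & set(self.families)
        if needs_traits and (self.traits is None or not Path(self.traits).exists()):
            raise FileNotFoundError(
                f"trait table required for {sorted(needs_traits)}")
        for name, p in self.env.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"env curve {name}: {p}")


def detect_clades(tree: Phylogeny, seed: int = 0):
    """Spectral clade detection; returns (k*, {name: tip list})."""
    profile = spectral.laplacian_spectrum(tree)
    k = profile.suggested_k
    assign = spectral.cluster_assignment(tree, max(k, 1), seed=seed)
    clades = {}
    for g in sorted(set(assign.values())):
        tips = sorted(t for t, gg in assign.items() if gg == g)
        try:
            sub = tree.extract_clade(tips)
            clades[f"cluster_{g + 1}"] = sorted(sub.tip_labels)
        except Exception:
            mrca_tips = sorted(
                t.label for t in _subtree_tips(tree.mrca(tips)))
            clades[f"cluster_{g + 1}"] = mrca_tips
    return k, clades


def _subtree_tips(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.children:
            yield n
        else:
            stack.extend(n.children)


def _fit_tree_free_families(bt, cfg, envs):
    """Best model per trait-free family on one set of branching times."""
    out = {}
    tables = {}
    if "time" in cfg.families:
        res = bd.fit_bd_family(bt, "time", f=cfg.f, seed=cfg.seed)
        tables["time"] = bd.fit_results_table(res)
        ok = [r for r in res if r.converged]
        out["null"] = min((r for r in ok if r.label == "BCST"),
                          key=lambda r: r.aic, default=None)
        out["time"] = min((r for r in ok if r.label != "BCST"),
                          key=lambda r: r.aic, default=None)
    if "env" in cfg.families and envs:
        best_env = None
        for name, curve in envs.items():
            res = bd.fit_bd_family(bt, "env", env=curve, f=cfg.f, seed=cfg.seed)
            tables[f"env_{name}"] = bd.fit_results_table(res)
            for r in res:
                if r.converged and (best_env is None or r.aic < best_env.aic):
                    r.metadata["proxy"] = name
                    best_env = r
        out["env"] = best_env
    if "episodic" in cfg.families:
        fits = episodic.fit_shifts(bt, max_shifts=cfg.max_shifts,
                                   grid_step=cfg.grid_step, f=cfg.f,
                                   seed=cfg.seed)
        s_star = episodic.select_num_shifts(fits)
        chosen = next(d for d in fits if d["s"] == s_star)
        tables["episodic"] = pd.DataFrame(
            [{"s": d["s"], "logL": d["fit"].loglik, "AIC": d["fit"].aic,
              **d["fit"].params} for d in fits])
        out["episodic"] = chosen["fit"]
    if "dd" in cfg.families:
        res = dd.fit_dd_family(bt, f=cfg.f, seed=cfg.seed)
        rows = [ModelRow(r.label, r.n_params, r.loglik, r.aic)
                for r in res if r.converged]
        tables["dd"] = akaike_table(rows) if rows else pd.DataFrame()
        out["dd"] = min((r for r in res if r.converged),
                        key=lambda r: r.aic, default=None)
    return out, tables


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the full study-shaped analysis; returns a report dict and writes
    CSV/JSON outputs under config.out. Stage failures are recorded in the
    manifest's stage ledger; at least one failed stage marks the run failed.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {}
    report = {"stages": stages}

    tree = parse_newick(Path(config.tree).read_text())
    envs = {name: read_env_csv(p) for name, p in config.env.items()}
    traits = (mk.read_trait_tsv(config.traits, tree)
              if config.traits else None)

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
            stages[name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            return result
        except Exception as exc:  # recorded, not fatal to later stages
            log.exception("stage %s failed", name)
            stages[name] = {"status": "failed", "error": str(exc),
                            "seconds": round(time.time() - t0, 2)}
            return None

    # ---- clade detection ----
    if config.clades:
        clades = json.loads(Path(config.clades).read_text())
        k_star = len(clades)
    else:
        detected = stage("detect_clades",
                         lambda: detect_clades(tree, config.seed))
        k_star, clades = detected if detected else (1, {})
    report["k_star"] = k_star
    report["clades"] = clades
    (outdir / "clades.json").write_text(json.dumps(clades, indent=1))

    # ---- per-clade trait-free fits and the cross-framework table ----
    units = {"whole_tree": tree}
    for name, tips in clades.items():
        try:
            units[name] = tree.extract_clade(tips)
        except Exception:
            continue
    cross = {}
    for name, subtree in units.items():
        bt = subtree.branching_times()
        ltt = pd.DataFrame(subtree.ltt_points(), columns=["age_Ma", "lineages"])
        ltt.to_csv(outdir / f"ltt_{name}.csv", index=False)
        res = stage(f"fits_{name}",
                    lambda bt=bt: _fit_tree_free_families(bt, config, envs))
        if res is None:
            continue
        best, tables = res
        for fam, table in tables.items():
            table.to_csv(outdir / f"models_{name}_{fam}.csv", index=False)
        rows = [ModelRow(f"{fam}:{r.label}", r.n_params, r.loglik, r.aic)
                for fam, r in best.items() if r is not None]
        if rows:
            cmp_table = akaike_table(rows)
            cmp_table.to_csv(outdir / f"cross_framework_{name}.csv", index=False)
            cross[name] = cmp_table
    report["cross_framework"] = {
        name: table.iloc[0]["model"] for name, table in cross.items()}

    # ---- Mk + stochastic mapping ----
    if traits is not None and "mk" in config.families:
        def mk_stage():
            model, lrt_table = mk.fit_mk(tree, traits, seed=config.seed)
            lrt_table.to_csv(outdir / "mk_lrt.csv", index=False)
            marg = mk.ancestral_marginals(tree, traits, model.Q)
            pd.DataFrame(marg, columns=list(mk.STATES)).to_csv(
                outdir / "mk_ancestral_marginals.csv", index=False)
            maps = mk.stochastic_map(tree, traits, model.Q,
                                     n_maps=config.n_maps, seed=config.seed)
            summary = mk.summarize_maps(maps)
            summary.as_frame().to_csv(outdir / "simmap_counts.csv", index=False)
            pd.DataFrame({"state": list(mk.STATES),
                          "time_proportion": summary.time_proportions}
                         ).to_csv(outdir / "simmap_time.csv", index=False)
            return {"structure": model.structure,
                    "time_proportions": summary.time_proportions.tolist()}
        report["mk"] = stage("mk", mk_stage)

    # ---- SSE (separate section, never merged into the AIC table) ----
    if traits is not None and "sse" in config.families:
        def sse_stage():
            space = sse.enumerate_model_space(d=config.sse_d, f=config.f)
            if config.sse_specs:
                space = [s for s in space if s.label in set(config.sse_specs)]
            fits = [sse.fit_sse(tree, traits, s, n_starts=1, seed=config.seed)
                    for s in space]
            n = tree.n_tips
            rows = []
            for s, r in zip(space, fits):
                rows.append({"model": r.label, "dependence": s.dependence,
                             "inheritance": s.inheritance,
                             "structure": s.structure, "np": r.n_params,
                             "logL": r.loglik, "AICc": r.aicc(n),
                             "converged": r.converged})
            table = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
            table["dAICc"] = table["AICc"] - table["AICc"].min()
            w = np.exp(-0.5 * table["dAICc"])
            table["wAICc"] = w / w.sum()
            table.to_csv(outdir / "sse_models.csv", index=False)
            best_i = int(np.argmin([r.aicc(n) if r.converged else np.inf
                                    for r in fits]))
            best_spec = fits[best_i].metadata.get("fitted_spec")
            if best_spec is not None:
                probs = sse.node_state_probs(tree, traits, best_spec)
                pd.DataFrame(probs, columns=list(mk.STATES)).to_csv(
                    outdir / "sse_node_probs.csv", index=False)
            return {"best": fits[best_i].label}
        report["sse"] = stage("sse", sse_stage)

    manifest = {
        "seed": config.seed, "f": config.f, "families": list(config.families),
        "tree": str(config.tree), "n_tips": tree.n_tips,
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    report["failed"] = any(s.get("status") == "failed" for s in stages.values())
    return report
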