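"""End-to-end pipeline orchestration from a single YAML config.

A config names either the three input TSV paths or a synthetic-design block,
lists the stages to run, and gives seeds and grids. Stages run in dependency
order, write plain-text outputs (TSV / JSON-lines / newick / GraphML) into
the output directory, and the run is summarized in a JSON manifest recording
per stage the input digest, seed, outputs and wall time — identical config
and seeds give identical output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import io as rio
from . import networks as rnet
from . import ordination as rord
from . import prevalence_variance as rprev
from . import screening as rscr
from . import threshold_surface as rthr
from . import synthetic_data as rsyn

STAGES = ("prevalence", "ordination", "thresholds", "screening", "networks")


class ConfigError(ValueError):
    """Raised when a pipeline config fails schema validation."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    if "input" not in config and "synthetic" not in config:
        raise ConfigError("config needs an 'input' or a 'synthetic' block")
    if "input" in config:
        block = config["input"]
        for key in ("asv", "taxonomy", "metadata"):
            if key not in block:
                raise ConfigError(f"input block lacks '{key}' path")
            if not Path(block[key]).exists():
                raise ConfigError(f"input path does not exist: {block[key]}")
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stochastic = {"ordination", "thresholds", "screening"} & set(stages)
    if stochastic and "seed" not in config:
        raise ConfigError(f"stages {sorted(stochastic)} need a 'seed'")
    if "out_dir" not in config:
        raise ConfigError("config lacks 'out_dir'")
    return config


def _load(config: dict):
    if "input" in config:
        b = config["input"]
        return rio.load_dataset(b["asv"], b["taxonomy"], b["metadata"])
    syn = config.get("synthetic") or {}
    design = rsyn.RiverDesign(n_stations=int(syn.get("n_stations", 60)))
    signal = rsyn.default_signal(noise_sd=float(syn.get("noise_sd", 0.0)))
    return rsyn.simulate_dataset(
        design, signal,
        n_noise_taxa=int(syn.get("n_noise_taxa", 200)),
        library_size=int(syn.get("library_size", 50_000)),
        seed=int(config.get("seed", 0)),
    )


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the enabled stages and return (and write) the manifest."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    config = validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(STAGES))

    dataset = _load(config)
    hell = rio.hellinger_transform(dataset.abundance)
    manifest: dict = {"seed": seed, "stages": {}}
    state: dict = {}

    def record(name: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "seed": seed,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {p.name: _digest(p) for p in outputs},
        }

    if "prevalence" in stages:
        t0 = time.time()
        rank = config.get("prevalence", {}).get("rank", "Genus")
        n_top = int(config.get("prevalence", {}).get("n_top", 15))
        screens = rprev.screen_rank(dataset, rank, n_top)
        path = out_dir / "prevalence_screens.tsv"
        screens.to_csv(path, sep="\t")
        state["screens"] = screens
        record("prevalence", t0, [path])

    if "ordination" in stages or "thresholds" in stages:
        state["dist"] = rord.bray_curtis(hell)

    if "ordination" in stages:
        t0 = time.time()
        opts = config.get("ordination", {})
        env_cols = opts.get(
            "variables",
            [c for c in dataset.metadata.columns
             if np.issubdtype(dataset.metadata[c].dtype, np.number)
             and c not in ("station", "latent_saprobity")],
        )
        env = rio.impute_pmm(dataset.metadata[env_cols], seed=seed)
        kept = rord.vif_filter(env, threshold=float(opts.get("vif", 5.0)))
        n_perm = int(opts.get("n_perm", 199))
        selected = rord.forward_select(
            state["dist"], env[kept], alpha=float(opts.get("alpha", 0.05)),
            n_perm=n_perm, seed=seed,
        )
        outputs = [out_dir / "selected_variables.tsv"]
        with open(outputs[0], "w") as fh:
            fh.write("variable\n" + "".join(f"{v}\n" for v in selected))
        if selected:
            result = rord.dbrda(state["dist"], env[selected],
                                n_perm=n_perm, seed=seed)
            scores = out_dir / "site_scores.tsv"
            result.site_scores.to_csv(scores, sep="\t")
            eig = out_dir / "eigenvalues.tsv"
            with open(eig, "w") as fh:
                fh.write("kind\teigenvalue\n")
                for v in result.constrained_eigenvalues:
                    fh.write(f"constrained\t{v:.10g}\n")
                for v in result.unconstrained_eigenvalues:
                    fh.write(f"unconstrained\t{v:.10g}\n")
            outputs += [scores, eig]
        record("ordination", t0, outputs)

    if "thresholds" in stages:
        t0 = time.time()
        opts = config.get("thresholds", {})
        gradient = dataset.metadata[opts.get("gradient", "chl_a")]
        pairs = rthr.build_pair_set(state["dist"], gradient)
        surface = rthr.fit_surface(pairs, seed=seed)
        step = float(opts.get("grid_step", 0.1))
        grid = np.arange(gradient.min(), gradient.max() + step / 2, step)
        result = rthr.detect_thresholds(surface, grid)
        path = out_dir / "thresholds.tsv"
        with open(path, "w") as fh:
            fh.write("threshold\n" + "".join(f"{t:.6g}\n"
                                             for t in result.thresholds))
        spath = out_dir / "spanning_score.tsv"
        with open(spath, "w") as fh:
            fh.write("gradient\tspanning_score\n")
            for gval, sval in zip(result.grid, result.spanning_score):
                fh.write(f"{gval:.6g}\t{sval:.6g}\n")
        record("thresholds", t0, [path, spath])

    if "screening" in stages:
        t0 = time.time()
        opts = config.get("screening", {})
        candidates = opts.get("candidates")
        ensemble = rscr.ensemble_screen(
            dataset,
            task=opts.get("task", "status"),
            n_runs=int(opts.get("n_runs", 100)),
            seed=seed,
            candidates=candidates,
            config=rscr.ScreenConfig(
                w_grid=tuple(opts.get("w_grid", (1, 2, 3, 4, 5))),
                l_grid=tuple(opts.get("l_grid", (0, 1, 2, 3, 4, 5))),
            ),
        )
        path = out_dir / "screening_runs.jsonl"
        with open(path, "w") as fh:
            for rec in ensemble.to_records():
                fh.write(json.dumps(rec) + "\n")
        state["ensemble"] = ensemble
        record("screening", t0, [path])

    if "networks" in stages:
        if "ensemble" not in state:
            raise ConfigError("the 'networks' stage needs 'screening' output")
        t0 = time.time()
        opts = config.get("networks", {})
        pct = float(opts.get("percentile", 95.0))
        retained = rnet.select_best_models(state["ensemble"])
        outputs: list[Path] = []
        if retained and any(m.accepted for m in retained):
            pa = rnet.presence_absence(retained)
            co = rnet.build_cooccurrence(pa, pct, taxonomy=dataset.taxonomy)
            ex = rnet.build_coexclusion(pa, pct, taxonomy=dataset.taxonomy)
            for name, g in (("cooccurrence", co), ("coexclusion", ex)):
                gpath = out_dir / f"{name}.graphml"
                nx.write_graphml(g, gpath)
                epath = out_dir / f"{name}_edges.tsv"
                with open(epath, "w") as fh:
                    fh.write("u\tv\tweight\n")
                    for u, v, data in g.edges(data=True):
                        fh.write(f"{u}\t{v}\t{data.get('weight', 1)}\n")
                outputs += [gpath, epath]
            if pa.shape[1] >= 2:
                tree, freq = rnet.taxonomy_dendrogram(
                    list(pa.columns), dataset.taxonomy,
                    occurrences=pa.sum(axis=0),
                )
                npath = out_dir / "taxonomy_dendrogram.nwk"
                tree.write(str(npath))
                outputs.append(npath)
        record("networks", t0, outputs)

    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
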