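"""End-to-end orchestration: load -> filter -> scale -> per-toxin model
comparison -> per-toxin rate-shift inference -> report bundle.

Every per-toxin analysis is independent (the workflow analyses one venom
component at a time); all stochastic stages draw their seeds from the single
configured seed through a fixed splitting scheme, so a manifest plus the
inputs fully determines every output.
"""

from __future__ import annotations

import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_fit import ALL_MODELS, GridSettings, aic_weights, compare_models
from .phylo_io import (
    ExpressionTable,
    TimeTree,
    presence_filter,
    prune_to_overlap,
    read_expression_table,
    read_newick,
    scale_by_within_species_variance,
)
from .rate_shift import (
    SamplerSettings,
    Shift,
    ShiftConfiguration,
    annotated_newick,
    best_shift_configuration,
    branch_rates,
    compute_bayes_factor,
    rate_through_time,
    rjmcmc_run,
)
from .trait_sim import (
    RegimePainting,
    SimulationConfig,
    simulate_levy_traits,
    simulate_pure_birth_tree,
    simulate_shifted_bm,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a full analysis run."""

    tree_path: str = ""
    table_path: str = ""
    out_dir: str = "pulseshift_out"
    presence_min_fraction: float = 0.5
    divisor: str = "sd"
    transform: str = "none"
    toxins: list | None = None
    # model comparison
    run_fits: bool = True
    models: tuple = ALL_MODELS
    restarts: int = 10
    grid_n: int = 1024
    grid_pad: float = 6.0
    maxfun: int = 400
    selection_factor: float = 2.0
    # rate shifts
    run_shifts: bool = True
    generations: int = 2_000_000
    thin: int = 200
    expected_shifts: float = 1.0
    time_varying_rates: bool = False
    rtt_grid: int = 64
    rtt_clades: dict = field(default_factory=dict)
    seed: int = 0
    threads: int = 1

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.models, list):
            cfg.models = tuple(cfg.models)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _toxin_seed(base: int, index: int) -> int:
    return int(
        np.random.SeedSequence(base, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, toxin: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for toxin {toxin!r}: {cause}")
        self.stage = stage
        self.toxin = toxin


def _analyse_toxin(
    name: str,
    index: int,
    tree: TimeTree,
    table: ExpressionTable,
    config: AnalysisConfig,
    out: Path,
):
    t_start = time.perf_counter()
    result: dict = {"toxin": name}
    stage = "scale"
    try:
        trait = scale_by_within_species_variance(
            table, name, divisor=config.divisor, transform=config.transform
        )
        stage = "prune"
        ptree, ptrait = prune_to_overlap(tree, trait)
        seed = _toxin_seed(config.seed, index)
        if config.run_fits:
            stage = "model_fit"
            fits, comp = compare_models(
                ptree,
                ptrait,
                config.models,
                factor=config.selection_factor,
                restarts=config.restarts,
                grid=GridSettings(config.grid_n, config.grid_pad),
                maxfun=config.maxfun,
                seed=seed,
            )
            result["comparison"] = comp
            (out / "fits").mkdir(exist_ok=True)
            with open(out / "fits" / f"{name}.json", "w") as fh:
                json.dump(
                    {
                        "toxin": name,
                        "fits": [f.to_dict() for f in fits],
                        "model_weights": comp.model_weights,
                        "class_weights": comp.class_weights,
                        "selected": comp.selected,
                    },
                    fh,
                    indent=1,
                )
        if config.run_shifts:
            stage = "rate_shift"
            settings = SamplerSettings(
                generations=config.generations,
                thin=config.thin,
                expected_shifts=config.expected_shifts,
                time_varying_rates=config.time_varying_rates,
                seed=seed,
            )
            post = rjmcmc_run(ptree, ptrait, settings)
            bf = compute_bayes_factor(post)
            best = best_shift_configuration(post)
            result["bayes_factor"] = bf
            result["best_configuration"] = best
            sdir = out / "shifts"
            sdir.mkdir(exist_ok=True)
            with open(sdir / f"{name}_bf.json", "w") as fh:
                json.dump(asdict(bf), fh, indent=1)
            with open(sdir / f"{name}_best_config.json", "w") as fh:
                json.dump(
                    {
                        "root_beta": best.root_beta,
                        "root_b": best.root_b,
                        "shifts": [asdict(s) for s in best.shifts],
                    },
                    fh,
                    indent=1,
                )
            br = branch_rates(post)
            with open(sdir / f"{name}_branch_rates.tsv", "w") as fh:
                fh.write(
                    "# posterior mean branch rates (trait^2/My); branch ids "
                    "are preorder node ids of the pruned tree\n"
                )
                br.to_csv(fh, sep="\t", index=False)
            with open(sdir / f"{name}_rates.nwk", "w") as fh:
                fh.write(annotated_newick(post) + "\n")
            curves = {"all": rate_through_time(post, grid=config.rtt_grid)}
            for cname, tips in config.rtt_clades.items():
                tips_here = [t for t in tips if t in ptree.tip_labels]
                if len(tips_here) >= 2:
                    curves[cname] = rate_through_time(
                        post, clade=tips_here, grid=config.rtt_grid
                    )
            frames = []
            for cname, rtt in curves.items():
                f = rtt.to_frame()
                f.insert(0, "clade", cname)
                frames.append(f)
            with open(sdir / f"{name}_rtt.tsv", "w") as fh:
                fh.write(
                    "# rate through time: posterior mean instantaneous rate "
                    "(trait^2/My) over lineages alive at each time "
                    "(My before present); 90% credible band\n"
                )
                pd.concat(frames).to_csv(fh, sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        (out / f"FAILED_{name}").write_text(f"stage {stage}: {exc}\n")
        raise StageError(stage, name, exc) from exc
    result["runtime_s"] = time.perf_counter() - t_start
    return result


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the complete workflow; returns a report dict and writes the
    output bundle (tables, JSON sidecars, manifest) under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_all = time.perf_counter()
    logger.info("loading tree %s and table %s", config.tree_path, config.table_path)
    tree = read_newick(config.tree_path)
    table = read_expression_table(config.table_path)
    table = presence_filter(table, config.presence_min_fraction)
    toxins = [
        t for t in table.toxin_families if config.toxins is None or t in config.toxins
    ]
    logger.info("analysing %d toxins: %s", len(toxins), toxins)
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(
                pool.map(
                    lambda it: _analyse_toxin(it[1], it[0], tree, table, config, out),
                    enumerate(toxins),
                )
            )
    else:
        results = [
            _analyse_toxin(name, i, tree, table, config, out)
            for i, name in enumerate(toxins)
        ]
    report = {"toxins": toxins, "results": results}
    if config.run_fits:
        rows = []
        for res in results:
            row = {"toxin": res["toxin"]}
            row.update(res["comparison"].row())
            rows.append(row)
        comp_df = pd.DataFrame(rows)
        with open(out / "comparison.tsv", "w") as fh:
            fh.write(
                "# Akaike weights per model class (pulsed = highest weight "
                "among the six jump models); selected requires weight >= "
                f"{config.selection_factor}x every competitor\n"
            )
            comp_df.to_csv(fh, sep="\t", index=False)
        report["comparison_table"] = comp_df
    manifest = {
        "pulseshift_version": __version__,
        "numpy_version": np.__version__,
        "config": {**asdict(config), "models": list(config.models)},
        "toxins": toxins,
        "per_toxin_seconds": {r["toxin"]: r["runtime_s"] for r in results},
        "total_seconds": time.perf_counter() - t_all,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    report["manifest"] = manifest
    return report


# ----------------------------------------------------------------------
# synthetic demo bundle


DEMO_TOXINS = {
    "SVMP": "JN",
    "SVSP": "BMJN",
    "vPLA2": "NIG",
    "TFTx": "JN",
    "CTL": "BMNIG",
    "CRISP": "EBJN",
    "BPP": "BM",
    "KSPI": "OU",
    "LAAO": "EB",
    "ePLA2": "SHIFTED_BM",
}

_DEMO_PARAMS = {
    "BM": {"sigma2": 0.05},
    "OU": {"sigma2": 0.1, "alpha_ou": 0.05},
    "EB": {"sigma2": 0.2, "r": -0.05},
    "JN": {"lam": 0.05, "delta": 1.5},
    "BMJN": {"sigma2": 0.02, "lam": 0.04, "delta": 1.5},
    "NIG": {"alpha_nig": 1.5, "delta_nig": 0.08},
    "BMNIG": {"sigma2": 0.02, "alpha_nig": 1.5, "delta_nig": 0.06},
    "EBJN": {"r": -0.03, "lam": 0.06, "delta": 1.5},
}

#: clade-specific additive offsets on the latent (log-abundance-like) scale,
#: emulating the contrasting family compositions of the three venomous snake
#: families (vipers: enzymatic SVMP/SVSP/vPLA2-rich; elapids: TFTx/ePLA2-rich;
#: colubrids: CRISP/KSPI-leaning)
_CLADE_OFFSETS = {
    "Viper": {"SVMP": 2.5, "SVSP": 2.0, "vPLA2": 2.0, "BPP": 1.0, "CTL": 1.0,
              "TFTx": -2.0, "ePLA2": -2.0},
    "Elapid": {"TFTx": 3.0, "ePLA2": 2.0, "LAAO": 0.5, "SVMP": -1.0,
               "vPLA2": -1.0},
    "Colubrid": {"CRISP": 2.0, "KSPI": 1.5, "SVMP": 0.5},
}


def _relabel(tree: TimeTree, prefix: str) -> TimeTree:
    labels = list(tree.labels)
    for i, v in enumerate(tree.tip_indices, start=1):
        labels[v] = f"{prefix}_{i:02d}"
    return TimeTree(tree.parent, tree.lengths, labels)


def make_demo_tree(seed: int, n_species: int = 52) -> tuple[TimeTree, dict]:
    """Three-clade, depth-60 chronogram: a viper-like clade sister to a
    (colubrid-like, elapid-like) pair, mirroring the family structure of
    venomous snakes."""
    n_v = max(3, round(n_species * 24 / 52))
    n_e = max(3, round(n_species * 18 / 52))
    n_c = max(3, n_species - n_v - n_e)
    sub = {}
    for name, n, depth, s in (
        ("Viper", n_v, 45.0, 1),
        ("Elapid", n_e, 40.0, 2),
        ("Colubrid", n_c, 35.0, 3),
    ):
        sub[name] = _relabel(simulate_pure_birth_tree(n, depth, seed * 10 + s), name)

    def chop(t: TimeTree) -> str:
        return t.to_newick().rstrip(";")

    newick = (
        f"({chop(sub['Viper'])}:15,({chop(sub['Colubrid'])}:15,"
        f"{chop(sub['Elapid'])}:10):10);"
    )
    tree = read_newick(newick)
    clades = {name: sub[name].tip_labels for name in sub}
    return tree, clades


def make_demo_data(seed: int, out, n_species: int = 52, n_toxins: int = 10) -> dict:
    """Write a synthetic demo bundle: a three-clade 52-tip depth-60 tree and
    a relative-abundance table for 10 toxin families with a stated generating
    model per toxin (compositions via softmax of clade-offset latent traits),
    replicate transcriptomes for a handful of species, and one sparse toxin.
    Byte-identical for identical seeds."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    tree, clades = make_demo_tree(seed, n_species)
    toxins = list(DEMO_TOXINS)[:n_toxins]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    latent = {}
    shift_record = {}
    for j, name in enumerate(toxins):
        model = DEMO_TOXINS[name]
        if model == "SHIFTED_BM":
            mrca = tree.mrca(clades["Elapid"])
            cfg = ShiftConfiguration(
                root_beta=0.02,
                shifts=(Shift(int(mrca), tree.lengths[mrca] * 0.5, 0.3),),
            )
            shift_record[name] = {
                "branch": int(mrca),
                "position": float(tree.lengths[mrca] * 0.5),
                "root_beta": 0.02,
                "beta": 0.3,
            }
            trait = simulate_shifted_bm(
                tree, RegimePainting(cfg), SimulationConfig("SHIFTED_BM", seed=seed * 100 + j)
            )
        else:
            trait = simulate_levy_traits(
                tree,
                SimulationConfig(model, dict(_DEMO_PARAMS[model]), seed=seed * 100 + j),
            )
        latent[name] = trait.as_series()
    # replicate transcriptomes for a few species in each clade
    rep_species = (
        clades["Viper"][:3] + clades["Elapid"][:3] + clades["Colubrid"][:2]
    )
    rows, index = [], []
    for sp in tree.tip_labels:
        clade = sp.split("_")[0]
        n_rep = 1 + (2 if sp in rep_species[:4] else 1 if sp in rep_species else 0)
        for _ in range(n_rep):
            z = np.array(
                [
                    latent[t][sp]
                    + _CLADE_OFFSETS.get(clade, {}).get(t, 0.0)
                    + rng.normal(0.0, 0.3)
                    for t in toxins
                ]
            )
            abund = np.exp(z - z.max())
            if "BPP" in toxins and clade == "Elapid":
                abund[toxins.index("BPP")] = 0.0  # sparse toxin
            abund /= abund.sum()
            rows.append(abund)
            index.append(sp)
    table = pd.DataFrame(rows, index=index, columns=toxins).round(6)
    tree_path = out / "demo_tree.nwk"
    table_path = out / "demo_expression.tsv"
    tree_path.write_text(tree.to_newick() + "\n")
    with open(table_path, "w") as fh:
        fh.write("species\t" + "\t".join(toxins) + "\n")
        for sp, row in zip(index, rows):
            fh.write(sp + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    manifest = {
        "seed": seed,
        "n_species": n_species,
        "generating_models": {t: DEMO_TOXINS[t] for t in toxins},
        "model_params": {
            t: _DEMO_PARAMS.get(DEMO_TOXINS[t], {}) for t in toxins
        },
        "shifted_bm": shift_record,
        "clades": clades,
        "replicated_species": rep_species,
        "sparse_toxin": "BPP" if "BPP" in toxins else None,
    }
    with open(out / "demo_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {
        "tree": str(tree_path),
        "table": str(table_path),
        "manifest": str(out / "demo_manifest.json"),
        "clades": clades,
    }
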