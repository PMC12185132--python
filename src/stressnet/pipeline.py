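"""End-to-end pipeline: simulate -> preprocess -> infer -> networks ->
compare -> enrich, with a flat sectioned config, per-stage derived seeds,
and a JSON manifest of produced files.

All randomness flows from one global seed: each stage derives its own
seed by hashing the stage name into the global seed, so stages are
individually reproducible and a rerun with the same config produces
byte-identical TSV outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import enrich as enrich_mod
from . import ggm, io, netops, preprocess, synth
from .containers import ExpressionMatrix, SampleTable

#: Stage defaults; the config file may override any of these, unknown keys
#: are rejected.  Types are inferred from the default values.
DEFAULTS: dict[str, dict] = {
    "global": {"seed": 42, "out_dir": "stressnet_run", "log_level": "INFO"},
    "simulate": {
        "p": 30,
        "k": 3,
        "n_per_condition": 120,
        "shared_density": 0.1,
        "specific_density": 0.05,
        "magnitude": 0.3,
        "dispersion": 0.1,
        "batch_offset": 0.5,
        "libsize_low": 5e5,
        "libsize_high": 2e6,
        "go_terms": 6,
    },
    "preprocess": {
        "cpm_threshold": 10.0,
        "sample_fraction": 0.3,
        "require_go_bp": True,
        "log_prior": 0.5,
    },
    "infer": {
        "grid": "0.01,0.03,0.05",
        "adaptive": True,
        "alpha": 0.05,
        "max_iter": 100,
        "tol": 0.001,
        "rho": 1.0,
    },
    "networks": {"tau": 0.05, "top_hubs": 10},
    "compare": {"hogs": 40, "conserved_fraction": 0.2, "panel_edges": 40},
    "enrich": {"min_size": 10, "max_size": 500, "p_cut": 0.05, "q_cut": 0.05},
}

STAGE_ORDER = ["simulate", "preprocess", "infer", "networks", "compare", "enrich"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed from the global seed and the stage name (stable hash)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Validated pipeline configuration (sections of key-value pairs)."""

    sections: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {sec: dict(vals) for sec, vals in DEFAULTS.items()}
        for sec, vals in self.sections.items():
            if sec not in DEFAULTS:
                raise ValueError(f"unknown config section {sec!r}")
            for key, value in vals.items():
                if key not in DEFAULTS[sec]:
                    raise ValueError(f"unknown config key {sec}.{key}")
                default = DEFAULTS[sec][key]
                if isinstance(default, bool):
                    value = str(value).strip().lower() in ("1", "true", "yes", "on")
                elif isinstance(default, int):
                    value = int(value)
                elif isinstance(default, float):
                    value = float(value)
                else:
                    value = str(value)
                merged[sec][key] = value
        self.sections = merged

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        return cls({sec: dict(parser[sec]) for sec in parser.sections()})

    def to_file(self, path) -> None:
        parser = configparser.ConfigParser()
        for sec in sorted(self.sections):
            parser[sec] = {k: str(v) for k, v in sorted(self.sections[sec].items())}
        with open(path, "w") as fh:
            parser.write(fh)

    def param_hash(self, section: str) -> str:
        blob = json.dumps(self.sections[section], sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _grid(text: str) -> list[float]:
    return [float(x) for x in str(text).split(",") if x.strip()]


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Execute all stages in order; returns the manifest (also written to
    ``manifest.json``).  A failing stage aborts with a
    :class:`StageFailure`; partial outputs gain a ``.partial`` marker."""
    out = Path(out_dir or config["global"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config_snapshot.ini")
    seed = config["global"]["seed"]
    manifest: dict = {"seed": seed, "stages": {}}
    state: dict = {}

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "files": sorted(f.name for f in files),
            "param_hash": config.param_hash(stage) if stage in DEFAULTS else "",
        }

    def run_stage(stage: str, fn) -> None:
        try:
            files = fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            (out / f"{stage}.partial").touch()
            raise StageFailure(stage, exc) from exc
        record(stage, files)

    # -- simulate -----------------------------------------------------------
    def _simulate() -> list[Path]:
        sc = config["simulate"]
        truth = synth.make_precision_set(
            p=sc["p"], K=sc["k"],
            shared_density=sc["shared_density"],
            specific_density=sc["specific_density"],
            magnitude=sc["magnitude"],
            seed=derive_seed(seed, "simulate"),
        )
        counts, samples = synth.simulate_expression(
            truth,
            n_per_condition=[sc["n_per_condition"]] * sc["k"],
            batch_offsets={"batch1": 0.0, "batch2": sc["batch_offset"]},
            libsize_range=(sc["libsize_low"], sc["libsize_high"]),
            dispersion=sc["dispersion"],
            seed=derive_seed(seed, "simulate.expression"),
        )
        go_map = synth.simulate_go_annotations(
            counts.gene_ids, n_terms=sc["go_terms"],
            seed=derive_seed(seed, "simulate.go"),
        )
        io.write_counts_tsv(counts, out / "counts.tsv")
        io.write_metadata_tsv(samples, out / "metadata.tsv")
        io.write_go_tsv(go_map, out / "go_map.tsv")
        io.write_truth_json(truth, out / "truth.json")
        state.update(truth=truth, counts=counts, samples=samples, go_map=go_map)
        return [out / f for f in
                ("counts.tsv", "metadata.tsv", "go_map.tsv", "truth.json")]

    # -- preprocess ---------------------------------------------------------
    def _preprocess() -> list[Path]:
        pc = config["preprocess"]
        cfg = preprocess.GeneFilterConfig(
            cpm_threshold=pc["cpm_threshold"],
            sample_fraction=pc["sample_fraction"],
            require_go_bp=pc["require_go_bp"],
            log_prior=pc["log_prior"],
        )
        standardized, dropped = preprocess.run_preprocess(
            state["counts"], state["samples"], cfg, state["go_map"]
        )
        standardized.values.to_csv(out / "standardized.tsv", sep="\t",
                                   index_label="gene", float_format="%.10g")
        (out / "dropped_genes.txt").write_text("\n".join(dropped) + ("\n" if dropped else ""))
        state["standardized"] = standardized
        return [out / "standardized.tsv", out / "dropped_genes.txt"]

    # -- infer --------------------------------------------------------------
    def _infer() -> list[Path]:
        ic = config["infer"]
        cfg = ggm.PenaltyConfig(
            grid=_grid(ic["grid"]), adaptive=ic["adaptive"],
            screening_alpha=ic["alpha"], admm_max_iter=ic["max_iter"],
            admm_tol=ic["tol"], admm_rho=ic["rho"],
            truncation=config["networks"]["tau"],
        )
        best, table, weights = ggm.infer_networks_input(
            state["standardized"], state["samples"], cfg
        )
        io.write_precision_h5(best, out / "precision.h5")
        io.write_precision_tsv(best, out / "precision_edges.tsv")
        table.to_csv(out / "aic_table.tsv", sep="\t", index=False,
                     float_format="%.10g")
        state.update(fit=best, weights=weights)
        return [out / f for f in
                ("precision.h5", "precision_edges.tsv", "aic_table.tsv")]

    # -- networks -----------------------------------------------------------
    def _networks() -> list[Path]:
        nc = config["networks"]
        nets = netops.networks_from_precision_set(
            state["fit"], tau=nc["tau"], species="synthetic"
        )
        files = []
        for cond, net in nets.items():
            f = out / f"network_{cond}.tsv"
            io.write_network_tsv(net, f)
            files.append(f)
        union = netops.union_conditions(list(nets.values()))
        io.write_network_tsv(union, out / "network_union.tsv")
        stats = {
            cond: netops.network_stats(net, top_n=nc["top_hubs"])
            for cond, net in {**nets, "union": union}.items()
        }
        (out / "network_stats.json").write_text(json.dumps(stats, indent=1,
                                                           sort_keys=True))
        state.update(nets=nets, union=union)
        return files + [out / "network_union.tsv", out / "network_stats.json"]

    # -- compare ------------------------------------------------------------
    def _compare() -> list[Path]:
        cc = config["compare"]
        panel = synth.make_species_panel(
            hogs=cc["hogs"], conserved_fraction=cc["conserved_fraction"],
            n_edges=cc["panel_edges"], seed=derive_seed(seed, "compare"),
        )
        netops_nets = []
        for sp in panel.species:
            per_condition = []
            for cond, edges in panel.edge_lists[sp].items():
                import networkx as nx

                g = nx.Graph()
                for a, b in edges:
                    g.add_edge(a, b, weight=1.0)
                per_condition.append(
                    netops.Network(species=sp, condition=cond, graph=g)
                )
            hog_net = netops.merge_hog_networks(
                [netops.project_to_hogs(n, panel.hog_maps[sp]) for n in per_condition]
            )
            netops_nets.append(hog_net)
        merged = netops.merge_hog_networks(netops_nets)
        clade_map = dict(synth.DEFAULT_CLADE_MAP)
        labels = netops.classify_network(merged, clade_map)
        rows = [
            {"hog_a": a, "hog_b": b, "label": lab.value}
            for (a, b), lab in sorted(labels.items())
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "conservation.tsv", sep="\t", index=False)
        netops.clade_sharing_tallies(merged, clade_map).to_csv(
            out / "clade_tallies.tsv", sep="\t", index=False
        )
        io.write_hog_network_tsv(merged, out / "hog_network.tsv")
        io.write_clade_map(clade_map, out / "clades.tsv")
        netops.write_hog_map(panel.hog_maps, out / "N0.tsv")
        state.update(panel=panel, merged=merged, labels=labels)
        return [out / f for f in ("conservation.tsv", "clade_tallies.tsv",
                                  "hog_network.tsv", "clades.tsv", "N0.tsv")]

    # -- enrich -------------------------------------------------------------
    def _enrich() -> list[Path]:
        ec = config["enrich"]
        union = state["union"]
        stats = netops.network_stats(union, top_n=1)
        background = sorted(union.nodes)
        if stats["hubs"] and stats["hubs"][0][1] > 0:
            hub = stats["hubs"][0][0]
            query = netops.neighborhood_of_set(union, [hub])
        else:
            query = []
        # background-restricted GO map; small synthetic term pool so sizes fit
        go_map = {g: t for g, t in state["go_map"].items() if g in set(background)}
        results = []
        if query and go_map:
            results = enrich_mod.ora(
                query, background, go_map,
                min_size=ec["min_size"], max_size=ec["max_size"],
                p_cut=ec["p_cut"], q_cut=ec["q_cut"],
            )
        enrich_mod.results_table(results).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
        )
        return [out / "enrichment.tsv"]

    stage_fns = {
        "simulate": _simulate,
        "preprocess": _preprocess,
        "infer": _infer,
        "networks": _networks,
        "compare": _compare,
        "enrich": _enrich,
    }
    for stage in STAGE_ORDER:
        run_stage(stage, stage_fns[stage])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_all_from_files(
    counts_path, metadata_path, go_path, config: RunConfig, out_dir
) -> dict:
    """Variant of :func:`run_all` starting from user-supplied input files
    (skips the simulate stage)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts_tsv(counts_path)
    samples = io.read_metadata_tsv(metadata_path)
    go_map = io.read_go_map(go_path) if go_path else {}
    pc = config["preprocess"]
    cfg = preprocess.GeneFilterConfig(
        cpm_threshold=pc["cpm_threshold"], sample_fraction=pc["sample_fraction"],
        require_go_bp=pc["require_go_bp"], log_prior=pc["log_prior"],
    )
    standardized, _ = preprocess.run_preprocess(counts, samples, cfg, go_map)
    ic = config["infer"]
    pcfg = ggm.PenaltyConfig(
        grid=_grid(ic["grid"]), adaptive=ic["adaptive"],
        screening_alpha=ic["alpha"], admm_max_iter=ic["max_iter"],
        admm_tol=ic["tol"], admm_rho=ic["rho"],
        truncation=config["networks"]["tau"],
    )
    best, table, _ = ggm.infer_networks_input(standardized, samples, pcfg)
    io.write_precision_h5(best, out / "precision.h5")
    table.to_csv(out / "aic_table.tsv", sep="\t", index=False)
    nets = netops.networks_from_precision_set(best, tau=config["networks"]["tau"])
    for cond, net in nets.items():
        io.write_network_tsv(net, out / f"network_{cond}.tsv")
    union = netops.union_conditions(list(nets.values()))
    io.write_network_tsv(union, out / "network_union.tsv")
    return {"out": str(out)}
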