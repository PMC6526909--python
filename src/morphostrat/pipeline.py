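"""End-to-end orchestration: matrix → search → consensus → indices →
supports → time-scaling/SCI → diversity curves → pulse detection.

A run is driven by a plain YAML config (see :func:`default_config` for the
full set of keys and their defaults; every default is echoed into the
manifest so a bare config is auditable).  Outputs are plain text; the
manifest records package versions, the fully resolved config, the seed and
a SHA-256 checksum of every output file, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import detect_pulses, diversity_curve
from .errors import MorphostratError, ValidationError
from .io import read_ages, read_matrix, read_trees, write_ages, write_matrix, write_trees
from .parsimony import ensemble_indices, format_indices, mpr_states
from .search import SearchConfig, search_mpt, strict_consensus
from .strat import sci, timescale
from .support import ResamplingConfig, bootstrap_support, symmetric_resampling
from .simulate import paper_shaped

log = logging.getLogger("morphostrat.pipeline")

__all__ = ["default_config", "load_config", "run_pipeline"]


def default_config() -> dict:
    return {
        "seed": None,  # mandatory
        "outdir": "morphostrat_run",
        "simulate": {"preset": None},  # "paper-shaped" or None to load inputs
        "inputs": {"matrix": None, "ages": None, "trees": None},
        "search": {
            "enabled": True,
            "n_starts": 1,
            "swap": "nni",
            "ratchet_iterations": 1,
            "ratchet_perturb_fraction": 0.25,
            "max_saved_trees": 20,
        },
        "support": {
            "enabled": True,
            "method": "bootstrap",
            "replicates": 5,
            "change_probability": 0.33,
            "n_starts": 1,
            "swap": "nni",
        },
        "sci": {"enabled": True, "min_branch": 0.0},
        "ancestral": {"enabled": True, "char": 0},
        "ltt": {
            "enabled": True,
            "bin_width": 1.0,
            "t_oldest": None,
            "min_rise": 3,
            "max_span": 3.0,
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_config(), user)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _write_tsv(path: Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict) -> dict:
    """Execute all enabled stages in order; returns the run manifest."""
    config = _merge(default_config(), config)
    if config["seed"] is None:
        raise ValidationError("config must set an integer seed")
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    stage = "setup"

    def emit(stage_name: str, path: Path):
        outputs.setdefault(stage_name, []).append(path.name)

    try:
        # -- stage: inputs ------------------------------------------------
        stage = "simulate" if config["simulate"]["preset"] else "load_inputs"
        ts_truth = None
        if config["simulate"]["preset"]:
            preset = config["simulate"]["preset"]
            if preset not in ("paper-shaped",):
                raise ValidationError(f"unknown simulate preset: {preset}")
            sim = paper_shaped(seed)
            matrix, ages, ts_truth = sim["matrix"], sim["ages"], sim["tree"]
            write_matrix(matrix, outdir / "matrix.nex")
            write_ages(ages, outdir / "ages.csv")
            write_trees([ts_truth], outdir / "true_tree.nwk", lengths=True)
            _write_json(outdir / "truth.json", sim["truth"]["tree"].to_json_dict())
            for name in ("matrix.nex", "ages.csv", "true_tree.nwk", "truth.json"):
                emit(stage, outdir / name)
        else:
            paths = config["inputs"]
            if not paths.get("matrix"):
                raise ValidationError("config needs inputs.matrix or a simulate preset")
            matrix = read_matrix(paths["matrix"])
            ages = read_ages(paths["ages"]) if paths.get("ages") else None
        log.info("[%s] matrix %d x %d", stage, matrix.n_taxa, matrix.n_chars)

        # -- stage: search ------------------------------------------------
        best_trees = None
        consensus = None
        if config["search"]["enabled"]:
            stage = "tree_search"
            sc = config["search"]
            search_cfg = SearchConfig(
                seed=seed,
                n_starts=sc["n_starts"],
                swap=sc["swap"],
                ratchet_iterations=sc["ratchet_iterations"],
                ratchet_perturb_fraction=sc["ratchet_perturb_fraction"],
                max_saved_trees=sc["max_saved_trees"],
            )
            best_len, best_trees = search_mpt(matrix, search_cfg)
            write_trees(best_trees, outdir / "best_trees.nex", format="nexus")
            consensus = strict_consensus(best_trees)
            write_trees([consensus], outdir / "consensus.nwk")
            _write_json(
                outdir / "search.json",
                {"best_length": best_len, "n_trees": len(best_trees)},
            )
            for name in ("best_trees.nex", "consensus.nwk", "search.json"):
                emit(stage, outdir / name)
            log.info("[%s] best length %d (%d trees)", stage, best_len, len(best_trees))

            # -- stage: indices -------------------------------------------
            stage = "parsimony_indices"
            report = ensemble_indices(best_trees[0], matrix)
            _write_json(outdir / "indices.json", format_indices(report))
            _write_tsv(outdir / "indices.tsv", report.to_rows())
            emit(stage, outdir / "indices.json")
            emit(stage, outdir / "indices.tsv")

            # -- stage: support -------------------------------------------
            if config["support"]["enabled"]:
                stage = "resampling_support"
                sp = config["support"]
                rep_search = SearchConfig(
                    seed=0,
                    n_starts=sp["n_starts"],
                    swap=sp["swap"],
                    ratchet_iterations=0,
                )
                rcfg = ResamplingConfig(
                    method=sp["method"],
                    seed=seed + 1,
                    replicates=sp["replicates"],
                    change_probability=sp["change_probability"],
                    search=rep_search,
                )
                fn = bootstrap_support if sp["method"] == "bootstrap" else symmetric_resampling
                table = fn(matrix, consensus, rcfg)
                _write_tsv(outdir / f"support_{sp['method']}.tsv", table.to_rows())
                emit(stage, outdir / f"support_{sp['method']}.tsv")

        # -- stage: stratigraphic congruence ------------------------------
        ts_tree = None
        if config["sci"]["enabled"]:
            stage = "strat_congruence"
            if ages is None:
                raise ValidationError(
                    "strat_congruence stage enabled but no ages file configured"
                )
            tree_for_sci = best_trees[0] if best_trees else None
            if tree_for_sci is None:
                tree_paths = config["inputs"].get("trees")
                if not tree_paths:
                    raise ValidationError(
                        "strat_congruence needs a tree: enable search or set inputs.trees"
                    )
                tree_for_sci = read_trees(tree_paths)[0]
            report = sci(tree_for_sci, ages)
            ts_tree = timescale(tree_for_sci, ages, config["sci"]["min_branch"])
            _write_json(
                outdir / "sci.json",
                {
                    "consistent": report.consistent,
                    "total": report.total,
                    "sci": report.sci,
                    "sci_display": report.sci_display,
                },
            )
            rows = [
                {
                    "node": node.label or "",
                    "age": node.age,
                    "ghost": ts_tree.ghost(node),
                }
                for node in ts_tree.postorder()
                if node.parent is not None
            ]
            _write_tsv(outdir / "timescaled_nodes.tsv", rows)
            write_trees([ts_tree], outdir / "timescaled.nwk", lengths=True)
            for name in ("sci.json", "timescaled_nodes.tsv", "timescaled.nwk"):
                emit(stage, outdir / name)
            log.info("[%s] SCI %d/%d = %.2f", stage, report.consistent, report.total, report.sci)

            # -- stage: ancestral states ----------------------------------
            if config["ancestral"]["enabled"] and tree_for_sci.is_binary():
                stage = "ancestral_states"
                char = int(config["ancestral"]["char"])
                anc = mpr_states(tree_for_sci, matrix, char)
                rows = [
                    {
                        "node": node.label or "",
                        "tip": node.is_tip,
                        "mpr_states": "".join(str(s) for s in sorted(states)),
                    }
                    for node, states in anc.states.items()
                ]
                _write_tsv(outdir / "ancestral_mpr.tsv", rows)
                emit(stage, outdir / "ancestral_mpr.tsv")

        # -- stage: diversity through time --------------------------------
        if config["ltt"]["enabled"]:
            stage = "paleodiversity"
            if ts_tree is None:
                raise ValidationError(
                    "paleodiversity needs the strat_congruence stage (a time-scaled tree)"
                )
            lt = config["ltt"]
            curve = diversity_curve(
                ts_tree,
                bin_width=lt["bin_width"],
                t_oldest=lt["t_oldest"],
            )
            events = detect_pulses(curve, lt["min_rise"], lt["max_span"])
            _write_tsv(outdir / "ltt.tsv", curve.to_rows())
            _write_tsv(
                outdir / "events.tsv",
                [
                    {"start": e.start, "end": e.end, "rise": e.rise, "label": e.label}
                    for e in events
                ]
                or [{"start": None, "end": None, "rise": None, "label": None}],
            )
            emit(stage, outdir / "ltt.tsv")
            emit(stage, outdir / "events.tsv")

    except MorphostratError as exc:
        raise MorphostratError(f"pipeline aborted in stage {stage}: {exc}") from exc

    # -- manifest ---------------------------------------------------------
    manifest = {
        "package": "morphostrat",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": list(outputs),
        "outputs": {
            stage_name: {name: _sha256(Path(config["outdir"]) / name) for name in names}
            for stage_name, names in outputs.items()
        },
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
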