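"""Config-driven orchestration of the full selection pipeline.

Stages: pre-filtering -> pairwise table (built once per dataset and cached
by dataset/evaluator hash) -> original and/or modified selectors ->
accuracy profile.  Every intermediate artifact is plain delimited text and
a run manifest records the config hash, seed and stage provenance, so a
rerun with an unchanged config and cache skips the expensive table stage
and reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import base_selectors, modified_selectors
from ._eval import CLASSIFIERS, EvalConfig
from .core_io import (
    Dataset,
    DiscretizationSpec,
    Ranking,
    load_dataset,
    read_pair_table,
    save_dataset,
    write_pair_table,
)
from .evaluation import accuracy_profile
from .pairtable import build_pair_table
from .prefilter import prefilter_top_n
from .synthetic import SyntheticSpec, generate

log = logging.getLogger("pairfs")

__all__ = ["ConfigError", "run_pipeline"]

SEARCH_METHODS = ("forward", "backward", "mrmr")
ALL_METHODS = tuple(modified_selectors.FILTERS) + SEARCH_METHODS


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message carries the field path."""


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def _eval_config(section: Mapping[str, Any], path: str, seed: int) -> EvalConfig:
    clf = section.get("classifier", "svm_linear")
    _require(clf in CLASSIFIERS, f"{path}.classifier",
             f"unknown classifier {clf!r}")
    cv = section.get("cv", "loocv")
    _require(cv in ("loocv", "stratified_kfold"), f"{path}.cv",
             f"unknown cv {cv!r}")
    return EvalConfig(classifier=clf, params=dict(section.get("params", {})),
                      cv=cv, n_folds=int(section.get("n_folds", 5)),
                      seed=seed)


def _hash(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _dataset_hash(ds: Dataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ds.values).tobytes())
    h.update(",".join(map(str, ds.labels)).encode())
    h.update(",".join(ds.feature_names).encode())
    return h.hexdigest()[:16]


def validate_config(config: Mapping[str, Any]) -> None:
    _require("dataset" in config or "synthetic" in config, "dataset",
             "config needs a 'dataset' path or a 'synthetic' spec")
    methods = config.get("methods", [])
    _require(bool(methods), "methods", "at least one method required")
    any_modified = False
    for k, m in enumerate(methods):
        name = m.get("name")
        _require(name in ALL_METHODS, f"methods[{k}].name",
                 f"unknown method {name!r}; choose from {sorted(ALL_METHODS)}")
        any_modified = any_modified or bool(m.get("modified", False))
    if any_modified:
        _require("table" in config, "table",
                 "modified methods need a 'table' section (build or path)")


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Execute the configured pipeline and return the artifact directory."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict[str, Any] = {
        "config_hash": _hash(dict(config)),
        "seed": seed,
        "stages": {},
    }

    # ---- input -----------------------------------------------------------
    if "dataset" in config:
        ds = load_dataset(config["dataset"],
                          config.get("label_column", "class"),
                          config.get("delimiter", ","))
    else:
        spec = SyntheticSpec(**{**config["synthetic"], "seed": seed})
        ds, roles = generate(spec)
        with (out / "roles.csv").open("w") as fh:
            fh.write("feature,role\n")
            for name in ds.feature_names:
                fh.write(f"{name},{roles[name]}\n")
    manifest["dataset_hash"] = _dataset_hash(ds)
    log.info("dataset: %d samples x %d features, %d classes",
             ds.n_samples, ds.n_features, len(ds.classes))

    disc = DiscretizationSpec(
        n_bins=int(config.get("bins", 5)),
        strategy=config.get("bin_strategy", "equal_frequency"),
    )

    # ---- prefilter -------------------------------------------------------
    pf = config.get("prefilter")
    if pf:
        n = int(pf.get("n", 1000))
        _require(1 <= n <= ds.n_features, "prefilter.n",
                 f"must be in 1..{ds.n_features}")
        ds, kept = prefilter_top_n(ds, n, disc)
        save_dataset(ds, out / "prefiltered.csv")
        manifest["stages"]["prefilter"] = {"n": n}
        log.info("prefilter kept %d features", n)

    # ---- pair table ------------------------------------------------------
    pt = None
    table_cfg = config.get("table")
    if table_cfg is not None:
        table_path = Path(table_cfg.get("path", out / "combn.csv"))
        cfg = _eval_config(table_cfg, "table", seed)
        cache_key = {"dataset": manifest["dataset_hash"],
                     "eval": cfg.describe()}
        cache_file = table_path.with_suffix(".key.json")
        cached = (
            table_path.exists() and cache_file.exists()
            and json.loads(cache_file.read_text()) == cache_key
        )
        if cached:
            pt = read_pair_table(table_path)
            manifest["stages"]["table"] = {"status": "cached",
                                           "path": str(table_path)}
            log.info("pair table loaded from cache: %s", table_path)
        else:
            pt = build_pair_table(ds, cfg,
                                  workers=int(table_cfg.get("workers", 1)))
            write_pair_table(pt, table_path)
            cache_file.write_text(json.dumps(cache_key, sort_keys=True))
            manifest["stages"]["table"] = {"status": "built",
                                           "rows": len(pt),
                                           "path": str(table_path)}
            log.info("pair table built: %d rows", len(pt))

    # ---- selectors -------------------------------------------------------
    t = int(config.get("top_pairs", modified_selectors.DEFAULT_TOP_PAIRS))
    eval_cfg = _eval_config(config.get("search_eval", {}), "search_eval", seed)
    rankings: dict[str, Ranking] = {}
    for m in config["methods"]:
        name, modified = m["name"], bool(m.get("modified", False))
        label = f"{'modified_' if modified else ''}{name}"
        kwargs = {}
        if name in ("chi2", "gain_ratio"):
            kwargs["disc"] = disc
        if name == "relief" and "k_neighbors" in m:
            kwargs["k_neighbors"] = int(m["k_neighbors"])
        if name == "fsdd" and "beta" in m:
            kwargs["beta"] = float(m["beta"])
        if name in modified_selectors.FILTERS:
            if modified:
                rk = modified_selectors.modified_filter_rank(
                    ds, name, pt, t, **kwargs)
            else:
                rk = modified_selectors.FILTERS[name](ds, **kwargs)
            rankings[label] = rk
        elif name == "mrmr":
            mm = int(m.get("m", min(30, ds.n_features)))
            rk = (modified_selectors.modified_mrmr(ds, disc, pt, t, mm)
                  if modified else base_selectors.mrmr_rank(ds, disc, mm))
            rankings[label] = rk
        else:  # forward / backward
            if name == "forward":
                res = (modified_selectors.modified_forward_search(
                            ds, pt, t, eval_cfg)
                       if modified else
                       base_selectors.forward_search(ds, eval_cfg))
            else:
                res = (modified_selectors.modified_backward_elimination(
                            ds, pt, t, eval_cfg)
                       if modified else
                       base_selectors.backward_elimination(ds, eval_cfg))
            rk = Ranking(order=np.array(res.chosen, dtype=int))
            rankings[label] = rk
            with (out / f"trace_{label}.json").open("w") as fh:
                json.dump([{"action": s.action,
                            "features": [ds.feature_names[f]
                                         for f in s.features],
                            "accuracy": s.accuracy} for s in res.trace],
                          fh, indent=1)
        with (out / f"ranking_{label}.csv").open("w") as fh:
            fh.write("feature,score\n")
            scores = rk.scores if rk.scores is not None else [""] * len(rk)
            for f, s in zip(rk.order, scores):
                sv = f"{s:.6f}" if s != "" else ""
                fh.write(f"{ds.feature_names[f]},{sv}\n")
        manifest["stages"][label] = {"n_selected": len(rk)}
        log.info("%s selected %d features", label, len(rk))

    # ---- evaluation ------------------------------------------------------
    ev = config.get("evaluate")
    if ev:
        counts = [int(c) for c in ev.get("counts", [5, 10, 15, 20, 25, 30])]
        classifiers = {
            name: _eval_config({"classifier": name, **(opts or {})},
                               f"evaluate.classifiers.{name}", seed)
            for name, opts in ev.get(
                "classifiers", {"knn": {"params": {"k": 3}},
                                "svm_linear": {}}).items()
        }
        # a wrapper search may select fewer features than the largest count;
        # clip the count grid to what every ranking can supply
        shortest = min(len(rk) for rk in rankings.values())
        used_counts = [c for c in counts if c <= shortest] or [shortest]
        prof = accuracy_profile(ds, rankings, used_counts, classifiers)
        prof.to_csv(out / "profile.csv", float_format="%.6f")
        manifest["stages"]["evaluate"] = {"counts": counts}

    manifest["versions"] = _versions()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out


def _versions() -> dict[str, str]:
    import sklearn

    from . import __version__

    return {"pairfs": __version__, "numpy": np.__version__,
            "sklearn": sklearn.__version__}
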