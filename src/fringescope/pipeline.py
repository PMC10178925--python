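"""End-to-end orchestration: load or simulate, score, ordinate, network.

``run_pipeline`` executes the full analysis in a fixed stage order —
load/simulate → LDA scoring and fringe calls → depth normalization →
Shannon + geochemical Pearson matrix + class aggregation → Bray-Curtis →
NMDS → envfit → RDA → CCA fringe-group test → ASV filter → co-occurrence
network → Louvain cliques → node/clique geochemistry correlations — and
writes every stage's table plus a machine-readable manifest.

All randomness flows from one root seed, expanded per stage through
``numpy`` seed sequences keyed on the stage name, so any stage rerun in
isolation reproduces its output.
"""

from __future__ import annotations

import datetime
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    aggregate_by_class,
    bray_curtis,
    group_shannon_test,
    normalize_counts,
    pearson_matrix,
    shannon_per_sample,
)
from .data_model import Dataset, load_dataset
from .lda import (
    LDAModel,
    call_fringe,
    published_model,
    score_table,
    select_threshold,
    train_lda,
)
from .network import (
    build_network,
    filter_asvs,
    louvain,
    node_geochem_correlation,
)
from .ordination import cca_group_test, envfit, nmds, rda_contribution
from .synthetic import GroundTruth, StudyParams, simulate_study

STAGES = (
    "simulate", "scores", "normalized_counts", "shannon", "pearson",
    "class_abundance", "bray_curtis", "nmds", "envfit", "rda", "cca",
    "network", "louvain", "node_geochem",
)

DEFAULT_ENV_VARIABLES = (
    "pH", "temperature", "DIC", "DOC", "DO", "sulfide", "ammonia", "nitrate",
)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(root_seed: int, stage: str) -> int:
    """Per-stage seed derived from the root seed and the stage name."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    outputs: dict[str, str]
    stats: dict[str, Any]
    version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    dataset: Dataset
    truth: GroundTruth | None = None
    scores: pd.Series | None = None
    calls: list | None = None
    ordination: Any = None
    vectors: list | None = None
    rda: list | None = None
    cca: list | None = None
    network: Any = None
    diversity: pd.Series | None = None
    diversity_test: Any = None
    extras: dict = field(default_factory=dict)


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _sig(x: float, digits: int = 4) -> float:
    return float(f"{x:.{digits}g}")


def run_pipeline(
    config: str | Path | Mapping,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run every stage and write TSVs plus ``manifest.json`` to ``out_dir``.

    Config keys (all optional unless loading real data):
    ``simulate`` (bool), ``seed``, ``out``, input paths under ``input:``
    (geochem/counts/taxonomy/metadata), ``lda: {model, threshold, fallback}``,
    ``envfit: {variables, n_perm}``, ``network: {rho_threshold, min_total,
    min_sites}``, ``class_overrides``, ``other_cutoff``.
    """
    cfg = _load_config(config)
    root_seed = int(seed if seed is not None else cfg.get("seed", 0))
    out_dir = Path(out_dir or cfg.get("out", "fringescope_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(root_seed, s) for s in STAGES}
    outputs: dict[str, str] = {}
    stats: dict[str, Any] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = str(path)

    # -- load or simulate ---------------------------------------------------
    truth = None
    try:
        if cfg.get("simulate", "input" not in cfg):
            dataset, truth = simulate_study(StudyParams(), seed=seeds["simulate"])
            for name, path in dataset.write(out_dir / "dataset").items():
                record(f"dataset_{name}", path)
            truth.write(out_dir / "dataset")
        else:
            paths = cfg["input"]
            dataset = load_dataset(paths["geochem"], paths["counts"],
                                   paths["taxonomy"], paths["metadata"])
    except Exception as exc:
        raise StageError("load", exc) from exc

    # -- LDA scoring and fringe calls --------------------------------------
    try:
        lda_cfg = dict(cfg.get("lda", {}))
        model_spec = lda_cfg.get("model", "published")
        model = (published_model() if model_spec == "published"
                 else LDAModel.read(model_spec))
        threshold = float(lda_cfg.get("threshold", model.threshold))
        fallback = lda_cfg.get("fallback", 0.0)
        fallbacks = ({v: float(fallback) for v in model.variables}
                     if fallback is not None else None)
        scores = pd.Series(score_table(dataset.geochem, model, fallbacks),
                           index=dataset.sample_ids, name="lda_score")
        calls = call_fringe(dataset.sample_ids, scores.to_numpy(), threshold)
        tab = pd.DataFrame({
            "lda_score": scores,
            "label": [c.label for c in calls],
            "margin": [c.margin for c in calls],
        })
        tab.to_csv(out_dir / "lda_scores.tsv", sep="\t",
                   index_label="sample_id", float_format="%.10g")
        record("scores", out_dir / "lda_scores.tsv")
    except Exception as exc:
        raise StageError("scores", exc) from exc

    # -- normalization, diversity, correlations, aggregation ---------------
    try:
        normalized = normalize_counts(dataset.counts)
        normalized.write(out_dir / "normalized_counts.tsv")
        record("normalized_counts", out_dir / "normalized_counts.tsv")

        H = shannon_per_sample(dataset.counts)
        H.to_csv(out_dir / "shannon.tsv", sep="\t", index_label="sample_id",
                 float_format="%.10g")
        record("shannon", out_dir / "shannon.tsv")
        div_test = None
        labels = dataset.metadata.table["fringe_label"]
        if labels.isin(("above", "at", "below")).sum() >= 6:
            div_test = group_shannon_test(H, labels)
            stats["shannon_group_p"] = _sig(div_test.p_value)

        r, _n = pearson_matrix(dataset.geochem)
        r.to_csv(out_dir / "pearson.tsv", sep="\t", float_format="%.10g")
        record("pearson", out_dir / "pearson.tsv")

        class_tab = aggregate_by_class(dataset.counts, dataset.taxonomy,
                                       cfg.get("class_overrides"),
                                       float(cfg.get("other_cutoff", 20.0)))
        class_tab.percents.to_csv(out_dir / "class_abundance.tsv", sep="\t",
                                  index_label="taxon", float_format="%.10g")
        record("class_abundance", out_dir / "class_abundance.tsv")
    except Exception as exc:
        raise StageError("community", exc) from exc

    # -- ordination ---------------------------------------------------------
    try:
        dist = bray_curtis(normalized)
        dist.to_frame().to_csv(out_dir / "bray_curtis.tsv", sep="\t",
                               float_format="%.10g")
        record("bray_curtis", out_dir / "bray_curtis.tsv")

        ord_res = nmds(dist, seed=seeds["nmds"],
                       n_restarts=int(cfg.get("nmds_restarts", 20)))
        ord_res.to_frame().to_csv(out_dir / "nmds_coords.tsv", sep="\t",
                                  index_label="sample_id", float_format="%.10g")
        record("nmds", out_dir / "nmds_coords.tsv")
        stats["nmds_stress"] = _sig(ord_res.stress)

        env_cfg = dict(cfg.get("envfit", {}))
        env_vars = [v for v in env_cfg.get("variables", DEFAULT_ENV_VARIABLES)
                    if v in dataset.geochem.variables]
        n_perm = int(env_cfg.get("n_perm", 999))
        vectors = envfit(ord_res, dataset.geochem, env_vars,
                         n_perm=n_perm, seed=seeds["envfit"])
        vec_tab = pd.DataFrame({
            "variable": [v.variable for v in vectors],
            "r_squared": [v.r_squared for v in vectors],
            "p_value": [v.p_value for v in vectors],
        })
        vec_tab.to_csv(out_dir / "envfit.tsv", sep="\t", index=False,
                       float_format="%.10g")
        record("envfit", out_dir / "envfit.tsv")
        stats["envfit"] = {v.variable: {"r2": _sig(v.r_squared), "p": v.p_value}
                           for v in vectors}

        rda = rda_contribution(normalized, dataset.geochem, env_vars)
        pd.DataFrame({
            "variable": [c.variable for c in rda],
            "percent": [c.percent for c in rda],
        }).to_csv(out_dir / "rda.tsv", sep="\t", index=False,
                  float_format="%.10g")
        record("rda", out_dir / "rda.tsv")
        stats["rda_percent"] = {c.variable: _sig(c.percent) for c in rda}

        cca = None
        if labels.isin(("above", "at", "below")).all():
            cca = cca_group_test(normalized, labels,
                                 n_perm=int(cfg.get("cca_n_perm", 999)),
                                 seed=seeds["cca"])
            pd.DataFrame({
                "axis": [a.axis for a in cca],
                "eigenvalue": [a.eigenvalue for a in cca],
                "pseudo_f": [a.pseudo_f for a in cca],
                "p_value": [a.p_value for a in cca],
            }).to_csv(out_dir / "cca.tsv", sep="\t", index=False,
                      float_format="%.10g")
            record("cca", out_dir / "cca.tsv")
            stats["cca_axis_p"] = [a.p_value for a in cca]
    except Exception as exc:
        raise StageError("ordination", exc) from exc

    # -- network ------------------------------------------------------------
    try:
        net_cfg = dict(cfg.get("network", {}))
        filtered_raw = filter_asvs(dataset.counts,
                                   float(net_cfg.get("min_total", 20)),
                                   int(net_cfg.get("min_sites", 3)))
        kept = normalized.counts.loc[filtered_raw.asv_ids]
        from .data_model import ASVTable
        filtered = ASVTable(kept, normalized=True)
        net = build_network(filtered,
                            float(net_cfg.get("rho_threshold", 0.7)),
                            bool(net_cfg.get("absolute", False)))
        net = louvain(net, seed=seeds["louvain"])
        node_tab, clique_tab = node_geochem_correlation(
            filtered, dataset.geochem,
            [v for v in DEFAULT_ENV_VARIABLES if v in dataset.geochem.variables],
            net)
        net.node_geochem = node_tab
        net.clique_geochem = clique_tab
        net.write(out_dir)
        record("network_edges", out_dir / "network_edges.tsv")
        record("network_nodes", out_dir / "network_nodes.tsv")
        if clique_tab is not None:
            clique_tab.to_csv(out_dir / "clique_geochem.tsv", sep="\t",
                              float_format="%.10g")
            record("clique_geochem", out_dir / "clique_geochem.tsv")
        stats["n_cliques"] = net.n_cliques
        stats["modularity"] = _sig(net.modularity)
        stats["n_edges"] = len(net.edges)
    except Exception as exc:
        raise StageError("network", exc) from exc

    manifest = RunManifest(
        config=cfg, seeds=seeds, outputs=outputs, stats=stats,
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
    )
    manifest.write(out_dir / "manifest.json")
    return PipelineResult(
        manifest=manifest, dataset=dataset, truth=truth, scores=scores,
        calls=calls, ordination=ord_res, vectors=vectors, rda=rda, cca=cca,
        network=net, diversity=H, diversity_test=div_test,
        extras={"normalized": normalized, "distance": dist,
                "class_table": class_tab, "pearson": r,
                "node_geochem": node_tab, "clique_geochem": clique_tab},
    )


# ---------------------------------------------------------------------------
# synthetic-truth evaluation

def fringe_recovery_cv(
    dataset: Dataset,
    truth: GroundTruth,
    n_folds: int = 5,
    seed: int = 0,
    variables: tuple[str, ...] = DEFAULT_ENV_VARIABLES,
) -> float:
    """Held-out accuracy of a Fisher discriminant trained on truth labels.

    Trains on the synthetic geochemistry against the generator's
    photosynthetic/non-photosynthetic truth with stratified-ish k-fold
    splits; a per-fold decision threshold is picked on the training scores.
    """
    X = dataset.geochem.values[list(variables)].to_numpy(dtype=float)
    y = truth.photosynthetic.loc[dataset.sample_ids].to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, n_folds)
    correct = 0
    for i in range(n_folds):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(n_folds) if j != i])
        model = train_lda(X[train], y[train], variables=list(variables))
        s_train = X[train] @ model.weights
        thr = select_threshold(s_train, y[train])
        s_test = X[test] @ model.weights
        correct += int(((s_test >= thr).astype(int) == y[test]).sum())
    return correct / len(y)


def compare_to_truth(result: PipelineResult, truth: GroundTruth | None = None,
                     seed: int = 0) -> dict[str, Any]:
    """Evaluate a synthetic run against the generator's ground truth.

    Reports trained-discriminant fringe accuracy (cross-validated),
    whether envfit flagged the true pH/temperature gradients, and the sign
    of the phototroph-dominated cliques' median pH correlation.
    """
    truth = truth or result.truth
    if truth is None:
        raise ValueError("no ground truth available (not a synthetic run?)")
    ds = result.dataset
    if set(ds.sample_ids) != set(truth.photosynthetic.index):
        raise ValueError("sample sets of run and truth disagree")

    out: dict[str, Any] = {}
    out["fringe_accuracy"] = fringe_recovery_cv(ds, truth, seed=seed)

    if result.vectors:
        pmap = {v.variable: v.p_value for v in result.vectors}
        out["envfit_detects_pH"] = pmap.get("pH", 1.0) < 0.05
        out["envfit_detects_temperature"] = pmap.get("temperature", 1.0) < 0.05

    clique_tab = result.extras.get("clique_geochem")
    if result.network is not None and clique_tab is not None and "pH" in clique_tab:
        guilds = truth.guilds
        mem = pd.Series(result.network.membership)
        photo_cliques = []
        for clique, members in mem.groupby(mem):
            frac = (guilds.loc[members.index] == "phototroph").mean()
            if frac > 0.5:
                photo_cliques.append(clique)
        if photo_cliques:
            out["phototroph_clique_median_pH_rho"] = float(
                clique_tab.loc[photo_cliques, "pH"].median())
    return out
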