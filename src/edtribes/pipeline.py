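"""End-to-end orchestration: generate → cohort → relevance → analyze.

The pipeline runs every analysis stage on one corpus and emits a single
structured report with provenance (config hash, package version, per-stage
seeds, record counts in/out).  Given the same corpus, configuration and
seed, the report is byte-identical; a SHA-256 hash over the result payload
makes that checkable.  Stage failures are recorded per stage and the
pipeline continues where dependencies allow.
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

import edtribes
from edtribes import cessation as cess_mod
from edtribes import cohort as cohort_mod
from edtribes import hazard as hazard_mod
from edtribes import networks as net_mod
from edtribes import relevance as rel_mod
from edtribes import similarity as sim_mod
from edtribes.corpus import Corpus, load_corpus, write_corpus
from edtribes.labels import ClassLabel
from edtribes.synth import GeneratorParams, generate_corpus, generate_rater_matrix

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "stage_seed", "report_hash"]


class ConfigError(ValueError):
    """Unknown or invalid configuration key/value."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; every default documented in methods."""

    corpus_dir: str | None = None  # load an existing corpus instead of generating
    out_dir: str | None = None  # artifact directory (None: report only)
    seed: int = 0
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    ratings_csv: str | None = None  # external rater scores; else simulated from truth
    n_raters: int = 5
    rater_noise: float = 0.1
    pa_threshold: float = 3.5
    pr_threshold: float = 2.5
    kappa_method: str = "cohen"
    ratio_threshold: float = 10.0
    min_support: int = 3
    gap_days: int = 90
    resolution_days: int = 10
    window_days: int = 30
    tf_mode: str = "raw"
    idf_mode: str = "log"
    tag_graph_mode: str = "calibrated"  # target = contact-graph edge count
    tag_graph_threshold: float = 0.99
    max_pairs: int = 2_000_000
    attribution: str = "nonexclusive"
    ties_method: str = "breslow"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "generator" in raw and isinstance(raw["generator"], dict):
            gen_known = {f.name for f in dataclasses.fields(GeneratorParams)}
            gen_unknown = set(raw["generator"]) - gen_known
            if gen_unknown:
                raise ConfigError(f"unknown generator keys: {sorted(gen_unknown)}")
            gen = dict(raw["generator"])
            if "time_span" in gen:
                gen["time_span"] = tuple(gen["time_span"])
            raw["generator"] = GeneratorParams(**gen)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d


def stage_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed (documented derivation)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (pd.Timestamp,)):
        return obj.isoformat()
    if isinstance(obj, ClassLabel):
        return obj.value
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def report_hash(results: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(results), sort_keys=True).encode()
    ).hexdigest()


def _labels_for(corpus: Corpus, truth, config: PipelineConfig) -> tuple[dict, dict]:
    """Class labels plus a record of how they were obtained."""
    info: dict = {}
    if config.ratings_csv:
        scores = pd.read_csv(config.ratings_csv, index_col="user_id")
        info["source"] = "ratings_csv"
    elif truth is not None:
        scores = generate_rater_matrix(
            truth, config.n_raters, config.rater_noise,
            seed=stage_seed(config.seed, "raters"),
        )
        info["source"] = "simulated_raters"
    else:
        lc = corpus.users.set_index("user_id")["latent_class"].dropna()
        labels = {u: ClassLabel(v) for u, v in lc.items()}
        info["source"] = "latent_class_column"
        return labels, info
    labels = cohort_mod.aggregate_rater_labels(
        scores, config.pa_threshold, config.pr_threshold
    )
    kappa, p = cohort_mod.rater_agreement(
        scores, method=config.kappa_method,
        pa_threshold=config.pa_threshold, pr_threshold=config.pr_threshold,
        seed=stage_seed(config.seed, "kappa"),
    )
    info.update(kappa=kappa, kappa_p=p, n_raters=scores.shape[1], n_rated=scores.shape[0])
    return labels, info


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the structured report.

    The report's ``results`` section contains every statistic the analysis
    modules define; ``provenance`` records the configuration, seeds, stage
    logs and the result hash.  When ``config.out_dir`` is set, the report
    and per-stage artifacts (corpus, networks, panel) are written there.
    """
    results: dict = {}
    stage_log: list[dict] = []
    failures: dict = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- corpus ---------------------------------------------------------
    truth = None
    if config.corpus_dir:
        corpus = load_corpus(config.corpus_dir)
    else:
        corpus, truth = generate_corpus(config.generator, stage_seed(config.seed, "generate"))
        if out_dir:
            write_corpus(corpus, out_dir / "corpus")
            truth.to_json(out_dir / "ground_truth.json")
    stage_log.append(
        {
            "stage": "corpus",
            "users": len(corpus.users),
            "photos": len(corpus.photos),
            "comments": len(corpus.comments),
            "contacts": len(corpus.contacts),
            "favorites": len(corpus.favorites),
        }
    )

    # --- cohort ---------------------------------------------------------
    seed_users = cohort_mod.find_seed_users(corpus)
    labels, label_info = _labels_for(corpus, truth, config)
    n_by_class = {
        c.value: sum(1 for v in labels.values() if v is c)
        for c in (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY, ClassLabel.NEUTRAL)
    }
    results["cohort"] = {
        "seed_rule_counts": {
            rule: sum(1 for s in seed_users.values() if rule in s)
            for rule in ("search", "group", "commenter", "favoriter")
        },
        "n_seed_users": len(seed_users),
        "labels": label_info,
        "class_sizes": n_by_class,
    }
    stage_log.append({"stage": "cohort", "in": len(corpus.users), "out": len(labels)})

    # --- relevance ------------------------------------------------------
    tag_set = rel_mod.select_relevant_tags(
        corpus, labels, config.ratio_threshold, config.min_support
    )
    flags = rel_mod.flag_relevant_photos(corpus, tag_set)
    volume = rel_mod.monthly_volume(corpus, labels, flags)
    self_stats = rel_mod.self_portrait_stats(corpus, labels, flags)
    try:
        pa_top, pr_top = rel_mod.indicative_tags(corpus, labels, top_k=20)
    except ValueError:
        pa_top, pr_top = [], []
    rho_tags, p_tags, n_shared = rel_mod.tag_rank_correlation(corpus, labels)
    usage = {
        "thinspiration_family": rel_mod.tag_usage_stats(
            corpus, labels, ["thinspiration", "thinspo"]
        ),
        "pro_ana_family": rel_mod.tag_usage_stats(
            corpus, labels, ["pro-ana", "pro-anorexia", "ana"]
        ),
    }
    results["relevance"] = {
        "n_relevant_tags": len(tag_set.tags),
        "relevant_tags": sorted(tag_set.tags),
        "n_relevant_photos": int(flags.sum()),
        "volume": {
            "spearman_rho": volume.spearman_rho,
            "spearman_p": volume.spearman_p,
            "median_photos_pa": volume.median_photos_pa,
            "median_photos_pr": volume.median_photos_pr,
            "ranksum_p": volume.ranksum_p,
            "monthly_totals": {
                "pa": int(volume.series["pa_count"].sum()),
                "pr": int(volume.series["pr_count"].sum()),
            },
        },
        "indicative_tags": {"pro_ana": pa_top, "pro_recovery": pr_top},
        "tag_rank_correlation": {"rho": rho_tags, "p": p_tags, "n_shared": n_shared},
        "tag_usage": usage,
        "self_portrait": dataclasses.asdict(self_stats),
    }
    stage_log.append({"stage": "relevance", "in": len(corpus.photos), "out": int(flags.sum())})
    if out_dir:
        flags.rename("is_relevant").to_csv(out_dir / "photo_flags.csv")

    # --- similarity -----------------------------------------------------
    try:
        docs, doc_class, _ = sim_mod.photo_documents(corpus, labels)
        vectors = sim_mod.build_tfidf(docs, tf_mode=config.tf_mode, idf_mode=config.idf_mode)
        summary = sim_mod.class_pair_similarity(
            vectors, doc_class, max_pairs=config.max_pairs,
            seed=stage_seed(config.seed, "similarity"),
        )
        results["similarity"] = {
            "mean_within_pa": summary.mean_within_pa,
            "mean_within_pr": summary.mean_within_pr,
            "mean_between": summary.mean_between,
            "n_pairs": summary.n_pairs,
            "mode": summary.mode,
            "ranksum_p": summary.ranksum_p,
        }
        stage_log.append({"stage": "similarity", "in": len(docs), "out": 3})
    except Exception as exc:  # noqa: BLE001 - stage isolation
        failures["similarity"] = str(exc)

    # --- networks -------------------------------------------------------
    networks = {}
    net_report: dict = {}
    for kind in ("contacts", "comments", "favorites"):
        g = net_mod.build_network(corpus, labels, kind)
        networks[kind] = g
    try:
        target = networks["contacts"].number_of_edges()
        networks["tags"] = net_mod.build_network(
            corpus, labels, "tags",
            tag_mode=config.tag_graph_mode,
            tag_threshold=config.tag_graph_threshold,
            tag_target_edges=target or None,
        )
    except sim_mod.CalibrationError as exc:
        failures["tags_network"] = str(exc)
        networks["tags"] = net_mod.build_network(
            corpus, labels, "tags", tag_mode="fixed",
            tag_threshold=config.tag_graph_threshold,
        )
    for kind, g in networks.items():
        entry: dict = {
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
        }
        if kind in ("contacts", "comments"):
            ic = net_mod.inclass_fractions(g, labels)
            entry["inclass"] = {
                "frac_pa": ic.frac_pa,
                "frac_pr": ic.frac_pr,
                "chi2": ic.chi2,
                "p": ic.pvalue,
                "contingency": ic.contingency.tolist(),
            }
        if kind == "favorites":
            ic = net_mod.inclass_fractions(g, labels)
            fp = net_mod.favorite_preference(g, labels)
            entry["inclass"] = {
                "frac_pa": ic.frac_pa,
                "frac_pr": ic.frac_pr,
                "chi2": ic.chi2,
                "p": ic.pvalue,
                "contingency": ic.contingency.tolist(),
            }
            entry["preference"] = {
                "pa_shares": fp.pa_shares,
                "pr_shares": fp.pr_shares,
                "pa_ratio": fp.pa_ratio,
            }
        scores = net_mod.neighbor_scores(g, labels)
        try:
            entry["auc"] = net_mod.network_auc(scores, labels)
        except ValueError as exc:
            entry["auc"] = None
            entry["auc_note"] = str(exc)
        entry["n_isolated"] = int((scores[["n_pa_neighbors", "n_pr_neighbors"]].sum(axis=1) == 0).sum())
        net_report[kind] = entry
        if out_dir:
            net_mod.export_graphml(g, out_dir / f"network_{kind}.graphml")
    results["networks"] = net_report
    stage_log.append({"stage": "networks", "in": len(labels), "out": len(networks)})

    # --- cessation ------------------------------------------------------
    events = cess_mod.detect_all_cessation(corpus, flags, labels, gap_days=config.gap_days)
    followup = (
        cess_mod.image_followup_table(corpus, labels, flags, events, config.attribution)
        if len(events)
        else None
    )
    results["cessation"] = {
        "n_users_with_relevant": len(events),
        "n_ceased": int(events["ceased"].sum()) if len(events) else 0,
        "n_censored": int(events["censored"].sum()) if len(events) else 0,
        "n_abandoned": int(events["abandoned"].sum()) if len(events) else 0,
        "followup": None
        if followup is None
        else {
            "rates": {f"{p}|{c}": v for (p, c), v in followup.rates.items()},
            "mean_days": {f"{p}|{c}": v for (p, c), v in followup.mean_days.items()},
            "counts": {f"{p}|{c}": v for (p, c), v in followup.counts.items()},
            "attribution": followup.attribution,
        },
    }
    stage_log.append({"stage": "cessation", "in": len(labels), "out": len(events)})

    # --- hazard ---------------------------------------------------------
    panel = hazard_mod.build_hazard_panel(
        corpus, labels, flags,
        resolution_days=config.resolution_days, window_days=config.window_days,
    )
    hz: dict = {"n_rows": len(panel), "n_events": int(panel["event"].sum()) if len(panel) else 0}
    for cls in ("pro_ana", "pro_recovery"):
        for fs in ("cumulative", "recent"):
            key = f"{cls}:{fs}"
            try:
                fit = hazard_mod.fit_hazard_model(
                    panel, cls, feature_set=fs, ties_method=config.ties_method
                )
                hz[key] = {
                    "coef": {k: float(v) for k, v in fit.params.items()},
                    "se": {k: float(v) for k, v in fit.standard_errors.items()},
                    "p": {k: float(v) for k, v in fit.pvalues.items()},
                    "n_events": fit.n_events,
                    "n_intervals": fit.n_intervals,
                    "converged": fit.converged,
                    "dropped": fit.transform.dropped,
                }
            except (hazard_mod.HazardFitError, ValueError) as exc:
                failures[f"hazard:{key}"] = str(exc)
    results["hazard"] = hz
    stage_log.append({"stage": "hazard", "in": len(panel), "out": sum(1 for k in hz if ":" in k)})
    if out_dir and len(panel):
        panel.to_csv(out_dir / "hazard_panel.csv", index=False)

    # --- report ---------------------------------------------------------
    report = {
        "results": _jsonable(results),
        "failures": failures,
        "provenance": {
            "package_version": edtribes.__version__,
            "seed": config.seed,
            "stage_seeds": {
                s: stage_seed(config.seed, s)
                for s in ("generate", "raters", "kappa", "similarity")
            },
            "config": _jsonable(config.to_dict()),
            "stage_log": stage_log,
            "report_hash": report_hash(results),
        },
    }
    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
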