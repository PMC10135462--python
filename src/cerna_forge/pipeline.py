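"""End-to-end orchestration: config, staged runs, manifests, demo.

``run_pipeline`` executes the stages in the study's order —
preprocessing (merge/batch removal) -> differential expression (mRNA
and miRNA) -> co-expression modules -> disease-specific gene
intersection -> diagnostic signature -> ceRNA network -> immune scoring
— against a bundle directory (real or generated), writing each stage's
tables plus a manifest (parameters, input hashes, seed, version) into a
run directory.  A stage whose manifest matches the current parameters
and inputs is not recomputed; its outputs are reloaded from disk.

``demo`` generates a default synthetic bundle, runs the full pipeline
on it and reports how much of the planted truth was recovered (module
ARI, DE sensitivity, triplet recovery, pruning outcome).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from cerna_forge import (
    io_prep,
    diffexpr,
    coexpr,
    signature as sig,
    cerna,
    immune,
    synthetic,
)

__all__ = ["PipelineConfig", "run_pipeline", "demo", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run."""

    bundle_dir: str = ""
    out_dir: str = "runs/run1"
    seed: int = 0
    # preprocessing
    remove_batch: bool = True
    # differential expression
    mrna_lfc_min: float = 0.58
    mirna_lfc_min: float = 2.0
    alpha: float = 0.05
    # co-expression
    top_variance_fraction: float = 0.25
    outlier_cut_height: float | None = None
    powers: tuple = tuple(range(1, 13))
    r2_target: float = 0.85
    min_module_size: int = 50
    merge_cut_height: float = 0.15
    n_selected_modules: int = 2
    # signature
    train_fraction: float = 0.8
    n_trees: int = 1000
    lasso_folds: int = 10
    cv_folds: int = 5
    lambda_rule: str = "min"
    # ceRNA
    hub_k: int = 15
    polarity: str = "up-down-up"
    # immune
    ssgsea_alpha: float = 0.25
    # stage toggles
    run_signature: bool = True
    run_cerna: bool = True
    run_immune: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("config file must hold a mapping")
        if "powers" in d:
            d["powers"] = tuple(d["powers"])
        return cls.from_dict(d)

    def validate(self) -> None:
        numeric = {
            "mrna_lfc_min": self.mrna_lfc_min,
            "mirna_lfc_min": self.mirna_lfc_min,
            "alpha": self.alpha,
            "top_variance_fraction": self.top_variance_fraction,
            "r2_target": self.r2_target,
            "merge_cut_height": self.merge_cut_height,
            "train_fraction": self.train_fraction,
            "ssgsea_alpha": self.ssgsea_alpha,
        }
        for name, v in numeric.items():
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValueError(f"config {name} must be numeric, got {v!r}")
            if v <= 0:
                raise ValueError(f"config {name} must be positive, got {v}")
        for name in ("min_module_size", "n_trees", "lasso_folds", "cv_folds", "hub_k", "seed"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"config {name} must be an integer, got {v!r}")
        if self.alpha >= 1 or self.top_variance_fraction > 1 or self.train_fraction > 1:
            raise ValueError("alpha, top_variance_fraction, train_fraction must be <= 1")
        if self.lambda_rule not in {"min", "1se"}:
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.polarity not in {"up-down-up", "down-up-down", "both"}:
            raise ValueError(f"unknown polarity {self.polarity!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Manifest-guarded stage runner with disk caching."""

    def __init__(self, run_dir: Path, name: str, params: dict, input_files: list[Path]):
        self.dir = run_dir / name
        self.name = name
        self.manifest = {
            "stage": name,
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()},
            "inputs": {str(p): _sha256(p) for p in input_files if p.exists()},
            "version": __import__("cerna_forge").__version__,
        }

    def fresh(self) -> bool:
        mf = self.dir / "manifest.json"
        if not mf.exists():
            return False
        try:
            with open(mf, "rt", encoding="utf-8") as fh:
                return json.load(fh) == self.manifest
        except (json.JSONDecodeError, OSError):
            return False

    def finish(self) -> None:
        with open(self.dir / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _write_de(table: pd.DataFrame, path: Path) -> None:
    table.rename_axis("feature_id").to_csv(path, sep="\t")


def _read_de(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every enabled stage; returns the run directory."""
    config.validate()
    bundle_dir = Path(config.bundle_dir)
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.json", "wt", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=1, default=list, sort_keys=True)
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)
        print(msg)

    try:
        out = _run_stages(config, bundle_dir, run_dir, say)
    finally:
        with open(run_dir / "run_log.txt", "wt", encoding="utf-8") as fh:
            fh.write("\n".join(log) + "\n")
    return out


def _run_stages(config, bundle_dir, run_dir, say) -> Path:
    rng = np.random.default_rng(config.seed)

    # --- stage: prep -------------------------------------------------------
    stage = "prep"
    try:
        mrna_path = bundle_dir / "mrna.tsv"
        mirna_path = bundle_dir / "mirna.tsv"
        samples_path = bundle_dir / "samples.tsv"
        st = _Stage(run_dir, stage, {"remove_batch": config.remove_batch},
                    [mrna_path, mirna_path, samples_path])
        st.dir.mkdir(exist_ok=True)
        if st.fresh():
            say("[prep] cached")
            mrna = io_prep.read_expression(st.dir / "mrna_corrected.tsv")
            mirna = io_prep.read_expression(st.dir / "mirna.tsv")
            samples = io_prep.read_sample_table(st.dir / "samples.tsv")
        else:
            mrna = io_prep.read_expression(mrna_path)
            mirna = io_prep.read_expression(mirna_path)
            samples = io_prep.read_sample_table(samples_path)
            keep = samples.loc[~samples["excluded"].astype(bool), "sample_id"].tolist()
            dropped = samples.shape[0] - len(keep)
            samples = samples[samples["sample_id"].isin(keep)].reset_index(drop=True)
            mrna = mrna[[s for s in mrna.columns if s in keep]]
            mirna = mirna[[s for s in mirna.columns if s in keep]]
            if config.remove_batch and samples["batch"].nunique() > 1:
                mrna = io_prep.remove_batch_effect(mrna, samples)
            io_prep.write_expression(mrna, st.dir / "mrna_corrected.tsv")
            io_prep.write_expression(mirna, st.dir / "mirna.tsv")
            io_prep.write_sample_table(samples, st.dir / "samples.tsv")
            st.finish()
            say(f"[prep] {mrna.shape[0]} genes, {mirna.shape[0]} miRNAs, "
                f"{len(keep)} samples kept ({dropped} excluded)")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'prep' failed: {e}") from e

    # --- stage: diffexpr ---------------------------------------------------
    stage = "diffexpr"
    try:
        st = _Stage(run_dir, stage,
                    {"mrna_lfc_min": config.mrna_lfc_min,
                     "mirna_lfc_min": config.mirna_lfc_min, "alpha": config.alpha},
                    [st.dir / "mrna_corrected.tsv", st.dir / "mirna.tsv"])
        st.dir.mkdir(exist_ok=True)
        if st.fresh():
            say("[diffexpr] cached")
            de_mrna = _read_de(st.dir / "de_mrna.tsv")
            de_mirna = _read_de(st.dir / "de_mirna.tsv")
        else:
            de_mrna = diffexpr.moderated_de(
                mrna, samples, lfc_min=config.mrna_lfc_min, alpha=config.alpha
            )
            de_mirna = diffexpr.moderated_de(
                mirna, samples, lfc_min=config.mirna_lfc_min, alpha=config.alpha
            )
            _write_de(de_mrna, st.dir / "de_mrna.tsv")
            _write_de(de_mirna, st.dir / "de_mirna.tsv")
            st.finish()
        n_up = int((de_mrna["direction"] == "up").sum())
        n_dn = int((de_mrna["direction"] == "down").sum())
        say(f"[diffexpr] mRNA: {n_up} up + {n_dn} down of {len(de_mrna)}; "
            f"miRNA: {int((de_mirna['direction'] != 'ns').sum())} of {len(de_mirna)}")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'diffexpr' failed: {e}") from e

    # --- stage: coexpr -----------------------------------------------------
    stage = "coexpr"
    try:
        st = _Stage(run_dir, stage,
                    {"fraction": config.top_variance_fraction,
                     "powers": config.powers, "r2_target": config.r2_target,
                     "min_module_size": config.min_module_size,
                     "merge_cut_height": config.merge_cut_height,
                     "outlier_cut_height": config.outlier_cut_height},
                    [run_dir / "prep" / "mrna_corrected.tsv"])
        st.dir.mkdir(exist_ok=True)
        xw = coexpr.select_top_variance(mrna, config.top_variance_fraction)
        if config.outlier_cut_height is not None:
            outliers = coexpr.detect_outlier_samples(xw, config.outlier_cut_height)
            if outliers:
                say(f"[coexpr] outlier samples removed: {outliers}")
                xw = xw.drop(columns=outliers)
                samples = samples[~samples["sample_id"].isin(outliers)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = coexpr.pick_soft_threshold(
                xw, config.powers, config.r2_target, fallback="sample-size"
            )
        tom = coexpr.compute_tom(xw, report.selected)
        assign = coexpr.detect_modules(
            tom, xw,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height,
        )
        mt = coexpr.module_trait(assign, samples)
        assign = coexpr.gene_stats(assign, xw, samples)
        report.table.to_csv(st.dir / "soft_threshold.tsv", sep="\t", index=False)
        mt.to_csv(st.dir / "module_trait.tsv", sep="\t")
        assign.eigengenes.to_csv(st.dir / "eigengenes.tsv", sep="\t")
        own_mm = [
            assign.mm.loc[g, assign.modules[g]] if assign.modules[g] != coexpr.GREY else np.nan
            for g in assign.modules.index
        ]
        pd.DataFrame(
            {"module": assign.modules, "MM": own_mm, "GS": assign.gs}
        ).rename_axis("gene").to_csv(st.dir / "modules.tsv", sep="\t")
        st.finish()
        sizes = assign.modules[assign.modules != coexpr.GREY].value_counts().to_dict()
        say(f"[coexpr] beta={report.selected} (R2 target met: {report.target_met}); "
            f"modules: {sizes}")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'coexpr' failed: {e}") from e

    # --- stage: specific genes --------------------------------------------
    try:
        ranked = mt.reindex(mt["r"].abs().sort_values(ascending=False).index)
        selected_modules = [
            m for m in ranked.index if m != coexpr.GREY
        ][: config.n_selected_modules]
        specific = coexpr.disease_specific_genes(de_mrna, assign, selected_modules)
        pd.Series(specific, name="gene").to_csv(
            run_dir / "coexpr" / "disease_specific_genes.tsv", sep="\t", index=False
        )
        say(f"[specific] modules {selected_modules} ∩ DE -> {len(specific)} genes")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'specific-genes' failed: {e}") from e

    # --- stage: signature --------------------------------------------------
    roc_results = {}
    if config.run_signature:
        try:
            st = _Stage(run_dir, "signature",
                        {"train_fraction": config.train_fraction,
                         "n_trees": config.n_trees, "cv_folds": config.cv_folds,
                         "lasso_folds": config.lasso_folds,
                         "lambda_rule": config.lambda_rule, "seed": config.seed},
                        [run_dir / "coexpr" / "disease_specific_genes.tsv"])
            st.dir.mkdir(exist_ok=True)
            if len(specific) < 2:
                say("[signature] skipped: fewer than 2 candidate genes")
            else:
                xs = mrna.loc[specific]
                train_t, valid_t = sig.split_train_validation(
                    samples, config.train_fraction, seed=int(rng.integers(0, 2**31 - 1))
                )
                tr_cols = train_t["sample_id"].tolist()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    selected = sig.lasso_select(
                        xs[tr_cols], train_t, n_folds=config.lasso_folds,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        lambda_rule=config.lambda_rule,
                    )
                feats = [g for g, _ in selected] or specific
                model = sig.rf_fit_and_importance(
                    xs.loc[feats, tr_cols], train_t, n_trees=config.n_trees,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                model.lasso_coefficients = dict(selected)
                roc_tr = sig.evaluate_roc(model, xs.loc[feats, tr_cols], train_t)
                roc_results["train_auc"] = roc_tr.auc
                pd.DataFrame({
                    "threshold": roc_tr.thresholds,
                    "sensitivity": roc_tr.sensitivity,
                    "specificity": roc_tr.specificity,
                }).to_csv(st.dir / "roc_train.tsv", sep="\t", index=False)
                if len(valid_t):
                    va_cols = valid_t["sample_id"].tolist()
                    roc_va = sig.evaluate_roc(model, xs.loc[feats, va_cols], valid_t)
                    roc_results["valid_auc"] = roc_va.auc
                    pd.DataFrame({
                        "threshold": roc_va.thresholds,
                        "sensitivity": roc_va.sensitivity,
                        "specificity": roc_va.specificity,
                    }).to_csv(st.dir / "roc_valid.tsv", sep="\t", index=False)
                cv_mean, cv_folds = sig.cross_validate(
                    xs, samples, n_folds=config.cv_folds,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    n_trees=min(config.n_trees, 200), lasso_folds=config.lasso_folds,
                )
                roc_results["cv_mean_auc"] = cv_mean
                with open(st.dir / "signature.json", "wt", encoding="utf-8") as fh:
                    json.dump({
                        "features": model.features,
                        "lasso_coefficients": model.lasso_coefficients,
                        "n_trees": model.n_trees,
                        "seed": model.seed,
                        "importance": model.importance.to_dict(),
                        "train_auc": roc_results.get("train_auc"),
                        "valid_auc": roc_results.get("valid_auc"),
                        "cv_mean_auc": cv_mean,
                        "cv_fold_aucs": cv_folds,
                    }, fh, indent=1)
                st.finish()
                say(f"[signature] {len(specific)} candidates -> LASSO {len(feats)} genes; "
                    f"train AUC {roc_results.get('train_auc', float('nan')):.3f}, "
                    f"valid AUC {roc_results.get('valid_auc', float('nan')):.3f}, "
                    f"CV AUC {cv_mean:.3f}")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage 'signature' failed: {e}") from e

    # --- stage: cerna ------------------------------------------------------
    pruned = None
    triplets = []
    if config.run_cerna:
        try:
            st = _Stage(run_dir, "cerna",
                        {"hub_k": config.hub_k, "polarity": config.polarity},
                        [bundle_dir / "targets_mrna.tsv",
                         bundle_dir / "targets_lnc_db1.tsv",
                         bundle_dir / "targets_lnc_db2.tsv",
                         bundle_dir / "directions.tsv"])
            st.dir.mkdir(exist_ok=True)
            targets = pd.read_csv(bundle_dir / "targets_mrna.tsv", sep="\t")
            db1 = pd.read_csv(bundle_dir / "targets_lnc_db1.tsv", sep="\t")
            db2 = pd.read_csv(bundle_dir / "targets_lnc_db2.tsv", sep="\t")
            directions = pd.read_csv(
                bundle_dir / "directions.tsv", sep="\t", index_col="node_id"
            )["direction"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mrna_pairs = cerna.build_mrna_mirna_pairs(
                    targets, de_mrna, de_mirna, specific, polarity=config.polarity
                )
                lnc_pairs = cerna.consensus_lncrna_pairs(
                    db1, db2, sorted({m for m, _ in mrna_pairs})
                )
                net = cerna.assemble_network(mrna_pairs, lnc_pairs)
            say(f"[cerna] {len(mrna_pairs)} mRNA pairs + {len(lnc_pairs)} lncRNA pairs -> "
                f"{net.number_of_nodes()} nodes / {net.number_of_edges()} edges")
            if net.number_of_nodes():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hubs = cerna.rank_hubs(net, config.hub_k)
                hub_lncs = [
                    n for n, d in hubs.subnetwork.nodes(data=True)
                    if d["node_class"] == "lncRNA"
                ]
                dirs = {l: directions.get(l, "ns") for l in hub_lncs}
                pruned, triplets = cerna.prune_by_validation(hubs, dirs)
                cerna.write_edge_list(net, st.dir / "network_edges.tsv")
                cerna.write_graphml(net, st.dir / "network.graphml")
                cerna.write_edge_list(pruned.subnetwork, st.dir / "hub_pruned_edges.tsv")
                full_triplets = cerna.enumerate_triplets(net)
                pd.DataFrame(
                    [(t.mrna, t.mirna, t.lncrna) for t in full_triplets],
                    columns=["mrna", "mirna", "lncrna"],
                ).to_csv(st.dir / "network_triplets.tsv", sep="\t", index=False)
                pd.DataFrame(
                    [(t.mrna, t.mirna, t.lncrna) for t in triplets],
                    columns=["mrna", "mirna", "lncrna"],
                ).to_csv(st.dir / "triplets.tsv", sep="\t", index=False)
                pd.DataFrame(hubs.ranked, columns=["node", "degree"]).to_csv(
                    st.dir / "hubs.tsv", sep="\t", index=False
                )
                st.finish()
                say(f"[cerna] hubs: {len(hubs.ranked)}; after pruning: "
                    f"{pruned.subnetwork.number_of_nodes()} nodes, "
                    f"{len(triplets)} triplets")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage 'cerna' failed: {e}") from e

    # --- stage: immune -----------------------------------------------------
    if config.run_immune:
        try:
            st = _Stage(run_dir, "immune", {"alpha": config.ssgsea_alpha},
                        [bundle_dir / "immune_sets.gmt"])
            st.dir.mkdir(exist_ok=True)
            sets = immune.read_gmt(bundle_dir / "immune_sets.gmt")
            scores = immune.ssgsea_scores(mrna, sets, alpha=config.ssgsea_alpha)
            scores.rename_axis("gene_set").to_csv(st.dir / "ssgsea_scores.tsv", sep="\t")
            comp = immune.compare_groups(scores, samples)
            comp.to_csv(st.dir / "group_comparison.tsv", sep="\t", index=False)
            hub_mrnas = sorted(
                {t.mrna for t in triplets}
            ) if triplets else specific[: 3]
            if hub_mrnas:
                corr = immune.correlate_hub_scores(mrna, hub_mrnas, scores)
                corr.to_csv(st.dir / "hub_immune_correlation.tsv", sep="\t", index=False)
            st.finish()
            say(f"[immune] {len(sets)} gene sets scored; "
                f"{int((comp['p'] < 0.05).sum())} differ between groups at p<0.05")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage 'immune' failed: {e}") from e

    return run_dir


def demo(seed: int = 1, out_dir: str | Path = "runs/demo", n_trees: int = 200) -> Path:
    """Generate a default bundle, run the pipeline, report truth recovery."""
    from sklearn.metrics import adjusted_rand_score

    out_dir = Path(out_dir)
    bundle = synthetic.generate_cohort(seed=seed)
    bundle_dir = synthetic.write_bundle(bundle, out_dir / "bundle")
    config = PipelineConfig(
        bundle_dir=str(bundle_dir), out_dir=str(out_dir / "run"),
        seed=seed, n_trees=n_trees,
    )
    run_dir = run_pipeline(config)
    truth = bundle.truth

    modules_tsv = pd.read_csv(run_dir / "coexpr" / "modules.tsv", sep="\t", index_col="gene")
    planted = {
        g: m for g, m in truth.module_membership.items() if m != "background"
    }
    common = [g for g in planted if g in modules_tsv.index]
    ari = adjusted_rand_score(
        [planted[g] for g in common], [modules_tsv.loc[g, "module"] for g in common]
    ) if common else float("nan")

    de_mrna = _read_de(run_dir / "diffexpr" / "de_mrna.tsv")
    planted_genes = [g for g in truth.de_features if g in de_mrna.index]
    called = de_mrna.loc[planted_genes, "direction"] != "ns"
    de_sensitivity = float(called.mean()) if planted_genes else float("nan")

    trip_path = run_dir / "cerna" / "network_triplets.tsv"
    found = set()
    if trip_path.exists():
        tt = pd.read_csv(trip_path, sep="\t")
        found = set(map(tuple, tt.to_numpy()))
    truth_triplets = set(map(tuple, truth.true_triplets))
    recovered = len(truth_triplets & found)

    pruned_edges = run_dir / "cerna" / "hub_pruned_edges.tsv"
    n_pruned_nodes = 0
    if pruned_edges.exists():
        pe = pd.read_csv(pruned_edges, sep="\t")
        n_pruned_nodes = len(set(pe["node_a"]) | set(pe["node_b"])) if len(pe) else 0

    summary = {
        "seed": seed,
        "module_ari": round(float(ari), 4),
        "de_sensitivity": round(de_sensitivity, 4),
        "triplets_recovered": recovered,
        "triplets_planted": len(truth_triplets),
        "pruned_hub_nodes": n_pruned_nodes,
    }
    with open(out_dir / "recovery_summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"[demo] recovery summary: {summary}")
    return out_dir
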