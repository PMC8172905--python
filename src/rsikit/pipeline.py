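"""End-to-end orchestration: score -> stratify -> enrich -> associate ->
classify -> survival, from a single YAML config, with a run manifest.

Each stage writes its TSV/JSON artifact into the output directory; the
manifest records the config snapshot, seed, package version and a sha256
checksum per artifact, so a fixed config and seed reproduce byte-identical
outputs. Disabling a stage never changes the artifacts of the stages that
still run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import gini_importance, select_features, train_eval, youden_cutpoint
from .enrichment import ENRICHMENT_Z_THRESHOLD, enrich_matrix
from .errors import ValidationError
from .immune import m1_m2_log_ratio, spearman_with_p, validate_immune_fractions
from .io import ExpressionMatrix, read_expression
from .rsi import RSI_THRESHOLD, score_matrix
from .signatures import rsi_signature, tcia_gene_set, read_signature_yaml
from .survival import cox_univariate, km_fit, logrank, surv_cutpoint
from .synthetic import SyntheticCohort, SyntheticConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report"]

ALL_STAGES = ("score", "enrich", "associate", "classify", "survival")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one YAML document)."""

    outdir: Path
    expression_path: Path | None = None
    immune_fractions_path: Path | None = None
    survival_path: Path | None = None
    covariates_path: Path | None = None  # needs sample_id + immune_subtype
    signature_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    rsi_threshold: float = RSI_THRESHOLD
    z_threshold: float = ENRICHMENT_Z_THRESHOLD
    n_trees: int = 500
    n_splits: int = 5
    minprop: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValidationError(f"unknown stages: {sorted(bad)}")
        if self.synthetic is None and self.expression_path is None:
            raise ValidationError("need an expression matrix or a synthetic block")
        for name in ("expression_path", "immune_fractions_path",
                     "survival_path", "covariates_path", "signature_path"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise ValidationError(f"{name} does not exist: {p}")
        if not (np.isfinite(self.rsi_threshold) and np.isfinite(self.z_threshold)):
            raise ValidationError("thresholds must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        syn = doc.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        stages = tuple(doc.pop("stages", ALL_STAGES))
        return cls(synthetic=syn, stages=stages, **doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write("# produced by rsikit run_pipeline\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    sig = (read_signature_yaml(cfg.signature_path)
           if cfg.signature_path else rsi_signature())
    tcia = tcia_gene_set()

    cohort: SyntheticCohort | None = None
    if cfg.synthetic is not None:
        cohort = generate(cfg.synthetic, signature=sig, tcia=tcia)
        expr = cohort.expression
        immune = cohort.immune_fractions
        surv = cohort.survival
        subtypes = cohort.subtypes
    else:
        expr = read_expression(cfg.expression_path)
        immune = (pd.read_csv(cfg.immune_fractions_path, sep="\t", index_col=0,
                              comment="#")
                  if cfg.immune_fractions_path else None)
        surv = (pd.read_csv(cfg.survival_path, sep="\t", comment="#")
                if cfg.survival_path else None)
        subtypes = None
        if cfg.covariates_path:
            cov = pd.read_csv(cfg.covariates_path, sep="\t", comment="#")
            subtypes = cov.set_index("sample_id")["immune_subtype"]

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (str(v) if isinstance(v, Path) else
                       dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                       else list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "stages": {},
        "artifacts": {},
        "exclusions": {},
        "status": "running",
    }
    manifest_path = cfg.outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    def _emit(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    scores = None
    enr = None
    try:
        if "score" in cfg.stages:
            scores = score_matrix(expr, sig, cfg.rsi_threshold)
            p = cfg.outdir / "scores.tsv"
            _write_tsv(scores, p)
            _emit("scores", p)
            manifest["stages"]["score"] = {
                "n_samples": len(scores),
                "rsi_mean": float(scores["rsi"].mean()),
                "rsi_sd": float(scores["rsi"].std(ddof=1)),
                "n_low": int((scores["category"] == "RSI-Low").sum()),
                "n_high": int((scores["category"] == "RSI-High").sum()),
                "threshold": cfg.rsi_threshold,
            }

        if "enrich" in cfg.stages:
            enr = enrich_matrix(expr, tcia, z_threshold=cfg.z_threshold)
            p = cfg.outdir / "enrichment.tsv"
            _write_tsv(enr.table, p)
            _emit("enrichment", p)
            manifest["stages"]["enrich"] = {
                "fraction_enriched": enr.fraction_enriched,
                "threshold": cfg.z_threshold,
            }
            if scores is not None:
                merged = scores.merge(enr.table[["sample_id", "enriched"]],
                                      on="sample_id")
                ct = pd.crosstab(
                    np.where(merged["enriched"], "Enriched", "Non-enriched"),
                    merged["category"],
                )
                ct.index.name = "tcia_status"
                p = cfg.outdir / "contingency.tsv"
                _write_tsv(ct, p, index=True)
                _emit("contingency", p)

        if "associate" in cfg.stages:
            if scores is None:
                raise ValidationError("associate stage requires the score stage")
            assoc_rows = []
            idx = scores.set_index("sample_id")["rsi"]
            if enr is not None:
                z = enr.table.set_index("sample_id")["z"]
                rho, pv = spearman_with_p(idx.loc[z.index].to_numpy(),
                                          z.to_numpy())
                assoc_rows.append(("rsi_vs_tcia_z", rho, pv, len(z)))
            if immune is not None:
                validate_immune_fractions(immune)
                ratio = m1_m2_log_ratio(immune)
                manifest["exclusions"]["m1_m2_zero"] = ratio.n_excluded
                common = ratio.values.index.intersection(idx.index)
                rho, pv = spearman_with_p(idx.loc[common].to_numpy(),
                                          ratio.values.loc[common].to_numpy())
                assoc_rows.append(("rsi_vs_log2_m1_m2", rho, pv, len(common)))
            assoc = pd.DataFrame(assoc_rows,
                                 columns=["pair", "spearman_rho", "p", "n"])
            p = cfg.outdir / "associations.tsv"
            _write_tsv(assoc, p)
            _emit("associations", p)
            manifest["stages"]["associate"] = {
                "pairs": {r.pair: float(r.spearman_rho) for r in assoc.itertuples()}
            }

        if "classify" in cfg.stages:
            if subtypes is None:
                raise ValidationError("classify stage requires immune subtypes")
            y = (subtypes.loc[expr.sample_ids] == "C2").to_numpy().astype(int)
            X = expr.data.loc[list(sig.genes)].T
            fi = gini_importance(X, y, n_trees=cfg.n_trees, seed=cfg.seed)
            selected = select_features(fi)
            p = cfg.outdir / "importance.tsv"
            _write_tsv(fi.table.assign(mean_mdg=fi.mean_mdg,
                                       selected=fi.table["gene"].isin(selected)), p)
            _emit("importance", p)
            rep = train_eval(X[selected], y, n_splits=cfg.n_splits,
                             n_trees=cfg.n_trees, seed=cfg.seed)
            cp = youden_cutpoint(rep.oof_scores, rep.labels)
            p = cfg.outdir / "roc.tsv"
            _write_tsv(rep.roc_points, p)
            _emit("roc", p)
            report_doc = {
                "selected_genes": selected,
                "accuracy": rep.accuracy,
                "accuracy_ci": list(rep.accuracy_ci),
                "auc": rep.auc,
                "confusion": rep.confusion,
                "scheme": rep.scheme,
                "seed": rep.seed,
                "youden_cutpoint": dataclasses.asdict(cp),
            }
            p = cfg.outdir / "classifier_report.json"
            p.write_text(json.dumps(report_doc, indent=2))
            _emit("classifier_report", p)
            manifest["stages"]["classify"] = {
                "selected_genes": selected, "auc": rep.auc,
                "accuracy": rep.accuracy,
            }

        if "survival" in cfg.stages:
            if surv is None:
                raise ValidationError("survival stage requires survival records")
            if scores is None:
                raise ValidationError("survival stage requires the score stage")
            merged = surv.merge(scores, on="sample_id")
            t = merged["time"].to_numpy()
            e = merged["event"].to_numpy()
            curves = []
            for label, grp in merged.groupby("category"):
                km = km_fit(grp["time"].to_numpy(), grp["event"].to_numpy())
                curves.append(pd.DataFrame({
                    "group": label, "time": km.times,
                    "survival": km.survival, "at_risk": km.at_risk,
                }))
            p = cfg.outdir / "km_curves.tsv"
            _write_tsv(pd.concat(curves, ignore_index=True), p)
            _emit("km_curves", p)
            surv_doc: dict = {}
            if merged["category"].nunique() == 2 and e.sum() > 0:
                chi2, pv = logrank(t, e, merged["category"].to_numpy())
                hr = cox_univariate(t, e,
                                    (merged["category"] == "RSI-High").to_numpy()
                                    .astype(float))
                surv_doc["logrank"] = {"chi2": chi2, "p": pv}
                surv_doc["cox_rsi_high"] = {
                    "hr": hr.hr, "ci": [hr.ci_low, hr.ci_high], "p": hr.p,
                    "converged": hr.converged,
                }
            cp = surv_cutpoint(t, e, merged["rsi"].to_numpy(), cfg.minprop)
            surv_doc["optimal_cutpoint"] = dataclasses.asdict(cp)
            p = cfg.outdir / "survival_tests.json"
            p.write_text(json.dumps(surv_doc, indent=2))
            _emit("survival_tests", p)
            manifest["stages"]["survival"] = surv_doc
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["status"] = "complete"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable markdown summary of a completed (or partial) run."""
    lines = [f"# rsikit run report (v{manifest.get('version', '?')})", ""]
    status = manifest.get("status", "unknown")
    if status != "complete":
        lines.append(f"**Partial run** — status: {status}")
        lines.append("")
    lines.append(f"- seed: {manifest.get('seed')}")
    for stage, info in manifest.get("stages", {}).items():
        lines.append(f"\n## {stage}")
        for key, val in info.items():
            lines.append(f"- {key}: {val}")
    excl = manifest.get("exclusions", {})
    if excl:
        lines.append("\n## exclusions")
        for key, val in excl.items():
            lines.append(f"- {key}: {val}")
    lines.append("\n## artifacts")
    for name, art in manifest.get("artifacts", {}).items():
        lines.append(f"- {name}: {art['path']} (sha256 {art['sha256'][:12]}...)")
    return "\n".join(lines) + "\n"
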