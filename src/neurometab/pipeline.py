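"""End-to-end orchestration: simulate -> behavior -> features -> screen -> roc.

A :class:`RunConfig` (loadable from YAML) names every analysis choice that
is a genuine fork — CRLB threshold, inclusion mode, permutation count and
sidedness, t-test variant, ROC positive class and CI method — so a run is
fully specified by (config, seed) and reruns are byte-identical.  Each
stage writes its own CSV; a manifest records the config hash, seed and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .behavior import behavior_table, two_way_anova_sidak
from .features import apply_crlb_filter, derive_features, metabolite_inclusion
from .roc import binormal_roc, fit_simple_logistic
from .screen import group_tests, screen, screen_frame
from .synth import CohortSpec, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of one full pipeline run."""

    outdir: str = "results/run"
    simulate: bool = True
    animals_csv: str | None = None
    metabolites_csv: str | None = None
    seed: int | None = None
    regions: tuple = ("PFC", "HPC")
    indices: tuple = ("preference", "recognition")
    max_crlb_pct: float = 50.0
    min_n: int = 5
    inclusion_mode: str = "per_group"
    permutations: int = 5000
    sidedness: str = "two_sided"
    t_variant: str = "welch"
    roc_positive: str | None = None  # must be set explicitly for the ROC stage
    roc_features: tuple = ("Glu/GABA", "tCr", "NAA/tCr")
    roc_region: str = "PFC"
    roc_ci_method: str = "hanley-mcneil"
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> "RunConfig":
        if not 0 <= self.max_crlb_pct:
            raise ValueError("max_crlb_pct must be non-negative")
        if self.min_n < 0:
            raise ValueError("min_n must be non-negative")
        if self.inclusion_mode not in ("per_group", "total"):
            raise ValueError("inclusion_mode must be per_group or total")
        if self.t_variant not in ("welch", "student"):
            raise ValueError("t_variant must be welch or student")
        if self.sidedness not in ("two_sided", "greater", "less"):
            raise ValueError("bad sidedness")
        needs_seed = self.simulate or self.permutations > 0
        if needs_seed and self.seed is None:
            raise ValueError("a seed is required whenever any stochastic stage runs")
        return self

    def content_hash(self) -> str:
        # outdir is where results land, not part of the analysis identity
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict of in-memory stage outputs (tables and result lists);
    all CSV/JSON artifacts land under ``config.outdir``.
    """
    cfg = config.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        if cfg.simulate:
            spec = CohortSpec(seed=int(cfg.seed), **cfg.cohort)
            animals, measurements, truth = generate_cohort(spec)
            write_cohort(animals, measurements, truth, out)
        else:
            if not (cfg.animals_csv and cfg.metabolites_csv):
                raise ValueError("need animals_csv and metabolites_csv when not simulating")
            animals = pd.read_csv(cfg.animals_csv)
            measurements = pd.read_csv(cfg.metabolites_csv)
            truth = None

        stage = "behavior"
        btab = behavior_table(animals)
        _csv(btab, out / "behavior_results.csv", index=False)
        anova_rows = []
        for session in cfg.indices:
            sub = animals[animals["session"] == session]
            long = pd.concat(
                [
                    sub.assign(target="target", value=sub["et_target"]),
                    sub.assign(target="other", value=sub["et_other"]),
                ]
            )
            res = two_way_anova_sidak(long, value="value")
            a = res["anova"].reset_index().assign(session=session)
            anova_rows.append(a)
        _csv(pd.concat(anova_rows), out / "anova.csv", index=False)

        stage = "features"
        filtered = apply_crlb_filter(measurements, cfg.max_crlb_pct)
        genotypes = animals.drop_duplicates("id").set_index("id")["genotype"]
        inclusion = metabolite_inclusion(filtered, genotypes, cfg.min_n, cfg.inclusion_mode)
        feats = derive_features(filtered)
        _csv(feats, out / "features.csv")
        _csv(inclusion, out / "inclusion_report.csv")

        stage = "screen"
        pivots = btab.pivot_table(index="id", columns="session", values="pi", aggfunc="first")
        screen_frames = []
        for region in cfg.regions:
            for index_name in cfg.indices:
                if index_name not in pivots.columns:
                    continue
                res = screen(
                    feats, pivots[index_name], region, index_name,
                    B=cfg.permutations, seed=int(cfg.seed),
                    sidedness=cfg.sidedness, included=inclusion,
                )
                screen_frames.append(screen_frame(res))
        screen_df = pd.concat([f for f in screen_frames if len(f)], ignore_index=True)
        _csv(screen_df, out / "screen_results.csv", index=False)
        _csv(
            screen_df[["feature", "region", "index", "r", "neglog10_p", "tier"]],
            out / "volcano.csv", index=False,
        )

        stage = "group tests"
        gt = pd.concat(
            [group_tests(feats, genotypes, r, cfg.t_variant) for r in cfg.regions],
            ignore_index=True,
        )
        _csv(gt, out / "group_tests.csv", index=False)

        stage = "roc"
        roc_rows, roc_results = [], []
        if cfg.roc_positive is not None:
            sub = feats.xs(cfg.roc_region, level="region")
            for feat in cfg.roc_features:
                col = sub[feat].dropna()
                g = genotypes.loc[col.index]
                pos = col[g == cfg.roc_positive].to_numpy()
                neg = col[g != cfg.roc_positive].to_numpy()
                lab = (g == cfg.roc_positive).astype(int)
                logit = fit_simple_logistic(col.to_numpy(), lab.to_numpy())
                rr = binormal_roc(
                    neg, pos, feature=feat, positive=cfg.roc_positive,
                    ci_method=cfg.roc_ci_method, seed=cfg.seed,
                )
                rr.logistic = logit
                roc_results.append(rr)
                roc_rows.append(
                    {
                        "feature": feat, "region": cfg.roc_region,
                        "positive": cfg.roc_positive, "auc": rr.auc,
                        "auc_ci_low": rr.auc_ci_low, "auc_ci_high": rr.auc_ci_high,
                        "cutoff": rr.cutoff,
                        "sensitivity_pct": rr.sensitivity_pct,
                        "specificity_pct": rr.specificity_pct,
                        "logistic_intercept": logit.intercept,
                        "logistic_slope": logit.slope,
                        "separated": logit.separated,
                        "n_pos": rr.n1, "n_neg": rr.n0,
                        "note": "in-sample training (all samples used to fit)",
                    }
                )
            _csv(pd.DataFrame(roc_rows), out / "roc_results.csv", index=False)
    except Exception as exc:
        (out / "INVALID").write_text(f"stage {stage!r} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "config": dataclasses.asdict(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))

    _write_report(out, screen_df, gt, roc_rows, inclusion)
    return {
        "animals": animals, "measurements": measurements, "truth": truth,
        "behavior": btab, "features": feats, "inclusion": inclusion,
        "screen": screen_df, "group_tests": gt, "roc": roc_results,
        "manifest": manifest,
    }


def _write_report(out: Path, screen_df, gt, roc_rows, inclusion) -> None:
    lines = ["# Pipeline report", ""]
    lines += ["## Per-feature n after CRLB filtering", ""]
    lines.append(inclusion.reset_index().to_string(index=False))
    lines += ["", "## Correlation screen (permutation-calibrated)", ""]
    hits = screen_df[screen_df["tier"] != "none"]
    lines.append(hits.to_string(index=False) if len(hits) else "no features passed the q95 tier")
    lines += ["", "## Genotype group tests", ""]
    sig = gt[gt["p"] < 0.05]
    lines.append(sig.to_string(index=False) if len(sig) else "no significant group differences")
    if roc_rows:
        lines += ["", "## ROC biomarker table (in-sample training)", ""]
        lines.append(pd.DataFrame(roc_rows).to_string(index=False))
    (out / "report.md").write_text("\n".join(lines) + "\n")
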