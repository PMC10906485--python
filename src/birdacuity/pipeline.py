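"""End-to-end orchestration: ingest, classify, transform, exclude
outliers, fit, rank, compare, report.

The pipeline mirrors a comparative acuity analysis: per-species record
selection and unit conversion; ecological classification; pruning the
phylogeny to the analyzed species; log transforms; Pagel's lambda on
acuity; an acuity ~ eye size PGLS with Cook's-distance outlier exclusion
and refit; a collinearity screen; the all-subsets AIC model table over
eye size plus the five ecological variables (and the ecological-only
space with eye size forced absent); the residual cascade (relative eye
size, residual acuity); and a phylogenetic ANOVA with Holm-corrected
post hocs and estimated marginal means for every ecological variable
crossed with the three responses.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ecology import (
    SpeciesRecord,
    build_profile,
    select_record,
    to_cpd,
)
from .group_compare import marginal_means, phyl_anova
from .inference import FitError, fit_gls, pagels_lambda, residual_cascade
from .model_select import collinearity_screen, fit_all_subsets
from .phylo import Tree, normalize_label, parse_newick

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "PipelineError",
    "load_traits",
    "load_config",
    "run_pipeline",
    "analyze",
    "exclude_outliers",
    "write_report",
]

ECO_VARS = ["habitat_class", "light_class", "diet_class", "prey_mobility", "foraging_mode"]
RESPONSES = ["log_acuity", "relative_eye_size", "residual_acuity"]

_HABITAT_COLS = {
    "habitat_understory": "understory",
    "habitat_mid_high": "mid_high",
    "habitat_aerial": "aerial",
    "habitat_open_water": "open_water",
    "habitat_ground": "ground",
    "habitat_water_surface": "water_surface",
    "habitat_canopy": "canopy",
}


class PipelineError(ValueError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; the seed is mandatory."""

    tree_path: str | None = None
    traits_path: str | None = None
    output_dir: str | None = None
    seed: int | None = None
    log_base: str | float = "e"  # "e", "10", or a numeric base
    habitat_threshold_pct: float = 70.0
    diet_threshold_pct: float = 50.0
    corr_threshold: float = 0.7
    cooks_rule: str = "4/n"
    n_sims: int = 1000
    lambda_boundary_mixture: bool = False
    subset: str = "all"  # all | rgc_only | behavior_only
    rgc_rerun: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        for name in ("habitat_threshold_pct", "diet_threshold_pct"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} must be in (0, 100)")
        if not (0.0 < self.corr_threshold):
            raise ValueError("corr_threshold must be positive")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if self.subset not in ("all", "rgc_only", "behavior_only"):
            raise ValueError(f"unknown subset {self.subset!r}")

    def log(self, x):
        if self.log_base == "e":
            return np.log(x)
        if self.log_base in ("10", 10, 10.0):
            return np.log10(x)
        return np.log(x) / math.log(float(self.log_base))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read a config from JSON or a flat key=value file."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        raw = json.loads(text)
    else:
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key=value): {line!r}")
            k, v = line.split("=", 1)
            raw[k.strip()] = v.strip()
    fields = PipelineConfig.__dataclass_fields__
    kwargs = {}
    for k, v in raw.items():
        if k not in fields:
            raise ValueError(f"unknown config key {k!r}")
        ftype = fields[k].type
        if isinstance(v, str):
            if "int" in ftype:
                v = int(v)
            elif "float" in ftype and k != "log_base":
                v = float(v)
            elif "bool" in ftype:
                v = v.lower() in ("1", "true", "yes")
        kwargs[k] = v
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------


def _row_to_record(row: pd.Series) -> SpeciesRecord:
    habitat_pct = {
        stratum: float(row[col])
        for col, stratum in _HABITAT_COLS.items()
        if col in row.index and pd.notna(row[col])
    }
    diet_raw = {
        col[len("diet_") :]: float(row[col])
        for col in row.index
        if col.startswith("diet_") and pd.notna(row[col])
    }
    keywords = []
    if pd.notna(row.get("habitat_keywords", None)) and str(row["habitat_keywords"]):
        keywords = [t for t in str(row["habitat_keywords"]).split(";") if t]
    maneuvers = []
    if pd.notna(row.get("maneuvers", None)) and str(row["maneuvers"]):
        maneuvers = [t for t in str(row["maneuvers"]).split(";") if t]

    def _optional(col):
        v = row.get(col, None)
        return float(v) if v is not None and pd.notna(v) else None

    return SpeciesRecord(
        species=normalize_label(str(row["species"])),
        acuity_cpd=to_cpd(float(row["acuity_value"]), str(row["acuity_unit"])),
        method=str(row["method"]),
        source_year=int(row["source_year"]),
        eye_axial_length_mm=_optional("eye_axial_length_mm"),
        body_mass_g=_optional("body_mass_g"),
        habitat_pct=habitat_pct,
        diet_raw=diet_raw,
        habitat_keywords=keywords,
        nocturnal=bool(int(row.get("nocturnal", 0) or 0)),
        maneuvers=maneuvers,
    )


def load_traits(path) -> list[SpeciesRecord]:
    """Read the species trait CSV into one record per row."""
    df = pd.read_csv(path)
    required = {"species", "acuity_value", "acuity_unit", "method", "source_year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traits CSV missing columns: {sorted(missing)}")
    return [_row_to_record(row) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# outlier exclusion
# ---------------------------------------------------------------------------


def exclude_outliers(fit, rule: str, labels: list[str]):
    """Split species into kept and excluded by a Cook's-distance rule.

    ``"4/n"`` excludes observations with D_i > 4/n; ``"topk:K"``
    excludes the K most influential.  The exclusion list is sorted by
    D_i descending.  Single pass: no iterative re-exclusion.
    """
    D = np.asarray(fit.cooks_d, dtype=float)
    n = len(labels)
    if len(D) != n:
        raise ValueError("labels do not match the fitted observations")
    if rule == "4/n":
        mask = D > 4.0 / n
    elif rule.startswith("topk:"):
        try:
            k = int(rule.split(":", 1)[1])
        except ValueError:
            raise ValueError(f"bad topk rule {rule!r}")
        if k < 0 or k > n:
            raise ValueError(f"topk K={k} out of range")
        mask = np.zeros(n, dtype=bool)
        if k > 0:
            mask[np.argsort(D, kind="mergesort")[-k:]] = True
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    excluded = sorted(
        ((labels[i], float(D[i])) for i in np.flatnonzero(mask)),
        key=lambda t: -t[1],
    )
    kept = [labels[i] for i in range(n) if not mask[i]]
    return kept, excluded


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Everything one pipeline run computed, plus provenance."""

    config: dict
    config_hash: str
    version: str
    sample_sizes: dict
    lambda_acuity: dict
    fits: dict  # named coefficient tables / diagnostics
    excluded_species: list  # (species, cooks_d), descending
    collinearity_flags: list
    model_table: "pd.DataFrame"
    model_table_eco_only: "pd.DataFrame"
    species_table: "pd.DataFrame"
    anova: dict  # {response: {eco_var: {...}}}
    skipped_variables: list
    marginal: dict  # {response: {eco_var: {"phylogenetic": [...], "ordinary": [...]}}}
    pruned_newick: str
    contrast_table: "pd.DataFrame"
    rgc_subreport: dict | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "version": self.version,
            "sample_sizes": self.sample_sizes,
            "lambda_acuity": self.lambda_acuity,
            "fits": self.fits,
            "excluded_species": self.excluded_species,
            "collinearity_flags": self.collinearity_flags,
            "model_table": self.model_table.to_dict(orient="records"),
            "model_table_eco_only": self.model_table_eco_only.to_dict(orient="records"),
            "anova": self.anova,
            "skipped_variables": self.skipped_variables,
            "marginal": self.marginal,
            "rgc_subreport": self.rgc_subreport,
        }


def _fit_summary(fit) -> dict:
    return fit.to_dict()


def _stage(name: str):
    class _StageCtx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _StageCtx()


def analyze(tree: Tree, records: list[SpeciesRecord], config: PipelineConfig) -> AnalysisReport:
    """Run the full analysis on an in-memory tree and record list."""
    # 1. record selection (unit conversion already applied at ingest)
    with _stage("record selection"):
        by_species: dict[str, list[SpeciesRecord]] = {}
        for r in records:
            by_species.setdefault(r.species, []).append(r)
        selected = {sp: select_record(rs) for sp, rs in by_species.items()}
    n_input = len(selected)

    # 2. ecological classification
    with _stage("classification"):
        profiles = {
            sp: build_profile(
                r,
                habitat_threshold=config.habitat_threshold_pct,
                diet_threshold=config.diet_threshold_pct,
            )
            for sp, r in selected.items()
        }

    # 3. drop species missing eye size or body mass
    dropped_missing = sorted(
        sp
        for sp, r in selected.items()
        if r.eye_axial_length_mm is None
        or r.body_mass_g is None
        or not np.isfinite(r.eye_axial_length_mm)
        or not np.isfinite(r.body_mass_g)
    )
    analyzed = {sp: r for sp, r in selected.items() if sp not in set(dropped_missing)}

    # subset filter (rgc_only / behavior_only)
    if config.subset == "rgc_only":
        subset_excluded = sorted(sp for sp, r in analyzed.items() if r.method != "RGC")
    elif config.subset == "behavior_only":
        subset_excluded = sorted(sp for sp, r in analyzed.items() if r.method != "behavioral")
    else:
        subset_excluded = []
    analyzed = {sp: r for sp, r in analyzed.items() if sp not in set(subset_excluded)}
    if len(analyzed) < 4:
        raise PipelineError("stage 'subset': fewer than 4 species left to analyze")

    # 4. prune tree
    with _stage("prune"):
        tips = set(tree.tip_labels)
        not_in_tree = sorted(set(analyzed) - tips)
        if not_in_tree:
            raise FitError(f"species missing from tree: {not_in_tree}")
        pruned = tree.prune(set(analyzed))

    # 5. assemble the working frame in tree tip order; log transforms
    with _stage("transform"):
        order = pruned.tip_labels
        df = pd.DataFrame(
            {
                "species": order,
                "acuity_cpd": [analyzed[sp].acuity_cpd for sp in order],
                "eye_axial_length_mm": [analyzed[sp].eye_axial_length_mm for sp in order],
                "body_mass_g": [analyzed[sp].body_mass_g for sp in order],
                "method": [analyzed[sp].method for sp in order],
            }
        ).set_index("species")
        for var in ECO_VARS:
            df[var] = [getattr(profiles[sp], var) for sp in order]
        df["log_acuity"] = config.log(df["acuity_cpd"])
        df["log_eye_size"] = config.log(df["eye_axial_length_mm"])
        df["log_body_mass"] = config.log(df["body_mass_g"])

    # 6. Pagel's lambda on log acuity
    with _stage("pagels_lambda"):
        C_full = pruned.vcv()
        lam = pagels_lambda(
            df["log_acuity"].to_numpy(),
            C_full,
            boundary_mixture=config.lambda_boundary_mixture,
        )

    # 7. acuity ~ eye size, outlier exclusion, refit and re-prune
    with _stage("outlier exclusion"):
        n = len(df)
        X = np.column_stack([np.ones(n), df["log_eye_size"].to_numpy()])
        fit_pre = fit_gls(
            X, df["log_acuity"].to_numpy(), C_full, names=["(Intercept)", "log_eye_size"]
        )
        kept, excluded = exclude_outliers(fit_pre, config.cooks_rule, list(df.index))
        if len(kept) < 4:
            raise FitError("outlier rule removed too many species")
        if excluded:
            pruned = pruned.prune(kept)
            order = pruned.tip_labels
            df = df.loc[order]
            C_full = pruned.vcv()
        n = len(df)
        X = np.column_stack([np.ones(n), df["log_eye_size"].to_numpy()])
        fit_acuity_eye = fit_gls(
            X, df["log_acuity"].to_numpy(), C_full, names=["(Intercept)", "log_eye_size"]
        )
        Xm = np.column_stack([np.ones(n), df["log_body_mass"].to_numpy()])
        fit_acuity_mass = fit_gls(
            Xm, df["log_acuity"].to_numpy(), C_full, names=["(Intercept)", "log_body_mass"]
        )

    # 8. collinearity screen
    with _stage("collinearity screen"):
        pred_table = df[["log_eye_size"] + ECO_VARS]
        flags = collinearity_screen(pred_table, threshold=config.corr_threshold)

    # 9. all-subsets model tables (with eye size; ecological-only)
    with _stage("model selection"):
        mt = fit_all_subsets(
            df, "log_acuity", ["log_eye_size"], ECO_VARS, C_full
        )
        mt_eco = fit_all_subsets(
            df,
            "log_acuity",
            ["log_eye_size"],
            ECO_VARS,
            C_full,
            force_absent=["log_eye_size"],
        )

    # 10. residual cascade
    with _stage("residual cascade"):
        rel_eye, resid_acuity, (fit_eye_mass, fit_acuity_rel) = residual_cascade(
            df["log_acuity"].to_numpy(),
            df["log_eye_size"].to_numpy(),
            df["log_body_mass"].to_numpy(),
            C_full,
        )
        df["relative_eye_size"] = rel_eye
        df["residual_acuity"] = resid_acuity

    # 11. phylogenetic ANOVA + post hocs + marginal means, per variable x response
    anova: dict = {resp: {} for resp in RESPONSES}
    marginal: dict = {resp: {} for resp in RESPONSES}
    skipped: list = []
    contrast_rows = []
    combo_idx = 0
    for resp in RESPONSES:
        for var in ECO_VARS:
            combo_idx += 1
            counts = df[var].value_counts()
            try:
                res = phyl_anova(
                    df[resp].to_numpy(),
                    df[var],
                    pruned,
                    n_sims=config.n_sims,
                    seed=int(config.seed) + combo_idx,
                )
            except (FitError, ValueError) as exc:
                skipped.append({"response": resp, "variable": var, "reason": str(exc)})
                continue
            anova[resp][var] = {
                "f_stat": res.f_stat,
                "p_classical": res.p_classical,
                "p_phylogenetic": res.p_phylogenetic,
                "n_sims": res.n_sims,
                "seed": res.seed,
                "group_means": res.group_means,
            }
            mm_phy = marginal_means(df[resp].to_numpy(), df[var], C_full)
            mm_ord = marginal_means(df[resp].to_numpy(), df[var], None)
            marginal[resp][var] = {
                "phylogenetic": mm_phy.to_dict(orient="records"),
                "ordinary": mm_ord.to_dict(orient="records"),
            }
            ct = res.contrasts()
            ct.insert(0, "response", resp)
            ct.insert(1, "category", var)
            contrast_rows.append(ct)
    contrast_table = (
        pd.concat(contrast_rows, ignore_index=True)
        if contrast_rows
        else pd.DataFrame(
            columns=["response", "category", "level_a", "level_b", "t", "p_raw", "p_classical", "p_holm"]
        )
    )

    # 12. optional RGC-only re-run (summary only)
    rgc_sub = None
    if config.rgc_rerun and config.subset == "all":
        sub_cfg = PipelineConfig(**{**config.to_dict(), "subset": "rgc_only", "rgc_rerun": False})
        try:
            sub = analyze(tree, records, sub_cfg)
            rgc_sub = {
                "sample_sizes": sub.sample_sizes,
                "lambda_acuity": sub.lambda_acuity,
                "fits": {k: sub.fits[k] for k in ("acuity_vs_eye_size",)},
                "best_model": sub.model_table.iloc[0].to_dict(),
            }
        except (PipelineError, FitError, ValueError) as exc:
            rgc_sub = {"error": str(exc)}

    sample_sizes = {
        "n_input_species": n_input,
        "n_dropped_missing_data": len(dropped_missing),
        "n_excluded_subset": len(subset_excluded),
        "n_excluded_outliers": len(excluded),
        "n_analyzed": len(df),
        "dropped_missing_data": dropped_missing,
        "excluded_subset": subset_excluded,
        "n_rgc": int((df["method"] == "RGC").sum()),
        "n_behavioral": int((df["method"] == "behavioral").sum()),
    }

    fits = {
        "acuity_vs_eye_size_pre_exclusion": _fit_summary(fit_pre),
        "acuity_vs_eye_size": _fit_summary(fit_acuity_eye),
        "acuity_vs_body_mass": _fit_summary(fit_acuity_mass),
        "eye_size_vs_body_mass": _fit_summary(fit_eye_mass),
        "acuity_vs_relative_eye_size": _fit_summary(fit_acuity_rel),
    }
    # df subscript convention is ambiguous in common usage; emit both
    for v in fits.values():
        v["df_residual_n_minus_p"] = v["df_residual"]
        v["df_n"] = v["n_obs"]

    return AnalysisReport(
        config=config.to_dict(),
        config_hash=config.hash(),
        version=__version__,
        sample_sizes=sample_sizes,
        lambda_acuity=lam.to_dict(),
        fits=fits,
        excluded_species=[[sp, d] for sp, d in excluded],
        collinearity_flags=[
            {"a": f.a, "b": f.b, "measure": f.measure, "score": f.score} for f in flags
        ],
        model_table=mt.table,
        model_table_eco_only=mt_eco.table,
        species_table=df.reset_index(),
        anova=anova,
        skipped_variables=skipped,
        marginal=marginal,
        pruned_newick=pruned.to_newick(),
        contrast_table=contrast_table,
        rgc_subreport=rgc_sub,
    )


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Load inputs from the configured paths, analyze, optionally write."""
    if not config.tree_path or not config.traits_path:
        raise PipelineError("stage 'ingest': tree_path and traits_path are required")
    with _stage("ingest"):
        tree = parse_newick(Path(config.tree_path).read_text())
        records = load_traits(config.traits_path)
    report = analyze(tree, records, config)
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def write_report(report: AnalysisReport, directory) -> dict:
    """Serialize a report: JSON, tidy CSVs, pruned Newick, log file."""
    if report.model_table is None or len(report.model_table) == 0:
        raise ValueError("incomplete report: empty model table")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _jsonable(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    paths["report"] = d / "report.json"
    paths["report"].write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    paths["model_table"] = d / "model_table.csv"
    report.model_table.to_csv(paths["model_table"], index=False)
    paths["model_table_eco_only"] = d / "model_table_eco_only.csv"
    report.model_table_eco_only.to_csv(paths["model_table_eco_only"], index=False)
    paths["contrasts"] = d / "contrasts.csv"
    report.contrast_table.to_csv(paths["contrasts"], index=False)
    paths["species"] = d / "species.csv"
    report.species_table.to_csv(paths["species"], index=False)
    paths["tree"] = d / "pruned_tree.nwk"
    paths["tree"].write_text(report.pruned_newick + "\n")
    paths["log"] = d / "run.log"
    lines = [
        f"birdacuity {report.version}",
        f"config_hash {report.config_hash}",
        f"seed {report.config['seed']}",
        *(f"{k} {v}" for k, v in sorted(report.sample_sizes.items()) if isinstance(v, int)),
        f"lambda_hat {report.lambda_acuity['lambda_hat']:.6f}",
        f"n_models {len(report.model_table)}",
        f"n_models_eco_only {len(report.model_table_eco_only)}",
    ]
    paths["log"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}
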