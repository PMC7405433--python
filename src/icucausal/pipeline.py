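"""Orchestration of the two-arm causal analysis.

Reproduces the full analysis grid on any cohort frame: the unadjusted
(raw) marginal risk difference, the traditional arm (complete-case
logistic regression + G-computation of the ATU), and the robust arm
(multiple imputation + super-learner nuisances + one-step TMLE, pooled by
Rubin's rules), each under the applicable data treatments (complete cases
in the exposure, complete cases in exposure and confounders, imputation).
Also drives the BMI-cutoff sensitivity analysis and report rendering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cohort import (
    CONFOUNDERS,
    EXPOSURE,
    Cohort,
    DEFAULT_BMI_CUTOFF,
    derive_anthropometrics,
    complete_case_filter,
    summarize_baseline,
)
from .errors import ConfigError, DataError
from .estimators import (
    EffectEstimate,
    LogisticFit,
    fit_logistic,
    gcomp_effect,
    raw_rd_from_cohort,
)
from .impute import ImputationSet, PooledEstimate, chained_impute, pool_rubin
from .learners import full_library, reduced_library
from .tmle import DEFAULT_G_BOUNDS, robust_pipeline

logger = logging.getLogger(__name__)

GRID_ROWS = ("raw_rd", "gcomp_atu", "tmle_atu")
GRID_COLS = ("complete_A", "complete_AC", "imputed")

_ROW_METHOD = {"raw_rd": "regression", "gcomp_atu": "regression_gcomp",
               "tmle_atu": "tmle_sl"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All analysis settings; profiles encode the two standard setups."""

    seed: int = 0
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF
    confounders: list[str] = field(default_factory=lambda: list(CONFOUNDERS))
    m: int = 50
    n_iter: int = 10
    k_folds: int = 10
    loss: str = "log"
    g_bounds: tuple[float, float] = DEFAULT_G_BOUNDS
    library: str = "full"
    se_method: str = "delta"

    def candidates(self):
        if self.library == "full":
            return full_library(self.seed)
        if self.library == "reduced":
            return reduced_library(self.seed)
        raise ConfigError(f"unknown library {self.library!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def profile(cls, name: str, **overrides) -> "AnalysisConfig":
        if name == "paper":
            cfg = cls()
        elif name == "test":
            cfg = cls(m=5, n_iter=5, k_folds=5, library="reduced")
        else:
            raise ConfigError(f"unknown profile {name!r}")
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        profile = raw.pop("profile", None)
        base = cls.profile(profile) if profile else cls()
        known = set(asdict(base))
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        raw.update(overrides)
        if "g_bounds" in raw:
            raw["g_bounds"] = tuple(raw["g_bounds"])
        return replace(base, **raw)


# ---------------------------------------------------------------------------
# Analysis grid
# ---------------------------------------------------------------------------

@dataclass
class AnalysisGrid:
    """Method-by-data-treatment grid of effect estimates (cells may be absent)."""

    cells: dict[tuple[str, str], EffectEstimate | None] = field(default_factory=dict)

    def set(self, row: str, col: str, est: EffectEstimate | None) -> None:
        if row not in GRID_ROWS or col not in GRID_COLS:
            raise ConfigError(f"invalid grid cell ({row}, {col})")
        if est is not None:
            if est.method != _ROW_METHOD[row] or est.data_treatment != col:
                raise DataError(
                    f"cell provenance mismatch at ({row}, {col}): "
                    f"{est.method}/{est.data_treatment}")
        self.cells[(row, col)] = est

    def get(self, row: str, col: str) -> EffectEstimate | None:
        return self.cells.get((row, col))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (row, col), est in sorted(self.cells.items()):
            if est is None:
                rows.append(dict(estimand=row, data_treatment=col))
                continue
            rows.append(dict(
                estimand=row, data_treatment=col, method=est.method,
                point_pct=100 * est.point, ci_low_pct=100 * est.ci_low,
                ci_high_pct=100 * est.ci_high, p_value=est.p_value, n=est.n))
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        out = {}
        for (row, col), est in self.cells.items():
            key = f"{row}|{col}"
            out[key] = None if est is None else dict(
                estimand=est.estimand, method=est.method,
                data_treatment=est.data_treatment, point=est.point,
                se=est.se, ci_low=est.ci_low, ci_high=est.ci_high,
                p_value=est.p_value, n=est.n)
        return json.dumps(out, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisGrid":
        grid = cls()
        for key, val in json.loads(text).items():
            row, col = key.split("|")
            if val is None:
                grid.cells[(row, col)] = None
            else:
                grid.cells[(row, col)] = EffectEstimate(
                    val["estimand"], val["method"], val["data_treatment"],
                    val["point"], val["se"], val["ci_low"], val["ci_high"],
                    val["p_value"], val["n"])
        return grid


# ---------------------------------------------------------------------------
# Arms
# ---------------------------------------------------------------------------

def run_traditional(
    cohort: Cohort, config: AnalysisConfig
) -> tuple[LogisticFit, EffectEstimate, dict]:
    """Complete-case logistic regression + G-computation of the ATU.

    Returns the fitted coefficient table, the ATU estimate, and extras
    (raw risk differences under both complete-case treatments, counts).
    """
    analysis_vars = [EXPOSURE] + list(config.confounders)
    cc, n_discarded = complete_case_filter(cohort, analysis_vars)
    fit = fit_logistic(cc.data, confounders=config.confounders)
    atu = gcomp_effect(fit, cc.data, estimand="atu",
                       data_treatment="complete_AC",
                       se_method=config.se_method, seed=config.seed)
    extras = {
        "n_complete": len(cc),
        "n_discarded": n_discarded,
        "raw_rd_complete_A": raw_rd_from_cohort(cohort.data, "complete_A"),
        "raw_rd_complete_AC": raw_rd_from_cohort(cc.data, "complete_AC"),
    }
    return fit, atu, extras


def _pool_effects(points_vars, n, estimand, method, data_treatment):
    pooled = pool_rubin(points_vars, df_complete=n - 1)
    eff = pooled.as_effect(estimand=estimand, method=method,
                           data_treatment=data_treatment, n=n)
    eff.method = method
    return eff, pooled


def run_robust(
    cohort: Cohort, config: AnalysisConfig,
    imputation_set: ImputationSet | None = None,
) -> tuple[PooledEstimate, ImputationSet, list[dict]]:
    """MICE -> (super learner + one-step TMLE) per imputation -> Rubin pool."""
    if imputation_set is None:
        imputation_set = chained_impute(
            cohort, m=config.m, n_iter=config.n_iter, seed=config.seed,
            bmi_cutoff=config.bmi_cutoff)
    pooled, diagnostics = robust_pipeline(
        imputation_set, candidates=config.candidates(), k=config.k_folds,
        loss=config.loss, g_bounds=config.g_bounds, seed=config.seed,
        confounders=config.confounders)
    return pooled, imputation_set, diagnostics


def run_grid(cohort: Cohort, config: AnalysisConfig) -> tuple[AnalysisGrid, dict]:
    """Full summary grid: both arms under every applicable data treatment."""
    t0 = time.time()
    grid = AnalysisGrid()
    fit, atu_cc, extras = run_traditional(cohort, config)
    grid.set("raw_rd", "complete_A", extras["raw_rd_complete_A"])
    grid.set("raw_rd", "complete_AC", extras["raw_rd_complete_AC"])
    grid.set("gcomp_atu", "complete_A", None)   # not defined without confounders
    grid.set("gcomp_atu", "complete_AC", atu_cc)
    grid.set("tmle_atu", "complete_A", None)
    logger.info("traditional arm done in %.1fs (n=%d complete cases)",
                time.time() - t0, extras["n_complete"])

    # TMLE on complete cases (no imputation)
    t1 = time.time()
    analysis_vars = [EXPOSURE] + list(config.confounders)
    cc, _ = complete_case_filter(cohort, analysis_vars)
    cc_set = ImputationSet([cc.data], [], {}, 0, config.seed, config.bmi_cutoff)
    pooled_cc, diag_cc = robust_pipeline(
        cc_set, candidates=config.candidates(), k=config.k_folds,
        loss=config.loss, g_bounds=config.g_bounds, seed=config.seed,
        confounders=config.confounders)
    grid.set("tmle_atu", "complete_AC",
             pooled_cc.as_effect(estimand="atu", method="tmle_sl",
                                 data_treatment="complete_AC", n=len(cc)))
    logger.info("complete-case TMLE done in %.1fs", time.time() - t1)

    # imputation column
    t2 = time.time()
    imp = chained_impute(cohort, m=config.m, n_iter=config.n_iter,
                         seed=config.seed, bmi_cutoff=config.bmi_cutoff)
    n = len(cohort)
    raw_pairs, gcomp_pairs = [], []
    for df in imp.completed:
        rd = raw_rd_from_cohort(df, "imputed")
        raw_pairs.append((rd.point, rd.se**2))
        f = fit_logistic(df, confounders=config.confounders)
        g = gcomp_effect(f, df, estimand="atu", data_treatment="imputed",
                         se_method=config.se_method, seed=config.seed)
        gcomp_pairs.append((g.point, g.se**2))
    eff_raw, _ = _pool_effects(raw_pairs, n, "raw_rd", "regression", "imputed")
    eff_gcomp, _ = _pool_effects(gcomp_pairs, n, "atu", "regression_gcomp", "imputed")
    eff_raw.estimand = "raw_rd"
    grid.set("raw_rd", "imputed", eff_raw)
    grid.set("gcomp_atu", "imputed", eff_gcomp)
    pooled_rb, _, diag_rb = run_robust(cohort, config, imputation_set=imp)
    grid.set("tmle_atu", "imputed",
             pooled_rb.as_effect(estimand="atu", method="tmle_sl",
                                 data_treatment="imputed", n=n))
    logger.info("imputation column done in %.1fs (m=%d)", time.time() - t2, imp.m)

    meta = {
        "coefficient_table": fit.coefficient_frame(),
        "n_total": n,
        "n_complete": extras["n_complete"],
        "n_discarded": extras["n_discarded"],
        "tmle_diagnostics": {"complete_AC": diag_cc, "imputed": diag_rb},
        "config_hash": config.hash(),
    }
    return grid, meta


# ---------------------------------------------------------------------------
# Sensitivity analysis over BMI cutoffs
# ---------------------------------------------------------------------------

def run_sensitivity(
    cohort: Cohort,
    cutoffs: Sequence[float],
    config: AnalysisConfig,
) -> dict[float, dict]:
    """Re-derive the exposure at each BMI cutoff and rerun both arms.

    Returns ``{cutoff: {"grid": AnalysisGrid, "prevalence": float, ...}}``;
    a cutoff yielding an empty exposure group gets a warning and no grid.
    """
    out: dict[float, dict] = {}
    for cutoff in cutoffs:
        if cutoff <= 0:
            raise ConfigError(f"non-positive BMI cutoff {cutoff}")
        df = derive_anthropometrics(cohort.data, cutoff=cutoff)
        recut = Cohort(df, list(cohort.provenance))
        obesity = df[EXPOSURE].astype("boolean")
        known = obesity.notna()
        prevalence = (float((obesity[known] == True).mean())  # noqa: E712
                      if known.any() else float("nan"))
        entry: dict = {"prevalence": prevalence, "cutoff": cutoff}
        n_exposed = int((obesity == True).sum())  # noqa: E712
        if n_exposed == 0 or n_exposed == int(known.sum()):
            logger.warning("cutoff %.1f yields a degenerate exposure group; skipped",
                           cutoff)
            entry["grid"] = None
        else:
            cfg = replace(config, bmi_cutoff=cutoff)
            grid, meta = run_grid(recut, cfg)
            entry["grid"] = grid
            entry["meta"] = meta
        out[cutoff] = entry
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def render_reports(
    outdir: str | Path,
    grid: AnalysisGrid | None = None,
    cohort: Cohort | None = None,
    coefficient_table: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    extra_manifest: dict | None = None,
) -> list[Path]:
    """Write baseline tables, the coefficient table, the grid, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if cohort is not None:
        tables = summarize_baseline(cohort)
        for name, tab in tables.items():
            p = outdir / f"baseline_{name}.csv"
            tab.to_csv(p, index=False)
            written.append(p)
    if coefficient_table is not None:
        p = outdir / "coefficients.csv"
        coefficient_table.to_csv(p, index=False)
        written.append(p)
    if grid is not None:
        p = outdir / "summary_grid.csv"
        grid.to_frame().to_csv(p, index=False)
        written.append(p)
        p = outdir / "summary_grid.json"
        p.write_text(grid.to_json())
        written.append(p)
    manifest = {
        "config": asdict(config) if config else None,
        "config_hash": config.hash() if config else None,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(p)
    return written
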