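"""File I/O, configuration and the end-to-end pipeline orchestrator.

The pipeline chains: panel loading (or synthetic generation) -> correlation
pruning (25 -> 19 variables) -> Ward clustering (k = 3) -> per-cluster
profiling -> forward-AIC multinomial logit -> likelihood-ratio tests ->
goodness of fit -> random-forest permutation importance, writing one CSV per
table-shaped output plus a JSON summary stamped with the resolved config.
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

from . import classify, cluster as cluster_mod, panel as panel_mod
from .curves import (CurveConfig, RheoCurve, RVACurve, TPACurve,
                     extract_pasting_features, extract_rheometry_features,
                     extract_tpa_features)
from .synth import PANEL_VARIABLES_25, PanelSpec, gen_feature_panel

__all__ = [
    "PipelineConfig",
    "read_curve_csv",
    "read_panel_csv",
    "read_panel_xlsx",
    "extract_features_table",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run (snapshotted with every output)."""

    panel_path: str | None = None
    name_map: dict[str, str] = field(default_factory=dict)
    corr_threshold: float = 0.75
    drop_policy: str = "paper"
    k: int = 3
    standardize: bool = True
    reference_cluster: int = 1
    mlr_tol: float = 1e-8
    mlr_max_iter: int = 500
    rf_trees: int = 500
    rf_vars_per_split: int = 3
    seed: int = 20180245
    level_off_eps: float = 0.05
    ptemp_rate: float = 0.10
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if min(self.corr_threshold, self.mlr_tol, self.level_off_eps,
               self.ptemp_rate) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def curve_config(self) -> CurveConfig:
        return CurveConfig(smoothing_window=self.smoothing_window,
                           level_off_eps=self.level_off_eps,
                           ptemp_rate=self.ptemp_rate)


# ----------------------------------------------------------------------------
# readers

_CURVE_TYPES = {
    "rheo": (RheoCurve, ["time_min", "temp_C", "g_prime_kPa", "g_double_prime_kPa"]),
    "rva": (RVACurve, ["time_min", "temp_C", "viscosity"]),
    "tpa": (TPACurve, ["time_s", "force_kg"]),
}


def read_curve_csv(path: str | Path, kind: str) -> dict[str, object]:
    """Read long-format curve CSVs into per-sample curve objects.

    ``kind`` is one of ``rheo``/``rva``/``tpa``.  Single-trace files need no
    ``sample_id`` column (the stem is used); multi-sample files are split on
    it.
    """
    if kind not in _CURVE_TYPES:
        raise ValueError(f"unknown curve kind {kind!r}")
    cls, cols = _CURVE_TYPES[kind]
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "sample_id" not in df.columns:
        df["sample_id"] = Path(path).stem
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        out[str(sid)] = cls(**{c: grp[c].to_numpy(dtype=float) for c in cols})
    return out


#: Columns every quality panel must resolve (the routine assays).
REQUIRED_PANEL_VARIABLES = ("AC", "GT", "PC")


def _validate_panel(panel: pd.DataFrame, name_map: dict[str, str]) -> pd.DataFrame:
    if name_map:
        panel = panel.rename(columns=name_map)
    required = [v for v in REQUIRED_PANEL_VARIABLES if v not in panel.columns]
    if required:
        raise ValueError(f"missing required panel columns: {required}")
    missing = [v for v in PANEL_VARIABLES_25 if v not in panel.columns]
    if missing:
        import warnings
        warnings.warn(f"panel is missing variables: {missing}", stacklevel=3)
    keep = [v for v in PANEL_VARIABLES_25 if v in panel.columns]
    panel = panel[keep]
    bad = panel.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna() & panel.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {panel.index[r]!r}, variable {panel.columns[c]!r}")
    return panel.astype(float)


def read_panel_csv(path: str | Path, name_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a samples-by-variables panel CSV (first column = sample id)."""
    df = pd.read_csv(path, index_col=0)
    df.index.name = "sample_id"
    return _validate_panel(df, name_map or {})


def read_panel_xlsx(path: str | Path, name_map: dict[str, str] | None = None,
                    sheet: int | str = 0) -> pd.DataFrame:
    """Read a panel from a spreadsheet (one row per accession, named columns)."""
    df = pd.read_excel(path, sheet_name=sheet, index_col=0)
    df.index.name = "sample_id"
    return _validate_panel(df, name_map or {})


# ----------------------------------------------------------------------------
# curve -> feature-table assembly


def extract_features_table(
    samples: dict[str, dict[str, object]],
    config: CurveConfig = CurveConfig(smoothing_window=1),
) -> pd.DataFrame:
    """Extract all instrument features for a set of samples.

    ``samples`` maps sample id to a dict with any of ``rheo``/``rva``/``tpa``
    curves (the layout :func:`ricotype.synth.gen_cooking_study` produces).
    Returns one row per sample with the canonical variable names; S2/S4/ADH
    are reported as magnitudes.
    """
    rows = {}
    for sid, d in samples.items():
        feats: dict[str, float | None] = {}
        if "rheo" in d:
            feats.update(extract_rheometry_features(d["rheo"], config).to_dict())
        if "rva" in d:
            feats.update(extract_pasting_features(d["rva"], config).to_dict())
        if "tpa" in d:
            feats.update(extract_tpa_features(d["tpa"], config).to_dict())
        rows[sid] = feats
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ----------------------------------------------------------------------------
# orchestrator


def run_pipeline(
    config: PipelineConfig,
    panel: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run prune -> cluster -> profile -> select -> LR -> GoF -> importance.

    The panel comes from ``panel`` if given, else from ``config.panel_path``,
    else a synthetic study panel (25 variables, study-condition defaults) is
    generated with ``config.seed``.  Returns a report bundle; when
    ``out_dir`` is set, table-shaped CSVs and ``summary.json`` are written
    there.
    """
    if panel is None:
        if config.panel_path is not None:
            p = Path(config.panel_path)
            reader = read_panel_xlsx if p.suffix.lower() in (".xlsx", ".xls") else read_panel_csv
            panel = reader(p, config.name_map)
        else:
            panel, _ = gen_feature_panel(PanelSpec(include_redundant=True), seed=config.seed)

    pruned, corr_report = panel_mod.prune_correlated(
        panel, threshold=config.corr_threshold, drop_policy=config.drop_policy)

    clustering = cluster_mod.ward_cluster(pruned, k=config.k, standardize=config.standardize)
    profile = cluster_mod.cluster_profile(pruned, clustering.labels)

    model = classify.forward_aic_select(
        pruned, clustering.labels, reference=config.reference_cluster,
        tol=config.mlr_tol, max_iter=config.mlr_max_iter)
    lr_table = classify.lr_test_table(model)
    fit = classify.goodness_of_fit(model)
    importance = classify.rf_importance(
        pruned[model.variables], clustering.labels,
        n_trees=config.rf_trees, vars_per_split=config.rf_vars_per_split,
        seed=config.seed)

    summary = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_samples": int(len(panel)),
        "n_variables": {"input": int(panel.shape[1]),
                        "pruned": int(pruned.shape[1]),
                        "selected": len(model.variables)},
        "dropped_variables": corr_report.dropped,
        "cluster_sizes": {int(k): int(v) for k, v in clustering.sizes.items()},
        "selected_variables": model.variables,
        "null_deviance": fit.null_deviance,
        "deviance": fit.deviance,
        "model_chi2": fit.model_chi2,
        "aic": fit.aic,
        "pseudo_r2": fit.pseudo_r2,
        "accuracy_pct": fit.accuracy_pct,
        "rf_oob_error": importance.oob_error,
        "rf_rankings": {str(c): importance.ranking(c)[:5]
                        for c in clustering.sizes.index},
    }
    bundle = {
        "panel": panel, "pruned": pruned, "correlations": corr_report,
        "clustering": clustering, "profile": profile, "model": model,
        "lr_table": lr_table, "fit": fit, "importance": importance,
        "summary": summary,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pruned.to_csv(out / "panel_pruned.csv")
        corr_report.matrix.to_csv(out / "correlation_matrix.csv")
        clustering.labels.to_csv(out / "cluster_labels.csv")
        pd.DataFrame(clustering.linkage,
                     columns=["left", "right", "height", "size"]
                     ).to_csv(out / "linkage.csv", index=False)
        profile.to_csv(out / "cluster_profile.csv")
        coef = pd.concat({"estimate": model.params, "se": model.bse}, axis=1)
        coef.to_csv(out / "mlr_coefficients.csv")
        lr_table.to_csv(out / "lr_tests.csv")
        importance.standardized.to_csv(out / "rf_importance.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return bundle
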