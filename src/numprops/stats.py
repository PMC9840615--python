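"""Validation statistics for numerosity-stimulus feature tables.

Three analyses quantify how numerical and visual stimulus properties relate
to each other and to aggregate comparison behavior:

1. Pearson correlations between every visual property and the dot ratio,
   per dataset (15 properties x 5 datasets = 75 tests, Bonferroni at
   0.05/75).
2. Simple regressions of each behavioral outcome (mean error rate, mean
   correct RT) on each property alone — the property's explained variance
   R² (16 properties x 5 datasets = 80 tests per outcome, Bonferroni at
   0.05/80).
3. Hierarchical regressions: each visual property entered first, dot ratio
   second; ΔR² = R²(property + dot ratio) − R²(property) with a 1-df
   incremental F-test (75 tests per outcome, Bonferroni at 0.05/75).  A
   pooled analysis across datasets adds dataset indicator (dummy) variables
   to both models.

The entry point is :class:`ValidationAnalysis`, whose ``fit()`` returns a
:class:`ValidationResults` holding the three grids with significance flags,
a text ``summary()``, and ``save()`` for CSVs plus grayscale heatmaps
(darker shade = larger magnitude).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .features import VISUAL_PROPERTIES

__all__ = [
    "bonferroni_alpha",
    "correlate_with_ratio",
    "r2_single",
    "delta_r2",
    "ValidationAnalysis",
    "ValidationResults",
    "run_validation",
    "OUTCOMES",
    "PAPER_FAMILY_SIZES",
]

OUTCOMES = ("mean_err", "mean_rt_correct")

#: family sizes in paper mode: correlations, single regressions (per
#: outcome), hierarchical regressions (per outcome)
PAPER_FAMILY_SIZES = {"correlations": 75, "r2": 80, "delta_r2": 75}


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test significance threshold family_alpha / m."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return family_alpha / m


def _complete(cols: list[np.ndarray]) -> np.ndarray:
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    return mask


def correlate_with_ratio(features: pd.DataFrame,
                         properties: list[str] | None = None) -> pd.DataFrame:
    """Pearson r (and two-sided p, df = n−2) of each property vs dot_ratio.

    Rows with missing values are dropped pairwise.  Zero-variance properties
    are reported with r = NaN and a reason.
    """
    if properties is None:
        properties = [p for p in VISUAL_PROPERTIES if p in features.columns]
    ratio = features["dot_ratio"].to_numpy(dtype=float)
    rows = []
    for prop in properties:
        x = features[prop].to_numpy(dtype=float)
        mask = _complete([x, ratio])
        n = int(mask.sum())
        if n < 3:
            rows.append({"property": prop, "r": np.nan, "p": np.nan,
                         "n": n, "reason": "fewer than 3 complete rows"})
            continue
        if np.std(x[mask]) == 0 or np.std(ratio[mask]) == 0:
            rows.append({"property": prop, "r": np.nan, "p": np.nan,
                         "n": n, "reason": "zero variance"})
            continue
        r, p = sps.pearsonr(x[mask], ratio[mask])
        rows.append({"property": prop, "r": float(r), "p": float(p),
                     "n": n, "reason": ""})
    return pd.DataFrame(rows)


def r2_single(x, y) -> tuple[float, float, int]:
    """R² and model-F p-value of OLS of ``y`` on ``x`` plus an intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = _complete([x, y])
    n = int(mask.sum())
    if n < 4:
        return np.nan, np.nan, n
    if np.std(x[mask]) == 0:
        return np.nan, np.nan, n
    fit = sm.OLS(y[mask], sm.add_constant(x[mask])).fit()
    return float(fit.rsquared), float(fit.f_pvalue), n


def delta_r2(control, dot_ratio, outcome, dummies=None
             ) -> tuple[float, float, float, float, int]:
    """ΔR² of adding dot ratio after the control predictor(s).

    Model A regresses the outcome on the control column(s) (plus dataset
    dummies when pooling); model B adds dot ratio.  Returns
    (delta_r2, p_incremental_F, r2_A, r2_B, n).  The p-value comes from
    F = ΔR² / ((1 − R²_B)/(n − p_B − 1)) with 1 numerator df, identical to
    the squared t of dot ratio's coefficient in model B.
    """
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if control.shape[0] == 1 and control.shape[1] > 1:
        control = control.T
    dot_ratio = np.asarray(dot_ratio, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    cols = [control[:, j] for j in range(control.shape[1])]
    cols += [dot_ratio, outcome]
    mask = _complete(cols)
    n = int(mask.sum())
    k = control.shape[1] + (0 if dummies is None else
                            np.atleast_2d(np.asarray(dummies)).shape[1])
    if n < k + 4:
        return np.nan, np.nan, np.nan, np.nan, n
    Xa = control[mask]
    if dummies is not None:
        d = np.asarray(dummies, dtype=float)
        if d.ndim == 1:
            d = d[:, None]
        Xa = np.column_stack([Xa, d[mask]])
    y = outcome[mask]
    r = dot_ratio[mask]
    with np.errstate(invalid="ignore"):
        cc = np.corrcoef(Xa[:, 0], r)[0, 1]
    fit_a = sm.OLS(y, sm.add_constant(Xa)).fit()
    if np.isclose(abs(cc), 1.0):
        warnings.warn("control predictor collinear with dot ratio; "
                      "delta_r2 set to 0", RuntimeWarning, stacklevel=2)
        return 0.0, np.nan, float(fit_a.rsquared), float(fit_a.rsquared), n
    Xb = np.column_stack([Xa, r])
    fit_b = sm.OLS(y, sm.add_constant(Xb)).fit()
    r2a, r2b = float(fit_a.rsquared), float(fit_b.rsquared)
    delta = max(r2b - r2a, 0.0)  # clip float negatives from nesting
    p_b = Xb.shape[1]
    df_resid = n - p_b - 1
    if df_resid <= 0 or r2b >= 1.0:
        return delta, np.nan, r2a, r2b, n
    f = delta / ((1.0 - r2b) / df_resid)
    p = float(sps.f.sf(f, 1, df_resid))
    return delta, p, r2a, r2b, n


class ValidationResults:
    """The three validation grids, with Bonferroni flags and family sizes."""

    def __init__(self, correlations: pd.DataFrame, r2_grid: pd.DataFrame,
                 delta_r2_grid: pd.DataFrame, family_sizes: dict[str, int],
                 alpha: float):
        self.correlations = correlations
        self.r2_grid = r2_grid
        self.delta_r2_grid = delta_r2_grid
        self.family_sizes = family_sizes
        self.alpha = alpha

    def thresholds(self) -> dict[str, float]:
        return {k: bonferroni_alpha(self.alpha, m)
                for k, m in self.family_sizes.items()}

    def summary(self) -> str:
        th = self.thresholds()
        lines = ["Validation summary",
                 "==================",
                 f"family alpha: {self.alpha}",
                 "Bonferroni families: " + ", ".join(
                     f"{k}={m} (p < {th[k]:.5f})"
                     for k, m in self.family_sizes.items()),
                 "",
                 "Property-ratio correlations (r by dataset):"]
        pivot = self.correlations.pivot(index="property", columns="dataset",
                                        values="r")
        pivot = pivot.reindex([p for p in VISUAL_PROPERTIES
                               if p in pivot.index])
        lines.append(pivot.round(3).to_string())
        n_sig = int(self.correlations["significant"].sum())
        lines.append(f"significant correlations: {n_sig}"
                     f"/{len(self.correlations)}")
        for name, grid, col in (("R2", self.r2_grid, "r2"),
                                ("delta R2", self.delta_r2_grid, "delta_r2")):
            lines.append("")
            lines.append(f"{name} grid: {len(grid)} cells, "
                         f"{int(grid['significant'].sum())} significant")
            top = grid.sort_values(col, ascending=False).head(5)
            for row in top.itertuples(index=False):
                lines.append(f"  {row.property:<12s} {row.outcome:<16s} "
                             f"{row.dataset:<6s} {getattr(row, col):.3f}")
        return "\n".join(lines)

    def save(self, out_dir, heatmaps: bool = True) -> dict[str, str]:
        """Write correlations.csv, r2_grid.csv, delta_r2_grid.csv, run log
        and (optionally) grayscale heatmap PNGs into ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("correlations", self.correlations),
                         ("r2_grid", self.r2_grid),
                         ("delta_r2_grid", self.delta_r2_grid)):
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        log = out_dir / "run_log.txt"
        th = self.thresholds()
        log.write_text(
            "\n".join([f"family {k}: m={m}, threshold={th[k]:.6g}"
                       for k, m in self.family_sizes.items()]) + "\n\n"
            + self.summary() + "\n")
        paths["run_log"] = str(log)
        if heatmaps:
            paths.update(self._heatmaps(out_dir))
        return paths

    def _heatmaps(self, out_dir: Path) -> dict[str, str]:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        paths = {}
        jobs = []
        for outcome in self.r2_grid["outcome"].unique():
            jobs.append((f"r2_{outcome}", "r2",
                         self.r2_grid[self.r2_grid["outcome"] == outcome]))
        for outcome in self.delta_r2_grid["outcome"].unique():
            jobs.append((f"delta_r2_{outcome}", "delta_r2",
                         self.delta_r2_grid[
                             self.delta_r2_grid["outcome"] == outcome]))
        for name, col, df in jobs:
            pivot = df.pivot(index="property", columns="dataset", values=col)
            order = [p for p in ["dot_ratio"] + VISUAL_PROPERTIES
                     if p in pivot.index]
            pivot = pivot.reindex(order)
            fig, ax = plt.subplots(
                figsize=(1.2 * len(pivot.columns) + 3,
                         0.35 * len(pivot) + 2))
            im = ax.imshow(pivot.to_numpy(dtype=float), cmap="Greys",
                           vmin=0, aspect="auto")
            ax.set_xticks(range(len(pivot.columns)), pivot.columns)
            ax.set_yticks(range(len(pivot.index)), pivot.index)
            ax.set_title(name.replace("_", " "))
            fig.colorbar(im, ax=ax, shrink=0.8)
            fig.tight_layout()
            p = out_dir / f"{name}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            paths[name] = str(p)
        return paths


class ValidationAnalysis:
    """Joint validation of feature and behavior tables across datasets.

    Parameters
    ----------
    features : mapping dataset name -> feature table (FEATURE_COLUMNS schema)
    behavior : mapping dataset name -> per-stimulus behavior table
        (STIMID, mean_err, mean_rt_correct); joined on STIMID.
    paper_mode : use the fixed Bonferroni family sizes 75/80/75; otherwise
        family sizes are recomputed from the grid actually run.
    pooled : additionally run the hierarchical analysis on the pooled table
        with dataset indicator variables.
    """

    def __init__(self, features: dict[str, pd.DataFrame],
                 behavior: dict[str, pd.DataFrame],
                 alpha: float = 0.05, paper_mode: bool = True,
                 pooled: bool = True):
        if set(features) != set(behavior):
            raise ValueError("features and behavior must cover the same "
                             "datasets")
        self.datasets = sorted(features)
        self.alpha = alpha
        self.paper_mode = paper_mode
        self.pooled = pooled
        self.tables = {}
        for ds in self.datasets:
            merged = features[ds].merge(behavior[ds], on="STIMID",
                                        how="inner", validate="1:1")
            missing = set(features[ds]["STIMID"]) - set(merged["STIMID"])
            if missing:
                warnings.warn(f"{ds}: {len(missing)} stimuli without "
                              f"behavior rows dropped "
                              f"(e.g. {sorted(missing)[:3]})",
                              RuntimeWarning, stacklevel=2)
            self.tables[ds] = merged

    def _family_sizes(self) -> dict[str, int]:
        if self.paper_mode:
            return dict(PAPER_FAMILY_SIZES)
        n_ds = len(self.datasets)
        return {"correlations": len(VISUAL_PROPERTIES) * n_ds,
                "r2": (len(VISUAL_PROPERTIES) + 1) * n_ds,
                "delta_r2": len(VISUAL_PROPERTIES) * n_ds}

    def fit(self) -> ValidationResults:
        fam = self._family_sizes()
        th = {k: bonferroni_alpha(self.alpha, m) for k, m in fam.items()}

        corr_rows = []
        for ds in self.datasets:
            c = correlate_with_ratio(self.tables[ds])
            c.insert(0, "dataset", ds)
            corr_rows.append(c)
        corr = pd.concat(corr_rows, ignore_index=True)
        corr["significant"] = corr["p"] < th["correlations"]

        r2_rows = []
        props16 = ["dot_ratio"] + VISUAL_PROPERTIES
        for ds in self.datasets:
            t = self.tables[ds]
            for outcome in OUTCOMES:
                for prop in props16:
                    r2, p, n = r2_single(t[prop], t[outcome])
                    r2_rows.append({"dataset": ds, "outcome": outcome,
                                    "property": prop, "r2": r2, "p": p,
                                    "n": n})
        r2_grid = pd.DataFrame(r2_rows)
        r2_grid["significant"] = r2_grid["p"] < th["r2"]

        d_rows = []
        for ds in self.datasets:
            t = self.tables[ds]
            for outcome in OUTCOMES:
                for prop in VISUAL_PROPERTIES:
                    d, p, r2a, r2b, n = delta_r2(
                        t[prop].to_numpy(), t["dot_ratio"].to_numpy(),
                        t[outcome].to_numpy())
                    d_rows.append({"dataset": ds, "outcome": outcome,
                                   "property": prop, "delta_r2": d, "p": p,
                                   "r2_control": r2a, "r2_full": r2b,
                                   "n": n})
        if self.pooled and len(self.datasets) > 1:
            pooled = pd.concat(
                [t.assign(dataset=ds) for ds, t in self.tables.items()],
                ignore_index=True)
            dummies = pd.get_dummies(pooled["dataset"], drop_first=True
                                     ).to_numpy(dtype=float)
            for outcome in OUTCOMES:
                for prop in VISUAL_PROPERTIES:
                    d, p, r2a, r2b, n = delta_r2(
                        pooled[prop].to_numpy(),
                        pooled["dot_ratio"].to_numpy(),
                        pooled[outcome].to_numpy(), dummies=dummies)
                    d_rows.append({"dataset": "pooled", "outcome": outcome,
                                   "property": prop, "delta_r2": d, "p": p,
                                   "r2_control": r2a, "r2_full": r2b,
                                   "n": n})
        delta_grid = pd.DataFrame(d_rows)
        delta_grid["significant"] = delta_grid["p"] < th["delta_r2"]

        return ValidationResults(corr, r2_grid, delta_grid, fam, self.alpha)


def run_validation(features: dict[str, pd.DataFrame],
                   behavior: dict[str, pd.DataFrame],
                   out_dir=None, alpha: float = 0.05,
                   paper_mode: bool = True,
                   heatmaps: bool = True) -> ValidationResults:
    """Fit the full validation and optionally write CSVs/heatmaps/run log."""
    res = ValidationAnalysis(features, behavior, alpha=alpha,
                             paper_mode=paper_mode).fit()
    if out_dir is not None:
        res.save(out_dir, heatmaps=heatmaps)
    return res
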