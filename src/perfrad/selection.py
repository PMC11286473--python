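"""Feature standardization, filtering and selection.

The selection chain applied to each region's feature table, mirroring the
emulated study design:

1. min-max-range standardization ``F* = (F - mean) / (max - min)`` with
   statistics fitted on the training rows only and applied to all rows;
2. two-sided independent two-sample t-test per feature (Student's,
   equal-variance, like SPSS's independent sample t-test); keep p < alpha
   strictly (alpha = 0.05, no multiple-testing correction);
3. cross-validated Lasso (least-squares L1 on 0/1 labels) per perfusion
   map over the t-test survivors; keep features with non-zero weight;
4. per-map retained sets are concatenated per region, and regions are
   combined into the named experimental groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

REGION_COMBOS = (
    ("ischemic",),
    ("infarct",),
    ("hypoxic",),
    ("ischemic", "infarct"),
    ("ischemic", "hypoxic"),
    ("infarct", "hypoxic"),
    ("ischemic", "infarct", "hypoxic"),
)


def _combo_name(regions: tuple, suffix: str) -> str:
    return "_".join(regions).capitalize() + "_" + suffix


#: The 14 named experimental groups (7 region combos x radiomics/parameters).
GROUP_NAMES = tuple(
    _combo_name(c, s) for s in ("radiomics", "parameters") for c in REGION_COMBOS
)


def group_regions(group_name: str) -> tuple[tuple, str]:
    """Parse a group name into (regions, 'radiomics'|'parameters')."""
    if group_name not in GROUP_NAMES:
        raise ValueError(f"unknown group {group_name!r}; valid groups: {sorted(GROUP_NAMES)}")
    parts = group_name.lower().split("_")
    kind = parts[-1]
    return tuple(parts[:-1]), kind


@dataclass
class StandardizationStats:
    """Per-feature mean / max / min fitted on the training rows."""

    mean: pd.Series
    max: pd.Series
    min: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        rng = self.max - self.min
        out = table.sub(self.mean, axis=1)
        degenerate = rng == 0
        safe = rng.where(~degenerate, 1.0)
        out = out.div(safe, axis=1)
        out.loc[:, degenerate[degenerate].index] = 0.0
        return out


def standardize(table: pd.DataFrame, fit_rows) -> tuple[pd.DataFrame, StandardizationStats]:
    """Range standardization fitted on ``fit_rows``, applied to all rows.

    Constant features (zero range on the fit rows) map to 0 with a
    warning rather than dividing by zero.
    """
    fit = table.loc[fit_rows]
    if len(fit) == 0:
        raise ValueError("empty fit set")
    stats_ = StandardizationStats(mean=fit.mean(), max=fit.max(), min=fit.min())
    n_const = int((stats_.max == stats_.min).sum())
    if n_const:
        warnings.warn(f"{n_const} constant feature(s) mapped to 0 by the degenerate-range rule")
    return stats_.transform(table), stats_


def ttest_filter(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per feature; keep p < alpha (strict).

    Returns a per-feature report (t, p, passed_ttest).  Features with
    undefined p (zero variance in both classes) are dropped.
    """
    labels = pd.Series(labels, index=table.index)
    classes = np.sort(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    a = table.loc[labels == classes[0]]
    b = table.loc[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 subjects for the t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0, equal_var=equal_var)
    passed = np.where(np.isnan(p), False, p < alpha)
    return pd.DataFrame({"t": t, "p": p, "passed_ttest": passed}, index=table.columns)


def lasso_select(
    table: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 100,
) -> pd.DataFrame:
    """Cross-validated L1-penalized least squares of the 0/1 label.

    The penalty is chosen by ``cv_folds``-fold CV over a log-spaced grid;
    features with non-zero weight at the chosen penalty are retained.  An
    empty input yields an empty report with a warning (not an error).
    """
    y = pd.Series(labels, index=table.index).astype(float)
    if y.nunique() < 2:
        raise ValueError("labels are constant; Lasso selection undefined")
    if table.shape[1] == 0:
        warnings.warn("no features survived filtering; empty selection returned")
        return pd.DataFrame(columns=["lasso_weight", "retained"])
    cv = KFold(n_splits=min(cv_folds, len(table)), shuffle=True, random_state=seed)
    model = LassoCV(alphas=n_alphas, cv=cv, max_iter=50000)  # log-spaced grid of n_alphas values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(table.to_numpy(), y.to_numpy())
    w = model.coef_
    report = pd.DataFrame({"lasso_weight": w, "retained": np.abs(w) > 0}, index=table.columns)
    report.attrs["alpha"] = float(model.alpha_)
    return report


@dataclass
class SelectionReport:
    """Per-feature selection outcome for one region."""

    table: pd.DataFrame          # t, p, passed_ttest, lasso_weight, retained
    retained: list = field(default_factory=list)
    alphas_by_map: dict = field(default_factory=dict)

    def counts_by_map(self) -> pd.Series:
        maps = [name.split("__")[1] for name in self.retained]
        return pd.Series(maps).value_counts()

    def counts_by_class(self) -> pd.Series:
        classes = [name.split("__")[3] for name in self.retained]
        return pd.Series(classes).value_counts()


def select_region_features(
    table: pd.DataFrame,
    labels: pd.Series,
    train_rows,
    alpha: float = 0.05,
    cv_folds: int = 5,
    seed: int = 0,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Standardize, t-test filter and Lasso-select one region's features.

    Statistics and selection use the training rows only; selection runs
    separately per perfusion map (column name token 2) and the retained
    sets are concatenated.  Returns the standardized full table and the
    report.
    """
    std, _ = standardize(table, train_rows)
    train = std.loc[train_rows]
    y_train = pd.Series(labels, index=table.index).loc[train_rows]
    tt = ttest_filter(train, y_train, alpha=alpha, equal_var=equal_var)

    report = tt.copy()
    report["lasso_weight"] = 0.0
    report["retained"] = False
    alphas = {}
    maps_of = pd.Series([c.split("__")[1] for c in std.columns], index=std.columns)
    for map_name in maps_of.unique():
        cols = tt.index[(maps_of == map_name) & tt.passed_ttest]
        if len(cols) == 0:
            continue
        lr = lasso_select(train[cols], y_train, cv_folds=cv_folds, seed=seed)
        if len(lr):
            report.loc[lr.index, "lasso_weight"] = lr["lasso_weight"]
            report.loc[lr.index, "retained"] = lr["retained"]
            alphas[map_name] = lr.attrs.get("alpha")
    retained = list(report.index[report.retained])
    return std, SelectionReport(table=report, retained=retained, alphas_by_map=alphas)


def assemble_group(
    group_name: str,
    radiomics_by_region: dict,
    parameters_by_region: dict,
) -> pd.DataFrame:
    """Column-concatenate per-region feature sets for one named group.

    ``radiomics_by_region`` maps region -> table of that region's
    *selected* (standardized) radiomics features; ``parameters_by_region``
    maps region -> table of the four regional perfusion-parameter means.
    A subject with missing values for a required region is an error.
    """
    regions, kind = group_regions(group_name)
    source = radiomics_by_region if kind == "radiomics" else parameters_by_region
    blocks = []
    for region in regions:
        if region not in source:
            raise ValueError(f"group {group_name!r} requires region {region!r}")
        blocks.append(source[region])
    out = pd.concat(blocks, axis=1)
    if out.isna().any().any():
        bad = list(out.index[out.isna().any(axis=1)])
        raise ValueError(f"subjects missing required region data for {group_name!r}: {bad}")
    return out
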