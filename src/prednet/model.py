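"""Model/Results facade over the predictive-network pipeline.

``ConfounderNetwork`` is built from a categorical survey DataFrame; its
``fit()`` runs the full stratified procedure and returns a
``ConfounderNetworkResults`` carrying hub-score estimates, their
cross-stratum variability, replication correlations and per-model AUC
diagnostics, with a ``summary()`` table in the spirit of statsmodels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encoding import CategoricalTable
from .evaluation import SplitConfig
from .gbm import GBMConfig
from .replication import PipelineConfig, ReplicationReport, run_pipeline


class ConfounderNetwork:
    """Screen a categorical survey for broadly influential variables.

    One gradient-boosted classifier is fitted per dummy variable, using
    every dummy from other source variables as predictors; gain
    importances form a directed weighted graph whose HITS hub scores
    rank variables by how much predictive information they carry about
    the rest of the questionnaire.  High-hub variables are candidate
    confounders for downstream association analyses.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per subject, one column per categorical variable.
    stratum : str or pandas.Series, optional
        Column name in ``data`` (or an aligned Series) giving the
        stratum in which the analysis replicates independently.
    gbm : GBMConfig, optional
        Boosting settings (default: 100 trees, depth 4, shrinkage 0.1).
    split : SplitConfig, optional
        Train fraction for the per-stratum 70/30 split.
    top_k : int
        Size of the reported confounder short-list (default 5).
    normalize_columns : bool
        Rescale each target's importances to sum 1 before graph
        assembly (default True).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        stratum: str | pd.Series | None = None,
        gbm: GBMConfig | None = None,
        split: SplitConfig | None = None,
        top_k: int = 5,
        normalize_columns: bool = True,
        min_stratum_size: int = 50,
    ):
        if isinstance(stratum, str):
            if stratum not in data.columns:
                raise ValueError(f"stratum column {stratum!r} not in data")
            strat = data[stratum]
            data = data.drop(columns=[stratum])
        else:
            strat = stratum
        self.table = CategoricalTable(data, strat)
        self.gbm = gbm or GBMConfig()
        self.split = split or SplitConfig()
        self.top_k = top_k
        self.normalize_columns = normalize_columns
        self.min_stratum_size = min_stratum_size

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ConfounderNetwork":
        return cls(data, **kwargs)

    def fit(self, seed: int = 0) -> "ConfounderNetworkResults":
        """Run the stratified pipeline; deterministic given ``seed``."""
        config = PipelineConfig(
            gbm=self.gbm,
            train_frac=self.split.train_frac,
            top_k=self.top_k,
            normalize_columns=self.normalize_columns,
            min_stratum_size=self.min_stratum_size,
            seed=seed,
        )
        report = run_pipeline(self.table, config)
        return ConfounderNetworkResults(self, report, seed)


class ConfounderNetworkResults:
    """Estimates and diagnostics from a fitted confounder screen."""

    def __init__(self, model: ConfounderNetwork, report: ReplicationReport,
                 seed: int):
        self.model = model
        self.report = report
        self.seed = seed

    # -- estimates ---------------------------------------------------
    @property
    def hub_scores(self) -> pd.DataFrame:
        """Per-node hub score in every stratum (NaN = degenerate there)."""
        return self.report.hub_matrix

    @property
    def mean_hub(self) -> pd.Series:
        return self.report.mean_hub

    @property
    def sd_hub(self) -> pd.Series:
        return self.report.sd_hub

    @property
    def corr(self) -> pd.DataFrame:
        """Cross-stratum Pearson correlation of hub vectors."""
        return self.report.corr

    @property
    def top_k(self) -> pd.DataFrame:
        return self.report.top_k

    def auc_summary(self) -> pd.DataFrame:
        return self.report.auc_summary()

    def auc_table(self, stratum: str) -> pd.DataFrame:
        return self.report.stratum_results[stratum].auc_frame()

    # -- presentation ------------------------------------------------
    def summary(self) -> str:
        """Human-readable run summary."""
        rep = self.report
        lines = [
            "Predictive-network confounder screen",
            "=" * 58,
            f"subjects: {self.model.table.n_subjects:>8}"
            f"    variables: {len(self.model.table.variables)}"
            f"    dummies: {len(rep.nodes)}",
            f"strata:   {', '.join(rep.strata)}",
            f"boosting: {self.model.gbm.n_trees} trees, depth "
            f"{self.model.gbm.max_depth}, shrinkage "
            f"{self.model.gbm.learn_rate}, train fraction "
            f"{self.model.split.train_frac}, seed {self.seed}",
            "",
            "Top hub variables (mean across strata, SD in parentheses)",
            "-" * 58,
        ]
        for _, row in rep.top_k.iterrows():
            lines.append(
                f"{int(row['rank']):>3}. {row['node']:<28} "
                f"{row['mean_hub']:.4f} ({row['sd_hub']:.4f})"
            )
        lines += ["", "Test AUC per stratum", "-" * 58]
        for _, row in rep.auc_summary().iterrows():
            lines.append(
                f"  {row['stratum']:<10} n={int(row['n_models']):>4}  "
                f"median={row['median']:.3f}  "
                f"IQR=[{row['q1']:.3f}, {row['q3']:.3f}]"
            )
        if len(rep.strata) > 1:
            mask = ~np.eye(len(rep.corr), dtype=bool)
            offdiag = rep.corr.values[mask]
            lines += [
                "",
                f"Cross-stratum hub-score Pearson r: "
                f"min={np.nanmin(offdiag):.3f}, "
                f"mean={np.nanmean(offdiag):.3f}",
            ]
        return "\n".join(lines)

    def plot_hub_decay(self, ax=None, n_top: int = 50):
        """Ranked mean hub scores (decay curve) with SD error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = self.mean_hub.sort_values(ascending=False).head(n_top)
        ax.errorbar(
            range(1, len(order) + 1), order.values,
            yerr=self.sd_hub[order.index].values, fmt="o", ms=3, capsize=2,
        )
        ax.set_xlabel("hub rank")
        ax.set_ylabel("mean hub score")
        return ax

    def save(self, outdir) -> None:
        self.report.write(outdir)
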