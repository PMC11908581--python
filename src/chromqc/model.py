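"""Quality-clustering model: the package's central fitting object.

:class:`QualityClusterModel` is built from a quality table (one row per
compound: ΔtR, SNR, skewness, peak area, length, sulfur count, target tR).
``fit()`` runs the full evaluation chain — standardize/normalize, PCA,
elbow-selected and silhouette-validated k-means, then a grid-searched
regressor per cluster — and returns a :class:`QualityClusterResults` object
carrying the partition, its selection evidence, per-cluster predictive
performance and summary statistics, with ``summary()`` for a readable
report.

Clusters are re-indexed by descending cluster-mean SNR so that cluster 0 is
always the strongest-signal cluster, independent of the k-means seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatogram import CSV_FLOAT_FORMAT
from .clustering import (
    ClusterResult,
    ReducedMatrix,
    kmeans_fit,
    pca_reduce,
    relabel_by_feature,
    select_k_elbow,
    silhouette_validate,
    wcss_curve,
)
from .dataset import (
    CLUSTER_FEATURES,
    REGRESSION_FEATURES,
    TARGET,
    FeatureTransform,
    QualityTable,
    drop_incomplete,
    preprocess,
)
from .errors import ParameterError
from .validation import (
    DEFAULT_CV_FOLDS,
    DEFAULT_TEST_FRACTION,
    MIN_CLUSTER_SIZE,
    SVR_FAMILY,
    EvaluationReport,
    ModelGrid,
    evaluate_clusters,
    summarize_cluster,
)

SUMMARY_COLUMNS = CLUSTER_FEATURES + [TARGET]


class QualityClusterModel:
    """Quality-sensitive clustering of compound measurements with
    per-cluster predictive validation.

    Parameters
    ----------
    table : QualityTable
        The assembled quality table; rows with missing features or target
        are dropped (and reported) before fitting.
    features : list of str
        Clustering features; the target is never among them.
    n_components, variance_threshold :
        PCA target — a fixed component count (default 2) or a cumulative
        variance-ratio threshold; give one of the two.
    k : int or None
        Number of clusters; None (default) selects k by the elbow method on
        the WCSS curve over ``k_range``.
    model_family : str
        ``"gradient_boosted_trees"`` or ``"support_vector_regression"``.
    grid : ModelGrid or None
        Hyperparameter search space; None uses the family default
        (``fast_grids=True`` swaps in the reduced gradient-boosting grid).
    """

    def __init__(
        self,
        table: QualityTable,
        features=None,
        target: str = TARGET,
        n_components: int | None = 2,
        variance_threshold: float | None = None,
        k: int | None = None,
        k_range=range(1, 9),
        model_family: str = SVR_FAMILY,
        grid: ModelGrid | None = None,
        fast_grids: bool = False,
        test_fraction: float = DEFAULT_TEST_FRACTION,
        cv_folds: int = DEFAULT_CV_FOLDS,
        min_cluster_size: int = MIN_CLUSTER_SIZE,
        n_init: int = 10,
    ):
        self.table = table
        self.features = list(features) if features is not None else list(CLUSTER_FEATURES)
        if target in self.features:
            raise ParameterError("the prediction target cannot be a clustering feature")
        self.target = target
        if variance_threshold is not None:
            n_components = None
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.k = k
        self.k_range = list(k_range)
        self.model_family = model_family
        self.grid = grid if grid is not None else ModelGrid.default(model_family, fast=fast_grids)
        self.test_fraction = test_fraction
        self.cv_folds = cv_folds
        self.min_cluster_size = min_cluster_size
        self.n_init = n_init

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "QualityClusterModel":
        """Build the model straight from a Table-dialect DataFrame."""
        return cls(QualityTable(df.copy()), **kwargs)

    def fit(self, seed: int = 0) -> "QualityClusterResults":
        """Run the full chain and return the results object."""
        clean, drop_report = drop_incomplete(
            self.table, columns=self.features + [self.target]
        )
        transform, matrix = preprocess(clean, feature_subset=self.features)
        reduced = pca_reduce(
            matrix,
            n_components=self.n_components,
            variance_threshold=self.variance_threshold,
        )
        curve = wcss_curve(reduced.scores, self.k_range, seed, n_init=self.n_init)
        k = self.k if self.k is not None else select_k_elbow(curve)
        cluster = kmeans_fit(reduced.scores, k, seed, n_init=self.n_init)
        cluster.wcss_curve = curve
        labels, mapping = relabel_by_feature(
            cluster.labels, clean.data["snr"].to_numpy(float), descending=True
        )
        cluster = ClusterResult(
            k=cluster.k,
            labels=labels,
            centroids=cluster.centroids[
                [old for old, _ in sorted(mapping.items(), key=lambda kv: kv[1])]
            ],
            wcss=cluster.wcss,
            seed=cluster.seed,
            wcss_curve=curve,
            mean_silhouette=cluster.mean_silhouette,
        )
        evaluation = evaluate_clusters(
            clean.data,
            labels,
            feature_columns=[f for f in REGRESSION_FEATURES if f in clean.data.columns],
            target_column=self.target,
            grid=self.grid,
            test_fraction=self.test_fraction,
            cv_folds=self.cv_folds,
            seed=seed,
            min_cluster_size=self.min_cluster_size,
        )
        summaries = {
            int(c): summarize_cluster(clean.data.loc[labels == c], SUMMARY_COLUMNS)
            for c in sorted(set(int(v) for v in labels))
        }
        return QualityClusterResults(
            model=self,
            table=clean,
            drop_report=drop_report,
            transform=transform,
            reduced=reduced,
            cluster=cluster,
            evaluation=evaluation,
            summaries=summaries,
            seed=seed,
        )


@dataclass
class QualityClusterResults:
    """Fitted results: the partition, its evidence and its validation."""

    model: QualityClusterModel
    table: QualityTable
    drop_report: dict
    transform: FeatureTransform
    reduced: ReducedMatrix
    cluster: ClusterResult
    evaluation: EvaluationReport
    summaries: dict
    seed: int
    _assignments: pd.DataFrame | None = field(default=None, repr=False)

    # -- convenience accessors -------------------------------------------
    @property
    def k(self) -> int:
        return self.cluster.k

    @property
    def labels(self) -> np.ndarray:
        return self.cluster.labels

    @property
    def mean_silhouette(self) -> float:
        return self.cluster.mean_silhouette

    @property
    def wcss_curve(self) -> dict:
        return self.cluster.wcss_curve

    @property
    def variance_ratios(self) -> np.ndarray:
        return self.reduced.variance_ratios

    def assignments(self) -> pd.DataFrame:
        if self._assignments is None:
            self._assignments = pd.DataFrame(
                {
                    "compound_id": self.table.data["compound_id"].to_numpy(),
                    "cluster": self.cluster.labels,
                }
            )
        return self._assignments

    def cluster_rows(self, c: int) -> pd.DataFrame:
        return self.table.data.loc[self.cluster.labels == c]

    # -- reporting --------------------------------------------------------
    def separating_features(self) -> list:
        """Features ranked by how strongly they separate the best-ranked
        from the worst-ranked cluster: |mean difference| / pooled std."""
        if not self.evaluation.ranking or len(self.evaluation.ranking) < 2:
            return []
        best, worst = self.evaluation.ranking[0], self.evaluation.ranking[-1]
        sb, sw = self.summaries[best], self.summaries[worst]
        scores = {}
        for feat in self.model.features:
            mb, mw = sb.loc["mean", feat], sw.loc["mean", feat]
            pooled = np.sqrt((sb.loc["std", feat] ** 2 + sw.loc["std", feat] ** 2) / 2.0)
            scores[feat] = abs(mb - mw) / pooled if pooled > 0 else np.inf
        return sorted(scores, key=scores.get, reverse=True)

    def summary(self) -> str:
        """Human-readable fitting report."""
        lines = []
        lines.append("Quality-cluster evaluation")
        lines.append("=" * 62)
        lines.append(f"n compounds (complete rows): {len(self.table)}")
        if self.drop_report:
            lines.append(f"rows dropped for missing values: {len(self.drop_report)}")
        ratios = ", ".join(f"{r:.3f}" for r in self.variance_ratios[: self.reduced.n_components])
        lines.append(
            f"PCA: {self.reduced.n_components} components (variance ratios {ratios}, "
            f"cumulative {self.variance_ratios[: self.reduced.n_components].sum():.3f})"
        )
        lines.append(f"k (elbow-selected): {self.k}   mean silhouette: {self.mean_silhouette:.3f}")
        lines.append("")
        lines.append(f"{'cluster':>7} {'n':>5} {'rmse_test':>10} {'r2_test':>8} {'verdict':>8}")
        by_cluster = {e.cluster_index: e for e in self.evaluation.evaluations}
        for c in sorted(self.summaries):
            n = int((self.cluster.labels == c).sum())
            e = by_cluster.get(c)
            if e is None:
                reason = self.evaluation.skipped.get(c, "skipped")
                lines.append(f"{c:>7} {n:>5} {'--':>10} {'--':>8}  ({reason})")
            else:
                r2 = f"{e.r2_test:.3f}" if e.r2_test is not None else "--"
                lines.append(
                    f"{c:>7} {n:>5} {e.rmse_test:>10.3f} {r2:>8} {e.verdict:>8}"
                )
        sep = self.separating_features()
        if sep:
            lines.append("")
            lines.append(
                "features separating best from worst cluster: " + ", ".join(sep[:3])
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "n_rows": len(self.table),
            "dropped": sorted(self.drop_report),
            "n_components": self.reduced.n_components,
            "variance_ratios": [float(r) for r in self.variance_ratios],
            "wcss_curve": {str(k): v for k, v in sorted(self.wcss_curve.items())},
            "k": self.k,
            "mean_silhouette": self.mean_silhouette,
            "seed": self.seed,
            "evaluations": [e.to_dict() for e in self.evaluation.evaluations],
            "skipped": {str(c): r for c, r in self.evaluation.skipped.items()},
            "ranking": self.evaluation.ranking,
            "separating_features": self.separating_features(),
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    # -- persistence ------------------------------------------------------
    def save_artifacts(self, out_dir, plots: bool = False) -> dict:
        """Persist every stage output; returns {artifact name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        p = out / "quality_table.csv"
        self.table.to_csv(p)
        paths["quality_table"] = p

        p = out / "transform.json"
        p.write_text(self.transform.to_json() + "\n")
        paths["transform"] = p

        p = out / "assignments.csv"
        self.assignments().to_csv(p, index=False)
        paths["assignments"] = p

        p = out / "diagnostics.json"
        p.write_text(self.to_json() + "\n")
        paths["diagnostics"] = p

        for c, summ in self.summaries.items():
            p = out / f"cluster_{c}_summary.csv"
            summ.to_csv(p, float_format=CSV_FLOAT_FORMAT)
            paths[f"summary_{c}"] = p

        if plots:
            from . import plots as _plots

            p = out / "clusters_pc1_pc2.png"
            _plots.plot_clusters(self, p)
            paths["cluster_plot"] = p
        return paths

    def plot_clusters(self, ax=None):
        from . import plots as _plots

        return _plots.scatter_clusters(self, ax=ax)
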