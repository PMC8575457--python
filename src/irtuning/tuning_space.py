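"""PCA of z-scored tuning profiles and the C2-vs-C4 phenotype readout.

Tuning of an acid-sensing sensillum is multidimensional (one axis per odor),
but across species and receptor mutants most of the variance lies on a single
C2 <-> C4 trade-off axis. PCA on z-scored response rows exposes that axis as
PC1; the projection of a sensillum's profile onto PC1 is the scalar phenotype
used throughout the landscape analysis. The PC1 sign is fixed so that the C4
loading is non-negative: larger PC1 means more C4-tuned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from irtuning.tables_io import ResponseMatrix

ClusterLabel = Literal["C2-max", "C4-max", "unclassified"]


class InsufficientDataError(ValueError):
    """Not enough complete rows to fit a PCA."""


class MissingOdorError(ValueError):
    """A row lacks a value for an odor the PCA was fitted on."""


@dataclass
class PCAResult:
    """Fitted principal components of a z-scored response matrix.

    ``loadings`` has odors as rows and components as columns (orthonormal
    columns); ``scores`` holds per-sensillum projections of the centered
    data; ``variance_fraction`` sums to 1 over all components.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: np.ndarray
    mean: pd.Series
    labels: pd.Series

    @property
    def odors(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def pc1_variance_fraction(self) -> float:
        return float(self.variance_fraction[0])

    def to_files(self, out_dir: str | Path, prefix: str = "pca") -> dict[str, Path]:
        """Write loadings/scores CSVs and a JSON summary of variance fractions."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "loadings": out_dir / f"{prefix}_loadings.csv",
            "scores": out_dir / f"{prefix}_scores.csv",
            "summary": out_dir / f"{prefix}_summary.json",
        }
        self.loadings.to_csv(paths["loadings"])
        scores = self.scores.copy()
        scores.insert(0, "label", self.labels.to_numpy())
        scores.to_csv(paths["scores"])
        with open(paths["summary"], "w") as fh:
            json.dump(
                {
                    "variance_fraction": [float(v) for v in self.variance_fraction],
                    "pc1_variance_fraction": self.pc1_variance_fraction,
                    "odors": self.odors,
                },
                fh,
                indent=2,
            )
        return paths


def run_pca(z_matrix: ResponseMatrix, orient_odor: str = "C4") -> PCAResult:
    """Complete-case PCA of z-scored rows on the covariance of the data.

    Rows with any missing odor value are dropped before fitting (at least two
    must survive). Components are ordered by decreasing explained variance;
    PC1 is oriented so the loading of ``orient_odor`` is >= 0, making larger
    PC1 scores mean stronger C4-side tuning.
    """
    complete = z_matrix.data.dropna(axis=0, how="any")
    if len(complete) < 2:
        raise InsufficientDataError(
            f"need >=2 complete rows for PCA, have {len(complete)} after dropping missing data"
        )
    values = complete.to_numpy(dtype=float)
    if np.allclose(values.var(axis=0), 0):
        raise InsufficientDataError("zero total variance; PCA undefined")

    model = PCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(values)
    loadings = model.components_.T  # odors x components, orthonormal columns

    if orient_odor in complete.columns:
        c4_loading = loadings[complete.columns.get_loc(orient_odor), 0]
        if c4_loading < 0:
            loadings[:, 0] *= -1.0
            scores[:, 0] *= -1.0

    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=complete.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=complete.index, columns=comp_names),
        variance_fraction=model.explained_variance_ratio_.copy(),
        mean=pd.Series(model.mean_, index=complete.columns),
        labels=z_matrix.labels.loc[complete.index].copy(),
    )


def project_pc1(row: pd.Series, result: PCAResult) -> float:
    """Project one z-scored response row onto PC1 of a fitted PCA.

    The score is dot(row - fitted mean, PC1 loading); linear in the row.
    """
    try:
        values = row.loc[result.odors].astype(float)
    except KeyError as err:
        raise MissingOdorError(f"row lacks odor(s) required by the PCA: {err}") from None
    if values.isna().any():
        missing = list(values.index[values.isna()])
        raise MissingOdorError(f"row {row.name!r} has missing values for {missing}")
    centered = values.to_numpy() - result.mean.to_numpy()
    return float(centered @ result.loadings["PC1"].to_numpy())


def project_pc1_by_label(z_matrix: ResponseMatrix, result: PCAResult) -> dict[str, np.ndarray]:
    """Per-genotype/species arrays of PC1 scores for all complete rows."""
    out: dict[str, list[float]] = {}
    for rid, row in z_matrix.data.iterrows():
        if row.isna().any():
            continue
        out.setdefault(z_matrix.labels.loc[rid], []).append(project_pc1(row, result))
    return {label: np.asarray(vals) for label, vals in out.items()}


def assign_cluster(z_c2: float, z_c4: float) -> ClusterLabel:
    """C2-max vs C4-max cluster from the two z-scored responses.

    Exact ties (and non-finite inputs) are flagged unclassified rather than
    broken arbitrarily.
    """
    if not (np.isfinite(z_c2) and np.isfinite(z_c4)):
        raise ValueError("cluster assignment requires finite z-scores")
    if z_c2 > z_c4:
        return "C2-max"
    if z_c4 > z_c2:
        return "C4-max"
    return "unclassified"
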