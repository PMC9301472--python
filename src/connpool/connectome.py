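"""Functional-connectivity construction and harmonization.

Turns ROI time-series matrices into model-ready connectivity matrices:

1. edge estimation — Pearson correlation or Tikhonov-regularized partial
   correlation ``(C + rho*I)^{-1}``;
2. proportional thresholding at a given sparsity (default 5% of the
   ``n(n-1)/2`` undirected edges, ranked by absolute value, signed weights
   retained);
3. per-subject standardization of the retained edges to zero mean, unit
   variance (population sd);
4. cohort-level removal of site and covariate (age, sex) effects by
   ordinary least squares on each retained edge position.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "CohortDataset",
    "DegenerateSeriesError",
    "pearson_connectivity",
    "tikhonov_connectivity",
    "proportional_threshold",
    "standardize_matrix",
    "residualize_covariates",
    "build_design_matrix",
    "load_cohort",
    "save_cohort",
    "validate_phenotypes",
]


class DegenerateSeriesError(ValueError):
    """A ROI time series has zero variance and cannot be correlated."""


@dataclass
class TimeSeriesMatrix:
    """BOLD time series for one subject: rows = timepoints, cols = ROIs."""

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D matrix")
        t, n = self.values.shape
        if t < 2:
            raise ValueError("need at least 2 timepoints")
        if n < 2:
            raise ValueError("need at least 2 ROIs")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted network for one subject."""

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str
    kind: str = "raw"
    is_thresholded: bool = False
    is_standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric within 1e-9")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def retained_edge_count(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.values[iu]))


@dataclass
class CohortDataset:
    """Aligned stack of connectivity matrices with phenotypes and a target."""

    matrices: list[ConnectivityMatrix]
    phenotypes: pd.DataFrame
    target_name: str

    def __post_init__(self):
        validate_phenotypes(self.phenotypes, require_score=self.target_name)
        if len(self.matrices) != len(self.phenotypes):
            raise ValueError("one connectivity matrix required per phenotype row")
        ids = list(self.phenotypes["subject_id"].astype(str))
        for cm, sid in zip(self.matrices, ids):
            if cm.subject_id != sid:
                raise ValueError(f"matrix order mismatch at subject {sid}")
        ns = {cm.n_nodes for cm in self.matrices}
        if len(ns) > 1:
            raise ValueError(f"inconsistent node counts across subjects: {sorted(ns)}")

    @property
    def n_nodes(self) -> int:
        return self.matrices[0].n_nodes

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def subject_ids(self) -> list[str]:
        return [cm.subject_id for cm in self.matrices]

    def stacked(self) -> np.ndarray:
        """(N, n, n) array of connectivity values."""
        return np.stack([cm.values for cm in self.matrices])

    @property
    def targets(self) -> np.ndarray:
        return self.phenotypes[self.target_name].to_numpy(dtype=np.float64)


def validate_phenotypes(df: pd.DataFrame, require_score: str | None = None) -> None:
    for col in ("subject_id", "site", "age", "sex"):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing required column '{col}'")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id '{dup}' in phenotype table")
    if require_score is not None:
        if require_score not in df.columns:
            raise ValueError(f"phenotype table missing score column '{require_score}'")
        if df[require_score].isna().any():
            raise ValueError(f"score column '{require_score}' has missing values")


# ---------------------------------------------------------------------------
# edge estimation
# ---------------------------------------------------------------------------

def pearson_connectivity(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of the demeaned ROI series.

    ``c[i, j] = t̃_iᵀ t̃_j / sqrt((t̃_iᵀ t̃_i)(t̃_jᵀ t̃_j))`` with ``t̃`` the
    per-ROI demeaned series; the diagonal is 1 until thresholding.
    """
    x = ts.values - ts.values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(x, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise DegenerateSeriesError(
            f"ROI '{ts.roi_labels[bad[0]]}' has zero variance for subject "
            f"{ts.subject_id}"
        )
    c = (x.T @ x) / np.outer(norms, norms)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(c, list(ts.roi_labels), ts.subject_id, kind="pearson")


def empirical_covariance(ts: TimeSeriesMatrix) -> np.ndarray:
    """Covariance ``(1/T) X̃ᵀ X̃`` of the demeaned series (1/T normalization)."""
    x = ts.values - ts.values.mean(axis=0, keepdims=True)
    t = x.shape[0]
    return (x.T @ x) / t


def tikhonov_connectivity(
    ts: TimeSeriesMatrix,
    rho: float = 0.1,
    partial_correlation: bool = False,
) -> ConnectivityMatrix:
    """Regularized precision matrix ``(C + rho*I)^{-1}``.

    ``C`` is the empirical covariance of the time series.  The ridge term
    damps indirect connections and makes the inverse well-posed.  With
    ``partial_correlation=True`` the precision matrix is rescaled to the
    partial-correlation convention ``-P_ij / sqrt(P_ii P_jj)``; by default
    the precision matrix itself is used as connectivity.
    """
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    c = empirical_covariance(ts)
    reg = c + rho * np.eye(c.shape[0])
    cond = np.linalg.cond(reg)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"(C + rho*I) is numerically singular (condition number {cond:.3e}); "
            "increase rho"
        )
    p = np.linalg.inv(reg)
    p = (p + p.T) / 2.0
    if partial_correlation:
        d = np.sqrt(np.diag(p))
        p = -p / np.outer(d, d)
        np.fill_diagonal(p, 1.0)
    return ConnectivityMatrix(p, list(ts.roi_labels), ts.subject_id, kind="tikhonov")


# ---------------------------------------------------------------------------
# thresholding and standardization
# ---------------------------------------------------------------------------

def retained_edge_target(n: int, sparsity: float) -> int:
    """floor(sparsity * n(n-1)/2): undirected edges kept at a given sparsity."""
    return int(math.floor(sparsity * n * (n - 1) / 2.0))


def proportional_threshold(cm: ConnectivityMatrix, sparsity: float = 0.05) -> ConnectivityMatrix:
    """Keep the top ``sparsity`` fraction of edges by absolute weight.

    The diagonal is zeroed; exactly ``floor(sparsity * n(n-1)/2)`` upper-
    triangle entries of largest magnitude survive (mirrored to the lower
    triangle) with their signed weights.  Ties at the cutoff magnitude are
    broken by (i, j) lexicographic order, so the result is deterministic.
    """
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = cm.n_nodes
    m = retained_edge_target(n, sparsity)
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.values[iu, ju]
    out = np.zeros_like(cm.values)
    if m > 0:
        # stable sort on (-|v|, i, j): lexicographic tie-break, deterministic
        order = np.lexsort((ju, iu, -np.abs(vals)))
        keep = order[:m]
        keep = keep[vals[keep] != 0.0]  # an all-zero matrix retains nothing
        out[iu[keep], ju[keep]] = vals[keep]
        out[ju[keep], iu[keep]] = vals[keep]
    return replace(cm, values=out, is_thresholded=True, is_standardized=False)


def standardize_matrix(cm: ConnectivityMatrix, ddof: int = 0) -> ConnectivityMatrix:
    """Z-score the retained edges of a thresholded matrix, per subject.

    Only nonzero (retained) upper-triangle entries participate; zeros stay
    exactly zero.  The default sd convention is the population sd (ddof 0).
    """
    if not cm.is_thresholded:
        raise ValueError("standardize_matrix expects a thresholded matrix")
    n = cm.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.values[iu, ju]
    mask = vals != 0.0
    if mask.sum() < 2:
        raise ValueError("need at least 2 retained edges to standardize")
    sd = vals[mask].std(ddof=ddof)
    if sd == 0.0:
        raise ValueError("all retained edge values are equal; zero variance")
    z = np.zeros_like(vals)
    z[mask] = (vals[mask] - vals[mask].mean()) / sd
    out = np.zeros_like(cm.values)
    out[iu, ju] = z
    out[ju, iu] = z
    return replace(cm, values=out, is_standardized=True)


def build_pipeline(
    ts: TimeSeriesMatrix,
    edge: str = "pearson",
    rho: float = 0.1,
    sparsity: float = 0.05,
    standardize: bool = True,
) -> ConnectivityMatrix:
    """Time series -> thresholded, standardized connectivity (single subject)."""
    if edge == "pearson":
        cm = pearson_connectivity(ts)
    elif edge == "tikhonov":
        cm = tikhonov_connectivity(ts, rho=rho)
    else:
        raise ValueError(f"unknown edge estimator '{edge}'")
    cm = proportional_threshold(cm, sparsity)
    if standardize:
        cm = standardize_matrix(cm)
    return cm


# ---------------------------------------------------------------------------
# covariate / site residualization
# ---------------------------------------------------------------------------

def build_design_matrix(
    phenotypes: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + one-hot sites (first level dropped) + numeric covariates.

    'site' and 'sex' are treated as categorical ('sex' as a 0/1 indicator
    against its first level); any other covariate is numeric.
    """
    cols: list[np.ndarray] = [np.ones(len(phenotypes))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise ValueError(f"covariate '{cov}' not in phenotype table")
        if cov in ("site", "sex"):
            levels = sorted(phenotypes[cov].astype(str).unique())
            for lvl in levels[1:]:
                cols.append((phenotypes[cov].astype(str) == lvl).to_numpy(float))
                names.append(f"{cov}[{lvl}]")
        else:
            cols.append(phenotypes[cov].to_numpy(dtype=np.float64))
            names.append(cov)
    x = np.column_stack(cols)
    return x, names


def residualize_covariates(
    ds: CohortDataset,
    covariates: Sequence[str] = ("site", "age", "sex"),
    fit_rows: Sequence[int] | None = None,
) -> CohortDataset:
    """Remove site/covariate effects from every retained edge by OLS.

    Per retained-edge position the edge value is regressed on an intercept,
    site indicators and the numeric covariates using ``fit_rows`` (default:
    all rows); the fitted component is subtracted for *all* rows.  Edge
    positions that are zero in every subject stay exactly zero.
    """
    x_full, names = build_design_matrix(ds.phenotypes, covariates)
    rows = np.arange(ds.n_subjects) if fit_rows is None else np.asarray(fit_rows)
    x_fit = x_full[rows]
    if len(rows) < x_fit.shape[1] + 2:
        raise ValueError(
            f"need at least {x_fit.shape[1] + 2} fit rows for {x_fit.shape[1]} "
            f"regressors, got {len(rows)}"
        )
    rank = np.linalg.matrix_rank(x_fit)
    if rank < x_fit.shape[1]:
        # report which columns are collinear with the preceding ones
        collinear = []
        for j in range(1, x_fit.shape[1]):
            if np.linalg.matrix_rank(x_fit[:, : j + 1]) <= np.linalg.matrix_rank(x_fit[:, :j]):
                collinear.append(names[j])
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {x_fit.shape[1]}); "
            f"collinear columns: {collinear}"
        )
    stack = ds.stacked()
    n = ds.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    edges = stack[:, iu, ju]  # (N, E)
    nonzero = np.any(edges != 0.0, axis=0)
    beta, *_ = np.linalg.lstsq(x_fit, edges[np.ix_(rows, np.flatnonzero(nonzero))], rcond=None)
    resid = edges.copy()
    resid[:, nonzero] = edges[:, nonzero] - x_full @ beta
    out_matrices = []
    for k, cm in enumerate(ds.matrices):
        v = np.zeros_like(cm.values)
        v[iu, ju] = resid[k]
        v[ju, iu] = resid[k]
        out_matrices.append(replace(cm, values=v))
    return CohortDataset(out_matrices, ds.phenotypes.copy(), ds.target_name)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    # round_trip parsing: written matrices reload bitwise-identically
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_connectivity(path: str | Path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a square TSV/CSV with ROI labels as header row and first column."""
    path = Path(path)
    df = _read_table(path)
    labels = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: connectivity matrix is not square")
    sid = subject_id or path.stem
    return ConnectivityMatrix(values, labels, sid)


def save_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.DataFrame(cm.values, columns=cm.roi_labels)
    df.insert(0, "roi", cm.roi_labels)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def load_timeseries(path: str | Path, subject_id: str | None = None) -> TimeSeriesMatrix:
    """Read a timepoints x ROIs TSV/CSV with a header row of ROI labels."""
    path = Path(path)
    df = _read_table(path)
    return TimeSeriesMatrix(
        df.to_numpy(dtype=np.float64), [str(c) for c in df.columns],
        subject_id or path.stem,
    )


def load_cohort(
    matrix_paths: Iterable[str | Path] | None = None,
    phenotype_path: str | Path | None = None,
    target_name: str = "score",
    timeseries_paths: Iterable[str | Path] | None = None,
    edge: str = "pearson",
    rho: float = 0.1,
    sparsity: float = 0.05,
    standardize: bool = True,
    logger=None,
) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from files on disk.

    Either precomputed square connectivity matrices (``matrix_paths``) or
    raw time series (``timeseries_paths``, run through the build pipeline)
    may be given; file stems are matched to ``subject_id`` in the phenotype
    CSV and ordered by the phenotype rows.
    """
    if phenotype_path is None:
        raise ValueError("phenotype_path is required")
    pheno = pd.read_csv(phenotype_path)
    validate_phenotypes(pheno, require_score=target_name)

    by_id: dict[str, ConnectivityMatrix] = {}
    if matrix_paths is not None:
        for p in matrix_paths:
            cm = load_connectivity(p)
            by_id[cm.subject_id] = cm
    elif timeseries_paths is not None:
        for p in timeseries_paths:
            ts = load_timeseries(p)
            by_id[ts.subject_id] = build_pipeline(
                ts, edge=edge, rho=rho, sparsity=sparsity, standardize=standardize
            )
    else:
        raise ValueError("provide matrix_paths or timeseries_paths")

    # restore build flags written by save_cohort, if present
    meta_path = Path(phenotype_path).parent / "cohort_meta.json"
    if matrix_paths is not None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        for cm in by_id.values():
            cm.kind = meta.get("kind", cm.kind)
            cm.is_thresholded = meta.get("is_thresholded", False)
            cm.is_standardized = meta.get("is_standardized", False)

    matrices = []
    for sid in pheno["subject_id"].astype(str):
        if sid not in by_id:
            raise FileNotFoundError(f"no connectivity matrix found for subject '{sid}'")
        matrices.append(by_id[sid])
    ds = CohortDataset(matrices, pheno, target_name)
    if logger is not None:
        logger.info(
            "cohort: N=%d n=%d sites=%s %s mean=%.3f sd=%.3f",
            ds.n_subjects, ds.n_nodes,
            dict(pheno["site"].value_counts()), target_name,
            ds.targets.mean(), ds.targets.std(),
        )
    return ds


def save_cohort(ds: CohortDataset, out_dir: str | Path) -> None:
    """Write matrices (one TSV per subject), phenotype CSV and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cm in ds.matrices:
        save_connectivity(cm, out / f"{cm.subject_id}.tsv")
    ds.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    meta = {
        "target_name": ds.target_name,
        "kind": ds.matrices[0].kind,
        "is_thresholded": ds.matrices[0].is_thresholded,
        "is_standardized": ds.matrices[0].is_standardized,
    }
    (out / "cohort_meta.json").write_text(json.dumps(meta, indent=2))
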