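"""Interpretation of the trained model: three-level CCA and saliency.

The three-level analysis relates, per subject, the n x q node embeddings
produced by the E2N layer (domain 1) to the n x 8 graph-theory node
measures (domain 2):

* level 1 — for each measure, the maximum pairwise Pearson correlation
  over embedding columns;
* level 2 — for each measure, the best correlation achievable by a linear
  combination of the embedding columns (the multiple correlation, i.e. the
  square root of the R² of regressing the measure on the embeddings);
* level 3 — the first canonical correlation between the full measure and
  embedding matrices, via SVD of the whitened cross-covariance
  ``Σ₁₁^{-1/2} Σ₁₂ Σ₂₂^{-1/2}``.

By construction level1 <= level2 <= level3 for each measure (nested
optimization spaces).  Saliency attribution is the gradient of the
predicted score with respect to each input edge (the binarized pooling
adjacency held fixed), symmetrized, and averaged across subjects for the
group edge table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .connectome import CohortDataset, ConnectivityMatrix
from .measures import MEASURE_NAMES, compute_node_measures
from .model import ModelConfig, forward_batch

__all__ = [
    "CCAResult",
    "SaliencyMatrix",
    "extract_node_embeddings",
    "level1_pairwise_max",
    "level2_per_measure_cca",
    "level3_full_cca",
    "cohort_cca",
    "saliency_map",
    "group_saliency",
]

_RIDGE = 1e-8  # default stabilization of within-set covariances


@dataclass
class CCAResult:
    level1: np.ndarray  # (p,)
    level2: np.ndarray  # (p,)
    level3: float
    w_gm: np.ndarray
    w_nf: np.ndarray
    subject_id: str = ""


@dataclass
class SaliencyMatrix:
    values: np.ndarray  # (n, n), symmetric
    roi_labels: list[str]
    scope: str = "subject"  # or "group"
    subject_id: str = ""


# ---------------------------------------------------------------------------
# node embeddings
# ---------------------------------------------------------------------------

def extract_node_embeddings(g, params, config: ModelConfig) -> np.ndarray:
    """E2N output (n x d) of the trained feature extractor for one matrix."""
    values = g.values if isinstance(g, ConnectivityMatrix) else np.asarray(g)
    _, inter = forward_batch(values, params, config)
    return inter["node_features"].data[0]


# ---------------------------------------------------------------------------
# three-level correlation analysis
# ---------------------------------------------------------------------------

def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def level1_pairwise_max(x_gm: np.ndarray, x_nf: np.ndarray) -> np.ndarray:
    """Per measure, the max Pearson correlation over embedding columns.

    Constant columns on either side are skipped (correlation undefined);
    if every embedding column is constant, raises.
    """
    x_gm, x_nf = np.asarray(x_gm, float), np.asarray(x_nf, float)
    if x_gm.shape[0] != x_nf.shape[0] or x_gm.shape[0] < 3:
        raise ValueError("domains need equal row counts >= 3")
    sd_gm = x_gm.std(axis=0)
    sd_nf = x_nf.std(axis=0)
    if not np.any(sd_nf > 0):
        raise ValueError("all embedding columns are constant")
    gm_c, nf_c = _center(x_gm), _center(x_nf)
    out = np.full(x_gm.shape[1], np.nan)
    ok_nf = sd_nf > 0
    for i in range(x_gm.shape[1]):
        if sd_gm[i] == 0:
            continue  # constant measure: leave NaN
        r = gm_c[:, [i]].T @ nf_c[:, ok_nf]
        r /= (x_gm.shape[0] * sd_gm[i] * sd_nf[ok_nf])
        out[i] = np.max(r)
    return out


def level2_per_measure_cca(x_gm: np.ndarray, x_nf: np.ndarray,
                           ridge: float = _RIDGE) -> np.ndarray:
    """Per measure, corr with the best linear combination of embeddings.

    Equals sqrt(R²) of the OLS regression of the measure on the embedding
    columns; a small ridge keeps the embedding Gram matrix invertible.
    """
    x_gm, x_nf = np.asarray(x_gm, float), np.asarray(x_nf, float)
    n = x_gm.shape[0]
    nf_c = _center(x_nf)
    gm_c = _center(x_gm)
    gram = nf_c.T @ nf_c / n + ridge * np.eye(x_nf.shape[1])
    out = np.full(x_gm.shape[1], np.nan)
    for i in range(x_gm.shape[1]):
        yi = gm_c[:, i]
        var_y = float(yi @ yi) / n
        if var_y == 0:
            continue
        cov = nf_c.T @ yi / n
        w = np.linalg.solve(gram, cov)
        proj = nf_c @ w
        sd = np.std(proj)
        if sd == 0:
            out[i] = 0.0
        else:
            out[i] = float(proj @ yi) / (n * sd * np.sqrt(var_y))
    return out


def _inv_sqrt(mat: np.ndarray, ridge: float) -> np.ndarray:
    # ridge scales with the covariance magnitude so exactly collinear
    # columns (flow = 1 - clustering on min-degree-2 graphs) stay benign:
    # the inflated null direction carries zero centered data, hence zero
    # cross-covariance
    scale = max(1.0, float(np.trace(mat)) / mat.shape[0])
    mat = mat + ridge * scale * np.eye(mat.shape[0])
    vals, vecs = np.linalg.eigh(mat)
    if np.min(vals) <= 0:
        raise np.linalg.LinAlgError(
            "within-set covariance is singular; increase the ridge parameter"
        )
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def level3_full_cca(x_gm: np.ndarray, x_nf: np.ndarray,
                    ridge: float = _RIDGE) -> tuple[float, np.ndarray, np.ndarray]:
    """First canonical correlation between the two domains.

    SVD of the whitened cross-covariance ``Σ₁₁^{-1/2} Σ₁₂ Σ₂₂^{-1/2}``;
    returns (r, w_gm, w_nf) with the canonical weights mapped back to the
    original column spaces.  Constant columns (a measure that happens to be
    degenerate on a given graph, e.g. clustering on a tree) carry no
    correlation information and are dropped; their weights are 0.
    """
    x_gm, x_nf = np.asarray(x_gm, float), np.asarray(x_nf, float)
    n = x_gm.shape[0]
    keep1 = np.flatnonzero(x_gm.std(axis=0) > 1e-12)
    keep2 = np.flatnonzero(x_nf.std(axis=0) > 1e-12)
    if keep1.size == 0 or keep2.size == 0:
        raise ValueError("a domain has no nonconstant columns; CCA undefined")
    gm_c, nf_c = _center(x_gm[:, keep1]), _center(x_nf[:, keep2])
    s11 = gm_c.T @ gm_c / n
    s22 = nf_c.T @ nf_c / n
    s12 = gm_c.T @ nf_c / n
    k1 = _inv_sqrt(s11, ridge)
    k2 = _inv_sqrt(s22, ridge)
    u, svals, vt = np.linalg.svd(k1 @ s12 @ k2)
    r = float(min(svals[0], 1.0))
    w_gm = np.zeros(x_gm.shape[1])
    w_nf = np.zeros(x_nf.shape[1])
    w_gm[keep1] = k1 @ u[:, 0]
    w_nf[keep2] = k2 @ vt[0, :]
    return r, w_gm, w_nf


def subject_cca(x_gm: np.ndarray, x_nf: np.ndarray, subject_id: str = "",
                ridge: float = _RIDGE) -> CCAResult:
    l1 = level1_pairwise_max(x_gm, x_nf)
    l2 = level2_per_measure_cca(x_gm, x_nf, ridge)
    l3, w_gm, w_nf = level3_full_cca(x_gm, x_nf, ridge)
    return CCAResult(l1, l2, l3, w_gm, w_nf, subject_id)


def cohort_cca(ds: CohortDataset, params, config: ModelConfig,
               ridge: float = _RIDGE) -> pd.DataFrame:
    """Per-subject three-level analysis; long-format results table.

    Columns: subject_id, level, measure ('' for level 3), value.  Figure-
    style summaries (mean ± sd across subjects) can be derived from it.
    """
    rows = []
    for cm in ds.matrices:
        x_nf = extract_node_embeddings(cm, params, config)
        x_gm = compute_node_measures(cm).values
        res = subject_cca(x_gm, x_nf, cm.subject_id, ridge)
        for j, name in enumerate(MEASURE_NAMES):
            rows.append({"subject_id": cm.subject_id, "level": 1,
                         "measure": name, "value": res.level1[j]})
            rows.append({"subject_id": cm.subject_id, "level": 2,
                         "measure": name, "value": res.level2[j]})
        rows.append({"subject_id": cm.subject_id, "level": 3,
                     "measure": "", "value": res.level3})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# saliency
# ---------------------------------------------------------------------------

def saliency_map(g, params, config: ModelConfig) -> SaliencyMatrix:
    """Gradient of the predicted score w.r.t. each input edge.

    Computed analytically by backpropagation with the binarized pooling
    adjacency held constant (it is piecewise constant in the input), then
    symmetrized as ``(PD + PDᵀ)/2``.
    """
    if isinstance(g, ConnectivityMatrix):
        values, labels, sid = g.values, list(g.roi_labels), g.subject_id
    else:
        values = np.asarray(g, float)
        labels = [f"roi_{i}" for i in range(values.shape[0])]
        sid = ""
    gt = Tensor(values, requires_grad=True)
    preds, _ = forward_batch(gt, params, config, adjacency_grad="detach")
    preds.sum().backward()
    pd_map = gt.grad
    pd_map = (pd_map + pd_map.T) / 2.0
    return SaliencyMatrix(pd_map, labels, scope="subject", subject_id=sid)


def group_saliency(maps: list[SaliencyMatrix], keep_fraction: float = 0.10,
                   rule: str = "top_fraction") -> tuple[SaliencyMatrix, pd.DataFrame]:
    """Average subject maps and keep the strongest edges.

    ``rule='top_fraction'`` keeps the top ``keep_fraction`` of edges by
    |mean PD|; ``rule='fraction_of_max'`` instead keeps edges with
    ``|PD| >= keep_fraction * max|PD|``.  Returns the group map and an
    edge table (region1, region2, pd_value) sorted by |PD| descending.
    """
    if not maps:
        raise ValueError("need at least one subject saliency map")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    mean_map = np.mean([m.values for m in maps], axis=0)
    labels = maps[0].roi_labels
    n = mean_map.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mags = np.abs(mean_map[iu, ju])
    if rule == "top_fraction":
        n_keep = max(1, int(np.floor(keep_fraction * len(mags))))
        order = np.argsort(-mags, kind="stable")[:n_keep]
    elif rule == "fraction_of_max":
        order = np.flatnonzero(mags >= keep_fraction * mags.max())
        order = order[np.argsort(-mags[order], kind="stable")]
    else:
        raise ValueError(f"unknown thresholding rule '{rule}'")
    table = pd.DataFrame({
        "region1": [labels[i] for i in iu[order]],
        "region2": [labels[j] for j in ju[order]],
        "pd_value": mean_map[iu[order], ju[order]],
    })
    group = SaliencyMatrix(mean_map, list(labels), scope="group")
    return group, table


def cohort_saliency(ds: CohortDataset, params, config: ModelConfig,
                    keep_fraction: float = 0.10,
                    rule: str = "top_fraction") -> tuple[SaliencyMatrix, pd.DataFrame]:
    maps = [saliency_map(cm, params, config) for cm in ds.matrices]
    return group_saliency(maps, keep_fraction, rule)
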