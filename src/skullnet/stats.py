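"""Comparative statistics over specimens' network parameters.

Specimens are compared by ordinary principal component analysis, by
phylogenetic PCA (which removes the trait covariance expected from shared
ancestry under Brownian motion on a given tree), by Mann–Whitney U tests
between ecological/taxonomic groups, and by flexible discriminant analysis
(optimal scoring with a linear basis) of morphological character states.

Conventions that published values depend on are exposed: correlation vs
covariance PCA (``standardize``), the PC sign convention (axes oriented so
declared reference parameters load positively — by default density D on
axis 1 and contact count K on axis 2), and continuity correction of the
rank-sum z (off by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GroupTestResult",
    "OrdinationResult",
    "FDAResult",
    "mann_whitney",
    "pca",
    "phylogenetic_covariance",
    "ppca",
    "fda",
    "group_battery",
    "normalize_taxon",
]


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTestResult:
    """Rank-sum comparison of two groups; ``z`` is signed, report ``z_abs``."""

    u: float
    z: float
    p: float
    n_a: int
    n_b: int
    method: str

    @property
    def z_abs(self) -> float:
        return abs(self.z)


def _exact_u_pvalue(u: float, n_a: int, n_b: int, alternative: str) -> float:
    """Exact p by enumeration of all C(n_a+n_b, n_a) rank assignments."""
    n = n_a + n_b
    base = n_a * (n_a + 1) // 2
    counts: dict[int, int] = {}
    for combo in itertools.combinations(range(1, n + 1), n_a):
        ua = sum(combo) - base
        counts[ua] = counts.get(ua, 0) + 1
    total = sum(counts.values())
    mn = n_a * n_b
    if alternative == "greater":
        tail = sum(c for v, c in counts.items() if v >= u)
    elif alternative == "less":
        tail = sum(c for v, c in counts.items() if v <= u)
    else:
        lo, hi = min(u, mn - u), max(u, mn - u)
        tail = sum(c for v, c in counts.items() if v <= lo or v >= hi)
    return tail / total


def mann_whitney(
    a,
    b,
    alternative: str = "two_sided",
    mode: str = "auto",
    continuity: bool = False,
) -> GroupTestResult:
    """Mann–Whitney U test from rank sums (midranks for ties).

    ``mode="auto"`` uses exact enumeration when both samples have ≤ 10
    observations and there are no ties, and the tie-corrected normal
    approximation otherwise; the z statistic carries no continuity
    correction unless requested.  U and z are reported for sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    mn = n_a * n_b
    n = n_a + n_b

    has_ties = len(np.unique(pooled)) < n
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (
        mode == "auto" and n_a <= 10 and n_b <= 10 and not has_ties
    )
    if use_exact and has_ties:
        raise ValueError("exact enumeration requires tie-free data")

    # tie-corrected normal z (reported in both modes; Table-style |z|)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = mn / 12.0 * ((n + 1) - tie_term)
    diff = u - mn / 2.0
    if continuity and diff != 0:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = 0.0 if var <= 0 else diff / np.sqrt(var)

    if use_exact:
        p = _exact_u_pvalue(u, n_a, n_b, alternative)
        method = "exact"
    else:
        from scipy.stats import norm

        if var <= 0:
            p = 1.0
        elif alternative == "greater":
            p = float(norm.sf(z))
        elif alternative == "less":
            p = float(norm.cdf(z))
        else:
            p = float(2 * norm.sf(abs(z)))
        method = "normal_tie_corrected"
    return GroupTestResult(
        u=float(u), z=float(z), p=float(min(p, 1.0)), n_a=n_a, n_b=n_b, method=method
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Scores, loadings, and per-axis variance fractions of an ordination."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    kind: str


def _orient_axes(
    loadings: np.ndarray, scores: np.ndarray, columns: list[str], orient: dict[int, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Fix eigenvector signs: reference parameter positive on its axis,
    otherwise the largest-|loading| entry positive."""
    for j in range(loadings.shape[1]):
        ref = orient.get(j + 1)
        if ref is not None and ref in columns:
            val = loadings[columns.index(ref), j]
        else:
            val = loadings[np.argmax(np.abs(loadings[:, j])), j]
        if val < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


DEFAULT_ORIENT = {1: "D", 2: "K"}


def pca(
    table: pd.DataFrame,
    standardize: bool = True,
    orient: dict[int, str] | None = None,
) -> OrdinationResult:
    """Principal component analysis of the specimen × parameter table.

    Correlation PCA by default (the nine parameters mix counts with ratios);
    set ``standardize=False`` for covariance PCA.
    """
    if table.shape[0] < 2:
        raise ValueError("PCA needs at least 2 specimens")
    if orient is None:
        orient = DEFAULT_ORIENT
    x = table.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    xc = x - mu
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [c for c, s in zip(table.columns, sd) if s == 0]
            raise ValueError(f"constant column(s) under standardization: {const}")
        xc = xc / sd
    cov = xc.T @ xc / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    scores = xc @ eigvec
    eigvec, scores = _orient_axes(eigvec, scores, list(table.columns), orient)
    comp = [f"PC{i+1}" for i in range(len(eigval))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp),
        loadings=pd.DataFrame(eigvec, index=table.columns, columns=comp),
        variance_explained=eigval / eigval.sum(),
        kind="pca",
    )


def normalize_taxon(name: str) -> str:
    """Case-fold, trim, and treat underscores as spaces (tree vs table ids)."""
    return " ".join(str(name).strip().casefold().replace("_", " ").split())


def phylogenetic_covariance(tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion tip covariance: shared root-to-MRCA path lengths.

    ``tree`` is a rooted dendropy Tree with branch lengths; ``taxa`` selects
    and orders the tips (matching by normalized name).  Extra tips are
    ignored; a requested taxon missing from the tree is an error naming it.
    """
    tip_of: dict[str, object] = {}
    for leaf in tree.leaf_node_iter():
        tip_of[normalize_taxon(leaf.taxon.label)] = leaf
    wanted = [normalize_taxon(t) for t in taxa]
    missing = [t for t, w in zip(taxa, wanted) if w not in tip_of]
    if missing:
        raise ValueError(f"tree is missing specimens: {missing}")

    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(id(node.parent_node), 0.0)
        edge = node.edge.length or 0.0
        depth[id(node)] = parent_depth + edge

    n = len(taxa)
    sigma = np.zeros((n, n))
    leaves = [tip_of[w] for w in wanted]
    ancestors = []
    for leaf in leaves:
        chain = []
        node = leaf
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        ancestors.append(set(chain))
    for i in range(n):
        sigma[i, i] = depth[id(leaves[i])]
        for j in range(i + 1, n):
            # deepest common ancestor along i's root path
            node = leaves[i]
            mrca_depth = 0.0
            while node is not None:
                if id(node) in ancestors[j]:
                    mrca_depth = depth[id(node)]
                    break
                node = node.parent_node
            sigma[i, j] = sigma[j, i] = mrca_depth
    return sigma


def ppca(
    table: pd.DataFrame,
    tree,
    standardize: bool = True,
    orient: dict[int, str] | None = None,
) -> OrdinationResult:
    """Phylogenetic PCA: eigenanalysis of the evolutionary (co)variance.

    With tip covariance Σ from the tree, the phylogenetic mean is
    a = (1ᵀΣ⁻¹1)⁻¹ 1ᵀΣ⁻¹X and the evolutionary covariance
    P = (X−1aᵀ)ᵀ Σ⁻¹ (X−1aᵀ)/(n−1); components are eigenvectors of P (of
    its correlation rescaling when ``standardize``) and scores are the
    phylogenetically centered data projected on them.
    """
    if orient is None:
        orient = DEFAULT_ORIENT
    sigma = phylogenetic_covariance(tree, list(table.index))
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance") from exc
    x = table.to_numpy(dtype=float)
    ones = np.ones((x.shape[0], 1))
    denom = float((ones.T @ sigma_inv @ ones).item())
    a = (ones.T @ sigma_inv @ x) / denom  # 1×p phylogenetic mean
    xc = x - ones @ a
    p_mat = xc.T @ sigma_inv @ xc / (x.shape[0] - 1)
    if standardize:
        d = np.sqrt(np.diag(p_mat))
        if np.any(d == 0):
            const = [c for c, s in zip(table.columns, d) if s == 0]
            raise ValueError(f"constant column(s) under standardization: {const}")
        p_use = p_mat / np.outer(d, d)
        xc = xc / d
    else:
        p_use = p_mat
    eigval, eigvec = np.linalg.eigh(p_use)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    scores = xc @ eigvec
    eigvec, scores = _orient_axes(eigvec, scores, list(table.columns), orient)
    comp = [f"pPC{i+1}" for i in range(len(eigval))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp),
        loadings=pd.DataFrame(eigvec, index=table.columns, columns=comp),
        variance_explained=eigval / eigval.sum(),
        kind="ppca",
    )


# ---------------------------------------------------------------------------
# flexible discriminant analysis (optimal scoring, linear basis)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FDAResult:
    """Optimal-scoring discriminant fit and its training confusion."""

    class_scores: pd.DataFrame       # classes × discriminants (θ)
    directions: pd.DataFrame         # features × discriminants (β)
    confusion: pd.DataFrame          # true × predicted counts
    misclassification_error: float
    predictions: pd.Series

    @property
    def n_errors(self) -> int:
        total = int(self.confusion.to_numpy().sum())
        return total - int(np.diag(self.confusion.to_numpy()).sum())


def fda(features: pd.DataFrame, labels: pd.Series, basis: str = "linear") -> FDAResult:
    """Flexible discriminant analysis with a linear regression basis.

    Optimal scoring: class-indicator scores are regressed on the features
    and the scores updated by eigen-decomposition, which with a linear basis
    is equivalent to linear discriminant analysis.  Observations are
    classified by Gaussian discriminant (nearest centroid after sphering,
    with log class-frequency priors) in the discriminant-variate space; the
    reported error is the training (resubstitution) rate.
    """
    if basis != "linear":
        raise ValueError("only the linear optimal-scoring basis is supported")
    labels = pd.Series(labels, index=features.index).astype(str)
    classes = sorted(labels.unique())
    j_cls = len(classes)
    if j_cls < 2:
        raise ValueError("need at least 2 classes")
    counts = labels.value_counts()
    small = sorted(c for c in classes if counts[c] < 2)
    if small:
        raise ValueError(f"class(es) with < 2 members: {small}")
    x = features.to_numpy(dtype=float)
    n, p = x.shape
    xc = x - x.mean(axis=0)
    y = np.zeros((n, j_cls))
    for i, lab in enumerate(labels):
        y[i, classes.index(lab)] = 1.0

    xtx = xc.T @ xc
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        warnings.warn("collinear features; using pseudo-inverse", stacklevel=2)
    xtx_pinv = np.linalg.pinv(xtx)
    hat_y = xc @ (xtx_pinv @ (xc.T @ y))  # projection of Y onto [1, X] minus the mean part
    ybar = y.mean(axis=0)
    # Y' P_[1,X] Y = Yc' H Yc + n ybar ybar'
    ypy = (y - ybar).T @ hat_y + n * np.outer(ybar, ybar)
    w = y.T @ y  # diag of class counts
    w_isqrt = np.diag(1.0 / np.sqrt(np.diag(w)))
    m_sym = w_isqrt @ ypy @ w_isqrt
    # deflate the trivial constant score (direction W^{1/2} 1)
    v0 = np.sqrt(np.diag(w))
    v0 = v0 / np.linalg.norm(v0)
    proj = np.eye(j_cls) - np.outer(v0, v0)
    m_sym = proj @ m_sym @ proj
    eigval, eigvec = np.linalg.eigh(m_sym)
    order = np.argsort(eigval)[::-1][: j_cls - 1]
    eigval = np.clip(eigval[order], 0, None)
    theta = w_isqrt @ eigvec[:, order]
    # normalize scores: θ'Wθ/n = 1
    norms = np.sqrt(np.einsum("ij,jk,ki->i", theta.T, w, theta) / n)
    norms[norms == 0] = 1.0
    theta = theta / norms

    beta = xtx_pinv @ (xc.T @ (y @ theta))  # p × (J−1) directions
    z = xc @ beta                            # discriminant variates

    # pooled within-class covariance of variates; sphere, then Gaussian rule
    centroids = np.vstack([z[labels.to_numpy() == c].mean(axis=0) for c in classes])
    resid = z - centroids[[classes.index(l) for l in labels]]
    dof = max(n - j_cls, 1)
    sw = resid.T @ resid / dof
    eval_w, evec_w = np.linalg.eigh(sw)
    tol = max(eval_w.max(), 0) * 1e-10 if eval_w.size else 0
    inv_sqrt = np.array([1.0 / np.sqrt(v) if v > tol else 0.0 for v in eval_w])
    whiten = evec_w @ np.diag(inv_sqrt) @ evec_w.T
    zw = z @ whiten
    cw = centroids @ whiten
    priors = np.array([counts[c] / n for c in classes])
    d2 = ((zw[:, None, :] - cw[None, :, :]) ** 2).sum(axis=2)
    disc = -0.5 * d2 + np.log(priors)
    pred_idx = disc.argmax(axis=1)
    predictions = pd.Series([classes[i] for i in pred_idx], index=features.index)

    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for true, hat in zip(labels, predictions):
        confusion.loc[true, hat] += 1
    err = float((labels.to_numpy() != predictions.to_numpy()).mean())
    disc_cols = [f"DA{i+1}" for i in range(theta.shape[1])]
    return FDAResult(
        class_scores=pd.DataFrame(theta, index=classes, columns=disc_cols),
        directions=pd.DataFrame(beta, index=features.columns, columns=disc_cols),
        confusion=confusion,
        misclassification_error=err,
        predictions=predictions,
    )


# ---------------------------------------------------------------------------
# the Table-1-shaped battery
# ---------------------------------------------------------------------------

def group_battery(
    table: pd.DataFrame,
    traits: pd.DataFrame,
    grouping: str,
    ordinations: list[OrdinationResult] | None = None,
    continuity: bool = False,
) -> pd.DataFrame:
    """Mann–Whitney grid: every parameter (plus the first two components of
    each supplied ordination) compared between the two levels of a binary
    trait column; rows are variables, columns |z|, p, and group sizes."""
    if grouping not in traits.columns:
        raise ValueError(f"trait column {grouping!r} not found")
    levels = sorted(traits.loc[table.index, grouping].dropna().unique())
    if len(levels) != 2:
        raise ValueError(
            f"grouping {grouping!r} must be binary over the analysis set, got {levels}"
        )
    mask_a = traits.loc[table.index, grouping] == levels[0]
    mask_b = traits.loc[table.index, grouping] == levels[1]
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"grouping {grouping!r} has an empty side")

    variables = table.copy()
    for ordn in ordinations or []:
        for col in ordn.scores.columns[:2]:
            variables[col] = ordn.scores.loc[table.index, col]

    rows = []
    for col in variables.columns:
        vals = variables[col].astype(float)
        res = mann_whitney(
            vals[mask_a].to_numpy(), vals[mask_b].to_numpy(),
            mode="normal", continuity=continuity,
        )
        rows.append(
            {"variable": col, "z_abs": res.z_abs, "p": res.p,
             f"n_{levels[0]}": res.n_a, f"n_{levels[1]}": res.n_b}
        )
    return pd.DataFrame(rows).set_index("variable")
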