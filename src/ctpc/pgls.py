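"""Phylogenetic generalized least squares with star/Brownian/Pagel covariance.

Species-mean traits are regressed on a habitat indicator under three residual
covariance structures: a star phylogeny (lambda = 0, phylogeny ignored), pure
Brownian motion on the tree (lambda = 1), and Pagel's model in which the
off-diagonal covariances are scaled by a lambda estimated by maximum
likelihood on [0, 1]. Models are compared by small-sample AIC (AICc) and
Akaike weights. Also provides Newick I/O, neighbour-joining tree construction
from a distance matrix, and the tree -> covariance conversion.

Likelihoods are ML (not REML) so that AICc values are comparable between the
fixed-lambda and estimated-lambda models.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

MODELS = ("star", "brownian", "pagel")


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Newick I/O and NJ
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; tips must be uniquely labeled with branch lengths."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise PhylogenyError(f"malformed Newick: {exc}") from exc
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise PhylogenyError("unlabeled tip in Newick input")
        labels.append(leaf.taxon.label)
        if leaf.edge.length is None:
            raise PhylogenyError(f"tip {leaf.taxon.label!r} lacks a branch length")
    if len(set(labels)) != len(labels):
        raise PhylogenyError("duplicate tip labels in Newick input")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    labels: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise PhylogenyError("matrix shape must match the label count")
        if not np.all(np.isfinite(self.matrix)):
            raise PhylogenyError("distances must be finite")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise PhylogenyError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise PhylogenyError("distance matrix diagonal must be zero")
        if np.any(self.matrix < -1e-12):
            raise PhylogenyError("distances must be non-negative")

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "DistanceMatrix":
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        n = len(taxa)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return cls([t.label for t in taxa], m)


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining (Q-criterion) tree; negative branch lengths clamped to 0."""
    n = len(d.labels)
    if n < 3:
        raise PhylogenyError("NJ needs at least 3 taxa")
    buf = io.StringIO()
    buf.write("." + "," + ",".join(str(l) for l in d.labels) + "\n")
    for i, lab in enumerate(d.labels):
        buf.write(str(lab) + "," + ",".join(f"{x:.17g}" for x in d.matrix[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        warnings.warn(f"NJ produced {n_clamped} negative branch length(s); clamped to 0")
    return tree


# ---------------------------------------------------------------------------
# Tree -> covariance
# ---------------------------------------------------------------------------

def phylo_cov(
    tree: dendropy.Tree,
    lam: float = 1.0,
    species: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list]:
    """Phylogenetic covariance: C[i, j] = root-to-MRCA path length, off-diagonals x lambda.

    ``lam = 0`` gives the star model (diagonal of root-to-tip depths);
    ``lam = 1`` the full Brownian covariance. Rows follow ``species`` when
    given (erroring on species missing from the tree), else sorted tip labels.
    """
    if not 0.0 <= lam <= 1.0:
        raise PhylogenyError("lambda must lie in [0, 1]")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon}
    if species is None:
        species = sorted(leaves)
    missing = [s for s in species if s not in leaves]
    if missing:
        raise PhylogenyError(f"species missing from tree: {missing}")
    depth = np.array([leaves[s].root_distance for s in species])
    pdm = tree.phylogenetic_distance_matrix()
    n = len(species)
    C = np.diag(depth).astype(float)
    for i in range(n):
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(leaves[species[i]].taxon,
                                         leaves[species[j]].taxon)
            # depth of the MRCA from root distances and the patristic distance
            C[i, j] = C[j, i] = lam * 0.5 * (depth[i] + depth[j] - dij)
    return C, list(species)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PhyloModelFit:
    """One PGLS fit of a species-mean trait on habitat."""

    model: str
    trait: str
    coef_names: list
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p: np.ndarray
    df: int
    lam: float
    logLik: float
    AICc: float
    n: int
    n_params: int
    aicc_ok: bool = True
    wAICc: Optional[float] = None
    y: np.ndarray = field(default=None, repr=False)


def _gls_profile(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """GLS estimates with profiled ML variance; returns (beta, ll, xtcix, s2_ml, resid_quad)."""
    n = len(y)
    cf = cho_factor(C, lower=True)
    Ci_X = cho_solve(cf, X)
    Ci_y = cho_solve(cf, y)
    xtcix = X.T @ Ci_X
    beta = np.linalg.solve(xtcix, X.T @ Ci_y)
    resid = y - X @ beta
    quad = float(resid @ cho_solve(cf, resid))
    s2_ml = quad / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    with np.errstate(divide="ignore"):  # exact fits: s2 -> 0, ll -> +inf
        ll = -0.5 * (n * np.log(2.0 * np.pi * s2_ml) + logdet + n)
    return beta, ll, xtcix, s2_ml, quad


def _lambda_cov(C1: np.ndarray, lam: float) -> np.ndarray:
    C = lam * C1
    np.fill_diagonal(C, np.diag(C1))
    return C


def pgls_fit(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    model: str = "pagel",
    trait_name: str = "value",
    design: str = "habitat",
) -> PhyloModelFit:
    """Fit one PGLS model of a species-mean trait on a habitat indicator.

    ``traits`` has one row per species with columns ``species``, the design
    column and the trait column. Coefficient t-tests use the unbiased variance
    with df = n - rank(X); AICc counts the residual variance (and lambda for
    the Pagel model) among the parameters.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if traits["species"].duplicated().any():
        raise ValueError("one value per species required (species duplicated)")
    species = list(traits["species"])
    n = len(species)
    if n < 3:
        raise ValueError("PGLS needs at least 3 species")
    y = traits[trait_name].to_numpy(float)
    hab = traits[design].to_numpy()
    if hab.dtype.kind in "OUS":
        levels = sorted(pd.unique(hab))
        if len(levels) != 2:
            raise ValueError(f"habitat design must have 2 levels, got {levels}")
        hab = (hab == levels[1]).astype(float)
    else:
        hab = hab.astype(float)
    X = np.column_stack([np.ones(n), hab])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    C1, _ = phylo_cov(tree, 1.0, species=species)

    if model == "star":
        lam = 0.0
    elif model == "brownian":
        lam = 1.0
    else:
        # profile likelihood in lambda can be multimodal: coarse grid
        # (including both endpoints) then bounded refinement around the best
        def nll(l: float) -> float:
            return -_gls_profile(_lambda_cov(C1, l), X, y)[1]

        grid = np.linspace(0.0, 1.0, 21)
        values = [nll(l) for l in grid]
        i = int(np.argmin(values))
        lo_b, hi_b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(nll, bounds=(lo_b, hi_b), method="bounded",
                              options={"xatol": 1e-6})
        lam = float(res.x) if res.fun <= values[i] else float(grid[i])
        if lam < 1e-6:
            lam = 0.0
        elif lam > 1.0 - 1e-6:
            lam = 1.0

    C = _lambda_cov(C1, lam)
    beta, ll, xtcix, _, quad = _gls_profile(C, X, y)
    k = X.shape[1]
    df = n - k
    s2 = quad / df if df > 0 else np.nan
    se = np.sqrt(np.diag(np.linalg.inv(xtcix)) * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df) if df > 0 else np.full(k, np.nan)

    n_params = k + 1 + (1 if model == "pagel" else 0)  # + sigma^2 (+ lambda)
    aicc_ok = n - n_params - 1 > 0
    aicc = (-2.0 * ll + 2.0 * n_params
            + 2.0 * n_params * (n_params + 1) / (n - n_params - 1)) if aicc_ok else np.nan
    if not aicc_ok:
        warnings.warn(f"AICc undefined for model={model}: n - p - 1 <= 0")
    return PhyloModelFit(
        model=model, trait=trait_name, coef_names=["intercept", design],
        beta=beta, se=se, t_stat=np.asarray(t), p=np.asarray(p), df=df,
        lam=lam, logLik=ll, AICc=aicc, n=n, n_params=n_params,
        aicc_ok=aicc_ok, y=y.copy(),
    )


def akaike_weights(aicc: np.ndarray) -> np.ndarray:
    """wAICc_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2)."""
    aicc = np.asarray(aicc, dtype=float)
    delta = aicc - np.nanmin(aicc)
    w = np.exp(-0.5 * delta)
    return w / np.nansum(w)


def compare_models(fits: Sequence[PhyloModelFit]) -> pd.DataFrame:
    """Rank a set of fits of the same data by AICc and attach Akaike weights."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if f.n != ref.n or not np.allclose(f.y, ref.y):
            raise ValueError("fits must be on identical data")
        if f.trait != ref.trait:
            raise ValueError("fits must model the same trait")
    if any(not f.aicc_ok for f in fits):
        raise ValueError("AICc undefined for some fits; cannot compare")
    w = akaike_weights([f.AICc for f in fits])
    rows = []
    for f, wi in zip(fits, w):
        f.wAICc = float(wi)
        rows.append({
            "trait": f.trait, "model": f.model, "lambda": f.lam,
            "beta_habitat": f.beta[1], "se": f.se[1], "t": f.t_stat[1],
            "df": f.df, "p": f.p[1], "logLik": f.logLik,
            "AICc": f.AICc, "wAICc": f.wAICc,
        })
    return (pd.DataFrame(rows)
            .sort_values("AICc", ignore_index=True))


def pgls_table(
    species_means: pd.DataFrame,
    tree: dendropy.Tree,
    traits: Sequence[str],
    models: Sequence[str] = MODELS,
) -> pd.DataFrame:
    """Full model-comparison table: one block of models per trait."""
    blocks = []
    for trait in traits:
        fits = [pgls_fit(species_means, tree, model=m, trait_name=trait)
                for m in models]
        blocks.append(compare_models(fits))
    return pd.concat(blocks, ignore_index=True)
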