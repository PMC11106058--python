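"""Synthetic-data generators for the network-regression study.

A random rooted binary phylogeny over ``V`` taxa stands in for the true
microbial community.  Each sample observes ``k`` taxa drawn uniformly without
replacement; its network connects co-occurring taxa with edge weight equal to
the inverse patristic distance.  The phenotype is generated under one of four
models:

``theoretical``
    ``y_i = <A_i, B>_F + eps`` with a sparse symmetric ``B`` whose entries are
    ``N(mu, sigma^2)`` on edges between influential nodes (per-node
    Bernoulli(pi) coin) and zero elsewhere; adjacency diagonals are zero.
``additive``
    ``y_i = sum of main effects b_j`` over influential taxa present in the
    sample, plus noise; diagonals are presence indicators.  Main effects are
    either i.i.d. normal or correlated as a Brownian motion along the tree.
``interaction``
    additive plus pairwise terms ``a_jl * b_jl`` with interaction
    coefficients ``b_jl ~ N(0.4, 1)`` drawn once per influential pair.
``redundant``
    the interaction phenotype capped at a threshold ``L`` (functional
    redundancy: co-occurring taxa sharing a function saturate the response).

Defaults follow the study conditions: ``V=30``, ``k=8``, ``pi=0.3``,
effect-size mean ``mu in {0.8, 1.6}`` with unit variance, unit noise, and the
per-setting redundancy caps ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import NetworkDataset

__all__ = [
    "PhyloTree",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tree",
    "patristic_distances",
    "brownian_covariance",
    "generate_node_influence",
    "generate_B_theoretical",
    "generate_main_effects",
    "sample_taxa_and_adjacency",
    "inverse_distance_adjacency",
    "generate_response",
    "simulate_dataset",
    "augment_dataset",
    "REDUNDANCY_CAPS",
]

# per-setting response caps for the functional-redundancy model, keyed by
# (node-influence probability, effect mean); chosen so some but not all
# responses are capped
REDUNDANCY_CAPS = {(0.3, 0.8): 3.0, (0.3, 1.6): 7.0, (0.8, 0.8): 22.0, (0.8, 1.6): 30.0}


@dataclass
class PhyloTree:
    """Rooted binary phylogeny with positive branch lengths over labelled leaves."""

    tree: dendropy.Tree
    labels: list[str]

    @property
    def V(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        # child edges of a rooted binary tree: 2V - 2
        return sum(1 for e in self.tree.preorder_edge_iter() if e.head_node is not self.tree.seed_node)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def simulate_tree(V: int, rng: np.random.Generator) -> PhyloTree:
    """Grow a random rooted binary tree by uniform random leaf-edge splitting.

    Starting from a two-leaf cherry, a uniformly chosen leaf edge is split
    (the leaf becomes a cherry) until ``V`` leaves exist; every one of the
    ``2V - 2`` child edges then receives an i.i.d. Uniform(0, 1) branch
    length.
    """
    if V < 2:
        raise ValueError(f"a phylogeny needs at least 2 leaves, got V={V}")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        leaves.append(child)
    while len(leaves) < V:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        leaves.append(node.new_child())
        leaves.append(node.new_child())
    labels = [f"t{i+1}" for i in range(V)]
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = 0.0
        else:
            node.edge.length = float(rng.uniform(0.0, 1.0))
    return PhyloTree(tree=tree, labels=labels)


def _leaf_depths(ptree: PhyloTree) -> np.ndarray:
    depth = {id(ptree.tree.seed_node): 0.0}
    for node in ptree.tree.preorder_node_iter():
        if node is ptree.tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    by_label = {leaf.taxon.label: depth[id(leaf)] for leaf in ptree.tree.leaf_node_iter()}
    return np.array([by_label[lab] for lab in ptree.labels])


def patristic_distances(ptree: PhyloTree) -> np.ndarray:
    """Matrix of path lengths between every pair of leaves (zero diagonal)."""
    pdm = ptree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in ptree.tree.taxon_namespace}
    V = ptree.V
    D = np.zeros((V, V))
    for i in range(V):
        for j in range(i + 1, V):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[ptree.labels[i]], taxa[ptree.labels[j]])
    return D


def brownian_covariance(ptree: PhyloTree) -> np.ndarray:
    """Brownian-motion trait covariance: shared root-to-MRCA path length.

    ``Sigma_ij = (depth_i + depth_j - d_ij) / 2`` with diagonal equal to the
    root-to-leaf depth.
    """
    depths = _leaf_depths(ptree)
    D = patristic_distances(ptree)
    Sigma = (depths[:, None] + depths[None, :] - D) / 2.0
    return (Sigma + Sigma.T) / 2.0


def generate_node_influence(V: int, pi: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(pi) influence indicator per node."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0, 1], got {pi}")
    return (rng.random(V) < pi).astype(np.int8)


def generate_B_theoretical(xi_true, mu, sigma_effect, rng) -> np.ndarray:
    """Sparse symmetric coefficient matrix for the theoretical model.

    ``b_ij = b_ji ~ N(mu, sigma^2)`` independently for each unordered pair of
    influential nodes, zero elsewhere; the diagonal is zero (presence/absence
    carries no effect in the theoretical setting).
    """
    xi = np.asarray(xi_true)
    V = xi.size
    B = np.zeros((V, V))
    for i in range(V):
        for j in range(i + 1, V):
            if xi[i] and xi[j]:
                B[i, j] = B[j, i] = rng.normal(mu, sigma_effect)
    return B


def generate_main_effects(ptree: PhyloTree, mu_b: float, mode: str,
                          rng: np.random.Generator, sigma: float = 1.0) -> np.ndarray:
    """Per-taxon main effects, i.i.d. (``random``) or tree-correlated.

    In ``phylogenetic`` mode the vector is one draw of ``N(mu_b 1, Sigma)``
    with ``Sigma`` the Brownian-motion covariance of the tree, so closely
    related taxa get similar effects.
    """
    V = ptree.V
    if mode == "random":
        return rng.normal(mu_b, sigma, size=V)
    if mode == "phylogenetic":
        Sigma = brownian_covariance(ptree)
        L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(V))
        return mu_b + L @ rng.standard_normal(V)
    raise ValueError(f"unknown coefficient mode {mode!r}")


def inverse_distance_adjacency(distances: np.ndarray, present: np.ndarray,
                               diagonal_mode: str = "zero") -> np.ndarray:
    """Adjacency of one sample: ``a_ij = 1/d_ij`` when both taxa are present.

    ``diagonal_mode='presence'`` writes 1 on the diagonal for present taxa
    (the realistic setting); ``'zero'`` leaves it at zero (theoretical).
    """
    present = np.asarray(present, dtype=bool)
    V = distances.shape[0]
    off = ~np.eye(V, dtype=bool)
    if np.any(distances[off] <= 0):
        raise ValueError("patristic distances between distinct leaves must be positive")
    A = np.zeros((V, V))
    idx = np.flatnonzero(present)
    for a, i in enumerate(idx):
        for j in idx[a + 1:]:
            A[i, j] = A[j, i] = 1.0 / distances[i, j]
    if diagonal_mode == "presence":
        A[idx, idx] = 1.0
    elif diagonal_mode != "zero":
        raise ValueError(f"unknown diagonal mode {diagonal_mode!r}")
    return A


def sample_taxa_and_adjacency(distances: np.ndarray, k: int, diagonal_mode: str,
                              rng: np.random.Generator):
    """Draw ``k`` taxa uniformly without replacement and build their network."""
    V = distances.shape[0]
    if not 1 <= k <= V:
        raise ValueError(f"k must be in 1..{V}, got {k}")
    subset = np.sort(rng.choice(V, size=k, replace=False))
    present = np.zeros(V, dtype=bool)
    present[subset] = True
    return subset, inverse_distance_adjacency(distances, present, diagonal_mode)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset (defaults = baseline setting)."""

    V: int = 30
    k: int = 8
    pi: float = 0.3
    mu: float = 1.6
    sigma_effect: float = 1.0
    n: int = 500
    model: str = "theoretical"           # theoretical | additive | interaction | redundant
    coeff_type: str = "random"           # random | phylogenetic
    interaction_mean: float = 0.4
    interaction_sd: float = 1.0
    L: float | None = None               # redundancy cap; defaults per (pi, mu)
    noise_sd: float = 1.0
    cap_before_noise: bool = False

    def __post_init__(self):
        if not 1 <= self.k <= self.V:
            raise ValueError(f"k must be in 1..{self.V}, got {self.k}")
        if self.model not in ("theoretical", "additive", "interaction", "redundant"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "redundant" and self.L is None:
            key = (self.pi, self.mu)
            if key not in REDUNDANCY_CAPS:
                raise ValueError(
                    f"no default redundancy cap for (pi, mu)={key}; set L explicitly"
                )
            self.L = REDUNDANCY_CAPS[key]

    @property
    def diagonal_mode(self) -> str:
        return "zero" if self.model == "theoretical" else "presence"


@dataclass
class SimulationTruth:
    """Everything needed to score recovery of a simulated dataset."""

    tree: PhyloTree
    distances: np.ndarray
    B_true: np.ndarray                   # (V, V) true coefficient matrix
    xi_true: np.ndarray                  # (V,) true node-influence indicators
    edge_influential: np.ndarray         # (V, V) bool, off-diagonal
    sampled_taxa: list = field(default_factory=list)
    b_main: np.ndarray | None = None     # realistic models
    b_interaction: np.ndarray | None = None
    Sigma_tree: np.ndarray | None = None


def generate_response(A, subset, truth: SimulationTruth, config: SimulationConfig,
                      rng: np.random.Generator) -> float:
    """One phenotype draw for a sample with adjacency ``A`` and taxa ``subset``."""
    eps = rng.normal(0.0, config.noise_sd)
    if config.model == "theoretical":
        return float(np.sum(A * truth.B_true) + eps)
    xi = truth.xi_true
    present_infl = [j for j in subset if xi[j]]
    raw = float(sum(truth.b_main[j] for j in present_infl))
    if config.model in ("interaction", "redundant"):
        for a, j in enumerate(present_infl):
            for l in present_infl[a + 1:]:
                raw += A[j, l] * truth.b_interaction[j, l]
    if config.model == "redundant":
        if config.L is None or not np.isfinite(config.L):
            raise ValueError("redundant model requires a finite cap L")
        if config.cap_before_noise:
            return float(min(raw, config.L) + eps)
        return float(min(raw + eps, config.L))
    return raw + eps


def simulate_dataset(config: SimulationConfig, rng: np.random.Generator | int):
    """Generate one full study dataset: tree, networks, phenotypes, and truth."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tree = simulate_tree(config.V, rng)
    distances = patristic_distances(tree)
    xi = generate_node_influence(config.V, config.pi, rng)
    edge_infl = (np.outer(xi, xi) > 0) & ~np.eye(config.V, dtype=bool)

    b_main = b_inter = Sigma = None
    if config.model == "theoretical":
        B_true = generate_B_theoretical(xi, config.mu, config.sigma_effect, rng)
    else:
        if config.coeff_type == "phylogenetic":
            Sigma = brownian_covariance(tree)
        b_main = generate_main_effects(tree, config.mu, config.coeff_type, rng,
                                       sigma=config.sigma_effect)
        B_true = np.diag(b_main * xi).astype(float)
        if config.model in ("interaction", "redundant"):
            b_inter = np.zeros((config.V, config.V))
            for i in range(config.V):
                for j in range(i + 1, config.V):
                    if xi[i] and xi[j]:
                        b_inter[i, j] = b_inter[j, i] = rng.normal(
                            config.interaction_mean, config.interaction_sd
                        )
            # one interaction term a_jl * b_jl per unordered pair maps to
            # off-diagonal coefficients b_jl / 2 in the symmetric matrix
            B_true = B_true + b_inter / 2.0

    truth = SimulationTruth(
        tree=tree, distances=distances, B_true=B_true, xi_true=xi,
        edge_influential=edge_infl, b_main=b_main, b_interaction=b_inter,
        Sigma_tree=Sigma,
    )
    adjacency = np.empty((config.n, config.V, config.V))
    response = np.empty(config.n)
    for i in range(config.n):
        subset, A = sample_taxa_and_adjacency(distances, config.k, config.diagonal_mode, rng)
        truth.sampled_taxa.append(subset)
        adjacency[i] = A
        response[i] = generate_response(A, subset, truth, config, rng)
    dataset = NetworkDataset(adjacency=adjacency, response=response, taxa=tree.labels)
    return dataset, truth


def augment_dataset(dataset: NetworkDataset, presence_sets, n_target: int,
                    rng: np.random.Generator, network_builder,
                    positivity_fix: bool = False):
    """Enlarge a dataset with perturbed pseudo-samples.

    Originals are cycled round-robin; each augmented copy gets (a) a response
    offset drawn from ``N(0, s_P^2 / 4)`` where ``s_P^2`` is the sample
    variance of the original responses, and (b) independently flipped
    presence indicators (a taxon present in the original is retained with
    probability 0.9, an absent one added with probability 0.1), from which
    the network is rebuilt with ``network_builder(presence_mask)``.  With
    ``positivity_fix`` a negative augmented response is replaced by a draw of
    ``(1/15) * chi-square(3)`` so augmented responses stay positive (for
    strictly positive phenotypes).

    Returns ``(augmented NetworkDataset, augmented presence list)`` holding
    originals followed by the pseudo-samples.
    """
    n = dataset.n
    if n < 2:
        raise ValueError("augmentation needs at least 2 original samples")
    if n_target <= n:
        raise ValueError(f"n_target must exceed the original n={n}")
    V = dataset.V
    sP2 = float(np.var(dataset.response, ddof=1))
    masks = []
    for p in presence_sets:
        mask = np.zeros(V, dtype=bool)
        mask[np.asarray(p, dtype=int)] = True
        masks.append(mask)

    adjacency = [dataset.adjacency[i] for i in range(n)]
    response = list(dataset.response)
    out_masks = list(masks)
    t = 0
    while len(response) < n_target:
        i = t % n
        t += 1
        keep = rng.random(V) < 0.9
        add = rng.random(V) < 0.1
        new_mask = np.where(masks[i], keep, add)
        resp = float(dataset.response[i] + rng.normal(0.0, np.sqrt(sP2 / 4.0)))
        if positivity_fix and resp < 0:
            resp = float(rng.chisquare(3) / 15.0)
        adjacency.append(network_builder(new_mask))
        response.append(resp)
        out_masks.append(new_mask)
    aug = NetworkDataset(adjacency=np.stack(adjacency), response=np.array(response),
                         taxa=dataset.taxa)
    return aug, [np.flatnonzero(m) for m in out_masks]
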