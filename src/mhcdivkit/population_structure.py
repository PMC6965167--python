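"""Between-population structure: Weir–Cockerham θ (F_ST), Nei's D_A genetic
distance, neighbor-joining dendrograms with bootstrap support, classical
metric MDS, and PCA of allele frequencies.

θ follows Weir & Cockerham (1984): per-allele variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are summed over alleles, with θ = Σa / Σ(a+b+c). Pairwise
values are computed on each population pair alone.

D_A is the single-locus form 1 − Σ_i √(x_i y_i) over the union allele set.

Because the analysis rests on a single locus, bootstrap support for the NJ
dendrogram resamples animals within populations (the usual unit — loci —
does not exist here); support is the percentage of replicates containing
each original bipartition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .io_core import DistanceMatrix, FrequencySpectrum, PopulationSample, ValidationError
from .allele_diversity import allele_frequencies

__all__ = [
    "StructureResult",
    "OrdinationResult",
    "wc_theta_pair",
    "wc_fst",
    "da_distance",
    "da_matrix",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "mds_from_distances",
    "pca_frequencies",
]


# ---------------------------------------------------------------------------
# Weir–Cockerham θ


def _per_population_stats(samples: list[PopulationSample], alleles: list[str]):
    """n_i, p̃_ia, ĥ_ia arrays (populations × alleles)."""
    r = len(samples)
    n = np.array([s.n for s in samples], dtype=float)
    p = np.zeros((r, len(alleles)))
    h = np.zeros((r, len(alleles)))
    index = {a: j for j, a in enumerate(alleles)}
    for i, s in enumerate(samples):
        for a, b in s.genotypes:
            p[i, index[a]] += 1
            p[i, index[b]] += 1
            if a != b:
                h[i, index[a]] += 1
                h[i, index[b]] += 1
        p[i] /= 2 * s.n
        h[i] /= s.n
    return n, p, h


def _wc_components(samples: list[PopulationSample]) -> tuple[float, float, float]:
    """Σa, Σb, Σc over alleles for a set of populations (Weir–Cockerham 1984)."""
    alleles = sorted({a for s in samples for a in s.allele_counts()})
    if len(alleles) < 2:
        raise ValidationError("θ undefined: populations are jointly monomorphic")
    n, p, h = _per_population_stats(samples, alleles)
    r = len(samples)
    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    sum_a = sum_b = sum_c = 0.0
    for j in range(len(alleles)):
        p_bar = float((n * p[:, j]).sum() / (r * n_bar))
        s2 = float((n * (p[:, j] - p_bar) ** 2).sum() / ((r - 1) * n_bar))
        h_bar = float((n * h[:, j]).sum() / (r * n_bar))
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
        sum_a += a
        sum_b += b
        sum_c += c
    return sum_a, sum_b, sum_c


def wc_theta_pair(sample_a: PopulationSample, sample_b: PopulationSample) -> float:
    """Pairwise Weir–Cockerham θ for two populations."""
    a, b, c = _wc_components([sample_a, sample_b])
    total = a + b + c
    if total == 0.0:
        raise ValidationError("θ undefined: zero total variance")
    return a / total


@dataclass
class StructureResult:
    overall_fst: float
    pairwise_fst: DistanceMatrix
    da: DistanceMatrix


def wc_fst(samples: list[PopulationSample]) -> StructureResult:
    """Overall θ across all populations plus the pairwise θ and D_A matrices."""
    if len(samples) < 2:
        raise ValidationError("F_ST requires >= 2 populations")
    for s in samples:
        if s.n < 2:
            raise ValidationError(f"population {s.label!r}: N >= 2 required")
    a, b, c = _wc_components(samples)
    if a + b + c == 0.0:
        raise ValidationError("θ undefined: zero total variance")
    overall = a / (a + b + c)

    labels = [s.label for s in samples]
    k = len(samples)
    pw = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        pw[i, j] = pw[j, i] = wc_theta_pair(samples[i], samples[j])
    spectra = [allele_frequencies(s) for s in samples]
    return StructureResult(
        overall_fst=overall,
        pairwise_fst=DistanceMatrix(labels, pw),
        da=da_matrix(spectra),
    )


# ---------------------------------------------------------------------------
# D_A


def da_distance(spectrum_a: FrequencySpectrum, spectrum_b: FrequencySpectrum) -> float:
    """Nei et al. D_A = 1 − Σ √(x_i y_i), single locus; alleles absent from a
    spectrum contribute frequency 0."""
    alleles = set(spectrum_a.frequencies) | set(spectrum_b.frequencies)
    bc = sum(
        np.sqrt(spectrum_a.frequencies.get(a, 0.0) * spectrum_b.frequencies.get(a, 0.0))
        for a in alleles
    )
    return float(1.0 - bc)


def da_matrix(spectra: list[FrequencySpectrum]) -> DistanceMatrix:
    labels = [sp.label for sp in spectra]
    k = len(spectra)
    values = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        values[i, j] = values[j, i] = da_distance(spectra[i], spectra[j])
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; unrooted tree as a trifurcating root.

    Ties in the Q criterion break on the lowest index pair (deterministic).
    Negative branch lengths are clamped to 0 with the deficit transferred to
    the sister branch, preserving the pair's path length (standard practice).
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValidationError("NJ requires >= 3 taxa")
    d = matrix.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_next[m - 2, : m - 2] = new_d[keep]
        d_next[: m - 2, m - 2] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        d = d_next

    # final three nodes join at the (unrooted) trifurcating root
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(children=list(nodes))
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = float(max(length, 0.0))
    return root


def tree_bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonicalized tip sets (the lexicographically
    smaller side of each split)."""
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def bootstrap_support(
    samples: list[PopulationSample], reps: int = 10_000, seed: int = 0
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree on D_A with animal-resampling bootstrap support.

    Each replicate resamples animals with replacement within every population,
    recomputes spectra → D_A → NJ, and scores the original tree's
    bipartitions. Support (0–100) is attached to internal nodes as names and
    returned as a mapping from canonical bipartition to percentage.
    """
    if len(samples) < 3:
        raise ValidationError("bootstrap support requires >= 3 populations")
    if reps < 100:
        raise ValidationError("bootstrap reps < 100 gives unstable supports")
    rng = np.random.default_rng(seed)
    spectra = [allele_frequencies(s) for s in samples]
    base = nj_tree(da_matrix(spectra))
    tips = frozenset(s.label for s in samples)
    base_splits = tree_bipartitions(base, tips)
    counts = {split: 0 for split in base_splits}
    for _ in range(reps):
        resampled = []
        for s in samples:
            idx = rng.integers(0, s.n, size=s.n)
            resampled.append(
                PopulationSample(s.label, [s.genotypes[i] for i in idx])
            )
        rep_splits = tree_bipartitions(
            nj_tree(da_matrix([allele_frequencies(s) for s in resampled])), tips
        )
        for split in base_splits & rep_splits:
            counts[split] += 1
    support = {split: 100.0 * c / reps for split, c in counts.items()}
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, tips - side, key=lambda s: (len(s), sorted(s)))
        if key in support:
            node.name = f"{support[key]:.0f}"
    return base, support


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # populations × k
    rsq: float | None = None
    explained_variance: np.ndarray | None = None
    loadings: "object | None" = None  # pandas DataFrame for PCA
    rank_deficient: bool = False


def mds_from_distances(matrix: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric scaling (principal coordinates): double-center the
    squared distances, eigendecompose, keep the top-k positive components.

    ``rsq`` is the squared Pearson correlation between the input distances
    and the embedded Euclidean distances over all pairs. If fewer than k
    positive eigenvalues exist the missing columns are zero and the result is
    flagged ``rank_deficient``.
    """
    d = matrix.values
    m = d.shape[0]
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((m, k))
    positive = 0
    for comp in range(min(k, m)):
        if eigval[comp] > 1e-12:
            coords[:, comp] = eigvec[:, comp] * np.sqrt(eigval[comp])
            positive += 1
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1))
    iu = np.triu_indices(m, 1)
    x, y = d[iu], emb[iu]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        rsq = 1.0 if np.allclose(x, y) else 0.0
    else:
        rsq = float(np.corrcoef(x, y)[0, 1] ** 2)
    return OrdinationResult(
        labels=list(matrix.labels),
        coordinates=coords,
        rsq=rsq,
        explained_variance=eigval[:k].clip(min=0.0),
        rank_deficient=positive < k,
    )


def pca_frequencies(spectra: list[FrequencySpectrum], k: int | None = None) -> OrdinationResult:
    """Covariance PCA of the populations × alleles frequency matrix.

    Columns (alleles) are mean-centered; no rescaling — allele frequencies
    share a scale. Returns scores, explained variances (non-increasing), and
    allele loadings per component ranked by absolute contribution (the
    "contributing alleles" report of the ordination figures).
    """
    import pandas as pd

    if len(spectra) < 2:
        raise ValidationError("PCA requires >= 2 populations")
    alleles = sorted({a for sp in spectra for a in sp.frequencies})
    x = np.array([[sp.frequencies.get(a, 0.0) for a in alleles] for sp in spectra])
    labels = [sp.label for sp in spectra]
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_comp = len(s) if k is None else min(k, len(s))
    scores = u[:, :n_comp] * s[:n_comp]
    explained = (s[:n_comp] ** 2) / max(len(spectra) - 1, 1)
    loadings = pd.DataFrame(
        vt[:n_comp].T, index=alleles, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    return OrdinationResult(
        labels=labels,
        coordinates=scores,
        explained_variance=explained,
        loadings=loadings,
    )
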