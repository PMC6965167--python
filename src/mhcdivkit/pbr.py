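"""Peptide-binding-region (PBR) functional diversity.

The PBR is the set of β1-domain residues (31 positions by default) that
contact bound peptides: two alleles with the same PBR present essentially the
same peptide repertoire even if they differ elsewhere. This module provides

* PBR extraction from translated alleles;
* per-genotype identity/similarity percentages over PBR positions, with
  "similar" meaning identical residues or a strictly positive BLOSUM62 score;
* the population-level similarity summary (mean ± SD over all observed
  genotypes) with a randomized-subset one-way ANOVA + Bonferroni comparison
  across populations;
* position × residue frequency profiles (the sequence-logo matrix) built from
  alleles above a frequency threshold, flattened to 620-coordinate vectors
  (31 positions × 20 amino acids) whose pairwise Pearson correlations measure
  repertoire covariation between populations;
* distinct-PBR counting across an allele catalog.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .io_core import (
    AlleleCatalog,
    DistanceMatrix,
    FrequencySpectrum,
    PBRMask,
    PopulationSample,
    ValidationError,
)
from .allele_diversity import allele_frequencies, randomized_subsets
from .population_structure import OrdinationResult, mds_from_distances

__all__ = [
    "AA_ORDER",
    "blosum62",
    "PBRProfile",
    "SimilarityResult",
    "translate_and_extract_pbr",
    "genotype_pbr_similarity",
    "population_pbr_similarity",
    "randomized_similarity_anova",
    "pbr_profile",
    "covariation_analysis",
    "count_distinct_pbr",
]

# fixed alphabetical one-letter order -> bit-reproducible 620-vectors
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    """BLOSUM62 substitution score for a residue pair."""
    return float(_BLOSUM62[a, b])


def translate_and_extract_pbr(catalog: AlleleCatalog, mask: PBRMask) -> dict[str, str]:
    """Per-allele PBR string: residues at the mask's 1-based positions, in
    mask order, from the frame-trimmed translation."""
    if mask.positions[-1] > catalog.peptide_length:
        raise ValidationError("mask position exceeds peptide length")
    return {
        name: "".join(pep[p - 1] for p in mask.positions)
        for name, pep in catalog.peptides.items()
    }


def genotype_pbr_similarity(pbr_a: str, pbr_b: str) -> tuple[float, float]:
    """(identity %, similarity %) between two PBR strings.

    Identity counts equal residues; similarity additionally counts pairs with
    a strictly positive BLOSUM62 score. Both are percentages of the string
    length, so identity ≤ similarity always.
    """
    if len(pbr_a) != len(pbr_b):
        raise ValidationError("PBR strings have unequal lengths")
    n = len(pbr_a)
    ident = sum(1 for x, y in zip(pbr_a, pbr_b) if x == y)
    similar = sum(
        1 for x, y in zip(pbr_a, pbr_b) if x == y or blosum62(x, y) > 0
    )
    return 100.0 * ident / n, 100.0 * similar / n


@dataclass
class SimilarityResult:
    label: str
    per_genotype_identity: np.ndarray
    per_genotype_similarity: np.ndarray
    mean_similarity: float
    sd_similarity: float


def population_pbr_similarity(
    sample: PopulationSample,
    catalog: AlleleCatalog,
    mask: PBRMask,
    include_homozygotes: bool = True,
    sample_sd: bool = False,
) -> SimilarityResult:
    """Mean ± SD of the per-animal similarity between each genotype's two
    alleles' PBR strings.

    Homozygotes score 100/100 and are included by default (all observed
    genotypes enter the summary); ``include_homozygotes=False`` is provided
    for sensitivity analysis. SD is the population convention (divide by n)
    unless ``sample_sd``.
    """
    pbr = translate_and_extract_pbr(catalog, mask)
    idents, sims = [], []
    for a, b in sample.genotypes:
        if not include_homozygotes and a == b:
            continue
        i, s = genotype_pbr_similarity(pbr[a], pbr[b])
        idents.append(i)
        sims.append(s)
    if not sims:
        raise ValidationError(f"population {sample.label!r}: no genotypes to score")
    sims_arr = np.array(sims)
    ddof = 1 if sample_sd else 0
    sd = float(sims_arr.std(ddof=ddof)) if len(sims_arr) > ddof else 0.0
    return SimilarityResult(
        label=sample.label,
        per_genotype_identity=np.array(idents),
        per_genotype_similarity=sims_arr,
        mean_similarity=float(sims_arr.mean()),
        sd_similarity=sd,
    )


def _bonferroni_pairwise(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    labels = list(groups)
    n_tests = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        p_adj = min(1.0, p * n_tests)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(p_adj),
                "significant": bool(p_adj <= alpha),
            }
        )
    return pd.DataFrame(rows)


def randomized_similarity_anova(
    samples: list[PopulationSample],
    catalog: AlleleCatalog,
    mask: PBRMask,
    subset_size: int = 30,
    n_sets: int = 5,
    seed: int = 0,
) -> list[dict]:
    """One-way ANOVA across populations on per-genotype PBR similarity, on
    ``n_sets`` randomized subsets of ``subset_size`` animals per population,
    with Bonferroni-adjusted pairwise t-tests.

    Returns one dict per set: {"set", "F", "p", "pairwise"(DataFrame)}.
    """
    for s in samples:
        if s.n < subset_size:
            raise ValidationError(
                f"population {s.label!r}: N={s.n} < subset size {subset_size}"
            )
    results = []
    for k in range(n_sets):
        groups: dict[str, np.ndarray] = {}
        for i, s in enumerate(samples):
            # one independent subset per (set, population)
            subset = randomized_subsets(
                s, size=subset_size, n_sets=1, seed=seed + 7919 * k + i
            )[0]
            groups[s.label] = population_pbr_similarity(
                subset, catalog, mask
            ).per_genotype_similarity
        f, p = stats.f_oneway(*groups.values())
        results.append(
            {
                "set": k,
                "F": float(f),
                "p": float(p),
                "pairwise": _bonferroni_pairwise(groups),
            }
        )
    return results


@dataclass
class PBRProfile:
    """Position × residue frequency matrix for one population's PBR."""

    label: str
    matrix: np.ndarray  # len(mask) × 20, rows sum to 1
    min_freq: float
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != 20:
            raise ValidationError("profile must have 20 residue columns")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("profile rows must sum to 1")

    def flatten(self) -> np.ndarray:
        """Row-major covariation vector; 31 positions × 20 residues = 620."""
        return self.matrix.reshape(-1)


def pbr_profile(
    spectrum: FrequencySpectrum,
    pbr_strings: dict[str, str],
    mask: PBRMask,
    min_freq: float = 0.05,
    renormalize: bool = True,
) -> PBRProfile:
    """Residue-frequency profile over alleles with frequency > ``min_freq``.

    Included alleles' frequencies are renormalized to sum to 1 (default), so
    row r, column aa holds the renormalized frequency mass of included
    alleles carrying aa at mask position r. With ``renormalize=False`` the
    raw frequencies are used and rows sum to the included mass instead.
    """
    included = {a: f for a, f in spectrum.frequencies.items() if f > min_freq}
    if not included:
        raise ValidationError(
            f"population {spectrum.label!r}: no allele above frequency {min_freq}"
        )
    total = sum(included.values())
    matrix = np.zeros((len(mask), 20))
    for allele, freq in included.items():
        weight = freq / total if renormalize else freq
        s = pbr_strings[allele]
        if len(s) != len(mask):
            raise ValidationError(f"PBR string for {allele!r} has wrong length")
        for r, aa in enumerate(s):
            matrix[r, _AA_INDEX[aa]] += weight
    if renormalize:
        matrix /= matrix.sum(axis=1, keepdims=True)
    return PBRProfile(
        label=spectrum.label,
        matrix=matrix,
        min_freq=min_freq,
        positions=mask.positions,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        raise ValidationError("zero-variance covariation vector")
    return float((xc * yc).sum() / denom)


def covariation_analysis(
    profiles: list[PBRProfile], mds_k: int = 2
) -> tuple[pd.DataFrame, OrdinationResult, float]:
    """Pairwise Pearson correlation of flattened profiles, metric MDS on the
    1 − PCC distances, and the grand mean of off-diagonal PCCs (the global
    covariation figure).

    Returns (PCC DataFrame, MDS OrdinationResult, global mean PCC).
    """
    if len(profiles) < 2:
        raise ValidationError("covariation needs >= 2 profiles")
    positions = {p.positions for p in profiles}
    if len(positions) != 1:
        raise ValidationError("profiles use different PBR masks")
    labels = [p.label for p in profiles]
    vectors = [p.flatten() for p in profiles]
    k = len(profiles)
    pcc = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        pcc[i, j] = pcc[j, i] = _pearson(vectors[i], vectors[j])
    distance = DistanceMatrix(labels, 1.0 - pcc)
    ordination = mds_from_distances(distance, k=mds_k)
    iu = np.triu_indices(k, 1)
    global_pcc = float(pcc[iu].mean())
    return pd.DataFrame(pcc, index=labels, columns=labels), ordination, global_pcc


def count_distinct_pbr(
    catalog: AlleleCatalog, mask: PBRMask
) -> tuple[int, int, list[list[str]]]:
    """(distinct PBR strings, total alleles, groups sharing a string).

    Alleles differing only synonymously (or outside the mask) share a PBR and
    are counted once — functionally they present the same repertoire.
    """
    pbr = translate_and_extract_pbr(catalog, mask)
    groups: dict[str, list[str]] = {}
    for name, s in pbr.items():
        groups.setdefault(s, []).append(name)
    duplicate_groups = [sorted(g) for g in groups.values() if len(g) > 1]
    return len(groups), len(pbr), sorted(duplicate_groups)
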