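"""Sequence-level diversity and selection.

Implements, for a single aligned multi-allelic locus:

* segregating (polymorphic) sites S, presence-based over the distinct alleles
  observed in a population;
* nucleotide diversity π with the small-sample correction
  π = n/(n−1) Σ_i Σ_j x_i x_j d_ij over gene-copy frequencies x and per-site
  p-distances d_ij;
* net divergence between populations, Π_net = Π_AB − (Π_A + Π_B)/2, reported
  per site or per sequence;
* Nei–Gojobori (1986) synonymous/nonsynonymous rates with the Jukes–Cantor
  correction d = −(3/4)·ln(1 − (4/3)p), averaged over distinct-allele pairs,
  and a one-tailed Z-test for positive selection (d_N > d_S) with
  codon-bootstrap variances.

The Nei–Gojobori conventions used here:

* synonymous site counts per codon are degeneracy fractions — at each codon
  position the fraction of the three possible base changes that are
  synonymous (changes to stop codons count as nonsynonymous, so S + N = 3 ×
  codons exactly);
* pairwise differences average equally over all minimal mutational pathways
  between two codons, excluding pathways passing through a stop codon;
* sites are averaged over the two sequences of each pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import norm

from .io_core import AlleleCatalog, PopulationSample, ValidationError
from .allele_diversity import allele_frequencies

__all__ = [
    "SelectionResult",
    "segregating_sites",
    "nucleotide_diversity",
    "between_population_diversity",
    "net_divergence",
    "nei_gojobori_pair",
    "nei_gojobori_dnds",
    "codon_z_test",
    "jukes_cantor",
]

_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
_BASES = "ACGT"


def segregating_sites(catalog: AlleleCatalog, allele_subset: list[str]) -> int:
    """Number of alignment columns with ≥2 distinct bases among the given
    alleles (frequency-ignoring: each distinct allele counts once)."""
    seqs = [catalog.trimmed(a) for a in dict.fromkeys(allele_subset)]
    if not seqs:
        raise ValidationError("allele subset is empty")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValidationError("unequal sequence lengths")
    arr = np.array([list(s) for s in seqs])
    return int(np.sum((arr != arr[0]).any(axis=0)))


def _pairwise_p_distance(seq_a: str, seq_b: str) -> float:
    if len(seq_a) != len(seq_b):
        raise ValidationError("unequal sequence lengths")
    diffs = sum(1 for x, y in zip(seq_a, seq_b) if x != y)
    return diffs / len(seq_a)


def nucleotide_diversity(sample: PopulationSample, catalog: AlleleCatalog) -> float:
    """π per site with the n/(n−1) correction, n = 2N gene copies.

    Equals the average per-site difference over all C(n, 2) gene-copy pairs.
    Monomorphic samples give 0.
    """
    if sample.n < 2:
        raise ValidationError("nucleotide diversity requires N >= 2")
    spectrum = allele_frequencies(sample)
    alleles = list(spectrum.frequencies)
    x = np.array([spectrum.frequencies[a] for a in alleles])
    d = np.array(
        [
            [_pairwise_p_distance(catalog.trimmed(a), catalog.trimmed(b)) for b in alleles]
            for a in alleles
        ]
    )
    n = sample.gene_copies
    return float(n / (n - 1) * x @ d @ x)


def between_population_diversity(
    sample_a: PopulationSample, sample_b: PopulationSample, catalog: AlleleCatalog
) -> float:
    """Π_AB: frequency-weighted mean per-site distance between one gene copy
    from each population."""
    sp_a = allele_frequencies(sample_a)
    sp_b = allele_frequencies(sample_b)
    total = 0.0
    for a, xa in sp_a.frequencies.items():
        for b, xb in sp_b.frequencies.items():
            total += xa * xb * _pairwise_p_distance(catalog.trimmed(a), catalog.trimmed(b))
    return total


def net_divergence(
    sample_a: PopulationSample,
    sample_b: PopulationSample,
    catalog: AlleleCatalog,
    per_sequence: bool = False,
) -> float:
    """Π_net = Π_AB − (Π_A + Π_B)/2; may be negative when within-population
    diversity exceeds between-population divergence.

    ``per_sequence=True`` multiplies by the alignment length, giving average
    counts of nucleotide differences rather than per-site values.
    """
    pi_ab = between_population_diversity(sample_a, sample_b, catalog)
    # within-population terms enter uncorrected (plain Σ x_i x_j d_ij) so that
    # the self-divergence identity Π_net(A, A) = 0 holds exactly
    pi_a = between_population_diversity(sample_a, sample_a, catalog)
    pi_b = between_population_diversity(sample_b, sample_b, catalog)
    net = pi_ab - (pi_a + pi_b) / 2.0
    if per_sequence:
        net *= catalog.trimmed_length
    return net


# ---------------------------------------------------------------------------
# Nei–Gojobori


@lru_cache(maxsize=None)
def _syn_fraction(codon: str, position: int) -> float:
    """Fraction (out of 3) of base changes at one codon position that are
    synonymous; changes creating stops count as nonsynonymous."""
    aa = _CODON_AA[codon]
    syn = 0
    for base in _BASES:
        if base == codon[position]:
            continue
        alt = codon[:position] + base + codon[position + 1 :]
        if _CODON_AA[alt] == aa and _CODON_AA[alt] != "*":
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3."""
    s = sum(_syn_fraction(codon, k) for k in range(3))
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaging equally over all minimal mutational pathways; pathways passing
    through a stop codon are excluded (if all pathways hit stops, the
    exclusion is waived — the raw average is used)."""
    diff_positions = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        s = n = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_cur, aa_nxt = _CODON_AA[current], _CODON_AA[nxt]
            if aa_nxt == "*" and nxt != codon_b:  # stop at an intermediate codon
                through_stop = True
            if aa_cur == aa_nxt and aa_nxt != "*":
                s += 1.0
            else:
                n += 1.0
            current = nxt
        pathways.append((s, n, through_stop))
    valid = [(s, n) for s, n, stop in pathways if not stop]
    if not valid:
        valid = [(s, n) for s, n, _ in pathways]
    s_mean = sum(s for s, _ in valid) / len(valid)
    n_mean = sum(n for _, n in valid) / len(valid)
    return s_mean, n_mean


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = −(3/4)·ln(1 − (4/3)p); requires p < 0.75."""
    if p >= 0.75:
        raise ValidationError(f"proportion of differences p={p:.4f} >= 0.75: saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairCounts:
    """Per-pair Nei–Gojobori counts over a codon set."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def p_s(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites > 0 else 0.0

    @property
    def p_n(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites > 0 else 0.0


def _codons(seq: str) -> list[str]:
    return [seq[k : k + 3] for k in range(0, len(seq), 3)]


def nei_gojobori_pair(
    seq_a: str, seq_b: str, codon_indices: list[int] | None = None
) -> PairCounts:
    """Nei–Gojobori site and difference counts for one sequence pair,
    optionally restricted to ``codon_indices`` (0-based)."""
    codons_a = _codons(seq_a)
    codons_b = _codons(seq_b)
    if len(codons_a) != len(codons_b):
        raise ValidationError("unequal sequence lengths")
    if codon_indices is None:
        codon_indices = list(range(len(codons_a)))
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for k in codon_indices:
        ca, cb = codons_a[k], codons_b[k]
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = _codon_differences(ca, cb)
        s_diffs += sd
        n_diffs += nd
    return PairCounts(s_sites, n_sites, s_diffs, n_diffs)


@dataclass
class SelectionResult:
    d_n: float
    d_s: float
    var_d_n: float
    var_d_s: float
    z: float
    p_value: float
    region: str
    n_pairs: int
    excluded_pairs: int
    codon_indices: list[int]
    allele_subset: list[str]
    # per-pair, per-codon counts (n_pairs × n_codons × 4:
    # syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs) — reused by the
    # codon bootstrap so the expensive pathway enumeration runs once
    _counts: np.ndarray | None = None


def _counts_tensor(
    catalog: AlleleCatalog, alleles: list[str], codon_indices: list[int]
) -> np.ndarray:
    """Per-pair, per-codon Nei–Gojobori counts, shape (pairs, codons, 4)."""
    pairs = list(itertools.combinations(alleles, 2))
    out = np.zeros((len(pairs), len(codon_indices), 4))
    codon_cache = {a: _codons(catalog.trimmed(a)) for a in alleles}
    for pi, (a, b) in enumerate(pairs):
        ca_all, cb_all = codon_cache[a], codon_cache[b]
        for ci, k in enumerate(codon_indices):
            ca, cb = ca_all[k], cb_all[k]
            sa, na = _codon_sites(ca)
            sb, nb = _codon_sites(cb)
            sd_, nd_ = _codon_differences(ca, cb)
            out[pi, ci] = ((sa + sb) / 2.0, (na + nb) / 2.0, sd_, nd_)
    return out


def _pairwise_dnds_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jukes–Cantor d_N, d_S per pair from summed counts; saturated or
    degenerate pairs come back as NaN."""
    sums = counts.sum(axis=1)  # pairs × 4
    with np.errstate(divide="ignore", invalid="ignore"):
        p_s = np.where(sums[:, 0] > 0, sums[:, 2] / sums[:, 0], 0.0)
        p_n = np.where(sums[:, 1] > 0, sums[:, 3] / sums[:, 1], 0.0)
        # the maximum() guards the log for saturated entries, which the
        # where() then replaces by NaN; unsaturated values are untouched
        d_s = np.where(p_s < 0.75, -0.75 * np.log(np.maximum(1.0 - 4.0 * p_s / 3.0, 1e-300)), np.nan)
        d_n = np.where(p_n < 0.75, -0.75 * np.log(np.maximum(1.0 - 4.0 * p_n / 3.0, 1e-300)), np.nan)
    return d_n, d_s


def nei_gojobori_dnds(
    catalog: AlleleCatalog,
    allele_subset: list[str],
    codon_mask: list[int] | None = None,
    region: str = "beta1",
) -> SelectionResult:
    """Population-level d_N and d_S: unweighted means of Jukes–Cantor-corrected
    pairwise rates over all distinct-allele pairs.

    Pairs where p ≥ 0.75 in either class are saturated and excluded (counted
    in ``excluded_pairs``). ``codon_mask`` holds 0-based codon indices (e.g.
    the PBR positions mapped to codons); ``None`` means the whole fragment.
    Variances and the Z-test are filled in by :func:`codon_z_test`.
    """
    alleles = list(dict.fromkeys(allele_subset))
    if len(alleles) < 2:
        raise ValidationError("dN/dS requires >= 2 distinct alleles")
    codon_indices = (
        list(codon_mask)
        if codon_mask is not None
        else list(range(catalog.trimmed_length // 3))
    )
    counts = _counts_tensor(catalog, alleles, codon_indices)
    d_n, d_s = _pairwise_dnds_from_counts(counts)
    usable = ~(np.isnan(d_n) | np.isnan(d_s))
    if not usable.any():
        raise ValidationError("all pairs saturated: no usable dN/dS pairs")
    return SelectionResult(
        d_n=float(d_n[usable].mean()),
        d_s=float(d_s[usable].mean()),
        var_d_n=math.nan,
        var_d_s=math.nan,
        z=math.nan,
        p_value=math.nan,
        region=region,
        n_pairs=int(usable.sum()),
        excluded_pairs=int((~usable).sum()),
        codon_indices=codon_indices,
        allele_subset=alleles,
        _counts=counts,
    )


def codon_z_test(
    result: SelectionResult, boot_reps: int = 1000, seed: int = 0
) -> SelectionResult:
    """One-tailed Z-test for positive selection (d_N > d_S).

    Z = (d_N − d_S) / sqrt(Var(d_N) + Var(d_S)) with variances estimated by
    bootstrap over codon columns; p is the upper normal tail. Zero total
    variance (no polymorphism) yields p = 1 by convention.
    """
    if len(result.codon_indices) < 2:
        raise ValidationError("codon bootstrap requires >= 2 codons")
    if result._counts is None:
        raise ValidationError("SelectionResult lacks its per-codon counts")
    rng = np.random.default_rng(seed)
    n_codons = result._counts.shape[1]
    boot_n, boot_s = [], []
    for _ in range(boot_reps):
        idx = rng.integers(0, n_codons, size=n_codons)
        d_n, d_s = _pairwise_dnds_from_counts(result._counts[:, idx, :])
        usable = ~(np.isnan(d_n) | np.isnan(d_s))
        if not usable.any():
            continue
        boot_n.append(float(d_n[usable].mean()))
        boot_s.append(float(d_s[usable].mean()))
    var_n = float(np.var(boot_n, ddof=1)) if len(boot_n) > 1 else 0.0
    var_s = float(np.var(boot_s, ddof=1)) if len(boot_s) > 1 else 0.0
    denom = math.sqrt(var_n + var_s)
    if denom == 0.0:
        z, p = 0.0, 1.0
    else:
        z = (result.d_n - result.d_s) / denom
        p = float(norm.sf(z))
    result.var_d_n = var_n
    result.var_d_s = var_s
    result.z = z
    result.p_value = p
    return result
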