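"""Within-population allele diversity: frequency spectra with bootstrap CIs,
heterozygosity, Weir–Cockerham F_IS, Hardy–Weinberg exact testing, and
high-frequency-allele summaries.

Statistical conventions
-----------------------
* Allele frequencies are direct counts over 2N gene copies.
* Expected heterozygosity uses Nei's unbiased estimator
  h_e = n/(n−1) · (1 − Σ p_i²) with n = 2N gene copies.
* F_IS is the Weir–Cockerham (1984) single-population estimator
  f̂ = 1 − Σ_a c_a / Σ_a (b_a + c_a), summing per-allele variance components.
* The Hardy–Weinberg "exact" test conditions on the observed allele counts:
  genotype tables are sampled from the null by random re-pairing of the 2N
  observed gene copies, and the p-value is the share of tables whose
  conditional probability is ≤ that of the observed table (Levene's exact
  enumeration is used for the two-allele case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_core import FrequencySpectrum, PopulationSample, ValidationError

__all__ = [
    "HeterozygosityResult",
    "HweResult",
    "allele_frequencies",
    "bootstrap_frequency_ci",
    "heterozygosity",
    "fis_weir_cockerham",
    "hwe_exact_test",
    "two_allele_exact_p",
    "high_frequency_summary",
    "cumulative_frequency",
    "pooled_spectrum",
    "randomized_subsets",
]


def allele_frequencies(sample: PopulationSample) -> FrequencySpectrum:
    """Allele relative frequencies by direct counting over 2N gene copies."""
    return FrequencySpectrum.from_counts(sample.label, sample.allele_counts())


def bootstrap_frequency_ci(
    sample: PopulationSample,
    allele: str,
    level: float = 0.95,
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for one allele's frequency, resampling animals.

    An allele absent from the sample yields the degenerate interval (0, 0);
    a fixed allele yields (1, 1).
    """
    if reps < 100:
        raise ValidationError("bootstrap reps < 100 gives unstable percentiles")
    rng = np.random.default_rng(seed)
    # per-animal dose of the target allele: 0, 1 or 2 copies
    doses = np.array(
        [(a == allele) + (b == allele) for a, b in sample.genotypes], dtype=np.int64
    )
    n = sample.n
    idx = rng.integers(0, n, size=(reps, n))
    boot = doses[idx].sum(axis=1) / (2 * n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


@dataclass(frozen=True)
class HeterozygosityResult:
    h_o: float
    h_e: float
    n_animals: int
    n_gene_copies: int


def heterozygosity(sample: PopulationSample) -> HeterozygosityResult:
    """Observed heterozygosity (share of heterozygous animals) and Nei's
    unbiased expected heterozygosity h_e = n/(n−1)(1 − Σp²), n gene copies."""
    if sample.n < 2:
        raise ValidationError("heterozygosity requires N >= 2 (unbiased correction)")
    het = sum(1 for a, b in sample.genotypes if a != b)
    h_o = het / sample.n
    spectrum = allele_frequencies(sample)
    p = np.array(list(spectrum.frequencies.values()))
    n = sample.gene_copies
    h_e = n / (n - 1) * (1.0 - float(np.sum(p * p)))
    return HeterozygosityResult(h_o=h_o, h_e=h_e, n_animals=sample.n, n_gene_copies=n)


def _wc_components_single(sample: PopulationSample) -> tuple[float, float]:
    """Weir–Cockerham per-allele components (Σc, Σ(b+c)) for one population."""
    n = sample.n
    counts = sample.allele_counts()
    het_count: dict[str, int] = {a: 0 for a in counts}
    for a, b in sample.genotypes:
        if a != b:
            het_count[a] += 1
            het_count[b] += 1
    sum_c = 0.0
    sum_bc = 0.0
    for allele, copies in counts.items():
        p = copies / (2 * n)
        h = het_count[allele] / n  # share of animals heterozygous for this allele
        c = h / 2.0
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        sum_c += c
        sum_bc += b + c
    return sum_c, sum_bc


def fis_weir_cockerham(sample: PopulationSample) -> float:
    """Multi-allelic Weir–Cockerham f (F_IS) for one population.

    Raises for monomorphic samples, where the statistic is undefined (as
    opposed to being 0).
    """
    if sample.n < 2:
        raise ValidationError("F_IS requires N >= 2")
    if len(sample.distinct_alleles()) < 2:
        raise ValidationError("F_IS undefined for a monomorphic sample")
    sum_c, sum_bc = _wc_components_single(sample)
    if sum_bc == 0.0:
        raise ValidationError("F_IS undefined: zero total variance component")
    return 1.0 - sum_c / sum_bc


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact testing


@dataclass(frozen=True)
class HweResult:
    f_is: float
    p_value: float
    mc_iterations: int
    seed: int


def _log_table_probability(pairs: np.ndarray, n_alleles: int) -> float:
    """Log conditional probability (up to a constant in the allele counts) of
    a genotype table: Levene's P ∝ 2^h / Π_ab n_ab!  with h heterozygotes.

    ``pairs`` holds per-animal sorted allele-index pairs, shape (N, 2).
    """
    h = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    codes = pairs[:, 0] * n_alleles + pairs[:, 1]
    _, table_counts = np.unique(codes, return_counts=True)
    return h * math.log(2.0) - float(gammaln(table_counts + 1).sum())


def two_allele_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Levene's exact HWE p-value for two alleles, by full enumeration of
    heterozygote counts conditional on the allele counts.

    The p-value sums the conditional probabilities of all tables no more
    probable than the observed one.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def log_prob(h: int) -> float:
        # h heterozygotes; (n_a - h)/2 AA homozygotes must be integral
        if (n_a - h) % 2 or h > min(n_a, n_b) or (n_a - h) < 0 or (n_b - h) < 0:
            return -math.inf
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return (
            math.lgamma(n + 1)
            - math.lgamma(aa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(bb + 1)
            + h * math.log(2.0)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = [h for h in range(n_a % 2, min(n_a, n_b) + 1, 2)]
    logps = np.array([log_prob(h) for h in hs])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    observed = probs[hs.index(n_ab)]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def hwe_exact_test(
    sample: PopulationSample,
    mc_steps: int = 100_000,
    seed: int = 0,
    force_mc: bool = False,
) -> HweResult:
    """Conditional exact test of Hardy–Weinberg proportions.

    For two alleles the p-value is Levene's full enumeration; otherwise a
    Monte-Carlo sample of ``mc_steps`` genotype tables is drawn by randomly
    re-pairing the observed 2N gene copies (an i.i.d. draw from the
    conditional null), and p is the share of tables with conditional
    probability ≤ the observed table's (within a small numerical tolerance).
    ``force_mc`` routes two-allele samples through the Monte-Carlo sampler
    as well (the two paths must agree within Monte-Carlo error).
    """
    alleles = sample.distinct_alleles()
    if len(alleles) < 2:
        raise ValidationError("HWE test requires >= 2 alleles")
    index = {a: i for i, a in enumerate(alleles)}
    n = sample.n
    pairs = np.array(
        [sorted((index[a], index[b])) for a, b in sample.genotypes], dtype=np.int64
    )
    counts = np.bincount(pairs.ravel(), minlength=len(alleles))

    f_is = fis_weir_cockerham(sample)

    if len(alleles) == 2 and not force_mc:
        n_ab = int(np.sum(pairs[:, 0] != pairs[:, 1]))
        n_aa = int(np.sum((pairs[:, 0] == 0) & (pairs[:, 1] == 0)))
        n_bb = n - n_ab - n_aa
        p = two_allele_exact_p(n_aa, n_ab, n_bb)
        return HweResult(f_is=f_is, p_value=p, mc_iterations=0, seed=seed)

    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(len(alleles)), counts)
    k = len(alleles)
    obs_logp = _log_table_probability(pairs, k)
    hits = 0
    for _ in range(mc_steps):
        perm = rng.permutation(copies).reshape(n, 2)
        perm.sort(axis=1)
        if _log_table_probability(perm, k) <= obs_logp + 1e-9:
            hits += 1
    # add-one correction keeps p in (0, 1] and is the standard MC-exact form
    p = (hits + 1) / (mc_steps + 1)
    return HweResult(f_is=f_is, p_value=p, mc_iterations=mc_steps, seed=seed)


# ---------------------------------------------------------------------------
# frequency summaries


def pooled_spectrum(
    spectra: list[FrequencySpectrum], label: str = "pooled"
) -> FrequencySpectrum:
    """Pool populations by summing reconstructed integer gene-copy counts.

    Counts are reconstructed as round(frequency × gene_copies) per population,
    matching direct counting when the spectra came from data and giving the
    closest integer reconstruction when they came from printed tables.
    """
    counts: dict[str, int] = {}
    for sp in spectra:
        for a, f in sp.frequencies.items():
            counts[a] = counts.get(a, 0) + int(round(f * sp.gene_copies))
    return FrequencySpectrum.from_counts(label, counts)


def high_frequency_summary(
    spectrum: FrequencySpectrum, threshold: float = 0.05
) -> pd.DataFrame:
    """Alleles with frequency strictly above ``threshold``, sorted by name,
    with the cumulative frequency as a percentage at 1 decimal.

    Returns a DataFrame with columns allele / frequency / cumulative_pct; the
    last row's cumulative_pct is the published-style "accounting for X% of
    all alleles" figure.
    """
    rows = [
        (a, f) for a, f in sorted(spectrum.frequencies.items()) if f > threshold
    ]
    df = pd.DataFrame(rows, columns=["allele", "frequency"])
    if len(df):
        df["cumulative_pct"] = (df["frequency"].cumsum() * 100).round(1)
    else:
        df["cumulative_pct"] = pd.Series(dtype=float)
    return df


def cumulative_frequency(spectrum: FrequencySpectrum, alleles: list[str]) -> float:
    """Cumulative percentage (1 decimal) of a named allele set."""
    total = sum(spectrum.frequencies.get(a, 0.0) for a in alleles)
    return round(total * 100, 1)


def randomized_subsets(
    sample: PopulationSample, size: int = 30, n_sets: int = 5, seed: int = 0
) -> list[PopulationSample]:
    """``n_sets`` independent without-replacement subsets of ``size`` animals.

    Used to confirm that heterozygosity estimates do not depend on the
    original sample size.
    """
    if size > sample.n:
        raise ValidationError(
            f"subset size {size} exceeds population size {sample.n}"
        )
    rng = np.random.default_rng(seed)
    subsets = []
    for k in range(n_sets):
        idx = rng.choice(sample.n, size=size, replace=False)
        subsets.append(
            PopulationSample(
                f"{sample.label}#sub{k}", [sample.genotypes[i] for i in idx]
            )
        )
    return subsets
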