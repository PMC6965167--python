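"""Printed allele-frequency summaries for the four newly typed populations.

These are the published high-frequency (>5%) rows of the allele-frequency
table for Cundinamarca, Nariño and Boyacá Normande, pooled Normande, and
Spanish Morucha, as printed (3 decimals), together with each column's sample
size and the published flags marking which alleles the study treated as
high-frequency. They serve as inputs for the desk-scale summary arithmetic:
cumulative high-frequency mass per population and pooled frequencies
reconstructed from integer gene-copy counts.

Note one quirk carried over from the source table: allele *007:01 is flagged
high-frequency in the pooled Normande column although its printed pooled
frequency (0.049, i.e. 11/222) sits just below a strict 5% cut. Summaries
over the flagged set therefore use the flags, while threshold-based
summaries use the strict rule.
"""

from __future__ import annotations

from .io_core import FrequencySpectrum

__all__ = [
    "REGION_N",
    "PRINTED_FREQUENCIES",
    "NORMANDE_HIGH_FREQ_ALLELES",
    "MORUCHA_HIGH_FREQ_COUNTS",
    "MORUCHA_GENE_COPIES",
    "MORUCHA_N_ALLELES",
    "reconstructed_counts",
    "pooled_frequency_from_regions",
    "total_normande_printed_spectrum",
    "morucha_reconstructed_spectrum",
]

# animals per column; gene copies = 2N
REGION_N = {
    "Cundinamarca": 41,
    "Nariño": 30,
    "Boyacá": 40,
    "Total Normande": 111,
    "Morucha": 54,
}

# printed relative frequencies (3 decimals) of the listed alleles per column
PRINTED_FREQUENCIES: dict[str, dict[str, float]] = {
    "BoLA-DRB3*001:01": {
        "Cundinamarca": 0.085, "Nariño": 0.150, "Boyacá": 0.087,
        "Total Normande": 0.103, "Morucha": 0.000,
    },
    "BoLA-DRB3*002:01": {
        "Cundinamarca": 0.073, "Nariño": 0.050, "Boyacá": 0.050,
        "Total Normande": 0.058, "Morucha": 0.000,
    },
    "BoLA-DRB3*003:01": {
        "Cundinamarca": 0.000, "Nariño": 0.033, "Boyacá": 0.000,
        "Total Normande": 0.009, "Morucha": 0.120,
    },
    "BoLA-DRB3*005:01": {
        "Cundinamarca": 0.085, "Nariño": 0.050, "Boyacá": 0.025,
        "Total Normande": 0.054, "Morucha": 0.111,
    },
    "BoLA-DRB3*007:01": {
        "Cundinamarca": 0.073, "Nariño": 0.050, "Boyacá": 0.025,
        "Total Normande": 0.049, "Morucha": 0.009,
    },
    "BoLA-DRB3*010:01": {
        "Cundinamarca": 0.024, "Nariño": 0.016, "Boyacá": 0.137,
        "Total Normande": 0.063, "Morucha": 0.028,
    },
    "BoLA-DRB3*012:01": {
        "Cundinamarca": 0.024, "Nariño": 0.000, "Boyacá": 0.125,
        "Total Normande": 0.054, "Morucha": 0.028,
    },
    "BoLA-DRB3*014:01:01": {
        "Cundinamarca": 0.085, "Nariño": 0.150, "Boyacá": 0.012,
        "Total Normande": 0.076, "Morucha": 0.000,
    },
    "BoLA-DRB3*020:01:01": {
        "Cundinamarca": 0.000, "Nariño": 0.000, "Boyacá": 0.037,
        "Total Normande": 0.013, "Morucha": 0.056,
    },
    "BoLA-DRB3*024:06": {
        "Cundinamarca": 0.073, "Nariño": 0.000, "Boyacá": 0.000,
        "Total Normande": 0.027, "Morucha": 0.000,
    },
    "BoLA-DRB3*048:02": {
        "Cundinamarca": 0.109, "Nariño": 0.200, "Boyacá": 0.012,
        "Total Normande": 0.099, "Morucha": 0.231,
    },
}

# the eight alleles flagged high-frequency for the pooled Normande breed
NORMANDE_HIGH_FREQ_ALLELES = [
    "BoLA-DRB3*001:01",
    "BoLA-DRB3*002:01",
    "BoLA-DRB3*005:01",
    "BoLA-DRB3*007:01",
    "BoLA-DRB3*010:01",
    "BoLA-DRB3*012:01",
    "BoLA-DRB3*014:01:01",
    "BoLA-DRB3*048:02",
]

# Morucha high-frequency alleles as integer gene-copy counts over 2N = 108
MORUCHA_HIGH_FREQ_COUNTS = {
    "BoLA-DRB3*048:02": 25,
    "BoLA-DRB3*003:01": 13,
    "BoLA-DRB3*005:01": 12,
    "BoLA-DRB3*020:01:01": 6,
}
MORUCHA_GENE_COPIES = 108
MORUCHA_N_ALLELES = 29


def reconstructed_counts(allele: str, region: str) -> int:
    """Integer gene-copy count closest to the printed frequency."""
    freq = PRINTED_FREQUENCIES[allele][region]
    return int(round(freq * 2 * REGION_N[region]))


def pooled_frequency_from_regions(allele: str) -> float:
    """Pooled Normande frequency of one allele from the three regional
    columns, via reconstructed integer counts (direct counting, not an
    average of frequencies)."""
    regions = ("Cundinamarca", "Nariño", "Boyacá")
    copies = sum(reconstructed_counts(allele, r) for r in regions)
    total = sum(2 * REGION_N[r] for r in regions)
    return copies / total


def total_normande_printed_spectrum() -> FrequencySpectrum:
    """Pooled Normande spectrum at the printed precision; the unlisted rare
    mass is carried in a single bookkeeping bucket."""
    freqs = {a: col["Total Normande"] for a, col in PRINTED_FREQUENCIES.items()}
    freqs = {a: f for a, f in freqs.items() if f > 0}
    rest = 1.0 - sum(freqs.values())
    freqs["(unlisted rare alleles)"] = rest
    return FrequencySpectrum(
        label="Total Normande", frequencies=freqs, gene_copies=2 * REGION_N["Total Normande"]
    )


def morucha_reconstructed_spectrum() -> FrequencySpectrum:
    """Morucha spectrum from reconstructed integer counts.

    The four published high-frequency alleles carry their exact counts
    (25/13/12/6 of 108 copies); the remaining 52 copies are spread as evenly
    as possible over the remaining 25 of the 29 published alleles, keeping
    every rare allele below the 5% line (≤3 copies each), as in the source
    distribution.
    """
    counts = dict(MORUCHA_HIGH_FREQ_COUNTS)
    remaining_copies = MORUCHA_GENE_COPIES - sum(counts.values())
    n_rare = MORUCHA_N_ALLELES - len(counts)
    base, extra = divmod(remaining_copies, n_rare)
    for i in range(n_rare):
        counts[f"(rare allele {i + 1:02d})"] = base + (1 if i < extra else 0)
    return FrequencySpectrum.from_counts("Morucha", counts)
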