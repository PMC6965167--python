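"""Domain types, readers/writers and dataset validation.

The analysis operates on a single highly multi-allelic locus (MHC class II
DRB3 exon 2). Three inputs define a dataset:

* an allele catalog — named, aligned, in-frame nucleotide sequences, one per
  allele (IPD-MHC style names such as ``BoLA-DRB3*001:01``);
* per-population genotype tables — one row per diploid animal with an
  unordered pair of allele names;
* a peptide-binding-region (PBR) mask — 1-based amino-acid positions on the
  translated β1 fragment that contact bound peptides.

Allele names are opaque strings: the ``*NNN:NN`` nomenclature is never parsed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AlleleCatalog",
    "PopulationSample",
    "PBRMask",
    "FrequencySpectrum",
    "DistanceMatrix",
    "ValidationError",
    "ValidationReport",
    "read_dataset",
    "validate_dataset",
    "write_outputs",
]

_VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """A dataset failed validation; the message names the offending record."""


@dataclass(frozen=True)
class PBRMask:
    """Ordered 1-based amino-acid positions of the peptide-binding region."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        if len(pos) == 0:
            raise ValidationError("PBR mask is empty")
        if any(p < 1 for p in pos):
            raise ValidationError("PBR mask positions are 1-based and must be >= 1")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("PBR mask positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.positions)

    def codon_slice(self, position: int) -> slice:
        """Nucleotide slice (0-based, on the frame-trimmed sequence) of one codon."""
        return slice(3 * (position - 1), 3 * position)


class AlleleCatalog:
    """Named exon-2 nucleotide sequences plus their translated peptides.

    Sequences are trimmed by ``frame_offset`` bases at the 5' end before
    translation; all retained sequences must share one trimmed length (the
    locus is treated as a gap-free alignment) and translate without internal
    stop codons. Sequences violating the stop rule are excluded and recorded
    in :attr:`excluded`.
    """

    def __init__(self, entries: Mapping[str, str], frame_offset: int = 0) -> None:
        if frame_offset not in (0, 1, 2):
            raise ValidationError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
        self.frame_offset = frame_offset
        self.entries: dict[str, str] = {}
        self.peptides: dict[str, str] = {}
        self.excluded: dict[str, str] = {}  # name -> reason

        length: int | None = None
        for name, seq in entries.items():
            seq = str(seq).upper()
            if set(seq) - _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValidationError(f"allele {name!r}: non-ACGT characters {bad}")
            trimmed = seq[frame_offset:]
            if len(trimmed) % 3 != 0:
                raise ValidationError(
                    f"allele {name!r}: trimmed length {len(trimmed)} is not a multiple of 3"
                )
            pep = str(Seq(trimmed).translate())
            if "*" in pep:
                # exon-2 fragments are internal coding sequence: any stop is an error
                self.excluded[name] = "internal stop codon"
                continue
            if length is None:
                length = len(trimmed)
            elif len(trimmed) != length:
                raise ValidationError(
                    f"allele {name!r}: trimmed length {len(trimmed)} != expected {length}"
                )
            self.entries[name] = seq
            self.peptides[name] = pep

        if not self.entries:
            raise ValidationError("allele catalog has no usable sequences")
        self._trimmed_length = length

    @property
    def trimmed_length(self) -> int:
        return int(self._trimmed_length)  # type: ignore[arg-type]

    @property
    def peptide_length(self) -> int:
        return self.trimmed_length // 3

    def trimmed(self, name: str) -> str:
        """Frame-trimmed nucleotide sequence of one allele."""
        return self.entries[name][self.frame_offset :]

    def names(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: object) -> bool:
        return name in self.entries


@dataclass
class PopulationSample:
    """Diploid genotypes for one labeled population.

    Genotype pairs are unordered — sequence-based typing carries no phase —
    and homozygotes are written as two identical names.
    """

    label: str
    genotypes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.genotypes) < 1:
            raise ValidationError(f"population {self.label!r} has no genotypes")
        self.genotypes = [(str(a), str(b)) for a, b in self.genotypes]

    @property
    def n(self) -> int:
        return len(self.genotypes)

    @property
    def gene_copies(self) -> int:
        return 2 * self.n

    def allele_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a, b in self.genotypes:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        return counts

    def distinct_alleles(self) -> list[str]:
        return sorted(self.allele_counts())

    def check_against(self, catalog: AlleleCatalog) -> None:
        for i, (a, b) in enumerate(self.genotypes):
            for name in (a, b):
                if name not in catalog:
                    raise ValidationError(
                        f"population {self.label!r} row {i}: unknown allele {name!r}"
                    )


@dataclass
class FrequencySpectrum:
    """Allele relative frequencies (with CI bounds) in one population."""

    label: str
    frequencies: dict[str, float]
    gene_copies: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"spectrum {self.label!r}: frequencies sum to {total}, not 1"
            )
        for name, (lo, hi) in self.ci.items():
            f = self.frequencies.get(name, 0.0)
            if not (lo - 1e-12 <= f <= hi + 1e-12):
                raise ValidationError(f"spectrum {self.label!r}: CI does not bracket {name!r}")

    def as_series(self, allele_order: Sequence[str] | None = None) -> pd.Series:
        if allele_order is None:
            allele_order = sorted(self.frequencies)
        return pd.Series(
            [self.frequencies.get(a, 0.0) for a in allele_order],
            index=list(allele_order),
            name=self.label,
        )

    @classmethod
    def from_counts(cls, label: str, counts: Mapping[str, int]) -> "FrequencySpectrum":
        total = sum(counts.values())
        if total <= 0:
            raise ValidationError(f"spectrum {label!r}: no gene copies")
        freqs = {a: c / total for a, c in counts.items() if c > 0}
        return cls(label=label, frequencies=freqs, gene_copies=total)


class DistanceMatrix:
    """Labeled symmetric matrix with a zero diagonal.

    F_ST and net-divergence variants may carry small negative off-diagonals,
    so no non-negativity is enforced.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        labels = list(labels)
        if values.shape != (len(labels), len(labels)):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal is not zero")
        # store an exactly symmetric, exactly hollow copy
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.labels = labels
        self.values = values

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# readers


def _read_mask(path: str | Path) -> PBRMask:
    positions = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        positions.append(int(line))
    return PBRMask(tuple(positions))


def read_genotype_table(path: str | Path) -> list[PopulationSample]:
    """Read a ``population<TAB>allele1<TAB>allele2`` table, grouping rows by
    population label while preserving input order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"population", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"genotype table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    samples: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        label = str(row.population)
        if label not in samples:
            samples[label] = []
            order.append(label)
        samples[label].append((str(row.allele1), str(row.allele2)))
    return [PopulationSample(label, samples[label]) for label in order]


def read_dataset(
    fasta_path: str | Path,
    genotype_path: str | Path,
    mask_path: str | Path,
    frame_offset: int = 0,
) -> tuple[AlleleCatalog, list[PopulationSample], PBRMask]:
    """Read and cross-validate the three dataset files.

    Raises :class:`ValidationError` naming the offending record for unknown
    alleles in the genotype table, duplicate FASTA names, or mask positions
    beyond the translated peptide.
    """
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in entries:
            raise ValidationError(f"duplicate FASTA record name {rec.id!r}")
        entries[rec.id] = str(rec.seq)
    catalog = AlleleCatalog(entries, frame_offset=frame_offset)

    samples = read_genotype_table(genotype_path)
    for sample in samples:
        sample.check_against(catalog)

    mask = _read_mask(mask_path)
    if mask.positions[-1] > catalog.peptide_length:
        raise ValidationError(
            f"mask position {mask.positions[-1]} exceeds peptide length "
            f"{catalog.peptide_length}"
        )
    return catalog, samples, mask


# ---------------------------------------------------------------------------
# validation report


@dataclass
class ValidationReport:
    per_population: pd.DataFrame  # columns: population, N, N_a
    excluded: dict[str, str]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "populations": self.per_population.to_dict(orient="records"),
                "excluded": self.excluded,
                "warnings": self.warnings,
            },
            indent=2,
        )


def validate_dataset(
    catalog: AlleleCatalog,
    samples: Iterable[PopulationSample],
    mask: PBRMask | None = None,
) -> ValidationReport:
    """Report per-population sample sizes and allele counts; never fails.

    Monomorphic populations yield a warning (several downstream statistics are
    undefined for them); sequences excluded for internal stops are listed with
    their reason.
    """
    rows = []
    warnings: list[str] = []
    for sample in samples:
        n_a = len(sample.distinct_alleles())
        rows.append({"population": sample.label, "N": sample.n, "N_a": n_a})
        if n_a == 1:
            warnings.append(f"population {sample.label!r} is monomorphic")
    if mask is not None and mask.positions[-1] > catalog.peptide_length:
        warnings.append("mask extends beyond peptide length")
    return ValidationReport(
        per_population=pd.DataFrame(rows, columns=["population", "N", "N_a"]),
        excluded=dict(catalog.excluded),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# writers


def write_outputs(results: Mapping[str, object], out_dir: str | Path) -> dict[str, str]:
    """Write analysis results and return a manifest {key: relative path}.

    DistanceMatrix / DataFrame values go to TSV (12-significant-digit floats,
    lossless on round trip at that precision), tree objects with a ``write``
    or Newick ``__str__`` go to ``.nwk``, everything JSON-serializable is
    collected into ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict[str, object] = {}
    for key, value in results.items():
        if isinstance(value, DistanceMatrix):
            rel = f"{key}.tsv"
            value.to_tsv(out / rel)
            manifest[key] = rel
        elif isinstance(value, pd.DataFrame):
            rel = f"{key}.tsv"
            value.to_csv(out / rel, sep="\t", index=False, float_format="%.17g")
            manifest[key] = rel
        elif hasattr(value, "write") and hasattr(value, "tips"):  # a tree
            rel = f"{key}.nwk"
            value.write(str(out / rel))
            manifest[key] = rel
        else:
            summary[key] = value
    rel = "summary.json"
    (out / rel).write_text(json.dumps(summary, indent=2, default=_jsonify))
    manifest["summary"] = rel
    return manifest


def _jsonify(obj: object) -> object:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")
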