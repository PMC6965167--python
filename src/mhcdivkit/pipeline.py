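"""End-to-end orchestration: validate → diversity → selection → structure →
PBR, from one configuration with a single master seed.

Each stage derives its own seed deterministically from the master seed and
the stage name (CRC-32), so toggling stages on or off never shifts another
stage's random stream. All outputs are written through
:func:`mhcdivkit.io_core.write_outputs`; the returned manifest maps output
keys to files with stage provenance.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allele_diversity as ad
from . import pbr as pbr_mod
from . import population_structure as ps
from . import sequence_diversity as sd
from .io_core import (
    AlleleCatalog,
    PBRMask,
    PopulationSample,
    ValidationError,
    read_dataset,
    validate_dataset,
    write_outputs,
)
from .synthetic import SimulationSpec, simulate_study

__all__ = ["RunConfig", "run_pipeline", "render_report", "stage_seed"]

logger = logging.getLogger("mhcdivkit")

ALL_STAGES = ("validate", "diversity", "selection", "structure", "pbr")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a simulation spec, never both."""

    fasta: str | None = None
    genotypes: str | None = None
    mask: str | None = None
    simulation: SimulationSpec | None = None
    frame_offset: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    min_freq: float = 0.05
    high_freq_threshold: float = 0.05
    subset_size: int = 30
    n_sets: int = 5
    boot_reps: int = 10_000
    mc_steps: int = 100_000
    z_boot_reps: int = 1000
    master_seed: int = 0
    out_dir: str = "results/run"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        has_files = all(x is not None for x in (self.fasta, self.genotypes, self.mask))
        if has_files == (self.simulation is not None):
            raise ValidationError(
                "config must provide exactly one of file inputs or a simulation spec"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")


def _load(config: RunConfig) -> tuple[AlleleCatalog, list[PopulationSample], PBRMask]:
    if config.simulation is not None:
        catalog, samples = simulate_study(config.simulation)
        return catalog, samples, config.simulation.pbr_mask
    return read_dataset(config.fasta, config.genotypes, config.mask, config.frame_offset)


def _diversity_stage(config, catalog, samples, mask) -> dict:
    seed = stage_seed(config.master_seed, "diversity")
    rows = []
    for i, sample in enumerate(samples):
        het = ad.heterozygosity(sample)
        try:
            hwe = ad.hwe_exact_test(sample, mc_steps=config.mc_steps, seed=seed + i)
            f_is, p = hwe.f_is, hwe.p_value
        except ValidationError:
            f_is, p = np.nan, np.nan
        rows.append(
            {
                "population": sample.label,
                "N": sample.n,
                "N_a": len(sample.distinct_alleles()),
                "h_o": het.h_o,
                "h_e": het.h_e,
                "F_IS": f_is,
                "HWE_p": p,
            }
        )
    spectra = [ad.allele_frequencies(s) for s in samples]
    freq_table = pd.concat(
        [sp.as_series(sorted({a for x in spectra for a in x.frequencies})) for sp in spectra],
        axis=1,
    ).reset_index(names="allele")
    hf = []
    for sp in spectra:
        tbl = ad.high_frequency_summary(sp, threshold=config.high_freq_threshold)
        tbl.insert(0, "population", sp.label)
        hf.append(tbl)
    return {
        "diversity_table": pd.DataFrame(rows),
        "allele_frequencies": freq_table,
        "high_frequency_summary": pd.concat(hf, ignore_index=True),
    }


def _selection_stage(config, catalog, samples, mask) -> dict:
    seed = stage_seed(config.master_seed, "selection")
    pbr_codons = [p - 1 for p in mask.positions]
    rows = []
    for i, sample in enumerate(samples):
        alleles = sample.distinct_alleles()
        s_count = sd.segregating_sites(catalog, alleles)
        pi = sd.nucleotide_diversity(sample, catalog)
        row = {"population": sample.label, "S": s_count, "pi": pi}
        for region, codon_mask in (("beta1", None), ("PBR", pbr_codons)):
            try:
                res = sd.nei_gojobori_dnds(catalog, alleles, codon_mask, region=region)
                res = sd.codon_z_test(res, boot_reps=config.z_boot_reps, seed=seed + i)
                row[f"dN_{region}"] = res.d_n
                row[f"dS_{region}"] = res.d_s
                row[f"Z_{region}"] = res.z
                row[f"p_{region}"] = res.p_value
            except ValidationError as exc:
                logger.warning("selection %s/%s: %s", sample.label, region, exc)
                for col in ("dN", "dS", "Z", "p"):
                    row[f"{col}_{region}"] = np.nan
        rows.append(row)
    net = np.zeros((len(samples), len(samples)))
    net_seq = np.zeros_like(net)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            net[i, j] = net[j, i] = sd.net_divergence(samples[i], samples[j], catalog)
            net_seq[i, j] = net_seq[j, i] = net[i, j] * catalog.trimmed_length
    labels = [s.label for s in samples]
    from .io_core import DistanceMatrix

    return {
        "selection_table": pd.DataFrame(rows),
        "net_divergence_per_site": DistanceMatrix(labels, net),
        "net_divergence_per_sequence": DistanceMatrix(labels, net_seq),
    }


def _structure_stage(config, catalog, samples, mask) -> dict:
    seed = stage_seed(config.master_seed, "structure")
    out: dict = {}
    structure = ps.wc_fst(samples)
    out["overall_fst"] = structure.overall_fst
    out["pairwise_fst"] = structure.pairwise_fst
    out["da_matrix"] = structure.da
    spectra = [ad.allele_frequencies(s) for s in samples]
    if len(samples) >= 3:
        tree, support = ps.bootstrap_support(samples, reps=config.boot_reps, seed=seed)
        out["nj_tree"] = tree
        out["nj_supports"] = {" | ".join(sorted(k)): v for k, v in support.items()}
        mds = ps.mds_from_distances(structure.da, k=2)
        out["mds_coordinates"] = pd.DataFrame(
            mds.coordinates, columns=["dim1", "dim2"]
        ).assign(population=mds.labels)[["population", "dim1", "dim2"]]
        out["mds_rsq"] = mds.rsq
    pca = ps.pca_frequencies(spectra)
    out["pca_scores"] = pd.DataFrame(
        pca.coordinates,
        columns=[f"PC{i+1}" for i in range(pca.coordinates.shape[1])],
    ).assign(population=pca.labels)
    out["pca_explained_variance"] = list(map(float, pca.explained_variance))
    out["pca_loadings"] = pca.loadings.reset_index(names="allele")
    return out


def _pbr_stage(config, catalog, samples, mask) -> dict:
    seed = stage_seed(config.master_seed, "pbr")
    pbr_strings = pbr_mod.translate_and_extract_pbr(catalog, mask)
    rows = []
    profiles = []
    for sample in samples:
        sim = pbr_mod.population_pbr_similarity(sample, catalog, mask)
        rows.append(
            {
                "population": sample.label,
                "mean_similarity": sim.mean_similarity,
                "sd_similarity": sim.sd_similarity,
            }
        )
        spectrum = ad.allele_frequencies(sample)
        try:
            profiles.append(
                pbr_mod.pbr_profile(spectrum, pbr_strings, mask, min_freq=config.min_freq)
            )
        except ValidationError as exc:
            logger.warning("pbr profile %s: %s", sample.label, exc)
    out: dict = {"pbr_similarity": pd.DataFrame(rows)}
    if len(profiles) >= 2:
        pcc, mds, global_pcc = pbr_mod.covariation_analysis(profiles)
        from .io_core import DistanceMatrix

        out["pbr_pcc"] = pcc.reset_index(names="population")
        out["pbr_global_pcc"] = global_pcc
        out["pbr_mds_coordinates"] = pd.DataFrame(
            mds.coordinates, columns=["dim1", "dim2"]
        ).assign(population=mds.labels)[["population", "dim1", "dim2"]]
    distinct, total, groups = pbr_mod.count_distinct_pbr(catalog, mask)
    out["pbr_distinct"] = {
        "distinct": distinct,
        "total_alleles": total,
        "duplicate_groups": groups,
    }
    if all(s.n >= config.subset_size for s in samples) and len(samples) >= 2:
        anova = pbr_mod.randomized_similarity_anova(
            samples, catalog, mask,
            subset_size=config.subset_size, n_sets=config.n_sets, seed=seed,
        )
        out["pbr_anova"] = pd.DataFrame(
            [{"set": r["set"], "F": r["F"], "p": r["p"]} for r in anova]
        )
        out["pbr_anova_pairwise"] = pd.concat(
            [r["pairwise"].assign(set=r["set"]) for r in anova], ignore_index=True
        )
    else:
        logger.warning("ANOVA skipped: some population smaller than subset size")
    return out


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured stages in order and write all outputs.

    Returns the manifest {output key: relative file path}. Any stage error
    aborts with a stage-named message; outputs of completed stages are
    retained on disk and listed in a partial manifest file.
    """
    catalog, samples, mask = _load(config)
    results: dict = {}
    provenance: dict[str, str] = {}
    stage_fns = {
        "validate": lambda: {
            "validation": validate_dataset(catalog, samples, mask).per_population,
            "validation_excluded": dict(catalog.excluded),
        },
        "diversity": lambda: _diversity_stage(config, catalog, samples, mask),
        "selection": lambda: _selection_stage(config, catalog, samples, mask),
        "structure": lambda: _structure_stage(config, catalog, samples, mask),
        "pbr": lambda: _pbr_stage(config, catalog, samples, mask),
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s (seed %d)", stage, stage_seed(config.master_seed, stage))
        try:
            stage_out = stage_fns[stage]()
        except Exception as exc:
            # flush what we have, then re-raise with the stage name
            manifest = write_outputs(results, config.out_dir)
            _write_manifest(config, manifest, provenance, partial=stage)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for key in stage_out:
            provenance[key] = stage
        results.update(stage_out)
    manifest = write_outputs(results, config.out_dir)
    _write_manifest(config, manifest, provenance, partial=None)
    return manifest


def _write_manifest(config, manifest, provenance, partial):
    record = {
        "master_seed": config.master_seed,
        "stages": list(config.stages),
        "stage_seeds": {s: stage_seed(config.master_seed, s) for s in config.stages},
        "parameters": {
            "min_freq": config.min_freq,
            "high_freq_threshold": config.high_freq_threshold,
            "subset_size": config.subset_size,
            "n_sets": config.n_sets,
            "boot_reps": config.boot_reps,
            "mc_steps": config.mc_steps,
            "z_boot_reps": config.z_boot_reps,
        },
        "outputs": {k: {"path": v, "stage": provenance.get(k)} for k, v in manifest.items()},
        "aborted_at_stage": partial,
    }
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    (Path(config.out_dir) / "manifest.json").write_text(json.dumps(record, indent=2))


def render_report(out_dir: str | Path) -> str:
    """Single markdown summary assembled from a finished run's output files.

    Sections whose stage outputs are missing are marked absent rather than
    failing. Numbers are re-read from the TSVs so the report always matches
    them.
    """
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines = ["# Run report", ""]

    def table_or_none(name: str) -> pd.DataFrame | None:
        path = out / f"{name}.tsv"
        return pd.read_csv(path, sep="\t") if path.exists() else None

    div = table_or_none("diversity_table")
    lines.append("## Diversity (per population)")
    if div is not None:
        lines.append(div.to_markdown(index=False, floatfmt=".6g"))
    else:
        lines.append("_absent_")
    lines.append("")

    sel = table_or_none("selection_table")
    sim = table_or_none("pbr_similarity")
    lines.append("## Sequence diversity and selection")
    if sel is not None:
        if sim is not None:
            sel = sel.merge(sim, on="population", how="left")
        lines.append(sel.to_markdown(index=False, floatfmt=".6g"))
    else:
        lines.append("_absent_")
    lines.append("")

    lines.append("## PBR covariation")
    summary_path = out / "summary.json"
    summary = json.loads(summary_path.read_text()) if summary_path.exists() else {}
    if "pbr_global_pcc" in summary:
        lines.append(f"Global mean PCC between population PBR vectors: "
                     f"{summary['pbr_global_pcc']:.6g}")
        if "mds_rsq" in summary:
            lines.append(f"MDS RSQ (D_A embedding): {summary['mds_rsq']:.6g}")
    else:
        lines.append("_absent_")
    lines.append("")
    lines.append(f"Master seed: {manifest['master_seed']}; stages: "
                 f"{', '.join(manifest['stages'])}.")
    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
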