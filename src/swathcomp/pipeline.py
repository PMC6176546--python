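"""End-to-end workflows: cross-species comparison and technical-replicate QC.

The comparison workflow runs: in-silico digestion of every species database
-> conserved-peptide index -> confidence/ambiguity/conservation filters ->
total-peak-area normalization -> peptide-to-protein rollup -> cyclic loess
-> moderated t + BH-FDR -> significance calls -> optional gene-set
enrichment -> QC (per-species CoV, pairwise R^2, sample dendrogram). It
writes every result table plus a machine-readable manifest with the
parameters, input checksums and the precursor counts surviving each filter.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as sio
from .digestion import (
    DigestParams,
    IbaqParams,
    build_conserved_index,
    read_fasta_proteome,
)
from .filtering import (
    Design,
    FilterPolicy,
    grouped_confidence_filter,
    remove_ambiguous,
    restrict_to_conserved,
    strict_filter,
)
from .quantify import (
    AbundanceMatrix,
    NormalizationParams,
    compute_cov,
    cyclic_loess_normalize,
    pairwise_r2,
    report_to_peptide_matrix,
    rollup_to_proteins,
    total_area_normalize,
)
from .stats import (
    EnrichmentResult,
    ModeratedTestModel,
    call_significant,
    enrichment_chisq,
    fit_moderated_t,
    hierarchical_cluster,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and parameters of the comparison workflow."""

    proteome_fastas: dict[str, str | Path]
    report_path: str | Path
    design_path: str | Path
    contrast: tuple[str, str]
    gene_set_path: str | Path | None = None
    output_dir: str | Path = "swathcomp_out"
    digest_params: DigestParams = field(default_factory=DigestParams)
    ibaq_params: IbaqParams = field(default_factory=IbaqParams)
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    norm_params: NormalizationParams = field(default_factory=NormalizationParams)
    alpha: float = 0.005

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = sio.load_yaml_config(path)
        base = Path(path).parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        kwargs: dict = {
            "proteome_fastas": {
                sp: _resolve(p) for sp, p in raw["proteome_fastas"].items()
            },
            "report_path": _resolve(raw["report"]),
            "design_path": _resolve(raw["design"]),
            "contrast": tuple(raw["contrast"]),
            "output_dir": _resolve(raw.get("output_dir", "swathcomp_out")),
            "alpha": float(raw.get("alpha", 0.005)),
        }
        if raw.get("gene_set"):
            kwargs["gene_set_path"] = _resolve(raw["gene_set"])
        for key, klass in (
            ("digest_params", DigestParams),
            ("ibaq_params", IbaqParams),
            ("filter_policy", FilterPolicy),
            ("norm_params", NormalizationParams),
        ):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything the comparison workflow computes."""

    de_table: pd.DataFrame
    model: ModeratedTestModel
    counts: dict[str, int]
    protein_matrix: AbundanceMatrix  # loess-normalized, linear scale
    qc: dict
    enrichment: EnrichmentResult | None
    call_counts: dict[str, int]
    manifest: dict


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full cross-species comparison workflow."""
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    report = _stage("read_report")(sio.read_quant_report, config.report_path)
    design = _stage("read_design")(sio.read_design, config.design_path, config.contrast)
    proteomes = [
        _stage("read_proteomes")(read_fasta_proteome, path, sp)
        for sp, path in config.proteome_fastas.items()
    ]
    index = _stage("conserved_index")(build_conserved_index, proteomes, config.digest_params)

    counts: dict[str, int] = {}
    n_samples = design.table.shape[0]
    counts["precursors_input"] = len(report) // max(n_samples, 1)
    filtered = _stage("grouped_confidence_filter")(
        grouped_confidence_filter, report, design, config.filter_policy
    )
    counts["precursors_confident"] = filtered[["sequence", "modifications", "charge"]].drop_duplicates().shape[0]
    filtered = _stage("remove_ambiguous")(remove_ambiguous, filtered)
    counts["precursors_unambiguous"] = filtered[["sequence", "modifications", "charge"]].drop_duplicates().shape[0]
    species_subset = sorted(
        set(design.species_in_group(config.contrast[0]))
        | set(design.species_in_group(config.contrast[1]))
    )
    filtered = _stage("restrict_to_conserved")(
        restrict_to_conserved, filtered, index, species_subset
    )
    counts["precursors_conserved"] = filtered[["sequence", "modifications", "charge"]].drop_duplicates().shape[0]

    peptide_matrix, gene_map = _stage("peptide_matrix")(report_to_peptide_matrix, filtered)
    peptide_matrix = _stage("total_area_normalize")(total_area_normalize, peptide_matrix)
    protein_matrix = _stage("rollup")(rollup_to_proteins, peptide_matrix, gene_map)
    counts["proteins_quantified"] = protein_matrix.data.shape[0]
    protein_matrix = _stage("cyclic_loess")(
        cyclic_loess_normalize, protein_matrix, config.norm_params
    )

    log_matrix = protein_matrix.to_log2()
    de_table, model = _stage("moderated_t")(fit_moderated_t, log_matrix, design)
    de_table, call_counts = _stage("significance_calls")(
        call_significant, de_table, config.alpha
    )

    enrichment = None
    if config.gene_set_path is not None:
        gene_set = _stage("read_gene_set")(sio.read_gene_set, config.gene_set_path)
        de_flags = de_table.set_index("gene")["significant"]
        de_flags.index = de_flags.index.str.upper()
        overlap = int(de_flags.index.isin(gene_set).sum())
        logger.info("gene set: %d of %d members quantified", overlap, len(gene_set))
        enrichment = _stage("enrichment")(enrichment_chisq, de_flags, gene_set)

    qc = _stage("qc")(_qc_report, protein_matrix, design)

    manifest = {
        "swathcomp_version": __version__,
        "parameters": {
            "digest_params": dataclasses.asdict(config.digest_params),
            "ibaq_params": dataclasses.asdict(config.ibaq_params),
            "filter_policy": dataclasses.asdict(config.filter_policy),
            "norm_params": dataclasses.asdict(config.norm_params),
            "alpha": config.alpha,
            "contrast": list(config.contrast),
        },
        "inputs": {
            "report": {"path": str(config.report_path), "sha256": sio.sha256_file(config.report_path)},
            "design": {"path": str(config.design_path), "sha256": sio.sha256_file(config.design_path)},
            "proteomes": {
                sp: {"path": str(p), "sha256": sio.sha256_file(p)}
                for sp, p in config.proteome_fastas.items()
            },
        },
        "counts": counts,
        "calls": call_counts,
    }

    result = PipelineResult(
        de_table=de_table,
        model=model,
        counts=counts,
        protein_matrix=protein_matrix,
        qc=qc,
        enrichment=enrichment,
        call_counts=call_counts,
        manifest=manifest,
    )
    if write_outputs:
        _write_outputs(result, outdir)
    return result


def _qc_report(protein_matrix: AbundanceMatrix, design: Design) -> dict:
    groups = {sp: design.samples_of_species(sp) for sp in design.species}
    groups = {sp: samples for sp, samples in groups.items() if len(samples) >= 2}
    cov = compute_cov(protein_matrix, groups)
    r2 = pairwise_r2(protein_matrix)
    clustering = hierarchical_cluster(protein_matrix)
    return {
        "median_cov_percent": {sp: float(cov[sp].median()) for sp in cov.columns},
        "pairwise_r2": r2.round(6).to_dict(),
        "min_within_species_r2": {
            sp: float(
                min(
                    r2.loc[s1, s2]
                    for i, s1 in enumerate(samples)
                    for s2 in samples[i + 1 :]
                )
            )
            for sp, samples in groups.items()
        },
        "dendrogram_newick": clustering.newick,
    }


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    result.de_table.to_csv(outdir / "differential_abundance.tsv", sep="\t", index=False)
    sio.write_matrix(result.protein_matrix, outdir / "protein_matrix.tsv")
    sio.write_json(result.qc, outdir / "qc.json")
    if result.enrichment is not None:
        sio.write_json(result.enrichment.to_dict(), outdir / "enrichment.json")
    with open(outdir / "dendrogram.nwk", "w", encoding="utf-8") as handle:
        handle.write(result.qc["dendrogram_newick"] + "\n")
    sio.write_json(result.manifest, outdir / "manifest.json")


def quantify_report(
    report: pd.DataFrame, norm_params: NormalizationParams = NormalizationParams()
) -> tuple[AbundanceMatrix, pd.Series]:
    """Report -> normalized protein matrix: total-area rescale at the peptide
    level, rollup by gene, then cyclic loess. Returns the linear-scale
    protein matrix and the peptide -> gene map used."""
    peptide_matrix, gene_map = report_to_peptide_matrix(report)
    peptide_matrix = total_area_normalize(peptide_matrix)
    protein_matrix = rollup_to_proteins(peptide_matrix, gene_map)
    return cyclic_loess_normalize(protein_matrix, norm_params), gene_map


# ---------------------------------------------------------------------------
# technical-replicate QC workflow
# ---------------------------------------------------------------------------


def technical_replicate_qc(
    report: pd.DataFrame,
    q_threshold: float = 1e-3,
    norm_params: NormalizationParams = NormalizationParams(),
) -> dict:
    """Strict-confidence QC of repeated measurements of one preparation.

    Applies the any-sample Q-value rule, total-area normalization, rollup
    and loess, then reports median peptide and protein CoV plus the minimum
    pairwise R^2.
    """
    filtered = strict_filter(report, q_threshold)
    filtered = remove_ambiguous(filtered)
    peptide_matrix, gene_map = report_to_peptide_matrix(filtered)
    peptide_matrix = total_area_normalize(peptide_matrix)
    protein_matrix = rollup_to_proteins(peptide_matrix, gene_map)
    protein_matrix = cyclic_loess_normalize(protein_matrix, norm_params)

    samples = peptide_matrix.samples
    peptide_cov = compute_cov(peptide_matrix, {"replicates": samples})["replicates"]
    protein_cov = compute_cov(protein_matrix, {"replicates": samples})["replicates"]
    r2 = pairwise_r2(protein_matrix)
    off_diag = [
        r2.iloc[i, j] for i in range(len(samples)) for j in range(len(samples)) if i < j
    ]
    return {
        "n_peptides": int(peptide_matrix.data.shape[0]),
        "n_proteins": int(protein_matrix.data.shape[0]),
        "median_peptide_cov_percent": float(peptide_cov.median()),
        "median_protein_cov_percent": float(protein_cov.median()),
        "min_pairwise_r2": float(min(off_diag)),
    }
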