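"""Peptide-to-protein rollup, normalization, iBAQ and QC statistics.

Protein abundance is the sum of the normalized peak areas of the protein's
peptides. Two normalization stages are applied in the comparison workflow:
a total-peak-area rescaling of each run at the peptide level (emulating the
across-run normalization of the extraction software), and cyclic loess on
the protein matrix to remove residual intensity-dependent bias between
samples.

The cyclic loess "fast" variant normalizes each sample against the mean log
profile: per iteration and sample j, M = log2(x_j) - rowmean(log2 X) is
regressed (loess, locally weighted regression) on the mean profile A =
rowmean(log2 X) and the fitted trend subtracted from log2(x_j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class AbundanceMatrix:
    """Rectangular features x samples abundance matrix with a scale flag.

    ``data`` holds features (precursors or genes) as rows, samples as
    columns; no missing cells. Linear-scale values must be >= 0; switching a
    matrix with zeros to log scale raises, naming the offending cell.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"scale must be {LINEAR!r} or {LOG2!r}")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            raise ValueError("abundance matrix contains missing cells")
        if self.scale == LINEAR and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative linear-scale value at ({self.data.index[i]}, {self.data.columns[j]})"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    def to_log2(self) -> "AbundanceMatrix":
        if self.scale == LOG2:
            return self
        values = self.data.to_numpy()
        if (values <= 0).any():
            i, j = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"cannot log-transform non-positive value at "
                f"({self.data.index[i]}, {self.data.columns[j]})"
            )
        return AbundanceMatrix(np.log2(self.data), scale=LOG2)

    def to_linear(self) -> "AbundanceMatrix":
        if self.scale == LINEAR:
            return self
        return AbundanceMatrix(np.exp2(self.data), scale=LINEAR)


@dataclass(frozen=True)
class NormalizationParams:
    """Cyclic-loess settings: 10 fast iterations at span 0.7, log base 2."""

    method: str = "cyclic_loess_fast"
    iterations: int = 10
    loess_span: float = 0.7
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must be in (0, 1]")


def report_to_peptide_matrix(
    report: pd.DataFrame,
) -> tuple[AbundanceMatrix, pd.Series]:
    """Pivot a long report to a precursor x sample intensity matrix.

    Returns the matrix plus a precursor -> gene map (requires unambiguous
    gene assignment, i.e. run :func:`swathcomp.filtering.remove_ambiguous`
    first).
    """
    from .filtering import PRECURSOR_COLS

    wide = report.pivot(index=PRECURSOR_COLS, columns="sample_id", values="intensity")
    if wide.isna().any().any():
        raise ValueError("report does not form a complete precursor x sample matrix")
    # keep the sample order of first appearance in the report
    sample_order = list(dict.fromkeys(report["sample_id"]))
    wide = wide[sample_order]
    gene_map = report.groupby(PRECURSOR_COLS, sort=False)["genes"].first()
    if gene_map.astype(str).str.contains(";").any():
        raise ValueError("ambiguous gene assignments present; remove them before rollup")
    gene_map = gene_map.reindex(wide.index)
    return AbundanceMatrix(wide, scale=LINEAR), gene_map


def total_area_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Rescale each sample so all column totals equal the mean original
    total; relative intensities within a sample are unchanged."""
    if matrix.scale != LINEAR:
        raise ValueError("total-area normalization operates on linear-scale values")
    totals = matrix.data.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0][0]
        raise ValueError(f"sample {zero!r} has zero total intensity")
    factors = totals.mean() / totals
    logger.info(
        "total_area_normalize: scale factors in [%.4g, %.4g]", factors.min(), factors.max()
    )
    return AbundanceMatrix(matrix.data * factors, scale=LINEAR)


def rollup_to_proteins(matrix: AbundanceMatrix, gene_map: pd.Series) -> AbundanceMatrix:
    """Sum peptide intensities per gene (linear scale)."""
    if matrix.scale != LINEAR:
        raise ValueError("rollup operates on linear-scale values")
    genes = gene_map.reindex(matrix.data.index)
    if genes.isna().any():
        missing = matrix.data.index[genes.isna()][0]
        raise ValueError(f"peptide {missing} has no gene mapping")
    protein = matrix.data.groupby(genes.to_numpy()).sum()
    protein.index.name = "gene"
    return AbundanceMatrix(protein, scale=LINEAR)


def cyclic_loess_normalize(
    matrix: AbundanceMatrix, params: NormalizationParams = NormalizationParams()
) -> AbundanceMatrix:
    """Fast cyclic loess: normalize each sample against the mean log profile.

    Accepts linear (strictly positive) or log2 input; the returned matrix is
    on the input's scale.
    """
    was_linear = matrix.scale == LINEAR
    log_mat = matrix.to_log2()
    x = log_mat.data.to_numpy().copy()
    n_samples = x.shape[1]
    for iteration in range(params.iterations):
        reference = x.mean(axis=1)
        medians = []
        delta = 0.01 * (reference.max() - reference.min())
        for j in range(n_samples):
            m = x[:, j] - reference
            a = reference
            fitted = lowess(
                m, a, frac=params.loess_span, it=3, delta=delta, return_sorted=False
            )
            x[:, j] -= fitted
            medians.append(float(np.median(np.abs(m))))
        logger.debug(
            "cyclic loess iteration %d: median |M| per sample %s",
            iteration + 1,
            np.round(medians, 4),
        )
    out = AbundanceMatrix(
        pd.DataFrame(x, index=log_mat.data.index, columns=log_mat.data.columns), scale=LOG2
    )
    return out.to_linear() if was_linear else out


def compute_ibaq(protein_intensity: float, observable_count: int) -> float | None:
    """iBAQ = protein intensity / number of theoretically observable tryptic
    peptides. Returns ``None`` (iBAQ undefined) when the count is zero."""
    if protein_intensity < 0:
        raise ValueError("protein intensity must be >= 0")
    if observable_count == 0:
        return None
    return protein_intensity / observable_count


def ibaq_table(intensities: pd.Series, observable_counts: pd.Series) -> pd.Series:
    """Vectorized iBAQ; proteins with zero observable peptides get NaN and a
    logged warning."""
    counts = observable_counts.reindex(intensities.index)
    undefined = counts.isna() | (counts == 0)
    if undefined.any():
        logger.warning(
            "iBAQ undefined for %d proteins with no observable peptides", int(undefined.sum())
        )
    out = intensities / counts.where(~undefined)
    out.name = "ibaq"
    return out


def merge_groups_by_gene(groups: pd.DataFrame) -> pd.Series:
    """Collapse protein groups to genes: groups spanning several genes are
    dropped (and logged); same-gene groups are summed.

    ``groups`` needs columns ``genes`` (semicolon-separated symbols) and
    ``ibaq``.
    """
    genes = groups["genes"].astype(str).str.split(";").map(lambda g: sorted({x for x in g if x}))
    multi = genes.map(len) > 1
    if multi.any():
        logger.info("dropping %d ambiguous protein groups spanning several genes", int(multi.sum()))
    kept = groups[~multi].copy()
    kept["gene"] = genes[~multi].map(lambda g: g[0])
    return kept.groupby("gene")["ibaq"].sum()


def compute_cov(matrix: AbundanceMatrix, groups: Mapping[str, list[str]]) -> pd.DataFrame:
    """Per-feature coefficient of variation (unbiased SD / mean, in %) within
    each sample group (typically: the samples of one species)."""
    if matrix.scale != LINEAR:
        raise ValueError("CoV is computed on linear-scale values")
    out = {}
    for name, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {name!r} needs >= 2 samples for a CoV")
        sub = matrix.data[samples]
        out[name] = sub.std(axis=1, ddof=1) / sub.mean(axis=1) * 100.0
    return pd.DataFrame(out)


def pairwise_r2(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Squared Pearson correlation of log2 abundances for every sample pair."""
    if len(matrix.data) < 2:
        raise ValueError("need >= 2 features for correlations")
    log_mat = matrix.to_log2()
    r = np.corrcoef(log_mat.data.to_numpy(), rowvar=False)
    r2 = pd.DataFrame(r * r, index=log_mat.samples, columns=log_mat.samples)
    np.fill_diagonal(r2.values, 1.0)
    return r2


def scale_relative(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Scale each feature by its total over all samples (row-stochastic),
    revealing relative enrichment between samples."""
    if matrix.scale != LINEAR:
        raise ValueError("relative scaling operates on linear-scale values")
    totals = matrix.data.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"feature {bad} has no positive values")
    return matrix.data.div(totals, axis=0)
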