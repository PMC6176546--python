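"""Peptide confidence, ambiguity and conservation filters.

A precursor — the peptide observation unit (sequence, modifications, charge);
the same sequence with different modifications or charge counts as a distinct
peptide — survives into the quantitative comparison only if it is

* quantified with high confidence (Q-value rules below),
* mapped unambiguously to a single gene in the spectral library, and
* sequence-conserved in every species of the comparison.

Two confidence rules are provided. The *strict* rule (technical-replicate
QC) removes a precursor if its Q-value exceeds the threshold in any sample.
The *grouped* rule (cross-species comparison) requires Q <= threshold over
all samples of a group while allowing a configurable number of outlier
samples within each species, and keeps a precursor if it qualifies in either
group. All samples' rows are retained for kept precursors: quantification
uses every sample.

Targeted extraction yields complete matrices, so a precursor present in some
but not all samples indicates corrupt input and raises rather than being
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .digestion import ConservedIndex

logger = logging.getLogger(__name__)

PRECURSOR_COLS = ["sequence", "modifications", "charge"]


@dataclass
class Design:
    """Sample-to-species and species-to-group assignment plus the contrast."""

    table: pd.DataFrame  # columns: sample_id, species, group
    contrast: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "species", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in design: {sorted(set(dupes))}")
        if self.contrast is not None:
            groups = set(self.table["group"])
            for g in self.contrast:
                if g not in groups:
                    raise ValueError(f"contrast group {g!r} not present in design")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table["species"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def species_in_group(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        return list(dict.fromkeys(sub["species"]))

    def samples_of_species(self, species: str) -> list[str]:
        return list(self.table.loc[self.table["species"] == species, "sample_id"])

    def samples_of_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])


@dataclass(frozen=True)
class FilterPolicy:
    """Confidence thresholds of the two Q-value rules.

    ``q_threshold_strict`` (1e-3) is the any-sample rule used for technical
    replicates; ``q_threshold_grouped`` (1e-4) the per-group rule for species
    comparisons, allowing ``outliers_allowed_per_species`` high-Q samples
    within each species of a group.
    """

    q_threshold_strict: float = 1e-3
    q_threshold_grouped: float = 1e-4
    outliers_allowed_per_species: int = 1
    group_mode: str = "either"

    def __post_init__(self) -> None:
        for name in ("q_threshold_strict", "q_threshold_grouped"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.outliers_allowed_per_species < 0:
            raise ValueError("outliers_allowed_per_species must be >= 0")
        if self.group_mode not in ("either", "both"):
            raise ValueError("group_mode must be 'either' or 'both'")


def _check_complete(report: pd.DataFrame) -> int:
    """Verify every precursor is observed exactly once in every sample."""
    n_samples = report["sample_id"].nunique()
    sizes = report.groupby(PRECURSOR_COLS, sort=False).size()
    bad = sizes[sizes != n_samples]
    if len(bad):
        key = bad.index[0]
        raise ValueError(
            f"precursor {key} observed in {bad.iloc[0]} of {n_samples} samples; "
            "targeted extraction requires complete matrices"
        )
    return n_samples


def strict_filter(report: pd.DataFrame, q_threshold: float = 1e-3) -> pd.DataFrame:
    """Keep precursors whose Q-value is <= ``q_threshold`` in every sample."""
    if report.empty:
        raise ValueError("empty report")
    _check_complete(report)
    worst = report.groupby(PRECURSOR_COLS, sort=False)["q_value"].max()
    kept_keys = worst.index[worst <= q_threshold]
    keys = pd.MultiIndex.from_frame(report[PRECURSOR_COLS])
    out = report[keys.isin(kept_keys)].copy()
    logger.info(
        "strict_filter(q<=%g): %d -> %d precursors",
        q_threshold,
        len(worst),
        len(kept_keys),
    )
    return out


def _group_qualifies(
    report: pd.DataFrame, design: Design, group: str, policy: FilterPolicy
) -> pd.Series:
    """Boolean per precursor: within every species of ``group``, at most
    ``outliers_allowed_per_species`` samples exceed the grouped threshold."""
    species = design.species_in_group(group)
    for sp in species:
        if len(design.samples_of_species(sp)) < 2:
            logger.warning("species %r has < 2 samples; outlier rule applied as stated", sp)
    sub = report[report["sample_id"].isin(design.samples_of_group(group))]
    bad = (
        sub.assign(_bad=sub["q_value"] > policy.q_threshold_grouped)
        .groupby(PRECURSOR_COLS + ["species"], sort=False)["_bad"]
        .sum()
        .unstack("species")
    )
    ok = (bad[species] <= policy.outliers_allowed_per_species).all(axis=1)
    return ok


def grouped_confidence_filter(
    report: pd.DataFrame, design: Design, policy: FilterPolicy = FilterPolicy()
) -> pd.DataFrame:
    """Keep precursors quantified with high confidence in either contrast
    group (or both, per ``policy.group_mode``); retain all samples' rows for
    kept precursors."""
    if report.empty:
        raise ValueError("empty report")
    _check_complete(report)
    if design.contrast is None:
        raise ValueError("design has no contrast defined")
    group_a, group_b = design.contrast
    ok_a = _group_qualifies(report, design, group_a, policy)
    ok_b = _group_qualifies(report, design, group_b, policy)
    ok_a, ok_b = ok_a.align(ok_b, fill_value=False)
    qualified = (ok_a | ok_b) if policy.group_mode == "either" else (ok_a & ok_b)
    kept_keys = qualified.index[qualified]
    keys = pd.MultiIndex.from_frame(report[PRECURSOR_COLS])
    out = report[keys.isin(kept_keys)].copy()
    logger.info(
        "grouped_confidence_filter(q<=%g, %s): %d -> %d precursors",
        policy.q_threshold_grouped,
        policy.group_mode,
        len(qualified),
        len(kept_keys),
    )
    return out


def remove_ambiguous(report: pd.DataFrame) -> pd.DataFrame:
    """Discard precursors mapping to more than one gene in the library."""
    genes = report["genes"].astype(str)
    if (genes.str.strip() == "").any():
        row = report.index[genes.str.strip() == ""][0]
        raise ValueError(f"precursor with empty gene set at row {row}")
    n_genes = genes.str.split(";").map(lambda g: len({x for x in g if x}))
    out = report[n_genes == 1].copy()
    logger.info("remove_ambiguous: %d -> %d rows", len(report), len(out))
    return out


def restrict_to_conserved(
    report: pd.DataFrame, index: ConservedIndex, species_subset: Iterable[str]
) -> pd.DataFrame:
    """Keep precursors whose bare sequence (modifications ignored) occurs in
    the in-silico digest of every species in ``species_subset``."""
    subset = list(species_subset)
    sequences = report["sequence"].unique()
    conserved = {s: index.is_conserved(s, subset) for s in sequences}
    mask = report["sequence"].map(conserved)
    out = report[mask].copy()
    logger.info(
        "restrict_to_conserved(%s): %d -> %d rows",
        ",".join(subset),
        len(report),
        len(out),
    )
    return out


def filter_report(
    report: pd.DataFrame,
    design: Design,
    policy: FilterPolicy = FilterPolicy(),
    index: ConservedIndex | None = None,
    species_subset: Iterable[str] | None = None,
    return_audit: bool = False,
):
    """Composite comparison filter: grouped confidence, ambiguity, then
    conservation (the three are independent row predicates, so the order
    does not change the result).

    With ``return_audit=True``, also return a per-precursor audit table of
    each rule's verdict.
    """
    stages: list[tuple[str, pd.DataFrame]] = []
    out = grouped_confidence_filter(report, design, policy)
    stages.append(("grouped_confidence", out))
    out = remove_ambiguous(out)
    stages.append(("ambiguity", out))
    if index is not None:
        subset = list(species_subset) if species_subset is not None else design.species
        out = restrict_to_conserved(out, index, subset)
        stages.append(("conservation", out))
    if not return_audit:
        return out

    all_keys = report[PRECURSOR_COLS].drop_duplicates().reset_index(drop=True)
    audit = all_keys.copy()
    prev_keys = pd.MultiIndex.from_frame(all_keys)
    for rule, stage_df in stages:
        kept = pd.MultiIndex.from_frame(stage_df[PRECURSOR_COLS].drop_duplicates())
        audit[rule] = np.where(prev_keys.isin(kept), "kept", "removed")
    return out, audit
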