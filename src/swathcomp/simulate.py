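"""Synthetic multi-species DIA datasets with known ground truth.

The generator emulates the statistical structure of a targeted-extraction
(SWATH/DIA) peptide report over four species in two groups (rodent: mouse,
rat; primate: marmoset, human; n = 5/5/6/5 biological samples):

* protein abundances are log-normal, spanning roughly six orders of
  magnitude on the linear scale;
* each gene yields several tryptic peptides, each with a peptide-specific
  multiplicative response factor (ionization efficiency differs by orders of
  magnitude between sequences);
* a configurable fraction of peptides is sequence-identical in all species
  (conserved); the rest carry at least one substitution in at least one
  species, with substitutions never touching K/R/P so tryptic boundaries are
  preserved across species;
* a configurable fraction of genes carries a true between-group fold change;
* every (sample, precursor) pair is observed exactly once (targeted
  extraction yields complete matrices) with multiplicative log-normal noise;
* a small fraction of observations receives a poor confidence score
  (Q-value above threshold), preferentially at low intensities.

Everything is driven by one master seed; independent pseudo-random streams
are derived per logical entity (sequences, abundances, noise, Q-values) so
the same seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .digestion import Proteome, ProteinEntry

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_proteomes",
    "generate_report",
    "generate_technical_replicates",
    "simulate_dataset",
]

#: residues usable inside a tryptic block: the 20 standard amino acids minus
#: K/R (cleavage sites), P (blocks cleavage) — ambiguity codes B/J/O/U/X/Z
#: are never emitted.
BODY_RESIDUES = np.array(list("ACDEFGHILMNQSTVWY"))
TERMINAL_RESIDUES = np.array(list("KR"))

_LOG2_10 = math.log2(10.0)
#: default gene abundance centre on log2 scale (~10^5 on the linear scale)
_ABUNDANCE_MEAN_LOG2 = 5.0 * _LOG2_10


def _default_species() -> dict[str, int]:
    return {"mouse": 5, "rat": 5, "marmoset": 6, "human": 5}


def _default_groups() -> dict[str, str]:
    return {"mouse": "rodent", "rat": "rodent", "marmoset": "primate", "human": "primate"}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic dataset.

    Defaults reproduce the reference study conditions: four species in two
    groups with 5/5/6/5 samples, 2000 genes with 2-8 peptides each, 70 %
    of peptides conserved across all species, 10 % of genes differentially
    abundant with |log2 fold change| uniform in [0.2, 2.0], peptide response
    factors with SD 1.0 on the log10 scale, 10 % multiplicative observation
    noise, and 2 % of observations flagged low-confidence.
    """

    seed: int = 0
    species: dict[str, int] = field(default_factory=_default_species)
    group_map: dict[str, str] = field(default_factory=_default_groups)
    contrast: tuple[str, str] = ("rodent", "primate")
    n_genes: int = 2000
    peptides_per_gene: tuple[int, int] = (2, 8)
    peptide_length: tuple[int, int] = (6, 20)
    conserved_fraction: float = 0.7
    de_fraction: float = 0.1
    log2fc_range: tuple[float, float] = (0.2, 2.0)
    response_factor_sd: float = 1.0  # log10 scale
    abundance_log10_sd: float = 0.8
    species_effect_sd: float = 0.0  # log2 per-gene, per-species offsets beyond the contrast
    noise_cv: float = 0.10
    qvalue_outlier_rate: float = 0.02
    q_confident_range: tuple[float, float] = (1e-8, 1e-5)
    q_outlier_range: tuple[float, float] = (2e-4, 1e-1)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.peptides_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_gene bounds must be positive and ordered")
        lo, hi = self.peptide_length
        if lo < 6 or hi < lo:
            raise ValueError("peptide_length bounds must be >= 6 and ordered")
        for name in ("conserved_fraction", "de_fraction", "qvalue_outlier_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("response_factor_sd", "abundance_log10_sd", "species_effect_sd", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.species:
            raise ValueError("species map must be non-empty")
        for sp, n in self.species.items():
            if n < 1:
                raise ValueError(f"sample count for {sp} must be positive")
            if sp not in self.group_map:
                raise ValueError(f"species {sp!r} missing from group_map")

    # -- derived views ----------------------------------------------------

    @property
    def species_list(self) -> list[str]:
        return list(self.species)

    def samples(self) -> list[tuple[str, str]]:
        """Ordered (sample_id, species) pairs."""
        out = []
        for sp, n in self.species.items():
            for i in range(n):
                out.append((f"{sp}_{i + 1}", sp))
        return out

    def group_species(self, group: str) -> list[str]:
        return [sp for sp, g in self.group_map.items() if g == group and sp in self.species]

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("sequences", "abundances", "noise", "qvalues", "charges")
        return {name: np.random.default_rng(child) for name, child in zip(names, children)}


@dataclass
class GroundTruth:
    """True simulation parameters, for parameter-recovery tests.

    ``genes`` has one row per gene with the true per-species mean (log2
    columns ``mean_log2_<species>``), the true contrast log2 fold change and
    the DE flag; ``peptides`` has one row per peptide with its parent gene,
    conservation status and response factor; ``noise`` (filled in by
    :func:`generate_report`) holds the per-observation noise multipliers.
    """

    genes: pd.DataFrame
    peptides: pd.DataFrame
    contrast: tuple[str, str]
    noise: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        known = set(self.genes["gene"])
        orphans = set(self.peptides["gene"]) - known
        if orphans:
            raise ValueError(f"peptides reference unknown genes: {sorted(orphans)[:5]}")
        flags = self.genes["de_flag"].to_numpy()
        nonzero = self.genes["true_log2fc"].to_numpy() != 0.0
        if not np.array_equal(flags, nonzero):
            raise ValueError("de_flag must be true iff |true log2fc| > 0")


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimulationConfig
    proteomes: dict[str, Proteome]
    truth: GroundTruth
    report: pd.DataFrame
    design: pd.DataFrame


def _draw_peptide(rng: np.random.Generator, length_bounds: tuple[int, int], used: set[str]) -> str:
    lo, hi = length_bounds
    while True:
        length = int(rng.integers(lo, hi + 1))
        body = rng.choice(BODY_RESIDUES, size=length - 1)
        terminal = rng.choice(TERMINAL_RESIDUES)
        seq = "".join(body) + str(terminal)
        if seq not in used:
            used.add(seq)
            return seq


def _mutate_peptide(rng: np.random.Generator, sequence: str, used: set[str]) -> str:
    """One substitution in the body of a tryptic block; never creates or
    destroys K/R/P so cleavage structure is identical across species."""
    while True:
        pos = int(rng.integers(0, len(sequence) - 1))  # never the terminal K/R
        current = sequence[pos]
        choices = [r for r in BODY_RESIDUES if r != current]
        replacement = str(rng.choice(np.array(choices)))
        variant = sequence[:pos] + replacement + sequence[pos + 1 :]
        if variant not in used:
            used.add(variant)
            return variant


def generate_proteomes(config: SimulationConfig) -> tuple[dict[str, Proteome], GroundTruth]:
    """Generate one protein per gene per species plus the ground truth.

    Protein sequences are concatenations of tryptic blocks (length 6-20,
    terminal K/R, no internal K/R/P) so that a 0-missed-cleavage digest
    recovers exactly the generated peptides. A peptide is either identical
    in all species or carries >= 1 substitution in at least one non-reference
    species.
    """
    streams = config._streams()
    rng_seq = streams["sequences"]
    rng_ab = streams["abundances"]
    species_list = config.species_list
    reference = species_list[0]
    others = species_list[1:]

    used: set[str] = set()
    pep_rows = []
    species_blocks: dict[str, list[list[str]]] = {sp: [] for sp in species_list}
    genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    lo, hi = config.peptides_per_gene
    n_peps = rng_seq.integers(lo, hi + 1, size=config.n_genes)

    for g_idx, gene in enumerate(genes):
        blocks = {sp: [] for sp in species_list}
        for _ in range(int(n_peps[g_idx])):
            ref_seq = _draw_peptide(rng_seq, config.peptide_length, used)
            conserved = bool(rng_seq.random() < config.conserved_fraction)
            variants = {sp: ref_seq for sp in species_list}
            if not conserved and others:
                mutate = [sp for sp in others if rng_seq.random() < 0.5]
                if not mutate:
                    mutate = [others[int(rng_seq.integers(0, len(others)))]]
                for sp in mutate:
                    variants[sp] = _mutate_peptide(rng_seq, ref_seq, used)
            conserved_species = [sp for sp in species_list if variants[sp] == ref_seq]
            pep_rows.append(
                {
                    "sequence": ref_seq,
                    "gene": gene,
                    "conserved": conserved,
                    "conserved_species": ";".join(conserved_species),
                }
            )
            for sp in species_list:
                blocks[sp].append(variants[sp])
        for sp in species_list:
            species_blocks[sp].append(blocks[sp])

    peptides = pd.DataFrame(pep_rows)
    peptides["response_factor_log2"] = (
        rng_ab.normal(0.0, config.response_factor_sd, size=len(peptides)) * _LOG2_10
    )

    # true abundances: shared base, optional species wobble, contrast effect
    base_log2 = rng_ab.normal(
        _ABUNDANCE_MEAN_LOG2, config.abundance_log10_sd * _LOG2_10, size=config.n_genes
    )
    mean_log2 = {sp: base_log2.copy() for sp in species_list}
    if config.species_effect_sd > 0:
        for sp in species_list:
            mean_log2[sp] = mean_log2[sp] + rng_ab.normal(
                0.0, config.species_effect_sd, size=config.n_genes
            )

    true_log2fc = np.zeros(config.n_genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    if n_de > 0:
        de_idx = rng_ab.choice(config.n_genes, size=n_de, replace=False)
        magnitude = rng_ab.uniform(*config.log2fc_range, size=n_de)
        sign = rng_ab.choice([-1.0, 1.0], size=n_de)
        true_log2fc[de_idx] = sign * magnitude
    group_a, group_b = config.contrast
    for sp in config.group_species(group_a):
        mean_log2[sp] = mean_log2[sp] + true_log2fc / 2.0
    for sp in config.group_species(group_b):
        mean_log2[sp] = mean_log2[sp] - true_log2fc / 2.0

    gene_table = pd.DataFrame({"gene": genes, "true_log2fc": true_log2fc})
    gene_table["de_flag"] = gene_table["true_log2fc"] != 0.0
    for sp in species_list:
        gene_table[f"mean_log2_{sp}"] = mean_log2[sp]

    proteomes = {}
    for sp in species_list:
        entries = []
        for gene, blocks in zip(genes, species_blocks[sp]):
            accession = f"{gene}_{sp.upper()}"
            entries.append(ProteinEntry(accession, gene, "".join(blocks)))
        proteomes[sp] = Proteome(species=sp, entries=entries)

    truth = GroundTruth(genes=gene_table, peptides=peptides, contrast=config.contrast)
    return proteomes, truth


def _noise_multipliers(rng: np.random.Generator, cv: float, shape: tuple[int, int]) -> np.ndarray:
    if cv == 0.0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=shape))


def generate_report(
    config: SimulationConfig,
    proteomes: dict[str, Proteome],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the long-format peptide report and the sample design table.

    Intensity = 2**(species gene mean + peptide response factor) x noise,
    where the noise is log-normal with mean 1 and the configured CV. Every
    (sample, precursor) pair appears exactly once. Q-values follow the
    two-component confidence model, with low-confidence observations biased
    toward low intensities. The report references the *reference* (library)
    peptide sequence for every species, as in targeted extraction against a
    single spectral library.
    """
    streams = config._streams()
    rng_noise = streams["noise"]
    rng_q = streams["qvalues"]
    rng_charge = streams["charges"]

    samples = config.samples()
    sample_ids = [s for s, _ in samples]
    sample_species = [sp for _, sp in samples]
    peptides = truth.peptides
    n_pep = len(peptides)
    n_samp = len(samples)

    gene_index = pd.Index(truth.genes["gene"])
    gene_pos = gene_index.get_indexer(peptides["gene"])
    mean_cols = {sp: truth.genes[f"mean_log2_{sp}"].to_numpy() for sp in config.species_list}
    rf = peptides["response_factor_log2"].to_numpy()

    log2_signal = np.empty((n_pep, n_samp))
    for j, sp in enumerate(sample_species):
        log2_signal[:, j] = mean_cols[sp][gene_pos] + rf
    noise = _noise_multipliers(rng_noise, config.noise_cv, (n_pep, n_samp))
    intensity = np.exp2(log2_signal) * noise

    # confidence model: m observations drawn without replacement, weighted
    # toward low intensities (Gumbel top-k gives a deterministic weighted
    # sample from one stream)
    n_obs = n_pep * n_samp
    flat = intensity.ravel()
    q = np.power(
        10.0,
        rng_q.uniform(
            math.log10(config.q_confident_range[0]),
            math.log10(config.q_confident_range[1]),
            size=n_obs,
        ),
    )
    m = int(round(config.qvalue_outlier_rate * n_obs))
    if m > 0:
        ranks = np.empty(n_obs, dtype=float)
        ranks[np.argsort(flat, kind="stable")] = np.arange(n_obs, dtype=float)
        weights = n_obs - ranks  # lowest intensity -> largest weight
        keys = np.log(weights) + rng_q.gumbel(size=n_obs)
        outliers = np.argpartition(-keys, m - 1)[:m]
        q[outliers] = np.power(
            10.0,
            rng_q.uniform(
                math.log10(config.q_outlier_range[0]),
                math.log10(config.q_outlier_range[1]),
                size=m,
            ),
        )

    charges = rng_charge.choice([2, 3], size=n_pep, p=[0.7, 0.3])

    report = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_pep),
            "species": np.repeat(sample_species, n_pep),
            "sequence": np.tile(peptides["sequence"].to_numpy(), n_samp),
            "modifications": "",
            "charge": np.tile(charges, n_samp),
            "genes": np.tile(peptides["gene"].to_numpy(), n_samp),
            "intensity": intensity.ravel(order="F"),
            "q_value": q.reshape(n_pep, n_samp).ravel(order="F"),
        }
    )
    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": sample_species,
            "group": [config.group_map[sp] for sp in sample_species],
        }
    )
    truth.noise = pd.DataFrame(noise, index=peptides["sequence"].to_numpy(), columns=sample_ids)
    return report, design


def generate_technical_replicates(
    config: SimulationConfig, n_reps: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Repeated measurements of a single preparation of the first species.

    All replicates share the same true abundances; only the observation noise
    differs, emulating a technical-replicate QC experiment.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    first = config.species_list[0]
    rep_config = dataclasses.replace(
        config,
        species={first: n_reps},
        group_map={first: config.group_map[first]},
        contrast=(config.group_map[first], config.group_map[first]),
        de_fraction=0.0,
        species_effect_sd=0.0,
    )
    proteomes, truth = generate_proteomes(rep_config)
    report, design = generate_report(rep_config, proteomes, truth)
    return report, design, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Convenience wrapper: proteomes + ground truth + report + design."""
    proteomes, truth = generate_proteomes(config)
    report, design = generate_report(config, proteomes, truth)
    return SimulatedDataset(
        config=config, proteomes=proteomes, truth=truth, report=report, design=design
    )
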