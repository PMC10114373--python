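"""Synthetic multi-patient single-cell cohorts with EMP structure.

Generates negative-binomial count matrices emulating a dissociated tumor
cohort: tumor cells in partial-EMT, epithelial-differentiated or mixed
states, stromal and immune cells, chromosome-block copy-number gains,
patient batch effects, hashtag (HTO) libraries with doublets, and matched
pseudo-bulk mixtures.  Every generated barcode is recorded in a
:class:`GroundTruth` manifest so downstream stages can be tested against
known labels.

The generative model is gene-wise: ``count(c, g) ~ NB(mean, dispersion)``
with ``mean = baseline(g) * program_effect(type(c), g) * cnv_ratio(c, g)
* batch(patient(c), g) * libsize(c)``.  Copy-number blocks act
multiplicatively on the mean, matching the relative-expression signal that
moving-average CNV inference reads out.  Doublets are sums of two
independently drawn cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import ValidationError

TUMOR_TYPES = ("tumor-pEMT", "tumor-epi", "tumor-mix")

DEFAULT_PROPORTIONS = {
    "tumor-pEMT": 0.25,
    "tumor-epi": 0.25,
    "tumor-mix": 0.10,
    "fibroblast": 0.20,
    "immune": 0.20,
}

# Which expression programs are active in which cell type.  The mixed tumor
# state carries both EMP programs, emulating hybrid cells.
PROGRAM_CELL_TYPES = {
    "pEMT": ("tumor-pEMT", "tumor-mix"),
    "epi": ("tumor-epi", "tumor-mix"),
    "fibroblast": ("fibroblast",),
    "immune": ("immune",),
}


@dataclass(frozen=True)
class CNVBlock:
    """A copy-number block: contiguous genes on one chromosome whose NB mean
    is multiplied by ``copy_ratio`` in cells of ``cell_type`` from ``patient``.
    Gene indices are 1-based positions on the chromosome, inclusive."""

    patient: str
    cell_type: str
    chromosome: str
    start: int
    end: int
    copy_ratio: float


@dataclass
class SyntheticConfig:
    """Parameters of the cohort generator.

    Defaults describe a small but realistic cohort: three patients with a
    few hundred cells each, five tumor/stroma/immune cell types, 2000 genes
    over six synthetic chromosomes plus a mitochondrial contig, one clonal
    copy-ratio-2 gain per patient, moderate patient batch effects and
    log-normal library-size variation, and hashed samples with 5% doublets.
    """

    n_patients: int = 3
    cells_per_patient: int = 400
    cell_type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_chromosomes: int = 6
    genes_per_chromosome: int = 330
    mito_gene_count: int = 20
    housekeeper_gene_count: int = 50
    cnv_blocks: Sequence[CNVBlock] | None = None  # None -> per-patient defaults
    program_gene_sets: Mapping[str, Mapping[int, float]] | None = None
    program_size: int = 60
    program_effect: float = 3.0
    program_cell_types: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in PROGRAM_CELL_TYPES.items()}
    )
    patient_batch_sd: float = 0.15
    libsize_lognormal_params: tuple[float, float] = (0.0, 0.35)
    baseline_lognormal_params: tuple[float, float] = (0.0, 1.0)
    nb_dispersion: float = 10.0
    mean_mito_fraction: float = 0.05
    housekeeper_mean: float = 3.0
    samples_per_patient: int = 2
    doublet_rate: float = 0.05
    hto_signal_mean: float = 200.0
    hto_background_mean: float = 5.0
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome + self.mito_gene_count

    def validate(self) -> None:
        total = float(sum(self.cell_type_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"cell_type_proportions must sum to 1, got {total!r}"
            )
        if any(f < 0 for f in self.cell_type_proportions.values()):
            raise ValidationError("cell_type_proportions must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not (0.0 <= self.doublet_rate <= 1.0):
            raise ValidationError("doublet_rate must lie in [0, 1]")
        if self.patient_batch_sd < 0:
            raise ValidationError("patient_batch_sd must be non-negative")
        for blk in self.resolved_cnv_blocks():
            if blk.copy_ratio <= 0:
                raise ValidationError(f"copy_ratio must be > 0 in {blk}")
            if blk.patient not in self.patient_ids():
                raise ValidationError(f"unknown patient in {blk}")
            if blk.cell_type not in self.cell_type_proportions:
                raise ValidationError(f"unknown cell type in {blk}")
            chroms = [f"chr{i + 1}" for i in range(self.n_chromosomes)]
            if blk.chromosome not in chroms:
                raise ValidationError(f"unknown chromosome in {blk}")
            if not (1 <= blk.start <= blk.end <= self.genes_per_chromosome):
                raise ValidationError(f"gene range out of bounds in {blk}")

    def patient_ids(self) -> list[str]:
        return [f"patient{i + 1}" for i in range(self.n_patients)]

    def resolved_cnv_blocks(self) -> list[CNVBlock]:
        """Default blocks: each patient carries one clonal copy-ratio-2 gain
        (150 genes, positions 50-199) on its own chromosome, in all tumor
        cell types."""
        if self.cnv_blocks is not None:
            return list(self.cnv_blocks)
        blocks = []
        for i, pat in enumerate(self.patient_ids()):
            chrom = f"chr{(i % self.n_chromosomes) + 1}"
            end = min(199, self.genes_per_chromosome)
            for ct in TUMOR_TYPES:
                blocks.append(CNVBlock(pat, ct, chrom, 50, end, 2.0))
        return blocks


@dataclass
class GroundTruth:
    """Manifest of a generated cohort: one row per barcode (doublets
    included), per-gene annotation, realized CNV blocks, and — once bulk
    mixtures have been generated — the true mixing fractions."""

    cells: pd.DataFrame
    genes: pd.DataFrame
    cnv_blocks: list[CNVBlock]
    bulk_fractions: pd.DataFrame | None = None


def _build_gene_table(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids, chroms, positions = [], [], []
    for c in range(config.n_chromosomes):
        for p in range(config.genes_per_chromosome):
            ids.append(f"gene-chr{c + 1}-{p + 1:04d}")
            chroms.append(f"chr{c + 1}")
            positions.append(p + 1)
    for m in range(config.mito_gene_count):
        ids.append(f"gene-MT-{m + 1:04d}")
        chroms.append("MT")
        positions.append(m + 1)
    genes = pd.DataFrame(
        {"chromosome": chroms, "position": positions}, index=pd.Index(ids, name="gene_id")
    )
    genes["mito"] = genes["chromosome"] == "MT"

    n_auto = config.n_chromosomes * config.genes_per_chromosome
    # housekeepers: evenly spread over autosomal genes, outside CNV block ranges
    blocked = np.zeros(n_auto, dtype=bool)
    for blk in config.resolved_cnv_blocks():
        c = int(blk.chromosome[3:]) - 1
        lo = c * config.genes_per_chromosome + blk.start - 1
        hi = c * config.genes_per_chromosome + blk.end
        blocked[lo:hi] = True
    free = np.flatnonzero(~blocked)
    if len(free) < config.housekeeper_gene_count + 1:
        raise ValidationError("not enough genes outside CNV blocks for housekeepers")
    hk_pick = free[np.linspace(0, len(free) - 1, config.housekeeper_gene_count).astype(int)]
    hk = np.zeros(len(genes), dtype=bool)
    hk[hk_pick] = True
    genes["housekeeper"] = hk
    return genes


def _assign_programs(
    config: SyntheticConfig, genes: pd.DataFrame
) -> dict[str, dict[int, float]]:
    """Resolve program gene sets: explicit config wins, else scatter
    ``program_size`` genes per program across autosomal, non-housekeeper,
    non-CNV-block genes (interleaved so no program is genomically clustered)."""
    if config.program_gene_sets is not None:
        sets = {k: dict(v) for k, v in config.program_gene_sets.items()}
    else:
        n_auto = config.n_chromosomes * config.genes_per_chromosome
        blocked = np.zeros(n_auto, dtype=bool)
        for blk in config.resolved_cnv_blocks():
            c = int(blk.chromosome[3:]) - 1
            blocked[c * config.genes_per_chromosome + blk.start - 1:
                    c * config.genes_per_chromosome + blk.end] = True
        hk = genes["housekeeper"].to_numpy()[:n_auto]
        pool = np.flatnonzero(~blocked & ~hk)
        programs = list(config.program_cell_types)
        need = config.program_size * len(programs)
        if len(pool) < need:
            raise ValidationError("not enough free genes for the requested programs")
        picked = pool[np.linspace(0, len(pool) - 1, need).astype(int)]
        sets = {
            prog: {int(g): config.program_effect for g in picked[i::len(programs)]}
            for i, prog in enumerate(programs)
        }
    mito_idx = set(np.flatnonzero(genes["mito"].to_numpy()))
    hk_idx = set(np.flatnonzero(genes["housekeeper"].to_numpy()))
    for prog, members in sets.items():
        for g, eff in members.items():
            if not (0 <= g < len(genes)):
                raise ValidationError(f"program {prog}: gene index {g} out of range")
            if eff < 1:
                raise ValidationError(f"program {prog}: effect sizes must be >= 1")
            if g in mito_idx or g in hk_idx:
                raise ValidationError(
                    f"program {prog}: gene {g} overlaps mito/housekeeper set"
                )
    return sets


def _baseline_means(config: SyntheticConfig, genes: pd.DataFrame,
                    rng: np.random.Generator) -> np.ndarray:
    mu, sigma = config.baseline_lognormal_params
    base = rng.lognormal(mean=mu, sigma=sigma, size=len(genes))
    hk = genes["housekeeper"].to_numpy()
    base[hk] = config.housekeeper_mean
    # scale mitochondrial means so the expected mito fraction hits the target
    mito = genes["mito"].to_numpy()
    f = config.mean_mito_fraction
    if mito.any() and 0 < f < 1:
        target_mass = f / (1 - f) * base[~mito].sum()
        base[mito] *= target_mass / base[mito].sum()
    return base


def _draw_cell_types(config: SyntheticConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n cells to the configured proportions,
    then a seeded shuffle, so realized counts match expectations exactly."""
    types = list(config.cell_type_proportions)
    fracs = np.array([config.cell_type_proportions[t] for t in types])
    counts = np.floor(fracs * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    counts[order[:rem]] += 1
    out = np.repeat(np.array(types, dtype=object), counts)
    rng.shuffle(out)
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_cohort(config: SyntheticConfig) -> tuple[AnnData, GroundTruth]:
    """Generate the cohort count matrix and its ground-truth manifest.

    Returns an :class:`~anndata.AnnData` with sparse integer counts in
    ``X``, per-cell metadata in ``obs`` (patient, sample, barcode) and
    per-gene metadata in ``var`` (chromosome, position, mito, housekeeper).
    True labels (cell type, EMP state, doublet status, HTO of origin) live
    only in the :class:`GroundTruth`.  Deterministic given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_assign, rng_counts = (np.random.default_rng(c) for c in ss.spawn(3))

    genes = _build_gene_table(config, rng_genes)
    programs = _assign_programs(config, genes)
    base = _baseline_means(config, genes, rng_genes)
    n_genes = len(genes)

    # per-(cell type, gene) program effect
    type_effect = {t: np.ones(n_genes) for t in config.cell_type_proportions}
    for prog, members in programs.items():
        for ct in config.program_cell_types.get(prog, ()):
            if ct not in type_effect:
                continue
            idx = np.fromiter(members, dtype=int)
            eff = np.array([members[g] for g in idx])
            type_effect[ct][idx] *= eff

    # per-(patient, cell type, gene) CNV ratio
    chrom_offsets = {f"chr{i + 1}": i * config.genes_per_chromosome
                     for i in range(config.n_chromosomes)}
    cnv_ratio: dict[tuple[str, str], np.ndarray] = {}
    for blk in config.resolved_cnv_blocks():
        key = (blk.patient, blk.cell_type)
        vec = cnv_ratio.setdefault(key, np.ones(n_genes))
        off = chrom_offsets[blk.chromosome]
        vec[off + blk.start - 1: off + blk.end] *= blk.copy_ratio

    mu_lib, sd_lib = config.libsize_lognormal_params
    rows, cell_records = [], []
    for pat in config.patient_ids():
        batch = np.exp(rng_counts.normal(0.0, config.patient_batch_sd, size=n_genes))
        samples = [f"{pat}-s{j + 1}" for j in range(config.samples_per_patient)]
        n_bar = config.cells_per_patient
        n_doub = int(round(n_bar * config.doublet_rate))
        n_sing = n_bar - n_doub

        def draw_cell(ct: str) -> np.ndarray:
            lib = rng_counts.lognormal(mu_lib, sd_lib)
            mean = base * type_effect[ct] * lib * batch
            ratio = cnv_ratio.get((pat, ct))
            if ratio is not None:
                mean = mean * ratio
            return _nb_draw(rng_counts, mean, config.nb_dispersion)

        sing_types = _draw_cell_types(config, n_sing, rng_assign)
        sing_samples = [samples[i % len(samples)] for i in range(n_sing)]
        rng_assign.shuffle(sing_samples)
        for i in range(n_sing):
            ct = sing_types[i]
            rows.append(draw_cell(ct))
            cell_records.append(
                dict(patient=pat, sample=sing_samples[i], cell_type=ct,
                     emp_state=_emp_state(ct), is_doublet=False,
                     hto_first=sing_samples[i], hto_second=None)
            )
        doub_types = _draw_cell_types(config, 2 * n_doub, rng_assign)
        for i in range(n_doub):
            ct1, ct2 = doub_types[2 * i], doub_types[2 * i + 1]
            s1, s2 = rng_assign.choice(samples, size=2, replace=True)
            rows.append(draw_cell(ct1) + draw_cell(ct2))
            cell_records.append(
                dict(patient=pat, sample=None, cell_type=f"{ct1}+{ct2}",
                     emp_state="doublet", is_doublet=True,
                     hto_first=s1, hto_second=s2)
            )

    barcodes = [f"BC{i:06d}" for i in range(len(rows))]
    cells = pd.DataFrame(cell_records, index=pd.Index(barcodes, name="barcode"))

    gene_program = np.array([""] * n_genes, dtype=object)
    for prog, members in programs.items():
        for g in members:
            gene_program[g] = prog if gene_program[g] == "" else gene_program[g] + "+" + prog
    genes_out = genes.copy()
    genes_out["program"] = gene_program

    X = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    obs = cells[["patient", "sample"]].copy()
    obs["sample"] = obs["sample"].astype(object)
    adata = AnnData(X=X, obs=obs, var=genes_out.copy())
    adata.uns["synthetic_config"] = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(config)
        if f.name not in ("cnv_blocks", "program_gene_sets", "program_cell_types",
                          "cell_type_proportions")
    }
    truth = GroundTruth(cells=cells, genes=genes_out,
                        cnv_blocks=config.resolved_cnv_blocks())
    return adata, truth


def _emp_state(cell_type: str) -> str:
    return {"tumor-pEMT": "pEMT", "tumor-epi": "epi", "tumor-mix": "mix"}.get(
        cell_type, "non-tumor"
    )


def generate_hto_counts(truth: GroundTruth, config: SyntheticConfig) -> AnnData:
    """Poisson HTO counts: each cell's HTO(s) of origin at the signal mean,
    every other hashtag at the background mean; doublets carry signal on both
    parental HTOs.  Deterministic given ``config.seed``."""
    if config.hto_signal_mean <= config.hto_background_mean:
        raise ValidationError(
            "hto_signal_mean must exceed hto_background_mean for demultiplexing"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    htos = sorted(
        set(truth.cells["hto_first"].dropna()) | set(truth.cells["hto_second"].dropna())
    )
    idx = {h: j for j, h in enumerate(htos)}
    n, k = len(truth.cells), len(htos)
    mean = np.full((n, k), config.hto_background_mean)
    for i, (_, row) in enumerate(truth.cells.iterrows()):
        for h in (row["hto_first"], row["hto_second"]):
            if h is not None and not pd.isna(h):
                mean[i, idx[h]] = config.hto_signal_mean
    counts = rng.poisson(mean)
    var = pd.DataFrame(
        {"feature_type": ["Antibody Capture"] * k}, index=pd.Index(htos, name="hto_id")
    )
    return AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=truth.cells.index.copy()),
        var=var,
    )


def generate_bulk_mixtures(
    adata: AnnData,
    truth: GroundTruth,
    n_mixtures: int,
    seed: int,
    cells_per_type: int = 100,
    library_size: int = 1_000_000,
    dirichlet_alpha: float = 1.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Pseudo-bulk mixtures with Dirichlet-drawn cell-type fractions.

    Each mixture is a fraction-weighted sum of mean count profiles of
    randomly resampled singlet cells per type, rescaled to ``library_size``
    total counts.  Returns the genes x mixtures count table and a copy of
    the ground truth carrying the realized fractions.
    """
    if n_mixtures < 1:
        raise ValidationError("n_mixtures must be >= 1")
    singlets = truth.cells.index[~truth.cells["is_doublet"]]
    types = sorted(truth.cells.loc[singlets, "cell_type"].unique())
    if len(types) < 2:
        raise ValidationError("need at least 2 cell types for mixtures")
    rng = np.random.default_rng(seed)
    pos = {b: i for i, b in enumerate(adata.obs_names)}
    by_type = {
        t: np.array([pos[b] for b in singlets[truth.cells.loc[singlets, "cell_type"] == t]])
        for t in types
    }
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    profiles, fracs = [], []
    for _ in range(n_mixtures):
        f = rng.dirichlet(np.full(len(types), dirichlet_alpha))
        bulk = np.zeros(adata.n_vars)
        for t, ft in zip(types, f):
            pick = rng.choice(by_type[t], size=cells_per_type, replace=True)
            bulk += ft * X[pick].mean(axis=0)
        bulk = np.round(bulk / bulk.sum() * library_size).astype(np.int64)
        profiles.append(bulk)
        fracs.append(f)
    names = [f"mixture{i + 1}" for i in range(n_mixtures)]
    table = pd.DataFrame(
        np.column_stack(profiles), index=adata.var_names.copy(), columns=names
    )
    frac_df = pd.DataFrame(np.vstack(fracs), index=names, columns=types)
    err = np.abs(frac_df.sum(axis=1) - 1.0).max()
    assert err < 1e-9
    out = GroundTruth(
        cells=truth.cells, genes=truth.genes, cnv_blocks=truth.cnv_blocks,
        bulk_fractions=frac_df,
    )
    return table, out
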