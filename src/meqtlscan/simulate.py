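"""Synthetic cohort generator with known ground truth.

Emulates the structure of a blood methylation meQTL discovery cohort:
covariates (sex, age, weight category), risk-allele genotype dosages under
Hardy-Weinberg equilibrium, a Dirichlet cell-type composition per sample,
and a beta-value methylation matrix generated additively on the M scale,

    M = base + sum_c offset_c * w_c + bS*S + bA*A + bW*W + delta*G + noise,

then mapped to beta = 2**M / (2**M + 1). Planted genotype effects (delta, in
M units per risk allele), the composition matrix, and all annotation
memberships are returned as ground truth so every downstream stage can be
tested for exact recovery.

The generator makes no claim about the true generative process of
population methylation data; it is a fixture whose defaults mirror the
structure of a ~350-sample, 52-SNP blood cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DimensionError
from .preprocess import m_to_beta

__all__ = [
    "SnpSpec",
    "ProbeSpec",
    "SimulationConfig",
    "GroundTruth",
    "AnnotationSet",
    "SimulatedDataset",
    "gen_samples",
    "gen_genotypes",
    "gen_methylation",
    "gen_annotation",
    "simulate_dataset",
    "blood_config",
    "write_dataset",
]

BLOOD_CELL_TYPES = ("granulocyte", "cd4_t", "cd8_t", "b_cell", "nk_cell", "monocyte")
#: Dirichlet concentrations roughly matching whole-blood mean proportions
#: (~56 % granulocytes, ~16 % CD4 T, ...) with realistic between-person spread.
BLOOD_DIRICHLET_ALPHA = (18.0, 5.0, 3.0, 2.0, 1.0, 3.0)

STATE_CATEGORIES = (
    "enhancer", "tss", "transcription", "quiescent",
    "heterochromatin", "polycomb", "znf_repeats",
)

# independent random streams per generator stage
_SALT_SAMPLES, _SALT_GENO, _SALT_METH, _SALT_ANNOT = 11, 13, 17, 19


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    chrom: str
    pos: int  # 1-based bp
    risk_allele: str
    maf: float


@dataclass(frozen=True)
class ProbeSpec:
    probe_id: str
    chrom: str
    pos: int  # 1-based bp
    base_level: float  # logit-scale (M) baseline methylation
    celltype_offsets: tuple = ()  # per-cell-type logit shifts


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    Effects are additive on the M scale; ``effect_specs`` maps
    (snp_id, probe_id) to delta in M units per risk allele.
    ``covariate_effects`` maps probe_id to (b_sex, b_age, b_weight).
    """

    n_samples: int = 350
    snp_specs: Sequence[SnpSpec] = ()
    probe_specs: Sequence[ProbeSpec] = ()
    effect_specs: Mapping = field(default_factory=dict)
    covariate_effects: Mapping = field(default_factory=dict)
    noise_sd: float = 0.25
    cell_types: Sequence[str] = BLOOD_CELL_TYPES
    dirichlet_alpha: Sequence[float] = BLOOD_DIRICHLET_ALPHA
    reference_probe_ids: Sequence[str] = ()
    sex_prob: float = 0.4  # P(female); the emulated cohort is ~60 % male
    age_range: tuple = (14.0, 34.0)
    weight_probs: tuple = (0.76, 0.20, 0.04)  # lean / overweight / obese
    missing_rate: float = 0.0
    detection_fail_rate: float = 0.0
    failed_probes: Sequence[str] = ()  # probes with elevated detection failure
    failed_probe_rate: float = 0.5
    chrom_lengths: Mapping = field(default_factory=lambda: {"chr1": 70_000_000})
    tissues: Sequence[str] = ("PBMC", "AN", "Liver")
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if not (0.0 <= self.sex_prob <= 1.0):
            raise ConfigurationError("sex_prob must be in [0, 1]")
        w = np.asarray(self.weight_probs, float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("weight_probs must be nonnegative and sum to 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if len(self.dirichlet_alpha) != len(self.cell_types):
            raise ConfigurationError("dirichlet_alpha length must match cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigurationError("dirichlet_alpha entries must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        snp_ids = {s.snp_id for s in self.snp_specs}
        probe_ids = [p.probe_id for p in self.probe_specs]
        if len(set(probe_ids)) != len(probe_ids):
            raise ConfigurationError("duplicate probe ids")
        for s in self.snp_specs:
            if not (0.0 < s.maf <= 0.5):
                raise ConfigurationError(f"{s.snp_id}: maf must be in (0, 0.5], got {s.maf}")
            if s.pos <= 0:
                raise ConfigurationError(f"{s.snp_id}: position must be positive")
        for p in self.probe_specs:
            if p.pos <= 0:
                raise ConfigurationError(f"{p.probe_id}: position must be positive")
            if p.celltype_offsets and len(p.celltype_offsets) != len(self.cell_types):
                raise ConfigurationError(f"{p.probe_id}: offsets length != number of cell types")
        probe_set = set(probe_ids)
        for (snp_id, probe_id) in self.effect_specs:
            if snp_id not in snp_ids or probe_id not in probe_set:
                raise ConfigurationError(
                    f"effect ({snp_id}, {probe_id}) references unknown SNP or probe"
                )
        if not set(self.reference_probe_ids) <= probe_set:
            raise ConfigurationError("reference_probe_ids must be a subset of the probe manifest")

    def snp_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.snp_id, s.chrom, s.pos, s.risk_allele, s.maf) for s in self.snp_specs],
            columns=["snp_id", "chrom", "pos", "risk_allele", "maf"],
        )

    def probe_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.probe_id, p.chrom, p.pos) for p in self.probe_specs],
            columns=["probe_id", "chrom", "pos"],
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    true_effects: dict  # (snp_id, probe_id) -> delta
    true_compositions: pd.DataFrame  # samples x cell types, rows sum to 1
    reference_probe_ids: tuple
    latent_dosages: pd.DataFrame | None = None  # dosages before missingness


@dataclass
class AnnotationSet:
    genes: pd.DataFrame  # BED6: chrom start end name score strand (0-based half-open)
    states: dict  # tissue -> BED4 DataFrame (chrom start end category)
    anchors: pd.DataFrame  # BEDPE: chrom1 s1 e1 chrom2 s2 e2 name score
    enhancers: pd.DataFrame  # BED3
    true_region_class: dict  # probe_id -> class
    true_states: dict  # (probe_id, tissue) -> category
    true_interaction_counts: dict  # probe_id -> planted overlapping anchor pairs
    true_promoter_interaction: dict  # probe_id -> bool
    true_enhancer_members: set


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    covariates: pd.DataFrame
    genotypes: pd.DataFrame
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    truth: GroundTruth
    annotation: AnnotationSet | None = None


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def _sample_ids(n: int):
    return pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample_id")


def gen_samples(config: SimulationConfig) -> pd.DataFrame:
    """Covariate table: sex (female=1, male=0), age in years, weight category
    (lean=0, overweight=1, obese=2)."""
    config.validate()
    rng = _rng(config, _SALT_SAMPLES)
    n = config.n_samples
    sex = rng.binomial(1, config.sex_prob, size=n)
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    weight = rng.choice(3, size=n, p=np.asarray(config.weight_probs, float))
    return pd.DataFrame(
        {"sex": sex, "age": age, "weight_category": weight}, index=_sample_ids(n)
    )


def gen_genotypes(config: SimulationConfig, return_latent: bool = False):
    """Risk-allele dosage matrix, Binomial(2, maf) per SNP (Hardy-Weinberg).

    Missing entries (at ``missing_rate``) are NaN in the observed matrix;
    ``return_latent=True`` additionally returns the complete dosages that
    the methylation generator conditions on.
    """
    config.validate()
    rng = _rng(config, _SALT_GENO)
    n = config.n_samples
    idx = _sample_ids(n)
    cols = [s.snp_id for s in config.snp_specs]
    latent = np.column_stack(
        [rng.binomial(2, s.maf, size=n) for s in config.snp_specs]
    ).astype(float) if cols else np.empty((n, 0))
    observed = latent.copy()
    if config.missing_rate > 0:
        mask = rng.random(observed.shape) < config.missing_rate
        observed[mask] = np.nan
    observed = pd.DataFrame(observed, index=idx, columns=cols)
    if return_latent:
        return observed, pd.DataFrame(latent, index=idx, columns=cols)
    return observed


def gen_methylation(config: SimulationConfig, covariates: pd.DataFrame,
                    genotypes: pd.DataFrame, latent_dosages: pd.DataFrame | None = None):
    """Beta matrix + detection-p matrix + :class:`GroundTruth`.

    ``genotypes`` may contain NaN (missingness); the planted effects use the
    complete latent dosages when supplied, falling back to the observed
    matrix with missing entries contributing no effect.
    """
    config.validate()
    if not covariates.index.equals(genotypes.index):
        raise DimensionError("covariates and genotypes must cover the same samples")
    rng = _rng(config, _SALT_METH)
    n = config.n_samples
    idx = covariates.index
    probes = [p.probe_id for p in config.probe_specs]
    k = len(probes)

    comp = rng.dirichlet(np.asarray(config.dirichlet_alpha, float), size=n)
    compositions = pd.DataFrame(comp, index=idx, columns=list(config.cell_types))

    base = np.array([p.base_level for p in config.probe_specs])
    offsets = np.zeros((k, len(config.cell_types)))
    for j, p in enumerate(config.probe_specs):
        if p.celltype_offsets:
            offsets[j] = np.asarray(p.celltype_offsets, float)

    M = np.tile(base, (n, 1)) + comp @ offsets.T

    S = covariates["sex"].to_numpy(float)
    A = covariates["age"].to_numpy(float)
    W = covariates["weight_category"].to_numpy(float)
    for j, p in enumerate(config.probe_specs):
        eff = config.covariate_effects.get(p.probe_id)
        if eff is not None:
            b_s, b_a, b_w = eff
            M[:, j] += b_s * S + b_a * A + b_w * W

    dosage_source = latent_dosages if latent_dosages is not None else genotypes
    probe_index = {pid: j for j, pid in enumerate(probes)}
    for (snp_id, probe_id), delta in config.effect_specs.items():
        g = dosage_source[snp_id].to_numpy(float)
        M[:, probe_index[probe_id]] += delta * np.nan_to_num(g)

    M += rng.normal(0.0, config.noise_sd, size=(n, k))
    beta = pd.DataFrame(m_to_beta(M), index=idx, columns=probes)

    detp = rng.beta(0.1, 100.0, size=(n, k))
    fail = rng.random((n, k)) < config.detection_fail_rate
    if config.failed_probes:
        bad_cols = [probe_index[p] for p in config.failed_probes]
        fail[:, bad_cols] |= rng.random((n, len(bad_cols))) < config.failed_probe_rate
    detp = np.where(fail, rng.uniform(0.0, 1.0, size=(n, k)), detp)
    detection_p = pd.DataFrame(detp, index=idx, columns=probes)

    truth = GroundTruth(
        true_effects=dict(config.effect_specs),
        true_compositions=compositions,
        reference_probe_ids=tuple(config.reference_probe_ids),
        latent_dosages=latent_dosages,
    )
    return beta, detection_p, truth


def gen_annotation(config: SimulationConfig,
                   anchor_probe_counts: Mapping | None = None) -> AnnotationSet:
    """Toy gene models, per-tissue chromatin-state tilings, interaction
    anchors, and enhancer intervals, with all memberships recorded.

    Interval outputs use BED conventions (0-based half-open); probe and TSS
    positions are 1-based.
    """
    config.validate()
    rng = _rng(config, _SALT_ANNOT)
    probes = config.probe_manifest()

    # --- non-overlapping genes along each chromosome ---
    gene_rows = []
    gi = 0
    for chrom, length in config.chrom_lengths.items():
        cursor = int(rng.integers(5_000, 50_000))
        while cursor < length - 60_000:
            glen = int(rng.integers(2_000, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((chrom, cursor, cursor + glen, f"GENE{gi:04d}", 0, strand))
            gi += 1
            cursor += glen + int(rng.integers(5_000, 120_000))
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # ground-truth region classes by direct scan
    tss_1based = np.where(genes["strand"] == "+", genes["start"] + 1, genes["end"])
    true_region = {}
    for _, pr in probes.iterrows():
        on_chr = genes["chrom"] == pr["chrom"]
        pos = pr["pos"]
        in_prom = bool(np.any(on_chr & (np.abs(tss_1based - pos) <= 1500)))
        in_body = bool(
            np.any(on_chr & (genes["start"] + 1 <= pos) & (pos <= genes["end"]))
        )
        if in_prom and in_body:
            cls = "ambiguous"
        elif in_prom:
            cls = "promoter"
        elif in_body:
            cls = "gene_body"
        else:
            cls = "intergenic"
        true_region[pr["probe_id"]] = cls

    # --- per-tissue state tilings (exact partition of each chromosome) ---
    cat_probs = np.array([0.10, 0.05, 0.15, 0.45, 0.10, 0.10, 0.05])
    states = {}
    true_states = {}
    for tissue in config.tissues:
        rows = []
        for chrom, length in config.chrom_lengths.items():
            cursor = 0
            while cursor < length:
                seg = int(rng.integers(1, 60)) * 200
                end = min(cursor + seg, length)
                cat = STATE_CATEGORIES[rng.choice(len(STATE_CATEGORIES), p=cat_probs)]
                rows.append((chrom, cursor, end, cat))
                cursor = end
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        states[tissue] = df
        for _, pr in probes.iterrows():
            sub = df[df["chrom"] == pr["chrom"]]
            hit = sub[(sub["start"] <= pr["pos"] - 1) & (pr["pos"] - 1 < sub["end"])]
            true_states[(pr["probe_id"], tissue)] = hit["name"].iloc[0] if len(hit) else None

    # promoter windows (0-based half-open) for partner-anchor placement
    prom_windows = [
        (genes["chrom"].iloc[i], max(0, int(tss_1based[i]) - 1 - 1500), int(tss_1based[i]) + 1500)
        for i in range(len(genes))
    ]

    # --- interaction anchors ---
    if anchor_probe_counts is None:
        anchor_probe_counts = {
            pr["probe_id"]: int(rng.integers(0, 5)) for _, pr in probes.iterrows()
        }
    anchor_rows = []
    true_counts = {}
    true_prom_flag = {}
    ai = 0
    probe_pos0 = {pr["probe_id"]: (pr["chrom"], pr["pos"] - 1) for _, pr in probes.iterrows()}
    for probe_id, k in anchor_probe_counts.items():
        chrom, p0 = probe_pos0[probe_id]
        true_counts[probe_id] = int(k)
        flag = False
        for _ in range(int(k)):
            left = (chrom, max(0, p0 - int(rng.integers(50, 400))),
                    p0 + int(rng.integers(50, 400)))
            if len(prom_windows) and rng.random() < 0.5:
                partner = prom_windows[int(rng.integers(0, len(prom_windows)))]
            else:
                start = int(rng.integers(0, config.chrom_lengths[chrom] - 5_000))
                partner = (chrom, start, start + int(rng.integers(500, 4_000)))
            hits_prom = any(
                partner[0] == c and partner[1] < e and s < partner[2]
                for c, s, e in prom_windows
            )
            flag = flag or hits_prom
            anchor_rows.append(left + partner + (f"INT{ai:05d}", 1))
            ai += 1
        true_prom_flag[probe_id] = flag
    anchors = pd.DataFrame(
        anchor_rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"],
    )
    # probe positions to avoid when placing decoy anchors
    occupied = {(c, p) for c, p in probe_pos0.values()}
    decoys = []
    for _ in range(20):
        chrom = list(config.chrom_lengths)[0]
        length = config.chrom_lengths[chrom]
        s1 = int(rng.integers(0, length - 10_000))
        s2 = int(rng.integers(0, length - 10_000))
        a = (chrom, s1, s1 + 300, chrom, s2, s2 + 300, f"INT{ai:05d}", 1)
        ai += 1
        if not any(c == chrom and s1 <= p < s1 + 300 or s2 <= p < s2 + 300
                   for c, p in occupied):
            decoys.append(a)
    if decoys:
        anchors = pd.concat(
            [anchors, pd.DataFrame(decoys, columns=anchors.columns)], ignore_index=True
        )

    # --- enhancer intervals (FANTOM-like BED3) ---
    enh_rows = []
    true_enh = set()
    probe_ids = list(probe_pos0)
    chosen = rng.choice(len(probe_ids), size=max(1, len(probe_ids) // 10), replace=False)
    for j in chosen:
        chrom, p0 = probe_pos0[probe_ids[j]]
        enh_rows.append((chrom, max(0, p0 - 200), p0 + 200))
        true_enh.add(probe_ids[j])
    for _ in range(15):
        chrom = list(config.chrom_lengths)[0]
        s = int(rng.integers(0, config.chrom_lengths[chrom] - 2_000))
        if not any(c == chrom and s <= p < s + 400 for c, p in probe_pos0.values()):
            enh_rows.append((chrom, s, s + 400))
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end"])

    return AnnotationSet(
        genes=genes, states=states, anchors=anchors, enhancers=enhancers,
        true_region_class=true_region, true_states=true_states,
        true_interaction_counts=true_counts,
        true_promoter_interaction=true_prom_flag,
        true_enhancer_members=true_enh,
    )


def simulate_dataset(config: SimulationConfig, annotation: bool = True) -> SimulatedDataset:
    """Generate the full cohort: covariates, genotypes, methylation, truth,
    and (optionally) annotation fixtures."""
    covariates = gen_samples(config)
    genotypes, latent = gen_genotypes(config, return_latent=True)
    beta, detection_p, truth = gen_methylation(config, covariates, genotypes, latent)
    annot = gen_annotation(config) if annotation else None
    return SimulatedDataset(
        config=config, covariates=covariates, genotypes=genotypes,
        beta=beta, detection_p=detection_p, truth=truth, annotation=annot,
    )


def _reference_offsets(n_cell_types: int, which: int) -> tuple:
    """Two-contrast offset design for cell-type discriminating probes.

    Even panel probes contrast myeloid (granulocyte, monocyte) against
    lymphoid types; odd probes contrast T cells against B/NK. The +/-4
    M-unit swing corresponds to near-fully-methylated vs near-unmethylated
    beta values, as observed at real discriminating CpGs.
    """
    o = np.zeros(n_cell_types)
    if which % 2 == 0:
        o[[0, 5]] = 4.0   # granulocyte, monocyte
        o[[1, 2, 3, 4]] = -4.0
    else:
        o[[1, 2]] = 4.0   # CD4 T, CD8 T
        o[[3, 4]] = -4.0  # B, NK
    return tuple(o)


def blood_config(
    n_samples: int = 350,
    n_snps: int = 52,
    probes_per_snp: int = 160,
    n_reference_probes: int = 43,
    effects: Mapping | None = None,
    noise_sd: float = 0.25,
    maf_range: tuple = (0.1, 0.5),
    window: int = 500_000,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """Default blood-like discovery-cohort configuration.

    SNPs are spaced 1.2 Mb apart on one synthetic chromosome with
    ``probes_per_snp`` CpGs scattered within +/-``window`` of each; the
    reference panel sits beyond the last cis window. ``effects`` maps
    (snp_index, probe_offset) or (snp_id, probe_id) to delta in M units.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    snp_spacing = 1_200_000
    snps = []
    for i in range(n_snps):
        pos = 600_000 + i * snp_spacing
        maf = float(rng.uniform(*maf_range))
        snps.append(SnpSpec(f"rs{i + 1:04d}", "chr1", pos, "A", round(maf, 3)))
    probes = []
    covariate_effects = {}
    for i, s in enumerate(snps):
        offs = rng.integers(-window, window + 1, size=probes_per_snp)
        for j, off in enumerate(sorted(set(int(o) for o in offs))[:probes_per_snp]):
            pid = f"cg{i:03d}{j:04d}"
            base = float(rng.normal(0.0, 2.0))
            probes.append(ProbeSpec(pid, "chr1", max(1, s.pos + off), base))
            covariate_effects[pid] = (
                float(rng.normal(0.0, 0.10)),
                float(rng.normal(0.0, 0.005)),
                float(rng.normal(0.0, 0.05)),
            )
    ref_start = 600_000 + n_snps * snp_spacing + 1_000_000
    n_ct = len(BLOOD_CELL_TYPES)
    ref_ids = []
    for r in range(n_reference_probes):
        pid = f"cgREF{r:03d}"
        ref_ids.append(pid)
        probes.append(
            ProbeSpec(pid, "chr1", ref_start + r * 1_000, 0.0, _reference_offsets(n_ct, r))
        )
    effect_specs = {}
    if effects:
        for key, delta in effects.items():
            if isinstance(key[0], int):
                snp_id = snps[key[0]].snp_id
                probe_id = f"cg{key[0]:03d}{key[1]:04d}"
            else:
                snp_id, probe_id = key
            effect_specs[(snp_id, probe_id)] = float(delta)
    length = ref_start + n_reference_probes * 1_000 + 1_000_000
    return SimulationConfig(
        n_samples=n_samples,
        snp_specs=tuple(snps),
        probe_specs=tuple(probes),
        effect_specs=effect_specs,
        covariate_effects=covariate_effects,
        noise_sd=noise_sd,
        reference_probe_ids=tuple(ref_ids),
        missing_rate=missing_rate,
        chrom_lengths={"chr1": int(length)},
        seed=seed,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> dict:
    """Write all tables in plain-text formats; returns a path manifest."""
    from . import io as _io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["covariates"] = _io.write_tsv(dataset.covariates, out / "covariates.tsv")
    paths["genotypes"] = _io.write_tsv(dataset.genotypes, out / "genotypes.tsv", na_rep="NA")
    paths["beta"] = _io.write_tsv(dataset.beta, out / "beta.tsv")
    paths["detection_p"] = _io.write_tsv(dataset.detection_p, out / "detection_p.tsv")
    paths["snp_manifest"] = _io.write_tsv(
        dataset.config.snp_manifest(), out / "snp_manifest.tsv", index=False
    )
    paths["probe_manifest"] = _io.write_tsv(
        dataset.config.probe_manifest(), out / "probe_manifest.tsv", index=False
    )
    if dataset.annotation is not None:
        ann = dataset.annotation
        paths["genes"] = _io.write_bed(ann.genes, out / "genes.bed")
        for tissue, df in ann.states.items():
            paths[f"states_{tissue}"] = _io.write_bed(df, out / f"states_{tissue}.bed")
        paths["interactions"] = _io.write_bedpe(ann.anchors, out / "interactions.bedpe")
        paths["enhancers"] = _io.write_bed(ann.enhancers, out / "enhancers.bed")
    truth_payload = {
        "true_effects": {f"{k[0]}|{k[1]}": v for k, v in dataset.truth.true_effects.items()},
        "reference_probe_ids": list(dataset.truth.reference_probe_ids),
        "true_compositions": {
            sid: row.tolist()
            for sid, row in dataset.truth.true_compositions.iterrows()
        },
        "cell_types": list(dataset.config.cell_types),
    }
    if dataset.annotation is not None:
        truth_payload["true_region_class"] = dataset.annotation.true_region_class
        truth_payload["true_interaction_counts"] = dataset.annotation.true_interaction_counts
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth_payload, indent=1))
    paths["ground_truth"] = str(truth_path)
    config_path = out / "config_echo.json"
    config_path.write_text(json.dumps(_config_to_jsonable(dataset.config), indent=1))
    paths["config"] = str(config_path)
    return paths


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["effect_specs"] = {f"{k[0]}|{k[1]}": v for k, v in config.effect_specs.items()}
    d["covariate_effects"] = {k: list(v) for k, v in config.covariate_effects.items()}
    d["chrom_lengths"] = dict(config.chrom_lengths)
    return d
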