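"""Pipeline orchestration: simulate -> preprocess -> scan -> annotate ->
enrich -> power, with a YAML configuration, a run manifest, and a per-SNP
report.

Every run is stamped with a hash of its configuration; rerunning the same
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .annotate import (
    assign_states,
    classify_regions,
    count_interactions_table,
    fisher_enrichment,
    membership_flags,
)
from .exceptions import ConfigurationError, DomainError
from .power import power_from_r2
from .preprocess import (
    CellCompositionSurrogate,
    ProbeFilter,
    ReferenceRangeSelector,
    beta_to_m,
    exclude_outlier_samples,
    pca,
)
from .scan import CisMeQTLScanner, pair_cis
from .simulate import blood_config, simulate_dataset

__all__ = ["load_config", "config_hash", "run_pipeline", "render_report", "RunResult"]


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Packaged defaults, optionally updated from a YAML file and overrides."""
    with resources.files("meqtlscan.config").joinpath("defaults.yaml").open() as fh:
        config = yaml.safe_load(fh)
    for source in (path and yaml.safe_load(Path(path).read_text()), overrides):
        if source:
            _deep_update(config, source)
    _validate_config(config)
    return config


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _validate_config(config: dict) -> None:
    checks = [
        ("window", lambda v: v > 0),
        ("detection_min_fraction", lambda v: 0 < v <= 1),
        ("detection_p_threshold", lambda v: 0 < v < 1),
        ("reference_range_min", lambda v: 0 <= v <= 1),
        ("outlier_n_pcs", lambda v: v >= 1),
        ("outlier_z_threshold", lambda v: v > 0),
        ("min_homozygote_count", lambda v: v >= 0),
        ("q_threshold", lambda v: 0 < v < 1),
        ("promoter_window", lambda v: v >= 0),
    ]
    for key, ok in checks:
        if key not in config or not ok(config[key]):
            raise ConfigurationError(f"config key {key!r} missing or out of range")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class RunResult:
    config: dict
    run_id: str
    dataset: object
    m_matrix: pd.DataFrame
    surrogate_scores: pd.DataFrame
    results: pd.DataFrame
    significant: pd.DataFrame
    annotations: pd.DataFrame
    enrichments: dict
    power_table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: dict, out_dir=None) -> RunResult:
    """Execute the full stage sequence and write all stage tables."""
    run_id = config_hash(config)
    out = _io.ensure_dir(out_dir or config["output_dir"])

    # --- stage: simulate (or load) ---
    sim = config.get("simulate", {})
    if sim.get("enabled", False):
        effects = {
            tuple(k.split("|")): float(v) for k, v in (sim.get("effects") or {}).items()
        }
        scfg = blood_config(
            n_samples=sim["n_samples"], n_snps=sim["n_snps"],
            probes_per_snp=sim["probes_per_snp"],
            n_reference_probes=sim["n_reference_probes"],
            effects=effects, noise_sd=sim["noise_sd"],
            seed=int(config.get("seed", sim.get("seed", 0))),
        )
        dataset = simulate_dataset(scfg)
        covariates, genotypes = dataset.covariates, dataset.genotypes
        beta, detection_p = dataset.beta, dataset.detection_p
        snp_manifest = scfg.snp_manifest()
        probe_manifest = scfg.probe_manifest()
        reference_probes = list(scfg.reference_probe_ids)
        annotation = dataset.annotation
    else:
        paths = config["paths"]
        for key in ("covariates", "genotypes", "beta", "snp_manifest", "probe_manifest"):
            if not paths.get(key):
                raise ConfigurationError(f"paths.{key} is required when simulate is disabled")
        dataset = None
        covariates = _io.read_matrix_tsv(paths["covariates"])
        genotypes = _io.read_matrix_tsv(paths["genotypes"])
        beta = _io.read_matrix_tsv(paths["beta"])
        detection_p = (
            _io.read_matrix_tsv(paths["detection_p"]) if paths.get("detection_p") else None
        )
        snp_manifest = _io.read_table_tsv(paths["snp_manifest"])
        probe_manifest = _io.read_table_tsv(paths["probe_manifest"])
        reference_probes = (
            Path(paths["reference_probes"]).read_text().split()
            if paths.get("reference_probes") else []
        )
        annotation = _load_annotation(paths)

    # --- stage: preprocess ---
    pf = ProbeFilter(config["detection_min_fraction"], config["detection_p_threshold"])
    pf.fit(beta, detection_p=detection_p)
    beta_f = pf.transform(beta)
    m_all = beta_to_m(beta_f)

    variable = ReferenceRangeSelector(config["reference_range_min"]).fit(beta_f)
    m_variable = m_all.loc[:, m_all.columns.intersection(variable.keep_)]
    n_pcs = min(config["outlier_n_pcs"], min(m_variable.shape) - 1)
    scores = pca(m_variable, n_components=n_pcs).scores
    retained, outlier_report = exclude_outlier_samples(
        scores, n_pcs=n_pcs, z_threshold=config["outlier_z_threshold"]
    )
    m_qc = m_all.loc[retained]
    covariates_qc = covariates.loc[retained]
    genotypes_qc = genotypes.loc[retained]

    surrogate_est = CellCompositionSurrogate(tuple(reference_probes)).fit(m_qc)
    surrogate = surrogate_est.result_

    # --- stage: scan ---
    scanner = CisMeQTLScanner(
        window=config["window"], q_threshold=config["q_threshold"],
        min_homozygote_count=config["min_homozygote_count"],
    )
    scan_probe_manifest = probe_manifest[
        probe_manifest["probe_id"].isin(m_qc.columns)
        & ~probe_manifest["probe_id"].isin(reference_probes)
    ]
    scanner.fit(
        m_qc, genotypes_qc, covariates=covariates_qc, surrogate=surrogate,
        snp_manifest=snp_manifest, probe_manifest=scan_probe_manifest,
    )
    results, significant = scanner.results_, scanner.significant_

    # --- stage: annotate + enrich ---
    tested_ids = sorted(set(results["probe_id"]))
    tested_manifest = probe_manifest[probe_manifest["probe_id"].isin(tested_ids)]
    annotations = pd.DataFrame(index=tested_manifest["probe_id"])
    enrichments = {}
    assoc = set(significant["probe_id"])
    if annotation is not None:
        region = classify_regions(tested_manifest, annotation.genes,
                                  config["promoter_window"])
        annotations["region_class"] = region
        states = assign_states(tested_manifest, annotation.states)
        annotations = annotations.join(states.add_prefix("state_"))
        inter = count_interactions_table(tested_manifest, annotation.anchors,
                                         annotation.genes, config["promoter_window"])
        annotations = annotations.join(inter)
        enh = membership_flags(tested_manifest, annotation.enhancers)
        annotations["in_enhancer"] = enh
        if assoc:
            region_membership = {
                cls: set(region.index[region == cls]) for cls in region.unique()
            }
            enrichments["genomic"] = fisher_enrichment(assoc, set(tested_ids),
                                                       region_membership)
            state_membership = {
                (tissue, cat): set(states.index[states[tissue] == cat])
                for tissue in states.columns
                for cat in states[tissue].unique()
            }
            enrichments["states"] = fisher_enrichment(assoc, set(tested_ids),
                                                      state_membership)
            enrichments["enhancers"] = fisher_enrichment(
                assoc, set(tested_ids), {"enhancer": set(enh.index[enh])}
            )

    # --- stage: power ---
    alpha = config.get("power_alpha", 0.05)
    n_terms = 6  # sex, age, weight, PC1, PC2, genotype
    power_rows = [
        {
            "snp_id": r["snp_id"], "probe_id": r["probe_id"],
            "partial_r2": r["partial_r2"],
            "power": power_from_r2(min(r["partial_r2"], 1 - 1e-12), int(r["n_used"]),
                                   n_terms, alpha),
        }
        for _, r in significant.iterrows()
    ]
    power_table = pd.DataFrame(power_rows,
                               columns=["snp_id", "probe_id", "partial_r2", "power"])

    for df in (results, significant, annotations, power_table):
        df.attrs["run_id"] = run_id
    for df in enrichments.values():
        df.attrs["run_id"] = run_id

    manifest = {
        "run_id": run_id,
        "parameters": {k: config[k] for k, _ in [
            ("window", 0), ("detection_min_fraction", 0), ("detection_p_threshold", 0),
            ("reference_range_min", 0), ("outlier_n_pcs", 0), ("outlier_z_threshold", 0),
            ("min_homozygote_count", 0), ("q_threshold", 0), ("promoter_window", 0),
        ]},
        "n_samples_retained": len(retained),
        "sample_exclusion": {k: v for k, v in outlier_report.items() if k != "excluded"},
        "probe_filter": pf.report_,
        "n_pairs_tested": len(results),
        "n_significant": len(significant),
        "pi0": scanner.pi0_,
        "surrogate_variance_explained": [float(v) for v in surrogate.variance_explained],
        "outputs": {},
    }
    outputs = {
        "scan_results": _io.write_tsv(results, out / "scan_results.tsv", index=False),
        "significant": _io.write_tsv(significant, out / "significant.tsv", index=False),
        "annotations": _io.write_tsv(annotations, out / "annotations.tsv"),
        "power": _io.write_tsv(power_table, out / "power.tsv", index=False),
    }
    for family, df in enrichments.items():
        outputs[f"enrichment_{family}"] = _io.write_tsv(
            df, out / f"enrichment_{family}.tsv", index=False
        )
    manifest["outputs"] = outputs
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    return RunResult(
        config=config, run_id=run_id, dataset=dataset, m_matrix=m_qc,
        surrogate_scores=surrogate.frame(), results=results, significant=significant,
        annotations=annotations, enrichments=enrichments, power_table=power_table,
        manifest=manifest,
    )


def _load_annotation(paths: dict):
    if not paths.get("genes"):
        return None
    from .simulate import AnnotationSet

    states = {t: _io.read_bed(p) for t, p in (paths.get("states") or {}).items()}
    return AnnotationSet(
        genes=_io.read_bed(paths["genes"]),
        states=states,
        anchors=_io.read_bedpe(paths["interactions"]) if paths.get("interactions")
        else pd.DataFrame(columns=_io.BEDPE_COLUMNS),
        enhancers=_io.read_bed(paths["enhancers"]) if paths.get("enhancers")
        else pd.DataFrame(columns=_io.BED3_COLUMNS),
        true_region_class={}, true_states={}, true_interaction_counts={},
        true_promoter_interaction={}, true_enhancer_members=set(),
    )


def render_report(results: pd.DataFrame, annotations: pd.DataFrame,
                  enrichments: dict, significant: pd.DataFrame | None = None,
                  q_threshold: float = 0.05) -> str:
    """Markdown per-SNP summary of a finished run.

    All inputs must come from the same run (checked via the ``run_id``
    stamped in each table's attrs when present).
    """
    ids = {df.attrs.get("run_id") for df in [results, annotations, *enrichments.values()]
           if df.attrs.get("run_id") is not None}
    if len(ids) > 1:
        raise DomainError(f"inputs come from different runs: {sorted(ids)}")
    if significant is None:
        significant = results[results["q"] < q_threshold]
    lines = ["# cis-meQTL scan report", ""]
    lines.append(f"Tested pairs: {len(results)}; significant (q < {q_threshold}): "
                 f"{len(significant)} at {significant['snp_id'].nunique()} SNPs.")
    lines.append("")
    for family, df in enrichments.items():
        hits = df[df["q"] < q_threshold]
        lines.append(f"Enrichment family `{family}`: {len(hits)} of {len(df)} "
                     f"categories at q < {q_threshold}.")
    lines.append("")
    state_cols = [c for c in annotations.columns if c.startswith("state_")]
    for snp_id, grp in results.groupby("snp_id"):
        sig = significant[significant["snp_id"] == snp_id]
        lines.append(f"## {snp_id}")
        if sig.empty:
            lines.append("Associated CpGs: none")
            lines.append("")
            continue
        med = float(sig["distance"].median())
        lines.append(f"Associated CpGs: {len(sig)} of {len(grp)} tested "
                     f"(median distance {med:.0f} bp)")
        for _, r in sig.iterrows():
            parts = [f"- {r['probe_id']}: distance {int(r['distance'])} bp, "
                     f"coef {r['coef']:+.3f} M/allele, q {r['q']:.2e}"]
            if r["probe_id"] in annotations.index:
                ann = annotations.loc[r["probe_id"]]
                if "region_class" in ann:
                    parts.append(f"class {ann['region_class']}")
                if state_cols:
                    states = ", ".join(
                        f"{c[len('state_'):]}:{ann[c]}" for c in state_cols
                    )
                    parts.append(f"states [{states}]")
                if "interaction_count" in ann:
                    parts.append(f"interactions {int(ann['interaction_count'])}")
            lines.append("; ".join(parts))
        lines.append("")
    return "\n".join(lines)
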