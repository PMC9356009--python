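"""File formats, configuration and the end-to-end pipeline driver.

The canonical cytokine exchange format is a long (tidy) TSV with header
``child_id, batch, viability_pct, stimulus, cytokine, concentration_pg_ml,
lod_pg_ml`` — one row per well, empty concentration meaning missing.
Genotypes travel as VCF v4.2 with a DS (dosage) FORMAT field and an INFO
key ``INFO`` carrying the imputation info score.  The pipeline runs the
stages in study order (flooring, sample QC, batch adjustment, media
normalization, induction testing, PPCA imputation for the clustering path,
unfolding + PCA, multiscale-bootstrap clustering, cQTL scan and phenotype
association) and writes a manifest of every artifact.

Seeding: one master seed; each stage uses ``default_rng([master, counter])``
with a fixed per-stage counter, so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import cqtl, ppca, qc, views
from .containers import ResponseTensor
from .cqtl import GenotypeSet
from .panels import (
    CytokinePanel,
    StimulusPanel,
    default_cytokine_panel,
    default_specificity_groups,
    default_stimulus_panel,
)
from .synth import SimConfig, derive_gina_step, generate_cohort

logger = logging.getLogger("cytoarch")

CYTOKINE_TSV_COLUMNS = [
    "child_id",
    "batch",
    "viability_pct",
    "stimulus",
    "cytokine",
    "concentration_pg_ml",
    "lod_pg_ml",
]

STAGE_SEEDS = {
    "simulate": 0,
    "impute": 10,
    "cluster_stimuli": 11,
    "cluster_cytokines": 12,
    "validation": 13,
}


def write_cytokine_table(tensor: ResponseTensor, path) -> None:
    rows = []
    for i, child in enumerate(tensor.children):
        b = int(tensor.batch[i])
        for k, cyto in enumerate(tensor.cytokines):
            lod = tensor.cytokine_panel.lod(cyto, b)
            for s, stim in enumerate(tensor.stimuli):
                v = tensor.values[i, k, s]
                rows.append(
                    (
                        child,
                        b,
                        tensor.viability[i],
                        stim,
                        cyto,
                        "" if np.isnan(v) else repr(float(v)),
                        lod,
                    )
                )
    df = pd.DataFrame(rows, columns=CYTOKINE_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cytokine_table(
    path,
    stimulus_panel: StimulusPanel | None = None,
    cytokine_panel: CytokinePanel | None = None,
) -> ResponseTensor:
    """Load a long-format cytokine TSV into a response tensor.

    Duplicate (child, stimulus, cytokine) rows and names unknown to the
    panels are rejected.
    """
    sp = stimulus_panel or default_stimulus_panel()
    cp = cytokine_panel or default_cytokine_panel()
    df = pd.read_csv(
        path, sep="\t", dtype={"child_id": str}, float_precision="round_trip"
    )
    if list(df.columns) != CYTOKINE_TSV_COLUMNS:
        raise ValueError(
            f"malformed header: expected {CYTOKINE_TSV_COLUMNS}, got {list(df.columns)}"
        )
    dup = df.duplicated(subset=["child_id", "stimulus", "cytokine"], keep=False)
    if dup.any():
        first = df.loc[dup, ["child_id", "stimulus", "cytokine"]].iloc[0]
        raise ValueError(
            "duplicate row for (child, stimulus, cytokine) = "
            f"({first['child_id']}, {first['stimulus']}, {first['cytokine']})"
        )
    unknown_s = set(df["stimulus"]) - set(sp.names)
    unknown_c = set(df["cytokine"]) - set(cp.names)
    if unknown_s or unknown_c:
        raise ValueError(f"unknown names: stimuli {unknown_s}, cytokines {unknown_c}")
    if (df["concentration_pg_ml"].dropna() < 0).any():
        raise ValueError("negative concentrations")
    children = list(dict.fromkeys(df["child_id"]))
    stims = [e.name for e in sp.by_rank()]
    cytos = cp.names
    values = np.full((len(children), len(cytos), len(stims)), np.nan)
    c_idx = {c: i for i, c in enumerate(children)}
    k_idx = {c: i for i, c in enumerate(cytos)}
    s_idx = {s: i for i, s in enumerate(stims)}
    conc = df["concentration_pg_ml"].to_numpy(dtype=float)
    ii = df["child_id"].map(c_idx).to_numpy()
    kk = df["cytokine"].map(k_idx).to_numpy()
    ss = df["stimulus"].map(s_idx).to_numpy()
    values[ii, kk, ss] = conc
    meta = df.drop_duplicates("child_id").set_index("child_id")
    batch = meta.loc[children, "batch"].to_numpy(dtype=int)
    viability = meta.loc[children, "viability_pct"].to_numpy(dtype=float)
    return ResponseTensor(values, children, batch, viability, sp, cp)


def wide_to_long(
    wide: pd.DataFrame,
    batch: pd.Series,
    viability: pd.Series,
    cytokine_panel: CytokinePanel | None = None,
) -> pd.DataFrame:
    """Convert a wide plate layout to the canonical long format.

    ``wide`` is indexed by (child_id, stimulus) with one column per
    cytokine; ``batch`` and ``viability`` are per-child.  Missingness in the
    long output is encoded by empty concentration fields on write, which is
    why the long layout is canonical.
    """
    cp = cytokine_panel or default_cytokine_panel()
    long = (
        wide.stack(future_stack=True)
        .rename("concentration_pg_ml")
        .reset_index()
    )
    long.columns = ["child_id", "stimulus", "cytokine", "concentration_pg_ml"]
    long["batch"] = long["child_id"].map(batch)
    long["viability_pct"] = long["child_id"].map(viability)
    long["lod_pg_ml"] = [
        cp.lod(c, int(b)) for c, b in zip(long["cytokine"], long["batch"])
    ]
    return long[CYTOKINE_TSV_COLUMNS]


def write_vcf(genotypes: GenotypeSet, path) -> None:
    """Write a minimal VCF v4.2 with per-child DS dosages."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Minor allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.children)
            + "\n"
        )
        for i in range(genotypes.n_snps):
            info = []
            if np.isfinite(genotypes.info[i]):
                info.append(f"INFO={genotypes.info[i]:.4f}")
            if genotypes.typed[i]:
                info.append("TYPED")
            ds = "\t".join(
                "." if np.isnan(v) else f"{v:.3f}" for v in genotypes.dosage[i]
            )
            fh.write(
                f"{genotypes.chrom[i]}\t{genotypes.pos[i]}\t{genotypes.ids[i]}\t"
                f"{genotypes.ref[i]}\t{genotypes.alt[i]}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tDS\t{ds}\n"
            )


def read_vcf(path, info_sidecar=None) -> GenotypeSet:
    """Read genotypes from VCF v4.2: DS dosages preferred, else GT as 0/1/2.

    Info scores come from the INFO field key ``INFO`` or, if absent, from a
    sidecar TSV with columns (snp, info).
    """
    from cyvcf2 import VCF

    sidecar = {}
    if info_sidecar is not None:
        sc = pd.read_csv(info_sidecar, sep="\t")
        sidecar = dict(zip(sc["snp"], sc["info"]))
    vcf = VCF(str(path))
    children = list(vcf.samples)
    ids, chrom, pos, ref, alt = [], [], [], [], []
    dosages, infos, typed = [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
        ds = var.format("DS")
        if ds is not None:
            row = ds[:, 0].astype(float)
            row[row < 0] = np.nan
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            row = np.where((gt < 0).any(axis=1), np.nan, gt.clip(0).sum(axis=1)).astype(
                float
            )
        dosages.append(row)
        inf = var.INFO.get("INFO")
        if inf is None:
            inf = sidecar.get(ids[-1], np.nan)
        infos.append(float(inf) if inf is not None else np.nan)
        typed.append(var.INFO.get("TYPED") is not None)
    dosage = np.array(dosages)
    freq = np.nanmean(dosage, axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    call_rate = 1.0 - np.isnan(dosage).mean(axis=1)
    hwe = np.array(
        [
            cqtl.hwe_test(
                int(np.nansum(np.round(d) == 0)),
                int(np.nansum(np.round(d) == 1)),
                int(np.nansum(np.round(d) == 2)),
            )
            for d in dosage
        ]
    )
    return GenotypeSet(
        ids=ids,
        chrom=chrom,
        pos=np.array(pos),
        ref=ref,
        alt=alt,
        dosage=dosage,
        children=children,
        call_rate=call_rate,
        info=np.array(infos),
        maf=maf,
        hwe_p=hwe,
        typed=np.array(typed, dtype=bool),
    )


@dataclass
class PipelineConfig:
    """Run-level settings; defaults follow the study conditions."""

    out_dir: str = "cytoarch_out"
    seed: int = 0
    cytokine_table: str | None = None  # None -> simulate
    vcf: str | None = None
    n_children: int = 340
    n_null_snps: int = 2000
    stimulus_exclusions: list[str] = field(default_factory=lambda: ["polyIC"])
    extra_exclusions: dict[str, str] = field(default_factory=dict)
    k_candidates: list[int] | None = None
    ppca_tol: float = 1e-6
    ppca_restarts: int = 3
    n_boot: int = 1000
    scales: list[float] = field(default_factory=lambda: list(cl.DEFAULT_SCALES))
    gwas_threshold: float = 5e-8
    scan_cytokine: str = "IL6"
    scan_stimulus_group: str = "bacterial"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_timings: dict[str, float]
    input_counts: dict[str, int]
    artifacts: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis in study order and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: list[str] = []
    counts: dict[str, int] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts.append(name)

    extra_exclusions = dict(config.extra_exclusions)
    with stage("load"):
        if config.cytokine_table is None:
            sim = SimConfig(
                n_children=config.n_children,
                batch_sizes=(
                    max(1, round(config.n_children * 54 / 340)),
                    config.n_children - max(1, round(config.n_children * 54 / 340)),
                ),
                seed=config.seed,
                n_null_snps=config.n_null_snps,
            )
            tensor, genotypes, clinical, truth = generate_cohort(sim)
            emit("cytokine_table.tsv", lambda p: write_cytokine_table(tensor, p))
            emit("genotypes.vcf", lambda p: write_vcf(genotypes, p))
            from .synth import truth_to_yaml

            emit("truth_model.yaml", lambda p: truth_to_yaml(truth, p))
            for child in tensor.meta.get("planted_nonresponder", []):
                extra_exclusions.setdefault(child, "no cytokine response to any stimulus")
        else:
            tensor = read_cytokine_table(config.cytokine_table)
            genotypes = read_vcf(config.vcf) if config.vcf else None
            clinical = None
        counts["children_input"] = tensor.n_children

    with stage("qc"):
        tensor = qc.floor_tensor_to_lod(tensor)
        tensor, report = qc.apply_sample_exclusions(tensor, extra_exclusions)
        for cid in report.excluded_low_viability:
            logger.info("excluded %s: viability below threshold", cid)
        for cid in report.excluded_inadequate:
            logger.info("excluded %s: inadequate responder", cid)
        for cid, reason in report.excluded_other.items():
            logger.info("excluded %s: %s", cid, reason)
        logger.info("sample QC: %s", report.summary())
        counts.update({f"qc_{k}": v for k, v in report.summary().items()})
        emit(
            "qc_report.tsv",
            lambda p: pd.DataFrame(
                [
                    {"child": c, "status": status}
                    for status, cs in [
                        ("low_viability", report.excluded_low_viability),
                        ("inadequate", report.excluded_inadequate),
                        ("other", list(report.excluded_other)),
                        ("retained", report.retained),
                    ]
                    for c in cs
                ]
            ).to_csv(p, sep="\t", index=False),
        )
        diag = qc.viability_diagnostics(tensor)
        logger.info("viability ~ batch p = %.3f", diag["viability_batch_p"])

    with stage("batch_adjust"):
        batch_model = qc.estimate_batch_model(tensor)
        tensor = qc.adjust_batch(tensor, batch_model)
        emit(
            "batch_coefficients.tsv",
            lambda p: batch_model.coefficient.stack()
            .rename("coefficient")
            .to_csv(p, sep="\t"),
        )

    with stage("normalize"):
        folds = qc.media_normalize(tensor)
        counts["fold_pairs"] = folds.shape[1]
        emit("fold_matrix.tsv", lambda p: folds.to_csv(p, sep="\t"))

    with stage("induction_tests"):
        # the media column is the reference, not a tested stimulus
        alpha = qc.bonferroni_alpha(len(tensor.cytokines), len(tensor.stimuli) - 1)
        induction = qc.test_induction(folds, alpha)
        counts["significant_pairs"] = int(induction["significant"].sum())
        emit("induction_tests.tsv", lambda p: induction.to_csv(p, sep="\t", index=False))

    with stage("impute"):
        analysis_folds = folds.drop(
            columns=config.stimulus_exclusions, level="stimulus", errors="ignore"
        )
        # children with no media reference (or no wells at all) have no fold
        # observations and cannot enter the imputation/clustering path
        has_data = analysis_folds.notna().any(axis=1)
        if (~has_data).any():
            logger.info(
                "dropping %d children with no observed fold inductions",
                int((~has_data).sum()),
            )
        analysis_folds = analysis_folds.loc[has_data]
        counts["children_clustering"] = int(has_data.sum())
        k_star, evidence = ppca.select_dimensionality(
            analysis_folds.to_numpy(), config.k_candidates
        )
        model = ppca.fit_ppca(
            analysis_folds.to_numpy(),
            k_star,
            seed=int(np.random.default_rng([config.seed, STAGE_SEEDS["impute"]]).integers(2**31)),
            tol=config.ppca_tol,
            n_restarts=config.ppca_restarts,
        )
        completed = pd.DataFrame(
            ppca.impute(analysis_folds.to_numpy(), model),
            index=analysis_folds.index,
            columns=analysis_folds.columns,
        )
        counts["ppca_k"] = k_star
        imputed_mask = analysis_folds.isna()
        long = completed.stack(["cytokine", "stimulus"], future_stack=True).rename(
            "log2_fold"
        )
        long = long.to_frame()
        long["imputed"] = imputed_mask.stack(["cytokine", "stimulus"], future_stack=True)
        emit("imputed_folds.tsv", lambda p: long.to_csv(p, sep="\t"))

    with stage("views_pca"):
        v_cs = views.unfold(completed, "child_stimulus_by_cytokine")
        v_ck = views.unfold(completed, "child_cytokine_by_stimulus")
        pca_cs = views.run_pca(v_cs)
        pca_ck = views.run_pca(v_ck)
        counts["child_cytokine_pc12_pct"] = int(
            round(100 * float(pca_ck.variance_fraction[:2].sum()))
        )
        emit(
            "pca_child_stimulus_scores.tsv",
            lambda p: pca_cs.scores.iloc[:, :5].to_csv(p, sep="\t"),
        )
        emit(
            "pca_child_cytokine_scores.tsv",
            lambda p: pca_ck.scores.iloc[:, :5].to_csv(p, sep="\t"),
        )

    with stage("cluster"):
        seed_s = int(
            np.random.default_rng([config.seed, STAGE_SEEDS["cluster_stimuli"]]).integers(2**31)
        )
        seed_c = int(
            np.random.default_rng([config.seed, STAGE_SEEDS["cluster_cytokines"]]).integers(2**31)
        )
        dend_s, sup_s = cl.pvcluster(
            v_ck.values.to_numpy(),
            n_boot=config.n_boot,
            scales=config.scales,
            seed=seed_s,
            labels=list(v_ck.values.columns),
        )
        dend_c, sup_c = cl.pvcluster(
            v_cs.values.to_numpy(),
            n_boot=config.n_boot,
            scales=config.scales,
            seed=seed_c,
            labels=list(v_cs.values.columns),
        )
        emit("stimulus_tree.nwk", lambda p: Path(p).write_text(cl.to_newick(dend_s, sup_s)))
        emit("cytokine_tree.nwk", lambda p: Path(p).write_text(cl.to_newick(dend_c, sup_c)))
        emit("stimulus_support.tsv", lambda p: sup_s.table(dend_s).to_csv(p, sep="\t", index=False))
        emit("cytokine_support.tsv", lambda p: sup_c.table(dend_c).to_csv(p, sep="\t", index=False))

    scan = None
    if genotypes is not None:
        with stage("cqtl"):
            filtered, removal_log = cqtl.snp_qc(genotypes, "imputed")
            counts["snps_after_qc"] = filtered.n_snps
            stim_panel = tensor.stimulus_panel
            traits = [
                (config.scan_cytokine, s)
                for s in stim_panel.group_members(config.scan_stimulus_group)
            ]
            scan_folds = folds  # non-imputed folds for genetic analysis
            scan = cqtl.genome_scan(scan_folds, filtered, traits, config.gwas_threshold)
            emit("snp_qc_log.tsv", lambda p: removal_log.to_csv(p, sep="\t", index=False))
            emit("cqtl_scan.tsv", lambda p: scan.head(5000).to_csv(p, sep="\t", index=False))
            top = scan.iloc[0]
            if np.isfinite(top["p"]):
                profile = cqtl.specificity_profile(
                    top["snp"],
                    scan_folds.drop(
                        columns=config.stimulus_exclusions,
                        level="stimulus",
                        errors="ignore",
                    ),
                    filtered,
                    default_specificity_groups(stim_panel, top["stimulus"]),
                )
                emit(
                    "specificity_profile.tsv",
                    lambda p: pd.DataFrame(
                        [
                            {"group": g, "n_pairs": len(rs), "nominal_hits": h}
                            for (g, rs), h in zip(
                                profile.results.items(),
                                profile.nominal_hits().values(),
                            )
                        ]
                    ).to_csv(p, sep="\t", index=False),
                )
        if clinical is not None:
            with stage("phenotypes"):
                sig = scan[scan["significant"]]
                snps = list(dict.fromkeys(sig["snp"])) or [scan.iloc[0]["snp"]]
                rec_by_child = {r.child: r for r in clinical}
                rows = []
                for snp in snps[:10]:
                    dose = genotypes.dosage_of(snp)
                    for pheno in ["unscheduled_asthma_visit", "oral_steroid_receipt"]:
                        flags = np.array(
                            [
                                getattr(rec_by_child[c], pheno)
                                for c in genotypes.children
                            ],
                            dtype=float,
                        )
                        res = cqtl.score_test_binary(
                            flags, dose.to_numpy(), snp=snp, trait_name=pheno
                        )
                        rows.append(res)
                    gina = np.array(
                        [
                            derive_gina_step(rec_by_child[c], 8) >= 2
                            for c in genotypes.children
                        ],
                        dtype=float,
                    )
                    rows.append(
                        cqtl.score_test_binary(
                            gina, dose.to_numpy(), snp=snp, trait_name="gina_step2_age8"
                        )
                    )
                emit(
                    "phenotype_assoc.tsv",
                    lambda p: pd.DataFrame(
                        [
                            {
                                "snp": r.snp,
                                "phenotype": r.trait,
                                "beta": r.beta,
                                "se": r.se,
                                "stat": r.stat,
                                "p": r.p,
                                "n": r.n,
                            }
                            for r in rows
                        ]
                    ).to_csv(p, sep="\t", index=False),
                )

    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        stage_timings=timings,
        input_counts=counts,
        artifacts=sorted(set(artifacts)),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
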