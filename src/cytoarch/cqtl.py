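"""Cytokine QTL mapping: SNP/trait QC, additive score tests, scans.

The association model is the classical additive-dosage score test (the
"score method" of standard GWAS software).  For a quantitative trait y and
minor-allele dosage g in [0, 2]:

    U = sum (g_i - gbar)(y_i - ybar)
    V = sigma0^2 * sum (g_i - gbar)^2        (sigma0^2 = null MLE variance)
    p from chi2_1 of U^2 / V
    beta = U / sum (g_i - gbar)^2,  SE = sqrt(sigma0^2 / sum (g-gbar)^2)

For a binary phenotype the logistic null score test is used with
U = sum g_i (y_i - pbar) and V = pbar (1 - pbar) * sum (g - gbar)^2.
Analyses are complete-case: children missing the trait are dropped, no
imputation enters the genetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, kstest

GENOME_WIDE_THRESHOLD = 5e-8

# SNP QC thresholds: directly-genotyped and imputation-derived stages
TYPED_CALL_RATE = 0.95
TYPED_HWE_P = 5.9e-7
TYPED_MAF = 0.005
IMPUTED_INFO = 0.75
IMPUTED_MAF = 0.05


@dataclass
class GenotypeSet:
    """Per-SNP metadata plus a SNP x child minor-allele dosage matrix."""

    ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # 1-based
    ref: list[str]
    alt: list[str]
    dosage: np.ndarray  # (n_snps, n_children), values in [0, 2], NaN missing
    children: list[str]
    call_rate: np.ndarray
    info: np.ndarray  # imputation info score; NaN for typed SNPs
    maf: np.ndarray
    hwe_p: np.ndarray
    typed: np.ndarray  # bool per SNP

    def __post_init__(self) -> None:
        d = self.dosage[~np.isnan(self.dosage)]
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if np.any((self.maf < 0) | (self.maf > 0.5)):
            raise ValueError("MAF must lie in [0, 0.5]")
        if np.any(self.pos <= 0):
            raise ValueError("positions must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.ids)

    def index_of(self, snp_id: str) -> int:
        return self.ids.index(snp_id)

    def dosage_of(self, snp_id: str) -> pd.Series:
        return pd.Series(self.dosage[self.index_of(snp_id)], index=self.children)

    def subset(self, keep: np.ndarray) -> "GenotypeSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        take = lambda xs: [xs[i] for i in keep]  # noqa: E731
        return replace(
            self,
            ids=take(self.ids),
            chrom=take(self.chrom),
            pos=self.pos[keep],
            ref=take(self.ref),
            alt=take(self.alt),
            dosage=self.dosage[keep],
            call_rate=self.call_rate[keep],
            info=self.info[keep],
            maf=self.maf[keep],
            hwe_p=self.hwe_p[keep],
            typed=self.typed[keep],
        )


@dataclass
class AssocResult:
    snp: str
    trait: tuple[str, str] | str
    beta: float
    se: float
    stat: float
    p: float
    n: int
    flagged: str = ""  # non-empty when the test is degenerate


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration (probability ordering, the standard
    exact-HWE convention).
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:  # orient to the rarer allele
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    ok = hom_major >= 0
    hets, hom_minor, hom_major = hets[ok], hom_minor[ok], hom_major[ok]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[np.flatnonzero(hets == n_het)[0]]
    return float(prob[prob <= observed * (1 + 1e-12)].sum())


def snp_qc(genotypes: GenotypeSet, stage: str) -> tuple[GenotypeSet, pd.DataFrame]:
    """Filter SNPs by the stage-appropriate QC rules, logging removals.

    ``typed``: call rate >= 0.95, exact-HWE p > 5.9e-7, MAF > 0.005.
    ``imputed``: info score >= 0.75 and MAF >= 0.05.
    """
    if stage == "typed":
        checks = [
            (genotypes.call_rate >= TYPED_CALL_RATE, "call_rate"),
            (genotypes.hwe_p > TYPED_HWE_P, "hwe"),
            (genotypes.maf > TYPED_MAF, "maf"),
        ]
    elif stage == "imputed":
        checks = [
            (np.nan_to_num(genotypes.info, nan=1.0) >= IMPUTED_INFO, "info"),
            (genotypes.maf >= IMPUTED_MAF, "maf"),
        ]
    else:
        raise ValueError(f"unknown QC stage {stage!r}")
    keep = np.ones(genotypes.n_snps, dtype=bool)
    records = []
    for mask, reason in checks:
        for i in np.flatnonzero(~mask & keep):
            records.append({"snp": genotypes.ids[i], "stage": stage, "reason": reason})
        keep &= mask
    log = pd.DataFrame(records, columns=["snp", "stage", "reason"])
    return genotypes.subset(keep), log


def ks_normality(values: np.ndarray) -> float:
    """Kolmogorov-Smirnov p for the standardized trait against N(0, 1)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise ValueError("at least 10 observations required")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (zero variance) trait")
    return float(kstest((x - x.mean()) / sd, "norm").pvalue)


def _complete_cases(trait, dosage) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(trait, dtype=float)
    g = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    return y[ok], g[ok]


def score_test_additive(
    trait, dosage, snp: str = "", trait_name="", min_n: int = 10
) -> AssocResult:
    """Additive score test of a quantitative trait on minor-allele dosage."""
    y, g = _complete_cases(trait, dosage)
    n = y.size
    if n < min_n:
        return AssocResult(snp, trait_name, np.nan, np.nan, np.nan, np.nan, n, "too_few")
    gc = g - g.mean()
    sgg = float(gc @ gc)
    if sgg == 0:
        return AssocResult(snp, trait_name, np.nan, np.nan, np.nan, np.nan, n, "constant_dosage")
    yc = y - y.mean()
    u = float(gc @ yc)
    sigma0 = float(yc @ yc) / n  # null MLE variance
    if sigma0 == 0:
        return AssocResult(snp, trait_name, 0.0, np.nan, np.nan, np.nan, n, "constant_trait")
    stat = u * u / (sigma0 * sgg)
    return AssocResult(
        snp,
        trait_name,
        beta=u / sgg,
        se=float(np.sqrt(sigma0 / sgg)),
        stat=stat,
        p=float(chi2.sf(stat, 1)),
        n=n,
    )


def score_test_binary(
    case_flags, dosage, snp: str = "", trait_name="", min_n: int = 10
) -> AssocResult:
    """Logistic-null score test of a binary phenotype on dosage."""
    y, g = _complete_cases(case_flags, dosage)
    n = y.size
    if n < min_n:
        return AssocResult(snp, trait_name, np.nan, np.nan, np.nan, np.nan, n, "too_few")
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ValueError("both classes must be present")
    gc = g - g.mean()
    sgg = float(gc @ gc)
    if sgg == 0:
        return AssocResult(snp, trait_name, np.nan, np.nan, np.nan, np.nan, n, "constant_dosage")
    u = float(g @ (y - pbar))
    v = pbar * (1 - pbar) * sgg
    stat = u * u / v
    return AssocResult(
        snp,
        trait_name,
        beta=u / v,  # one-step log-odds approximation
        se=float(1 / np.sqrt(v)),
        stat=stat,
        p=float(chi2.sf(stat, 1)),
        n=n,
    )


def genome_scan(
    folds: pd.DataFrame,
    genotypes: GenotypeSet,
    traits: list[tuple[str, str]],
    threshold: float = GENOME_WIDE_THRESHOLD,
) -> pd.DataFrame:
    """Score-test every SNP against every requested (cytokine, stimulus) trait.

    Runs on media-normalized, non-imputed fold inductions; children missing a
    trait are dropped for that trait only.  Returns a DataFrame sorted by p
    with a ``significant`` flag at ``threshold``.
    """
    if not traits:
        raise ValueError("empty trait list")
    shared = [c for c in genotypes.children if c in folds.index]
    d_all = genotypes.dosage[:, [genotypes.children.index(c) for c in shared]]
    frames = []
    for trait in traits:
        y = folds.loc[shared, trait].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        yv = y[ok]
        n = int(ok.sum())
        g = d_all[:, ok]
        gc = g - g.mean(axis=1, keepdims=True)
        sgg = np.einsum("ij,ij->i", gc, gc)
        yc = yv - yv.mean()
        u = gc @ yc
        sigma0 = float(yc @ yc) / max(n, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(sgg > 0, u * u / (sigma0 * sgg), np.nan)
            beta = np.where(sgg > 0, u / sgg, np.nan)
            se = np.where(sgg > 0, np.sqrt(sigma0 / sgg), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "snp": genotypes.ids,
                    "chrom": genotypes.chrom,
                    "pos": genotypes.pos,
                    "cytokine": trait[0],
                    "stimulus": trait[1],
                    "beta": beta,
                    "se": se,
                    "stat": stat,
                    "p": chi2.sf(stat, 1),
                    "n": n,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["p"] < threshold
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


@dataclass
class SpecificityProfile:
    """Per-group nominal association behaviour of one SNP."""

    snp: str
    results: dict[str, list[AssocResult]]
    nominal_alpha: float = 0.05
    group_sizes: dict[str, int] = field(default_factory=dict)

    def nominal_hits(self) -> dict[str, int]:
        return {
            g: sum(1 for r in rs if np.isfinite(r.p) and r.p < self.nominal_alpha)
            for g, rs in self.results.items()
        }

    def hit_fractions(self) -> dict[str, float]:
        return {
            g: hits / max(len(self.results[g]), 1)
            for g, hits in self.nominal_hits().items()
        }


def specificity_profile(
    snp_id: str,
    folds: pd.DataFrame,
    genotypes: GenotypeSet,
    groups: dict[str, list[tuple[str, str]]],
    nominal_alpha: float = 0.05,
) -> SpecificityProfile:
    """Test one SNP against every pair in each predefined pair group."""
    dosage = genotypes.dosage_of(snp_id).reindex(folds.index)
    results: dict[str, list[AssocResult]] = {}
    for group, pairs in groups.items():
        if not pairs:
            raise ValueError(f"empty specificity group {group!r}")
        results[group] = [
            score_test_additive(folds[pair], dosage, snp=snp_id, trait_name=pair)
            for pair in pairs
        ]
    return SpecificityProfile(
        snp_id,
        results,
        nominal_alpha,
        {g: len(p) for g, p in groups.items()},
    )
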