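"""Sample QC, detection-limit flooring, batch adjustment and fold testing.

The preprocessing chain mirrors a two-batch multiplex immunoassay workflow:

1. sub-LOD wells are recorded as half the per-cytokine per-batch lower
   detection limit (left-censoring convention);
2. children with viability < 5% on thawing are excluded, as are "inadequate
   responders" (viability < 20% AND all four sentinel responses below their
   pg/mL thresholds);
3. a per-(cytokine, stimulus) batch coefficient — the fitted batch-1 offset
   on the log2 scale, with batch 2 as baseline — is estimated and subtracted
   from batch-1 responses, re-flooring any adjusted value that falls below
   the batch-2 LOD;
4. fold induction is the log2 stimulus response minus the log2 media
   response of the same child and cytokine;
5. each pair's mean log2 fold is tested against zero with a right one-sided
   one-sample t-test at a Bonferroni-corrected level alpha = 0.05 / (number
   of pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ResponseTensor, fold_columns

VIABILITY_EXCLUDE = 5.0  # %
VIABILITY_INADEQUATE = 20.0  # %
# sentinel (cytokine, stimulus) responses and pg/mL thresholds for the
# inadequate-responder rule; all must fail jointly
SENTINELS = (
    ("IL2", "PHA", 5.0),
    ("IFNa2", "RSV", 5.0),
    ("IFNg", "RV16", 7.0),
    ("IL6", "Hin", 5.0),
)


def floor_to_lod(value: float, lod: float) -> float:
    """Half-LOD substitution for a single measurement (NaN passes through)."""
    if lod <= 0:
        raise ValueError("lod must be > 0")
    if np.isnan(value) or value >= lod:
        return value
    return lod / 2.0


def floor_tensor_to_lod(tensor: ResponseTensor) -> ResponseTensor:
    """Apply the half-LOD floor to every well, using each child's batch LOD."""
    out = tensor.copy()
    for b in (1, 2):
        lod = out.cytokine_panel.lod_matrix(b)
        sel = out.batch == b
        block = out.values[sel]
        low = block < lod[None, :, None]
        block[low] = np.broadcast_to((lod / 2.0)[None, :, None], block.shape)[low]
        out.values[sel] = block
    return out


@dataclass
class QCReport:
    excluded_low_viability: list[str]
    excluded_inadequate: list[str]
    excluded_other: dict[str, str]  # child -> free-text reason
    retained: list[str]

    def summary(self) -> dict[str, int]:
        return {
            "input": len(self.retained)
            + len(self.excluded_low_viability)
            + len(self.excluded_inadequate)
            + len(self.excluded_other),
            "excluded_low_viability": len(self.excluded_low_viability),
            "excluded_inadequate": len(self.excluded_inadequate),
            "excluded_other": len(self.excluded_other),
            "retained": len(self.retained),
        }


def apply_sample_exclusions(
    tensor: ResponseTensor,
    extra_exclusions: dict[str, str] | None = None,
    viability_exclude: float = VIABILITY_EXCLUDE,
    viability_inadequate: float = VIABILITY_INADEQUATE,
    sentinels=SENTINELS,
) -> tuple[ResponseTensor, QCReport]:
    """Drop low-viability children and inadequate responders.

    A child is an inadequate responder only when viability is below the 20%
    threshold AND every sentinel response is below its threshold (missing
    sentinel wells count as failing, carrying no evidence of response).
    ``extra_exclusions`` removes further children with a free-text reason.
    """
    for cyto, stim, _ in sentinels:
        if cyto not in tensor.cytokines or stim not in tensor.stimuli:
            raise ValueError(f"sentinel pair ({cyto}, {stim}) absent from panels")
    extra = dict(extra_exclusions or {})
    low, inadequate, other, retained = [], [], {}, []
    for i, child in enumerate(tensor.children):
        if child in extra:
            other[child] = extra[child]
            continue
        viab = tensor.viability[i]
        if viab < viability_exclude:
            low.append(child)
            continue
        if viab < viability_inadequate:
            fails = []
            for cyto, stim, threshold in sentinels:
                v = tensor.values[
                    i, tensor.cytokine_index(cyto), tensor.stimulus_index(stim)
                ]
                fails.append(np.isnan(v) or v < threshold)
            if all(fails):
                inadequate.append(child)
                continue
        retained.append(child)
    report = QCReport(low, inadequate, other, retained)
    return tensor.subset_children(retained), report


@dataclass
class BatchModel:
    """Per-pair batch-1 offsets on the log2 scale (batch 2 is baseline)."""

    coefficient: pd.DataFrame  # cytokine x stimulus; NaN where undefined
    se: pd.DataFrame
    n_batch1: pd.DataFrame
    n_batch2: pd.DataFrame
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


def estimate_batch_model(tensor: ResponseTensor, min_per_batch: int = 2) -> BatchModel:
    """Fit the batch-1 offset per (cytokine, stimulus) pair.

    The regression of log2 concentration on a batch indicator with batch 2
    as baseline reduces to the difference of batch means; the standard error
    is the pooled two-sample OLS standard error.  Pairs observed in fewer
    than ``min_per_batch`` children in either batch are flagged undefined
    and later passed through unadjusted.
    """
    log2v = tensor.log2_values()
    b1 = tensor.batch == 1
    b2 = tensor.batch == 2
    x1, x2 = log2v[b1], log2v[b2]
    n1 = np.sum(~np.isnan(x1), axis=0)
    n2 = np.sum(~np.isnan(x2), axis=0)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # sparse pairs legitimately yield NaN here; they are flagged undefined
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(x1, axis=0) if x1.size else np.full(log2v.shape[1:], np.nan)
        m2 = np.nanmean(x2, axis=0) if x2.size else np.full(log2v.shape[1:], np.nan)
        v1 = np.nanvar(x1, axis=0, ddof=1) if x1.size else np.full(log2v.shape[1:], np.nan)
        v2 = np.nanvar(x2, axis=0, ddof=1) if x2.size else np.full(log2v.shape[1:], np.nan)
    coef = m1 - m2
    dof = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(dof > 0, dof, np.nan)
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    defined = (n1 >= min_per_batch) & (n2 >= min_per_batch)
    coef = np.where(defined, coef, np.nan)
    se = np.where(defined, se, np.nan)
    cytos, stims = tensor.cytokines, tensor.stimuli
    undefined = [
        (cytos[k], stims[s])
        for k, s in zip(*np.nonzero(~defined))
    ]
    as_df = lambda a: pd.DataFrame(a, index=cytos, columns=stims)  # noqa: E731
    return BatchModel(
        coefficient=as_df(coef),
        se=as_df(se),
        n_batch1=as_df(n1),
        n_batch2=as_df(n2),
        undefined_pairs=undefined,
    )


def adjust_batch(tensor: ResponseTensor, model: BatchModel) -> ResponseTensor:
    """Subtract the pair coefficient from batch-1 log2 values.

    Batch-2 values are left bit-identical.  Adjusted concentrations that fall
    below the batch-2 LOD are re-floored to half the batch-2 LOD.  Undefined
    pairs pass through unadjusted.
    """
    coef = model.coefficient.reindex(
        index=tensor.cytokines, columns=tensor.stimuli
    ).to_numpy()
    out = tensor.copy()
    b1 = out.batch == 1
    if not b1.any():
        return out
    factor = np.exp2(np.nan_to_num(coef, nan=0.0))
    block = out.values[b1] / factor[None, :, :]
    lod2 = out.cytokine_panel.lod_matrix(2)
    low = block < lod2[None, :, None]
    block[low] = np.broadcast_to((lod2 / 2.0)[None, :, None], block.shape)[low]
    out.values[b1] = block
    return out


def media_normalize(tensor: ResponseTensor) -> pd.DataFrame:
    """Log2 fold-induction matrix: child x (cytokine, stimulus) pairs.

    value(c, k, s) = log2 conc(c, k, s) - log2 conc(c, k, media); NaN when
    either well is missing.  The media column is the reference and is absent
    from the result.
    """
    media = tensor.stimulus_panel.media_name
    log2v = tensor.log2_values()
    m_idx = tensor.stimulus_index(media)
    folds = log2v - log2v[:, :, m_idx][:, :, None]
    stim_keep = [s for s in tensor.stimuli if s != media]
    cols = fold_columns(tensor.cytokines, tensor.stimuli, media)
    data = np.stack(
        [
            folds[:, tensor.cytokine_index(k), tensor.stimulus_index(s)]
            for k, s in cols
        ],
        axis=1,
    )
    assert [s for _, s in cols[: len(stim_keep)]] == stim_keep
    return pd.DataFrame(data, index=list(tensor.children), columns=cols)


def bonferroni_alpha(n_cytokines: int, n_stimuli: int, family_alpha: float = 0.05) -> float:
    """Per-test level for the fold-induction family: alpha / (n_k * n_s)."""
    if n_cytokines < 1 or n_stimuli < 1:
        raise ValueError("counts must be >= 1")
    return family_alpha / (n_cytokines * n_stimuli)


def test_induction(folds: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Right one-sided one-sample t-test of mean log2 fold > 0 per pair.

    Mean fold induction is reported as 2^(mean log2 fold) — the geometric
    mean on the concentration-ratio scale.  Pairs with n < 2 or zero
    variance are flagged untestable rather than significant.
    """
    rows = []
    for pair in folds.columns:
        x = folds[pair].dropna().to_numpy()
        n = x.size
        mean = x.mean() if n else np.nan
        sd = x.std(ddof=1) if n >= 2 else np.nan
        if n >= 2 and sd > 0:
            t = mean / (sd / np.sqrt(n))
            p = float(stats.t.sf(t, df=n - 1))
            untestable = False
        else:
            t, p, untestable = np.nan, np.nan, True
        rows.append(
            {
                "cytokine": pair[0],
                "stimulus": pair[1],
                "n": n,
                "mean_log2_fold": mean,
                "mean_fold": float(np.exp2(mean)) if n else np.nan,
                "t": t,
                "p": p,
                "significant": (not untestable) and p < alpha,
                "untestable": untestable,
            }
        )
    return pd.DataFrame(rows)


def viability_diagnostics(tensor: ResponseTensor) -> dict:
    """Check whether viability tracks batch or any pair's response level.

    Returns the regression p for viability ~ batch and, per (cytokine,
    stimulus) pair, the Pearson r (and p) between log2 response and
    viability.
    """
    if tensor.n_children < 3:
        raise ValueError("at least 3 children required")
    batch_num = (tensor.batch == 1).astype(float)
    if np.ptp(batch_num) > 0:
        fit = stats.linregress(batch_num, tensor.viability)
        batch_p = float(fit.pvalue)
    else:
        batch_p = np.nan
    log2v = tensor.log2_values()
    rows = []
    for k, cyto in enumerate(tensor.cytokines):
        for s, stim in enumerate(tensor.stimuli):
            x = log2v[:, k, s]
            ok = ~np.isnan(x)
            if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(tensor.viability[ok]) > 0:
                r, p = stats.pearsonr(x[ok], tensor.viability[ok])
            else:
                r, p = np.nan, np.nan
            rows.append(
                {"cytokine": cyto, "stimulus": stim, "r": r, "p": p, "n": int(ok.sum())}
            )
    return {"viability_batch_p": batch_p, "response_viability": pd.DataFrame(rows)}
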