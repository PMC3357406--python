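"""Signature evaluation: PCA subtype discrimination and survival screening.

A gene signature is evaluated by fitting principal components on a
training expression matrix (per-gene standardization with training
statistics), projecting samples — possibly from an independent platform —
through the frozen loadings, and measuring how well component 1 separates
the subtypes by ROC AUC.  Genes are screened for survival association by
comparing overall survival between the top and bottom expression tertiles
with a two-sided log-rank test, separately per subtype context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ClinicalTable, ExpressionMatrix
from .stats import logrank_test, roc_auc, roc_points

log = logging.getLogger("lungdiverge")


@dataclass
class PcaSignatureModel:
    """Frozen PCA model: gene order, training centering/scaling, loadings.

    Loadings are unit-norm; the sign convention fixes each component's
    largest-magnitude loading to be positive.
    """

    genes: list[str]
    center: np.ndarray
    scale: np.ndarray | None
    loadings: np.ndarray  # genes x 2 (components 1 and 2)
    training_scores: pd.DataFrame  # samples x (PC1, PC2)


def _collapse_to_genes(expr: ExpressionMatrix, genes: set[str]) -> pd.DataFrame:
    """Mean-collapse probes to gene symbols (upper-cased), keeping only the
    requested genes; first annotation wins on symbol collisions."""
    sym = expr.annotation["symbol"].astype(str).str.upper()
    keep = sym.isin(genes)
    sub = expr.values.loc[keep.to_numpy()]
    return sub.groupby(sym[keep.to_numpy()].to_numpy()).mean()


def fit_pca_signature(
    expr_train: ExpressionMatrix,
    labels: pd.Series,
    genes: list[str],
    standardize: bool = True,
) -> PcaSignatureModel:
    """Fit components 1 and 2 on the signature genes of the training set.

    Per-gene centering (and by default z-scoring) uses training statistics;
    constant genes are dropped with a log message.  Requires at least three
    samples per class and two usable signature genes.
    """
    wanted = {g.upper() for g in genes}
    mat = _collapse_to_genes(expr_train, wanted)
    if labels.value_counts().min() < 3:
        raise ValueError("need at least 3 samples per class")
    sd = mat.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.info("dropping %d constant signature genes", int(constant.sum()))
        mat = mat.loc[~constant.to_numpy()]
        sd = sd[~constant]
    if len(mat) < 2:
        raise ValueError("fewer than 2 usable signature genes in training data")
    center = mat.mean(axis=1).to_numpy()
    scale = sd.to_numpy() if standardize else None
    x = mat.to_numpy(dtype=float) - center[:, None]
    if scale is not None:
        x = x / scale[:, None]
    # SVD of genes x samples: right singular vectors are sample scores
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = u[:, :2].copy()
    # sign convention: largest-magnitude loading positive per component
    for k in range(loadings.shape[1]):
        imax = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[imax, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = x.T @ loadings
    return PcaSignatureModel(
        genes=list(mat.index),
        center=center,
        scale=scale,
        loadings=loadings,
        training_scores=pd.DataFrame(
            scores, index=mat.columns, columns=["PC1", "PC2"]
        ),
    )


def project_samples(
    model: PcaSignatureModel,
    expr_test: ExpressionMatrix,
    min_gene_frac: float = 0.50,
    center_mode: str = "training",
) -> pd.DataFrame:
    """Project test samples through the frozen model loadings.

    ``center_mode='training'`` centers/scales test values with the frozen
    TRAINING statistics (the default; projecting the training set then
    reproduces the training scores exactly).  ``center_mode='test'``
    standardizes each gene with the test set's own statistics, which
    absorbs per-gene platform offsets and is the meaningful choice when
    the test data come from a different array.  Model genes absent from
    the test data are dropped from both loadings and data, with the
    remaining loading sub-vectors renormalized to unit norm; fewer than
    ``min_gene_frac`` shared genes is an error.
    """
    if center_mode not in ("training", "test"):
        raise ValueError(f"unknown center_mode {center_mode!r}")
    mat = _collapse_to_genes(expr_test, set(model.genes))
    present = [i for i, g in enumerate(model.genes) if g in mat.index]
    if len(present) < min_gene_frac * len(model.genes):
        raise ValueError(
            f"only {len(present)}/{len(model.genes)} model genes present in test data"
        )
    if len(present) < len(model.genes):
        log.warning(
            "projecting with %d/%d model genes; loadings renormalized",
            len(present), len(model.genes),
        )
    idx = np.asarray(present)
    genes_present = [model.genes[i] for i in present]
    raw = mat.loc[genes_present].to_numpy(dtype=float)
    if center_mode == "training":
        x = raw - model.center[idx][:, None]
        if model.scale is not None:
            x = x / model.scale[idx][:, None]
    else:
        x = raw - raw.mean(axis=1, keepdims=True)
        if model.scale is not None:
            sd = raw.std(axis=1, ddof=1, keepdims=True)
            sd[sd == 0] = 1.0
            x = x / sd
    loadings = model.loadings[idx, :]
    norms = np.linalg.norm(loadings, axis=0)
    norms[norms == 0] = 1.0
    scores = x.T @ (loadings / norms)
    return pd.DataFrame(scores, index=mat.columns, columns=["PC1", "PC2"])


@dataclass
class SeparationResult:
    auc: float
    polarity: int  # +1 if higher PC1 marks the positive class, else -1
    points: np.ndarray  # (FPR, TPR) pairs


def evaluate_separation(scores: pd.Series, labels: pd.Series) -> SeparationResult:
    """ROC AUC of PC1 against binary subtype labels.

    Score polarity is arbitrary after the PCA sign convention, so the AUC
    is reported orientation-free as max(AUC, 1 - AUC) with the chosen
    polarity recorded.
    """
    aligned = labels.loc[scores.index]
    raw = roc_auc(scores.to_numpy(), aligned.to_numpy())
    polarity = 1 if raw >= 0.5 else -1
    oriented_scores = scores.to_numpy() * polarity
    return SeparationResult(
        auc=max(raw, 1.0 - raw),
        polarity=polarity,
        points=roc_points(oriented_scores, aligned.to_numpy()),
    )


# ---------------------------------------------------------------------------
# survival screen
# ---------------------------------------------------------------------------

@dataclass
class SurvivalScreenResult:
    gene: str
    context: str  # "AC", "SqCC", or "NSCLC"
    p: float
    statistic: float
    direction: str  # "low_worse" or "high_worse"
    n_low: int
    n_high: int


def _tertile_split(values: pd.Series) -> tuple[list, list]:
    """Stable-sorted bottom and top thirds; both get floor(n/3) samples."""
    order = values.sort_values(kind="stable")
    k = len(order) // 3
    return list(order.index[:k]), list(order.index[-k:])


def survival_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: list[str],
    contexts: tuple[str, ...] = ("AC", "SqCC", "NSCLC"),
    alpha: float = 0.05,
) -> list[SurvivalScreenResult]:
    """Tertile log-rank screen of each gene in each subtype context.

    Samples are split into lowest and highest expression thirds (middle
    third excluded; ties at the boundary resolved by stable sort order)
    and overall survival is compared with a two-sided log-rank test.  The
    direction reports which tertile had worse observed survival, from the
    sign of (observed - expected) events in the low-expression group.
    """
    table = clinical.table
    has_surv = table["survival_time"].notna()
    mat = _collapse_to_genes(expr, {g.upper() for g in genes})
    results: list[SurvivalScreenResult] = []
    for context in contexts:
        if context == "NSCLC":
            members = table.index[table["subtype"].isin(("AC", "SqCC")) & has_surv]
        else:
            members = table.index[(table["subtype"] == context) & has_surv]
        members = [s for s in members if s in mat.columns]
        if len(members) < 6:
            log.info("context %s has %d samples with survival; skipped", context, len(members))
            continue
        for gene in mat.index:
            low, high = _tertile_split(mat.loc[gene, members])
            ids = low + high
            times = table.loc[ids, "survival_time"].to_numpy(dtype=float)
            events = table.loc[ids, "event"].to_numpy(dtype=int)
            groups = np.array(["low"] * len(low) + ["high"] * len(high))
            res = logrank_test(times, events, groups)
            direction = _worse_tertile(times, events, groups)
            results.append(
                SurvivalScreenResult(
                    gene=gene,
                    context=context,
                    p=res.p,
                    statistic=res.statistic,
                    direction=direction,
                    n_low=len(low),
                    n_high=len(high),
                )
            )
    return results


def _worse_tertile(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> str:
    """Which tertile has worse survival: sign of observed-minus-expected
    events in the low-expression group (more events than expected = worse)."""
    observed = expected = 0.0
    for tau in np.unique(times[events == 1]):
        at_risk = times >= tau
        n_tot = int(at_risk.sum())
        if n_tot == 0:
            continue
        n_low = int((at_risk & (groups == "low")).sum())
        d_tot = int(((times == tau) & (events == 1)).sum())
        d_low = int(((times == tau) & (events == 1) & (groups == "low")).sum())
        observed += d_low
        expected += d_tot * n_low / n_tot
    return "low_worse" if observed >= expected else "high_worse"


def kaplan_meier_table(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier step function: time, at-risk, events, survival."""
    order = np.argsort(times, kind="stable")
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    rows = []
    surv = 1.0
    for tau in np.unique(t[e == 1]):
        n_risk = int((t >= tau).sum())
        d = int(((t == tau) & (e == 1)).sum())
        surv *= 1.0 - d / n_risk
        rows.append({"time": float(tau), "at_risk": n_risk, "events": d, "survival": surv})
    return pd.DataFrame(rows)
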