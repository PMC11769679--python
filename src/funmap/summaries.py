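"""Reportable quantities from a fitted variational state.

Per-SNP posterior inclusion probabilities (PIPs), local/global FDR
causal-SNP selection, level-δ credible sets per single-effect component,
and per-annotation importance scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import AnnotationWeightPosterior, SingleEffectPosterior, VariationalState

logger = logging.getLogger("funmap")

__all__ = [
    "CredibleSet",
    "FineMapResult",
    "compute_pip",
    "select_by_global_fdr",
    "credible_sets",
    "feature_importance",
    "rank_annotations",
    "summarize",
]


@dataclass
class CredibleSet:
    component: int
    snps: list[int]
    coverage: float
    purity: float


@dataclass
class FineMapResult:
    pip: np.ndarray
    local_fdr: np.ndarray
    selected: np.ndarray
    credible_sets: list[CredibleSet]
    feature_importance: np.ndarray
    eta: float
    snp_ids: list[str] = field(default_factory=list)
    annotation_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        p = self.pip.shape[0]
        cs_id = np.array(["NA"] * p, dtype=object)
        for cs in self.credible_sets:
            for j in cs.snps:
                cs_id[j] = f"cs{cs.component}"
        ids = self.snp_ids or [f"snp_{j}" for j in range(p)]
        return pd.DataFrame(
            {
                "snp_id": ids,
                "pip": self.pip,
                "local_fdr": self.local_fdr,
                f"selected@{self.eta:g}": self.selected,
                "cs_id": cs_id,
            }
        )

    def annotations_frame(self) -> pd.DataFrame:
        m = self.feature_importance.shape[0]
        names = self.annotation_names or [f"annot_{k}" for k in range(m)]
        order = np.argsort(-self.feature_importance, kind="stable")
        rank = np.empty(m, dtype=int)
        rank[order] = np.arange(1, m + 1)
        return pd.DataFrame(
            {
                "annotation": names,
                "importance": self.feature_importance,
                "rank": rank,
            }
        )


def compute_pip(effects: list[SingleEffectPosterior]) -> np.ndarray:
    """PIPⱼ = 1 − Π_l (1 − α_lj), accumulated on the log scale."""
    log_none = np.zeros(effects[0].alpha.shape[0])
    for eff in effects:
        log_none += np.log1p(-np.clip(eff.alpha, 0.0, 1.0 - 1e-15))
    return -np.expm1(log_none)


def select_by_global_fdr(pip: np.ndarray, eta: float) -> np.ndarray:
    """Step-up selection controlling the global FDR at level η.

    Local fdrⱼ = 1 − PIPⱼ are sorted ascending (ties broken by original
    index); the global FDR after j selections is the running mean of the
    first j local fdrs, and every SNP in the longest prefix with
    FDR ≤ η is selected.
    """
    if not 0 < eta < 1:
        raise ValueError("eta must be in (0, 1)")
    pip = np.asarray(pip, dtype=float)
    fdr_local = 1.0 - pip
    order = np.argsort(fdr_local, kind="stable")
    cum = np.cumsum(fdr_local[order]) / np.arange(1, pip.size + 1)
    ok = np.flatnonzero(cum <= eta)
    selected = np.zeros(pip.size, dtype=bool)
    if ok.size:
        selected[order[: ok[-1] + 1]] = True
    return selected


def credible_sets(
    effects: list[SingleEffectPosterior],
    delta: float = 0.95,
    R: np.ndarray | None = None,
    purity_threshold: float | None = None,
) -> list[CredibleSet]:
    """Level-δ credible set per component: the smallest set of SNPs whose
    inclusion probabilities sum to at least δ.

    Components whose posterior is near-uniform (max α ≤ 2/p) are not
    reported — they correspond to excess components broadly spread over
    the locus.  When an LD matrix R is supplied, sets whose minimum
    absolute pairwise correlation (purity) falls below the threshold
    (default 0.5) are discarded; with no R the purity filter is off.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if purity_threshold is None:
        purity_threshold = 0.5 if R is not None else 0.0
    out: list[CredibleSet] = []
    p = effects[0].alpha.shape[0]
    for l, eff in enumerate(effects):
        alpha = eff.alpha
        if alpha.max() <= 2.0 / p:
            continue
        order = np.argsort(-alpha, kind="stable")
        cum = np.cumsum(alpha[order])
        k = int(np.searchsorted(cum, delta) + 1)
        k = min(k, p)
        snps = order[:k].tolist()
        coverage = float(cum[k - 1])
        if R is not None and len(snps) > 1:
            sub = np.abs(R[np.ix_(snps, snps)])
            purity = float(sub[np.triu_indices(len(snps), 1)].min())
        else:
            purity = 1.0
        if purity < purity_threshold:
            logger.debug(
                "component %d credible set dropped (purity %.3f < %.3f)",
                l, purity, purity_threshold,
            )
            continue
        out.append(CredibleSet(component=l, snps=snps, coverage=coverage, purity=purity))
    return out


def feature_importance(weights: list[AnnotationWeightPosterior]) -> np.ndarray:
    """FIⱼ = max over components of the squared posterior-mean weight."""
    if not weights:
        return np.empty(0)
    M = np.vstack([w.mu_w for w in weights])
    return (M**2).max(axis=0)


def rank_annotations(FI: np.ndarray, top_fraction: float) -> np.ndarray:
    """Indices of the top ⌈fraction·m⌉ annotations by importance (ties by
    original order)."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    FI = np.asarray(FI, dtype=float)
    k = int(np.ceil(top_fraction * FI.size))
    order = np.argsort(-FI, kind="stable")
    return order[:k]


def summarize(
    state: VariationalState,
    eta: float = 0.05,
    delta: float = 0.95,
    R: np.ndarray | None = None,
    purity_threshold: float | None = None,
    snp_ids: list[str] | None = None,
    annotation_names: list[str] | None = None,
) -> FineMapResult:
    """Assemble the full report from a fitted state."""
    pip = compute_pip(state.effects)
    fi = (
        feature_importance(state.weights)
        if state.weights is not None
        else np.empty(0)
    )
    return FineMapResult(
        pip=pip,
        local_fdr=1.0 - pip,
        selected=select_by_global_fdr(pip, eta),
        credible_sets=credible_sets(state.effects, delta, R, purity_threshold),
        feature_importance=fi,
        eta=eta,
        snp_ids=snp_ids or [],
        annotation_names=annotation_names or [],
    )
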