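"""Prediction assessment: margin MAE, correlation, and threshold-swept ROC.

Three criteria compare a predicted score series x against the normalized
NMA reference y on the residues valid in both:

* MAE with a tolerance band: deviations within ± margin (default 0.2) are
  forgiven; the per-residue error is max(0, |x − y| − margin) under the
  default "soft" semantics (an alternative "hard" semantics charges the
  full |x − y| outside the band). margin = 0 recovers Σ|x − y| / M exactly.
* Pearson correlation coefficient.
* ROC/AUC: residues with y above an NMA threshold (1, 0 or −1) are the
  positive class; the decision cutoff on x sweeps from −2 to 4 in steps of
  0.01 and the AUC is the trapezoid area under the resulting curve. The
  standard rate definitions TPR = TP/(TP+FN) and FPR = FP/(FP+TN) are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "mae_margin",
    "correlation",
    "roc_auc",
    "EvalReport",
    "evaluate_chain",
    "evaluate_chains",
]

SWEEP_START, SWEEP_STOP, SWEEP_STEP = -2.0, 4.0, 0.01


def _aligned(pred, ref, mask=None):
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference lengths differ")
    valid = np.isfinite(pred) & np.isfinite(ref)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    return pred[valid], ref[valid]


def mae_margin(
    pred,
    ref,
    margin: float = 0.2,
    mask=None,
    semantics: str = "soft",
) -> float:
    """Mean absolute error with a forgiveness margin.

    soft: error = max(0, |x − y| − margin); hard: error = 0 inside the
    band, full |x − y| outside. margin = 0 gives the plain MAE.
    """
    x, y = _aligned(pred, ref, mask)
    if len(x) == 0:
        raise ValueError("no overlapping valid residues")
    diff = np.abs(x - y)
    if semantics == "soft":
        err = np.maximum(0.0, diff - margin)
    elif semantics == "hard":
        err = np.where(diff <= margin, 0.0, diff)
    else:
        raise ValueError("semantics must be 'soft' or 'hard'")
    return float(err.mean())


def correlation(pred, ref, mask=None) -> float:
    """Pearson correlation coefficient between prediction and reference."""
    x, y = _aligned(pred, ref, mask)
    if len(x) < 3:
        raise ValueError("need at least 3 overlapping valid residues")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(scipy.stats.pearsonr(x, y).statistic)


def roc_auc(
    pred, ref, nma_threshold: float = 0.0, mask=None
) -> tuple[np.ndarray, float]:
    """Threshold-swept ROC curve and AUC.

    Positives are residues with reference score strictly above
    ``nma_threshold``. The decision cutoff sweeps −2..4 step 0.01 (predict
    flexible when x > cutoff). Returns (points, auc) where points is an
    (n, 2) array of (FPR, TPR) including the (0,0) and (1,1) endpoints.
    """
    x, y = _aligned(pred, ref, mask)
    pos = y > nma_threshold
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"reference has a single class at threshold {nma_threshold}"
        )
    cuts = np.arange(SWEEP_START, SWEEP_STOP + SWEEP_STEP / 2, SWEEP_STEP)
    pred_flex = x[None, :] > cuts[:, None]        # (n_cuts, M)
    tp = (pred_flex & pos[None, :]).sum(axis=1)
    fp = (pred_flex & ~pos[None, :]).sum(axis=1)
    tpr = tp / n_pos
    fpr = fp / n_neg
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


@dataclass
class EvalReport:
    """Per-chain and aggregate assessment results (JSON-serializable)."""

    per_chain: list[dict]
    mae_avg: float
    mae_plain_avg: float
    cc_avg: float
    cc_sd: float
    auc: dict[str, float]
    margin: float
    n_residues: int
    n_chains_cc: int = 0

    def to_dict(self) -> dict:
        return {
            "per_chain": self.per_chain,
            "aggregate": {
                "MAE": self.mae_avg,
                "MAE_plain": self.mae_plain_avg,
                "CC_avg": self.cc_avg,
                "CC_sd": self.cc_sd,
                "AUC": self.auc,
                "margin": self.margin,
                "n_residues": self.n_residues,
                "n_chains_cc": self.n_chains_cc,
            },
        }


def evaluate_chain(pred, ref, margin=0.2, mask=None, chain_id="chain") -> dict:
    out = {
        "chain": chain_id,
        "MAE": mae_margin(pred, ref, margin, mask),
        "MAE_plain": mae_margin(pred, ref, 0.0, mask),
    }
    try:
        out["CC"] = correlation(pred, ref, mask)
    except ValueError:
        out["CC"] = None
    return out


def evaluate_chains(
    preds: list,
    refs: list,
    margin: float = 0.2,
    masks: list | None = None,
    thresholds=(1.0, 0.0, -1.0),
    chain_ids: list | None = None,
) -> EvalReport:
    """Assess many chains: per-chain MAE/CC plus pooled-residue ROC/AUC.

    CCs are averaged unweighted over the chains where they are defined;
    AUC is computed on the pooled residues at each NMA threshold.
    """
    if masks is None:
        masks = [None] * len(preds)
    if chain_ids is None:
        chain_ids = [f"chain{i}" for i in range(len(preds))]
    per_chain = [
        evaluate_chain(p, r, margin, m, cid)
        for p, r, m, cid in zip(preds, refs, masks, chain_ids)
    ]
    ccs = np.array([c["CC"] for c in per_chain if c["CC"] is not None])
    pooled_pred, pooled_ref = [], []
    for p, r, m in zip(preds, refs, masks):
        x, y = _aligned(p, r, m)
        pooled_pred.append(x)
        pooled_ref.append(y)
    xp = np.concatenate(pooled_pred)
    yp = np.concatenate(pooled_ref)
    aucs = {}
    for t in thresholds:
        try:
            _, aucs[str(t)] = roc_auc(xp, yp, t)
        except ValueError:
            aucs[str(t)] = None
    return EvalReport(
        per_chain=per_chain,
        mae_avg=float(np.mean([c["MAE"] for c in per_chain])),
        mae_plain_avg=float(np.mean([c["MAE_plain"] for c in per_chain])),
        cc_avg=float(ccs.mean()) if len(ccs) else float("nan"),
        cc_sd=float(ccs.std(ddof=1)) if len(ccs) > 1 else 0.0,
        auc=aucs,
        margin=margin,
        n_residues=int(len(xp)),
        n_chains_cc=int(len(ccs)),
    )
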