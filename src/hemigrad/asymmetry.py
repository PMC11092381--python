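"""Hemispheric asymmetry indices of aligned gradient scores.

The asymmetry index (AI) is the plain homotopic difference of
template-aligned gradient scores: ``LL - RR`` for intra-hemispheric and
``LR - RL`` for inter-hemispheric patterns, evaluated on the first three
gradients. Positive AI means leftward asymmetry (the left-hemisphere
region sits higher along that gradient than its homologue). The ratio
form (LL-RR)/(LL+RR) is deliberately not offered: gradient scores are
signed, and a signed denominator exaggerates or breaks the index.

AI is computed strictly on template-aligned scores — alignment absorbs
eigenvector sign and rotation indeterminacy, which is what makes the
homotopic difference meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .stats import fdr_bh


@dataclass(frozen=True)
class AsymmetryIndex:
    """Per-pair intra (LL-RR) and inter (LR-RL) AI along G1-G3."""

    intra: np.ndarray  # n_pairs x n_gradients
    inter: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.intra.shape != self.inter.shape:
            raise ValueError("intra and inter AI must share a shape")
        if not (np.isfinite(self.intra).all() and np.isfinite(self.inter).all()):
            raise ValueError("AI contains non-finite values")


def compute_ai(aligned: dict[str, np.ndarray], n_gradients: int = 3,
               subject_id: str = "") -> AsymmetryIndex:
    """AI from a subject's aligned block scores ('LL','RR','LR','RL')."""
    required = {"LL", "RR", "LR", "RL"}
    missing = required - set(aligned)
    if missing:
        raise ValueError(f"missing aligned blocks: {sorted(missing)}")
    shapes = {aligned[k].shape for k in required}
    if len(shapes) != 1:
        raise ValueError(f"aligned blocks have mismatched shapes: {shapes}")
    n_comp = next(iter(shapes))[1]
    if n_comp < n_gradients:
        raise ValueError(
            f"blocks carry {n_comp} components, need >= {n_gradients}"
        )
    intra = aligned["LL"][:, :n_gradients] - aligned["RR"][:, :n_gradients]
    inter = aligned["LR"][:, :n_gradients] - aligned["RL"][:, :n_gradients]
    return AsymmetryIndex(intra=intra, inter=inter, subject_id=subject_id)


def ai_feature_matrix(ais: list[AsymmetryIndex], scope: str) -> pd.DataFrame:
    """Stack per-subject AI into a subjects x (n_pairs * n_gradients) frame.

    Columns are named ``G{k}_pair{i:03d}``; with 200 pairs and 3 gradients
    this is the 600-feature space fed to harmonization and prediction.
    """
    if scope not in ("intra", "inter"):
        raise ValueError("scope must be 'intra' or 'inter'")
    if not ais:
        raise ValueError("empty AI list")
    mats = [getattr(a, scope) for a in ais]
    n_pairs, n_grad = mats[0].shape
    cols = [
        f"G{k + 1}_pair{i:03d}" for k in range(n_grad) for i in range(n_pairs)
    ]
    data = np.stack([m.T.ravel() for m in mats])  # gradient-major ordering
    idx = [a.subject_id or str(i) for i, a in enumerate(ais)]
    return pd.DataFrame(data, index=idx, columns=cols)


def group_ai_maps(
    ais: list[AsymmetryIndex], groups: list[str], scope: str = "intra"
) -> pd.DataFrame:
    """Descriptive per-region AI maps per group.

    For each region x gradient x group: mean AI, Cohen's d (mean/sd),
    two-sided one-sample t against 0, and Benjamini-Hochberg q across
    regions within each gradient. Regions with zero across-subject sd are
    flagged (``degenerate``) and excluded from the FDR.
    """
    if len(ais) != len(groups):
        raise ValueError("one group label per subject required")
    labels = np.asarray(groups)
    for g in np.unique(labels):
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    stack = np.stack([getattr(a, scope) for a in ais])  # subj x pairs x grads
    rows = []
    n_pairs, n_grad = stack.shape[1], stack.shape[2]
    for g in np.unique(labels):
        sub = stack[labels == g]
        for k in range(n_grad):
            mat = sub[:, :, k]  # subj x pairs
            mean = mat.mean(axis=0)
            sd = mat.std(axis=0, ddof=1)
            degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
            d = np.where(degenerate, np.nan, mean / np.where(degenerate, 1, sd))
            t, p = scipy.stats.ttest_1samp(mat, 0.0, axis=0)
            p = np.where(degenerate, np.nan, p)
            q = np.full(n_pairs, np.nan)
            ok = ~degenerate
            if ok.any():
                q[ok] = fdr_bh(p[ok])
            for i in range(n_pairs):
                rows.append(
                    {
                        "region": i,
                        "gradient": f"G{k + 1}",
                        "group": g,
                        "mean": mean[i],
                        "d": d[i],
                        "t": t[i] if ok[i] else np.nan,
                        "p": p[i],
                        "q": q[i],
                        "significant": bool(ok[i] and q[i] < 0.05),
                        "degenerate": bool(degenerate[i]),
                    }
                )
    return pd.DataFrame(rows)
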