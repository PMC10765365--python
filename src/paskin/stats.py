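"""Spearman rank correlation of features against age.

The statistical surface is deliberately plain: one two-sided Spearman test
per feature × layer against age at α = 0.05, no multiple-testing correction
(an optional Benjamini–Hochberg flag exists but is off by default, matching
the reproduced analysis).  Ties get mid-ranks; p-values use the t
approximation t = ρ·sqrt((n−2)/(1−ρ²)) with an exact permutation option for
tiny n.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CorrelationResult", "spearman", "analyze_cohort", "plot_feature_vs_age"]

logger = logging.getLogger(__name__)

_FEATURES_PER_LAYER = ["mean_thickness_um", "total_volume_voxels", "branch_count", "mean_so2"]


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    layer: int | None  # None for whole-structure features (melanin volume)
    n: int
    rho: float
    p_value: float
    significant: bool


def spearman(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Spearman ρ and two-sided p-value with pairwise missing removal.

    ``method='t'`` uses the t approximation (ρ = ±1 → p = 0); ``'exact'``
    enumerates all rank permutations (n ≤ 8 only); ``'auto'`` (default)
    picks the exact enumeration for n ≤ 8, where the t approximation is at
    its weakest, and the t approximation otherwise.  Fewer than 3 complete
    pairs is an error; zero rank variance in either argument makes ρ
    undefined and returns (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = sps.rankdata(x)  # mid-ranks for ties
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    if method == "auto":
        method = "exact" if n <= 8 else "t"
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p-value supported for n <= 8 only")
        rho_obs = float(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        return rho_obs, count / total
    if method != "t":
        raise ValueError(f"unknown method {method!r}")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    return rho, float(p)


def analyze_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[CorrelationResult]:
    """Correlate every feature with age, per layer, plus melanin overall.

    Missing values are dropped pairwise per feature (layers can be missing
    independently); a feature that is missing for every subject is skipped
    with a warning.  ``bh_correction`` applies Benjamini–Hochberg across the
    tested features before the significance call (off by default).
    """
    if table["subject_id"].nunique() < 3:
        raise ValueError("cohort analysis needs at least 3 subjects")
    results: list[tuple[str, int | None, int, float, float]] = []
    for layer in (1, 2):
        sub = table[table["layer"] == layer]
        for feat in _FEATURES_PER_LAYER:
            vals = sub[feat].to_numpy(float)
            age = sub["age"].to_numpy(float)
            ok = np.isfinite(vals) & np.isfinite(age)
            if ok.sum() < 3:
                logger.warning("feature %s layer %s: <3 complete pairs, skipped", feat, layer)
                continue
            rho, p = spearman(age[ok], vals[ok])
            if not np.isfinite(rho):
                logger.warning("feature %s layer %s: zero rank variance, skipped", feat, layer)
                continue
            results.append((feat, layer, int(ok.sum()), rho, p))
    # melanin volume is a whole-structure feature: one value per subject
    mel = table.drop_duplicates("subject_id")[["age", "melanin_volume_voxels"]]
    vals = mel["melanin_volume_voxels"].to_numpy(float)
    age = mel["age"].to_numpy(float)
    ok = np.isfinite(vals) & np.isfinite(age)
    if ok.sum() >= 3:
        rho, p = spearman(age[ok], vals[ok])
        if np.isfinite(rho):
            results.append(("melanin_volume_voxels", None, int(ok.sum()), rho, p))
    else:
        logger.warning("melanin volume: <3 complete pairs, skipped")

    pvals = np.array([r[4] for r in results])
    if bh_correction and len(pvals):
        order = np.argsort(pvals)
        m = len(pvals)
        thresh = np.zeros(m, bool)
        running_max_k = -1
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= alpha * rank / m:
                running_max_k = rank
        for rank, idx in enumerate(order, start=1):
            thresh[idx] = rank <= running_max_k
        sig = thresh
    else:
        sig = pvals < alpha
    return [
        CorrelationResult(feature=f, layer=l, n=n, rho=r, p_value=p, significant=bool(s))
        for (f, l, n, r, p), s in zip(results, sig)
    ]


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "layer": "" if r.layer is None else r.layer,
                "n": r.n,
                "rho": r.rho,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def plot_feature_vs_age(
    table: pd.DataFrame, feature: str, path: str, layers: tuple[int, ...] = (1, 2)
) -> None:
    """Scatter of a feature against age, one panel per layer."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(layers), figsize=(4 * len(layers), 3.2), squeeze=False)
    for ax, layer in zip(axes[0], layers):
        sub = table[table["layer"] == layer]
        ax.scatter(sub["age"], sub[feature], s=14)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(feature)
        ax.set_title(f"layer {layer}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
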