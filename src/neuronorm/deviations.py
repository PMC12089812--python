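"""Extreme-deviation classification, burden statistics and group comparisons.

A regional deviation z-score is *infranormal* when z < -1.96 and
*supranormal* when z > 1.96; values in [-1.96, +1.96] are within the normal
range (the thresholds bound the central 95% of a standard normal, 2.5% per
tail).  Prevalence of extremes is compared between groups region by region
with the pooled-variance two-proportion z-test (no continuity correction)
and Benjamini-Hochberg FDR control across regions.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Z_THRESHOLD = 1.96

INFRANORMAL = "infranormal"
NORMAL = "normal"
SUPRANORMAL = "supranormal"


def classify_z(z, threshold: float = Z_THRESHOLD):
    """Label z-scores as infranormal (z < -threshold), supranormal
    (z > +threshold) or normal; the boundaries themselves are normal
    (strict inequalities)."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("z-scores must be finite")
    labels = np.where(
        arr < -threshold, INFRANORMAL, np.where(arr > threshold, SUPRANORMAL, NORMAL)
    )
    return labels if np.ndim(z) else str(labels[()])


def percentage(k: int, n: int) -> float:
    """Prevalence as a percentage, 100 * k / n."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n >= 1")
    return 100.0 * k / n


def region_extreme_percentages(
    z: pd.DataFrame, threshold: float = Z_THRESHOLD
) -> pd.DataFrame:
    """Per-region percentage of subjects with infra-/supranormal z.

    ``z`` is a subjects x regions table for one group.  Returns a long table
    with columns region, direction, k, n, pct.
    """
    if len(z) == 0:
        raise ValueError("empty group: no subjects to compute percentages over")
    _require_complete(z)
    n = len(z)
    rows = []
    vals = z.to_numpy(dtype=float)
    infra = (vals < -threshold).sum(axis=0)
    supra = (vals > threshold).sum(axis=0)
    for j, region in enumerate(z.columns):
        rows.append((region, INFRANORMAL, int(infra[j]), n, percentage(int(infra[j]), n)))
        rows.append((region, SUPRANORMAL, int(supra[j]), n, percentage(int(supra[j]), n)))
    return pd.DataFrame(rows, columns=["region", "direction", "k", "n", "pct"])


def _require_complete(z: pd.DataFrame) -> None:
    bad = z.index[z.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"missing z cells for subject(s): {bad[:10]}")


def subject_burden(z: pd.DataFrame, threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Per-subject counts of regions with extreme deviations.

    Returns a table indexed like ``z`` with columns n_infra, n_supra,
    any_infra, any_supra.  Requires a complete z matrix.
    """
    _require_complete(z)
    vals = z.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("z-scores must be finite")
    n_infra = (vals < -threshold).sum(axis=1)
    n_supra = (vals > threshold).sum(axis=1)
    return pd.DataFrame(
        {
            "n_infra": n_infra,
            "n_supra": n_supra,
            "any_infra": n_infra > 0,
            "any_supra": n_supra > 0,
        },
        index=z.index,
    )


def two_proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test, no continuity correction.

    Returns (z, two-sided p) with p = 2 * (1 - Phi(|z|)).  If the pooled
    proportion is 0 or 1 the variance vanishes; p is defined as 1 with a
    warning.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n >= 1 in both groups")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate (0 or 1); p defined as 1")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up across a family of p-values.

    Returns (reject flags, adjusted p-values) at FDR level ``q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def compare_extreme_proportions(
    z: pd.DataFrame,
    groups: pd.Series,
    case: str = "case",
    control: str = "control",
    threshold: float = Z_THRESHOLD,
    q: float = 0.05,
) -> pd.DataFrame:
    """Region x direction group comparison of extreme-deviation prevalence.

    ``groups`` is aligned with ``z`` rows.  BH-FDR is applied across all
    region x direction tests jointly.  Output columns: region, direction,
    k_case, n_case, pct_case, k_control, n_control, pct_control, z, p,
    p_adj, significant.
    """
    groups = pd.Series(groups).reindex(z.index)
    zc = z.loc[groups == case]
    zh = z.loc[groups == control]
    tab_c = region_extreme_percentages(zc, threshold)
    tab_h = region_extreme_percentages(zh, threshold)
    merged = tab_c.merge(
        tab_h, on=["region", "direction"], suffixes=("_case", "_control")
    )
    zs, ps = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate all-zero regions are expected
        for row in merged.itertuples():
            stat, p = two_proportion_z_test(
                row.k_case, row.n_case, row.k_control, row.n_control
            )
            zs.append(stat)
            ps.append(p)
    merged["z"] = zs
    merged["p"] = ps
    merged["significant"], merged["p_adj"] = bh_fdr(ps, q)
    return merged


def burden_comparison(
    z: pd.DataFrame,
    groups: pd.Series,
    case: str = "case",
    control: str = "control",
    threshold: float = Z_THRESHOLD,
) -> dict:
    """'Any-region' extreme burden comparison between two groups.

    For each direction: counts and percentage of subjects with at least one
    extreme deviation in any region, plus the two-proportion test.
    """
    groups = pd.Series(groups).reindex(z.index)
    out = {}
    burden = subject_burden(z, threshold)
    for direction, col in ((INFRANORMAL, "any_infra"), (SUPRANORMAL, "any_supra")):
        kc = int(burden.loc[(groups == case).to_numpy(), col].sum())
        nc = int((groups == case).sum())
        kh = int(burden.loc[(groups == control).to_numpy(), col].sum())
        nh = int((groups == control).sum())
        stat, p = two_proportion_z_test(kc, nc, kh, nh)
        out[direction] = {
            "k_case": kc,
            "n_case": nc,
            "pct_case": percentage(kc, nc),
            "k_control": kh,
            "n_control": nh,
            "pct_control": percentage(kh, nh),
            "z": stat,
            "p": p,
        }
    return out
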