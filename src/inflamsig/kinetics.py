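"""Stimulation-response values and longitudinal trajectory statistics.

A response is the arcsinh-transformed (cofactor 5, the mass-cytometry
convention) stimulated level minus the transformed unstimulated level.
Trajectories are summarized per (cell type, timepoint) as mean +/- SEM,
optionally re-expressed as z-scores against a young-control reference.
Group comparisons use Kruskal-Wallis across independent groups and the
Wilcoxon matched-pairs signed-rank test (zero differences dropped) for
pre vs post within subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kruskal, wilcoxon

__all__ = [
    "stimulation_response",
    "trajectory_summary",
    "group_comparisons",
    "plot_trajectories",
    "ARCSINH_COFACTOR",
]

ARCSINH_COFACTOR = 5.0


def stimulation_response(
    stim_value,
    unstim_value,
    transform: str = "arcsinh",
    cofactor: float = ARCSINH_COFACTOR,
):
    """Difference of transformed stimulated and unstimulated intensities.

    ``transform="arcsinh"`` applies arcsinh(x / cofactor) to raw (>= 0)
    intensities; ``"none"`` takes the values as already transformed;
    ``"ratio"`` returns stim / unstim on the raw scale.
    """
    stim = np.asarray(stim_value, dtype=float)
    unstim = np.asarray(unstim_value, dtype=float)
    if transform == "arcsinh":
        if np.any(stim < 0) or np.any(unstim < 0):
            raise ValueError("negative raw intensity")
        return np.arcsinh(stim / cofactor) - np.arcsinh(unstim / cofactor)
    if transform == "none":
        return stim - unstim
    if transform == "ratio":
        if np.any(unstim <= 0):
            raise ValueError("ratio transform needs positive unstimulated values")
        return stim / unstim
    raise ValueError(f"unknown transform {transform!r}")


def trajectory_summary(
    responses: pd.DataFrame,
    value_col: str = "response",
    group_cols: tuple = ("cell_type", "timepoint"),
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean +/- SEM of responses per group.

    ``reference`` (a young-control vector) turns values into z-scores
    z = (x - mean_ref) / sd_ref before summarizing.  Groups with a single
    subject are flagged (``sem`` NaN, ``flagged`` True); the 95% CI
    columns are mean +/- 1.96 SEM.
    """
    df = responses.copy()
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        mu, sd = ref.mean(), ref.std(ddof=1)
        if sd <= 0:
            raise ValueError("reference has zero variance")
        df[value_col] = (df[value_col] - mu) / sd
    rows = []
    for keys, grp in df.groupby(list(group_cols), sort=False):
        vals = grp[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        mean = float(vals.mean()) if n else np.nan
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append(
            {
                **dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,))),
                "mean": mean,
                "sem": sem,
                "n": n,
                "ci95_lo": mean - 1.96 * sem if n >= 2 else np.nan,
                "ci95_hi": mean + 1.96 * sem if n >= 2 else np.nan,
                "flagged": n < 2,
            }
        )
    return pd.DataFrame(rows)


def group_comparisons(
    groups: dict | None = None,
    paired: dict | None = None,
) -> pd.DataFrame:
    """Nonparametric comparisons across and within groups.

    ``groups`` maps label -> independent sample (Kruskal-Wallis across all
    of them); ``paired`` maps label -> (pre, post) arrays matched per
    subject (Wilcoxon matched-pairs signed-rank, zero differences
    dropped, exact distribution for n <= 25).
    """
    rows = []
    if groups:
        if len(groups) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 groups")
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
        if np.ptp(np.concatenate(samples)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = kruskal(*samples)
        rows.append(
            {
                "comparison": " vs ".join(groups),
                "test": "kruskal_wallis",
                "statistic": float(stat),
                "p": float(p),
                "flagged": False,
            }
        )
    if paired:
        for label, (pre, post) in paired.items():
            pre = np.asarray(pre, dtype=float)
            post = np.asarray(post, dtype=float)
            if pre.shape != post.shape:
                raise ValueError(f"unmatched pairs in {label!r}")
            diffs = post - pre
            nonzero = diffs[diffs != 0]
            if nonzero.size == 0:
                rows.append(
                    {
                        "comparison": label,
                        "test": "wilcoxon_signed_rank",
                        "statistic": 0.0,
                        "p": 1.0,
                        "flagged": True,  # degenerate: all differences zero
                    }
                )
                continue
            mode = "exact" if nonzero.size <= 25 and not _has_tied_ranks(nonzero) else "auto"
            stat, p = wilcoxon(
                pre, post, zero_method="wilcox", mode=mode
            )
            rows.append(
                {
                    "comparison": label,
                    "test": "wilcoxon_signed_rank",
                    "statistic": float(stat),
                    "p": float(p),
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows)


def plot_trajectories(summary: pd.DataFrame, timepoint_order=None, ax=None):
    """Mean +/- SEM response per cell type over timepoints."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    order = timepoint_order or list(dict.fromkeys(summary["timepoint"]))
    pos = {tp: i for i, tp in enumerate(order)}
    for cell, grp in summary.groupby("cell_type"):
        grp = grp[grp["timepoint"].isin(pos)].copy()
        grp["x"] = grp["timepoint"].map(pos)
        grp = grp.sort_values("x")
        ax.errorbar(
            grp["x"], grp["mean"], yerr=grp["sem"], marker="o",
            capsize=2, label=str(cell),
        )
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("response (mean +/- SEM)")
    ax.legend(fontsize="small")
    return ax


def _has_tied_ranks(diffs: np.ndarray) -> bool:
    a = np.abs(diffs)
    return np.unique(a).size < a.size
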