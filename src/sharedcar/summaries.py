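"""Area-level posterior products: odds-ratio surfaces, exceedance
classification, map binning and per-category box-plot summaries.

The shared-effect odds ratio of area i is exp(phi_i); the treatment-specific
surface is exp(u_ik + s_ik) (only the sum of the structured and unstructured
residual fields is well identified).  Exceedance probabilities P(OR > 1) are
classified with the 0.2/0.8 threshold rule, and mapped odds ratios are binned
at the fixed cutpoints 0.77, 0.91, 1.10, 1.30 with [low, high) edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import PosteriorSamples
from .synthetic import TREATMENTS

__all__ = [
    "MAP_BIN_EDGES",
    "MAP_BIN_LABELS",
    "shared_effect_summary",
    "treatment_specific_summary",
    "category_boxplot_summary",
    "ranked_caterpillar",
]

MAP_BIN_EDGES = (0.77, 0.91, 1.10, 1.30)
MAP_BIN_LABELS = ("<0.77", "0.77-0.91", "0.91-1.10", "1.10-1.30", "1.30+")


def _classify(p: np.ndarray) -> np.ndarray:
    out = np.where(p < 0.2, "low", np.where(p > 0.8, "high", "uncertain"))
    return out.astype(object)


def _summary_frame(log_or_draws: np.ndarray, area_ids: list[str]) -> pd.DataFrame:
    """Per-area summary from (m, n_areas) log odds-ratio draws."""
    med = np.exp(np.median(log_or_draws, axis=0))
    lo = np.exp(np.percentile(log_or_draws, 2.5, axis=0))
    hi = np.exp(np.percentile(log_or_draws, 97.5, axis=0))
    exceed = (log_or_draws > 0).mean(axis=0)  # exp(x) > 1 iff x > 0
    bins = np.digitize(med, MAP_BIN_EDGES, right=False)
    return pd.DataFrame(
        {
            "area_id": area_ids,
            "median_or": med,
            "cri_low": lo,
            "cri_high": hi,
            "exceed_prob": exceed,
            "exceed_class": _classify(exceed),
            "map_bin": [MAP_BIN_LABELS[b] for b in bins],
        }
    )


def shared_effect_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-area summary of the shared spatial odds ratio exp(phi_i)."""
    if "phi" not in samples.draws:
        raise ValueError("model variant has no shared component")
    return _summary_frame(samples.stacked("phi"), samples.area_ids)


def treatment_specific_summary(samples: PosteriorSamples, k: int) -> pd.DataFrame:
    """Per-area summary of the treatment-specific surface exp(u_ik + s_ik).

    Terms absent under the fitted variant contribute zero, so under a
    no-unstructured-effects variant this is exp(s) alone, and vice versa.
    """
    if not 0 <= k < len(TREATMENTS):
        raise ValueError("treatment index out of range")
    if "u" not in samples.draws and "s" not in samples.draws:
        raise ValueError("model variant has neither unstructured nor structured effects")
    total = None
    for name in ("u", "s"):
        if name in samples.draws:
            part = samples.stacked(name)[:, :, k]
            total = part if total is None else total + part
    return _summary_frame(total, samples.area_ids)


def category_boxplot_summary(summary: pd.DataFrame, categories) -> pd.DataFrame:
    """Box-plot quartiles (log scale) and exceedance percentages per
    area-level category (e.g. travel-time band or SES quintile).

    ``categories`` maps each area to a label, aligned with ``summary`` rows
    (a sequence) or keyed by area id (a mapping/Series).  The two percentage
    columns are the share of areas with exceedance probability below 0.2 and
    above 0.8.
    """
    if isinstance(categories, (dict, pd.Series)):
        labels = pd.Series(summary["area_id"]).map(dict(categories))
        if labels.isna().any():
            missing = summary["area_id"][labels.isna()].tolist()
            raise ValueError(f"areas without a category label: {missing[:5]}")
        labels = labels.to_numpy()
    else:
        labels = np.asarray(categories, dtype=object)
        if labels.shape[0] != len(summary):
            raise ValueError("category labels must align with the summary rows")
        if any(l is None for l in labels):
            raise ValueError("areas without a category label")
    log_or = np.log(summary["median_or"].to_numpy())
    p = summary["exceed_prob"].to_numpy()
    rows = []
    for cat in pd.unique(labels):
        m = labels == cat
        q1, q2, q3 = np.percentile(log_or[m], [25, 50, 75])
        rows.append(
            {
                "category": cat,
                "n_areas": int(m.sum()),
                "log_or_q1": q1,
                "log_or_median": q2,
                "log_or_q3": q3,
                "pct_low_exceedance": 100.0 * float((p[m] < 0.2).mean()),
                "pct_high_exceedance": 100.0 * float((p[m] > 0.8).mean()),
            }
        )
    return pd.DataFrame(rows)


def ranked_caterpillar(summary: pd.DataFrame) -> pd.DataFrame:
    """Areas ordered by median OR (stable sort; ties keep area order)."""
    order = np.argsort(summary["median_or"].to_numpy(), kind="stable")
    out = summary.iloc[order].reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
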