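"""Dose/time contrasts, single-guide extraction, interactions and guide QC.

The ISR-dynamics readout of a screen is the vector of seven post-induction
ISR measurements per perturbation (post-induction basal, then low and high
stressor dose at 0.25, 1 and 4 h).  Figure-level comparisons are simple
contrasts of per-sample estimates: a time contrast within a dose, or a
dose contrast within a timepoint, with standard errors added in quadrature.

Single-guide phenotypes come from the dual-guide design itself: every
construct that pairs guide g with a negative-control guide measures g
alone, and those measurements are combined by inverse-variance weighting.
Pair interactions are the departure of a dual-guide estimate from the sum
of its two single-guide estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .library import GuideLibrary, ParameterError


def contrast(table: pd.DataFrame, sample_a: str, sample_b: str, column: str = "isr_log2fc"):
    """Per-perturbation difference ``sample_a - sample_b`` with Wald stats.

    Returns a DataFrame with delta, se, z, p for perturbations present in
    both conditions (only retained, i.e. filtered, rows can appear).
    """
    se_col = column.replace("_log2fc", "") + "_se"
    a = table[table["sample_id"] == sample_a].set_index("perturbation")
    b = table[table["sample_id"] == sample_b].set_index("perturbation")
    if a.empty or b.empty:
        raise ParameterError(f"missing condition: {sample_a!r} or {sample_b!r}")
    common = a.index.intersection(b.index)
    delta = a.loc[common, column] - b.loc[common, column]
    se = np.sqrt(a.loc[common, se_col] ** 2 + b.loc[common, se_col] ** 2)
    z = delta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"perturbation": common, "delta": delta.to_numpy(), "se": se.to_numpy(), "z": z.to_numpy(), "p": p}
    ).reset_index(drop=True)


def dose_contrast(table: pd.DataFrame, time_label: str, column: str = "isr_log2fc"):
    """High-minus-low dose contrast at one treatment timepoint."""
    return contrast(table, f"high_{time_label}", f"low_{time_label}", column)


def time_contrast(table: pd.DataFrame, dose_label: str, t_a: str, t_b: str, column: str = "isr_log2fc"):
    """Within-dose contrast between two treatment timepoints."""
    return contrast(table, f"{dose_label}_{t_a}", f"{dose_label}_{t_b}", column)


def profile_matrix(table: pd.DataFrame, column: str = "isr_log2fc") -> pd.DataFrame:
    """Wide perturbation x sample matrix of the seven ISR measurements."""
    sub = table[table["sample_id"] != "pre"]
    return sub.pivot_table(index="perturbation", columns="sample_id", values=column)


def single_guide_phenotypes(
    pair_table: pd.DataFrame,
    construct_map: pd.DataFrame,
    control_ids,
    columns=("isr_log2fc", "growth_log2fc"),
) -> tuple[pd.DataFrame, list[str]]:
    """Single-guide estimates from constructs pairing each guide with a control.

    For each non-control guide g and sample, the estimate is the
    inverse-variance weighted mean over the perturbations that pair g with a
    negative-control guide.  Returns ``(table, unpaired)`` where unpaired
    lists guides that have no retained control pairing and are therefore
    absent from the table.
    """
    control_set = set(control_ids)
    pairs = construct_map.drop_duplicates("perturbation")[
        ["perturbation", "guide_first", "guide_second"]
    ]

    def _single_guide(row):
        a, b = row.guide_first, row.guide_second
        a_ctrl, b_ctrl = a in control_set, b in control_set
        if a_ctrl == b_ctrl:
            return None
        return b if a_ctrl else a

    pairs = pairs.assign(guide=[_single_guide(r) for r in pairs.itertuples()])
    pairs = pairs.dropna(subset=["guide"])
    merged = pair_table.merge(pairs[["perturbation", "guide"]], on="perturbation", how="inner")

    out_rows = []
    for (guide, sample), grp in merged.groupby(["guide", "sample_id"], sort=False):
        row = {"guide": guide, "sample_id": sample, "n_control_partners": len(grp)}
        for col in columns:
            se_col = col.replace("_log2fc", "") + "_se"
            vals = grp[col].to_numpy()
            ses = grp[se_col].to_numpy()
            ok = np.isfinite(vals) & np.isfinite(ses) & (ses > 0)
            if not ok.any():
                row[col] = np.nan
                row[se_col] = np.nan
                continue
            w = 1.0 / ses[ok] ** 2
            row[col] = float((w * vals[ok]).sum() / w.sum())
            row[se_col] = float(np.sqrt(1.0 / w.sum()))
        out_rows.append(row)
    singles = pd.DataFrame(out_rows)
    all_guides = {
        g
        for pair in zip(construct_map["guide_first"], construct_map["guide_second"])
        for g in pair
        if g not in control_set
    }
    covered = set(singles["guide"]) if not singles.empty else set()
    unpaired = sorted(all_guides - covered)
    return singles, unpaired


def pair_interaction(pair_estimate, pair_se, single_1, se_1, single_2, se_2):
    """Interaction eta = pair - (g1 + g2) with propagated standard error."""
    for v in (pair_estimate, pair_se, single_1, se_1, single_2, se_2):
        if v is None or (np.isscalar(v) and not np.isfinite(v)):
            raise ParameterError("all three estimates (pair and both singles) are required")
    eta = np.asarray(pair_estimate, float) - (np.asarray(single_1, float) + np.asarray(single_2, float))
    se = np.sqrt(
        np.asarray(pair_se, float) ** 2 + np.asarray(se_1, float) ** 2 + np.asarray(se_2, float) ** 2
    )
    return eta, se


def gc_filter_guides(library: GuideLibrary, min_gc: float = 0.25) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag guides whose protospacer GC fraction is below ``min_gc``.

    Low-GC guides are prone to off-target effects, so they are flagged for
    exclusion from interpretation; they are not removed from counting.  The
    boundary is a strict inequality: gc == min_gc is kept.
    """
    df = library.to_frame()
    flagged = df["gc_fraction"] < min_gc
    return df[~flagged].reset_index(drop=True), df[flagged].reset_index(drop=True)


def class_summary(
    singles: pd.DataFrame, guide_classes: pd.Series, column: str = "isr_log2fc"
) -> pd.DataFrame:
    """Median per (class, sample) of single-guide estimates."""
    merged = singles.assign(class_label=singles["guide"].map(guide_classes))
    return (
        merged.groupby(["class_label", "sample_id"])[column]
        .median()
        .unstack("sample_id")
        .reset_index()
    )


def rank_separation(values_a, values_b, alternative: str = "greater"):
    """One-sided Mann-Whitney rank test that group a exceeds group b."""
    res = stats.mannwhitneyu(values_a, values_b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def plot_dynamics_heatmap(profiles: pd.DataFrame, path, cmap: str = "RdBu_r", vmax: float | None = None):
    """Save a perturbation x sample heatmap of ISR estimates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = profiles.to_numpy()
    if vmax is None:
        vmax = float(np.nanmax(np.abs(data))) or 1.0
    fig, ax = plt.subplots(figsize=(6, max(3, 0.02 * len(profiles))))
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_xticks(range(len(profiles.columns)))
    ax.set_xticklabels(profiles.columns, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_ylabel(f"{len(profiles)} perturbations")
    fig.colorbar(im, ax=ax, label="ISR log2FC (vs controls)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
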