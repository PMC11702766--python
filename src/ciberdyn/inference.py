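"""Per-perturbation growth and ISR phenotypes from barcode counts.

Estimators
----------
ISR activity per barcode clone and sample is the matched-reporter log ratio

    r = log2((c_PCL5 + eps) / (c_UBC6 + eps))

with delta-method variance ``(1/ln2)^2 * (1/(c_PCL5+eps) + 1/(c_UBC6+eps))``.
Growth per barcode clone is the log2 change of the clone's share of the
normalizer (UBC6) reporter between a sample and the pre-induction sample.
Barcode clones of one perturbation are combined by inverse-variance
weighting; perturbation estimates are then centred on the negative-control
perturbations per sample (median by default, which forces the control
median to exactly zero) and perturbations carried by fewer than
``min_barcodes`` clones are dropped, as sparse barcode support makes the
weighted estimate unstable.

The delta-method variance reflects counting (Poisson) noise only.  Counts
from pooled growth are overdispersed between samples, so a global variance
inflation factor is estimated from the residual scatter between barcode
clones of the same perturbation (pooled over all perturbations with >= 2
clones, separately for the ISR and growth estimators) and multiplied into
the clone-level variances.  The matched-reporter ratio largely cancels
clone-abundance noise, so its inflation is near one, while growth contrasts
between samples absorb the full overdispersion.

Significance is a Wald z-test per perturbation with Benjamini-Hochberg FDR
across perturbations within each sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import PRE_SAMPLE
from .library import ParameterError

LN2_SQ_INV = 1.0 / np.log(2.0) ** 2


@dataclass
class InferenceConfig:
    """Estimator settings."""

    pseudocount: float = 0.5
    min_barcodes: int = 2
    control_center: str = "median"  # or "mean"
    fdr_alpha: float = 0.05
    variance_inflation: bool = True

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ParameterError("pseudocount must be > 0")
        if self.min_barcodes < 1:
            raise ParameterError("min_barcodes must be >= 1")
        if self.control_center not in ("median", "mean"):
            raise ParameterError("control_center must be 'median' or 'mean'")
        if not 0 < self.fdr_alpha < 1:
            raise ParameterError("fdr_alpha must be in (0, 1)")


def barcode_log_ratio(c_pcl5, c_ubc6, eps: float = 0.5):
    """Matched-reporter log2 ratio and its delta-method variance."""
    c_pcl5 = np.asarray(c_pcl5, dtype=float)
    c_ubc6 = np.asarray(c_ubc6, dtype=float)
    if eps <= 0:
        raise ParameterError("pseudocount must be > 0")
    if (c_pcl5 < 0).any() or (c_ubc6 < 0).any():
        raise ParameterError("counts must be non-negative")
    ratio = np.log2((c_pcl5 + eps) / (c_ubc6 + eps))
    var = LN2_SQ_INV * (1.0 / (c_pcl5 + eps) + 1.0 / (c_ubc6 + eps))
    return ratio, var


def aggregate_weighted(values, variances):
    """Inverse-variance weighted mean; returns (estimate, se, n)."""
    values = np.asarray(values, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if values.size == 0:
        raise ParameterError("need at least one barcode")
    if (variances <= 0).any():
        raise ParameterError("variances must be positive")
    w = 1.0 / variances
    est = float((w * values).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return est, se, int(values.size)


def growth_log2fc(counts_sample, counts_pre, total_sample: float, total_pre: float, eps: float = 0.5):
    """Per-barcode log2 change of UBC6 share versus pre-induction."""
    if total_sample <= 0 or total_pre <= 0:
        raise ParameterError("totals must be positive")
    c_s = np.asarray(counts_sample, dtype=float)
    c_p = np.asarray(counts_pre, dtype=float)
    if (c_s < 0).any() or (c_p < 0).any():
        raise ParameterError("counts must be non-negative")
    val = np.log2((c_s + eps) / total_sample) - np.log2((c_p + eps) / total_pre)
    var = LN2_SQ_INV * (1.0 / (c_s + eps) + 1.0 / (c_p + eps))
    return val, var


def estimate_variance_inflation(df: pd.DataFrame, value: str, var: str, group) -> float:
    """Pooled residual inflation of delta-method variances.

    For every group with n >= 2 members computes the weighted residual
    chi-square around the weighted mean; the inflation factor is the summed
    chi-square over its degrees of freedom, floored at 1 (the counting-noise
    minimum).
    """
    chi2 = 0.0
    dof = 0
    w = 1.0 / df[var].to_numpy()
    v = df[value].to_numpy()
    codes, _ = pd.factorize(df[group] if isinstance(group, str) else group, sort=False)
    n_groups = codes.max() + 1 if len(codes) else 0
    sw = np.bincount(codes, weights=w, minlength=n_groups)
    swv = np.bincount(codes, weights=w * v, minlength=n_groups)
    mean = swv / sw
    resid = v - mean[codes]
    per_group_chi2 = np.bincount(codes, weights=w * resid**2, minlength=n_groups)
    sizes = np.bincount(codes, minlength=n_groups)
    mask = sizes >= 2
    chi2 = per_group_chi2[mask].sum()
    dof = (sizes[mask] - 1).sum()
    if dof == 0:
        return 1.0
    return max(1.0, float(chi2 / dof))


def normalize_to_controls(
    estimates: pd.DataFrame,
    control_perturbations,
    columns=("isr_log2fc",),
    center: str = "median",
    by: str = "sample_id",
) -> pd.DataFrame:
    """Subtract the per-sample control center from every estimate.

    Control perturbations stay in the output; with median centring the
    median of the controls is exactly zero afterwards.
    """
    control_set = set(control_perturbations)
    if not control_set & set(estimates["perturbation"]):
        raise ParameterError("no control perturbations present in the estimates")
    fn = np.median if center == "median" else np.mean
    out = estimates.copy()
    for sample, idx in out.groupby(by).groups.items():
        block = out.loc[idx]
        ctrl = block[block["perturbation"].isin(control_set)]
        if ctrl.empty:
            raise ParameterError(f"no controls in sample {sample!r}")
        for col in columns:
            vals = ctrl[col].dropna()
            if vals.empty:
                continue
            out.loc[idx, col] = block[col] - fn(vals.to_numpy())
    return out


def apply_barcode_filter(table: pd.DataFrame, min_barcodes: int = 2) -> tuple[pd.DataFrame, int]:
    """Drop rows with fewer than ``min_barcodes`` supporting barcode clones."""
    keep = table["n_barcodes"] >= min_barcodes
    return table[keep].reset_index(drop=True), int((~keep).sum())


def wald_fdr(estimates, ses, alpha: float = 0.05, groups=None):
    """Wald z, two-sided normal p, and BH q (within groups if given)."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if (se <= 0).any():
        raise ParameterError("standard errors must be positive")
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = np.empty_like(p)
    if groups is None:
        q[:] = multipletests(p, alpha=alpha, method="fdr_bh")[1] if len(p) else p
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            m = groups == g
            q[m] = multipletests(p[m], alpha=alpha, method="fdr_bh")[1]
    return z, p, q


def _barcode_level_tables(
    counts: pd.DataFrame,
    construct_to_pert: pd.Series,
    sample_ids: list[str],
    eps: float,
    pre_sample: str,
):
    """Clone-level ISR and growth tables from the wide count table."""
    wide = counts.pivot_table(
        index="construct_id", columns="reporter", values=sample_ids, fill_value=0
    )
    constructs = wide.index.to_numpy()
    pert = construct_to_pert.reindex(constructs)
    if pert.isna().any():
        missing = constructs[pert.isna().to_numpy()][:5]
        raise ParameterError(f"counts contain constructs absent from the map: {list(missing)}")

    isr_rows = []
    growth_rows = []
    pre_u = wide[(pre_sample, "UBC6")].to_numpy() if (pre_sample, "UBC6") in wide else None
    total_pre = float(pre_u.sum()) if pre_u is not None else None
    for s in sample_ids:
        c_u = wide[(s, "UBC6")].to_numpy()
        c_p = wide[(s, "PCL5")].to_numpy()
        val, var = barcode_log_ratio(c_p, c_u, eps)
        isr_rows.append(
            pd.DataFrame(
                {
                    "construct_id": constructs,
                    "perturbation": pert.to_numpy(),
                    "sample_id": s,
                    "value": val,
                    "var": var,
                }
            )
        )
        if s != pre_sample and pre_u is not None:
            total_s = float(c_u.sum())
            gval, gvar = growth_log2fc(c_u, pre_u, total_s, total_pre, eps)
            growth_rows.append(
                pd.DataFrame(
                    {
                        "construct_id": constructs,
                        "perturbation": pert.to_numpy(),
                        "sample_id": s,
                        "value": gval,
                        "var": gvar,
                    }
                )
            )
    isr = pd.concat(isr_rows, ignore_index=True)
    growth = pd.concat(growth_rows, ignore_index=True) if growth_rows else None
    return isr, growth


def _aggregate(table: pd.DataFrame, inflation: float, prefix: str) -> pd.DataFrame:
    var = table["var"].to_numpy() * inflation
    w = 1.0 / var
    df = table.assign(_w=w, _wv=w * table["value"].to_numpy())
    g = df.groupby(["perturbation", "sample_id"], sort=False)
    agg = g.agg(sw=("_w", "sum"), swv=("_wv", "sum"), n_barcodes=("_w", "size")).reset_index()
    agg[f"{prefix}_log2fc"] = agg["swv"] / agg["sw"]
    agg[f"{prefix}_se"] = np.sqrt(1.0 / agg["sw"])
    return agg.drop(columns=["sw", "swv"])


def infer_phenotypes(
    counts: pd.DataFrame,
    construct_map: pd.DataFrame,
    config: InferenceConfig | None = None,
    pre_sample: str = PRE_SAMPLE,
    control_perturbations=None,
) -> pd.DataFrame:
    """Count table -> per (perturbation, sample) phenotype table.

    ``construct_map`` needs columns construct_id and either a perturbation
    column or guide_first/guide_second (from which the canonical unordered
    perturbation id is built); an ``is_control_pair`` column (or the
    ``control_perturbations`` argument) marks the normalization reference.

    The returned long table has one row per perturbation and sample with
    isr_log2fc/isr_se, growth_log2fc/growth_se (NaN for the pre-induction
    sample), n_barcodes, the control-relative normalization applied, the
    ISR Wald statistics z/p/q, and growth_z/growth_p/growth_q.
    """
    config = config or InferenceConfig()
    cm = construct_map.drop_duplicates("construct_id").copy()
    if "perturbation" not in cm.columns:
        from .library import perturbation_id

        cm["perturbation"] = [
            perturbation_id(a, b) for a, b in zip(cm["guide_first"], cm["guide_second"])
        ]
    construct_to_pert = cm.set_index("construct_id")["perturbation"]

    if control_perturbations is None:
        if "is_control_pair" in cm.columns:
            control_perturbations = cm.loc[cm["is_control_pair"], "perturbation"].unique()
        else:
            raise ParameterError(
                "control perturbations must be given or flagged via is_control_pair"
            )

    sample_ids = [c for c in counts.columns if c not in ("construct_id", "reporter")]
    if pre_sample not in sample_ids:
        raise ParameterError(f"pre-induction sample {pre_sample!r} missing from counts")

    isr_bc, growth_bc = _barcode_level_tables(
        counts, construct_to_pert, sample_ids, config.pseudocount, pre_sample
    )
    def _group_key(df):
        return df["perturbation"].astype(str) + "\x1f" + df["sample_id"].astype(str)

    isr_infl = (
        estimate_variance_inflation(isr_bc, "value", "var", _group_key(isr_bc))
        if config.variance_inflation
        else 1.0
    )
    growth_infl = (
        estimate_variance_inflation(growth_bc, "value", "var", _group_key(growth_bc))
        if (config.variance_inflation and growth_bc is not None)
        else 1.0
    )

    pheno = _aggregate(isr_bc, isr_infl, "isr")
    if growth_bc is not None:
        g = _aggregate(growth_bc, growth_infl, "growth").drop(columns=["n_barcodes"])
        pheno = pheno.merge(g, on=["perturbation", "sample_id"], how="left")
    else:
        pheno["growth_log2fc"] = np.nan
        pheno["growth_se"] = np.nan

    pheno["is_control"] = pheno["perturbation"].isin(set(control_perturbations))
    pheno, n_removed = apply_barcode_filter(pheno, config.min_barcodes)
    pheno.attrs["n_removed_by_barcode_filter"] = n_removed
    pheno.attrs["isr_variance_inflation"] = isr_infl
    pheno.attrs["growth_variance_inflation"] = growth_infl

    norm_cols = ["isr_log2fc"]
    if growth_bc is not None:
        norm_cols.append("growth_log2fc")
    pheno = normalize_to_controls(
        pheno, control_perturbations, columns=norm_cols, center=config.control_center
    )

    z, p, q = wald_fdr(
        pheno["isr_log2fc"], pheno["isr_se"], config.fdr_alpha, groups=pheno["sample_id"]
    )
    pheno["z"], pheno["p"], pheno["q"] = z, p, q
    gmask = pheno["growth_se"].notna() & (pheno["growth_se"] > 0)
    pheno["growth_z"] = np.nan
    pheno["growth_p"] = np.nan
    pheno["growth_q"] = np.nan
    if gmask.any():
        gz, gp, gq = wald_fdr(
            pheno.loc[gmask, "growth_log2fc"],
            pheno.loc[gmask, "growth_se"],
            config.fdr_alpha,
            groups=pheno.loc[gmask, "sample_id"],
        )
        pheno.loc[gmask, "growth_z"] = gz
        pheno.loc[gmask, "growth_p"] = gp
        pheno.loc[gmask, "growth_q"] = gq
    return pheno
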