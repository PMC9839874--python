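"""qPCR validation statistics: comparative Ct fold changes, percentile outlier
filtering, ANOVA + Tukey HSD, and BMD-based dose-dependence verdicts.

Relative expression follows the comparative Ct (2^-ddCt) method:

    dCt  = Ct(gene) - Ct(reference gene)           per sample
    ddCt = dCt - mean dCt of the control group     per gene
    FC   = 2^(-ddCt),   log2(FC) = -ddCt

Per gene and concentration, samples with log2(FC) outside the [Q1, Q3]
interval are removed (type-7 linear-interpolation quartiles); an IQR-fence
variant (Q1 - 1.5*IQR, Q3 + 1.5*IQR) is available as a config switch.
Dose-effect testing is one-way ANOVA across concentrations with Tukey HSD
post-hoc comparisons; dose-dependence delegates to the benchmark-dose module
with the extended qPCR model family.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .bmd import BmdConfig, DoseResponseModel

logger = logging.getLogger(__name__)

__all__ = [
    "ddct",
    "percentile_filter",
    "anova_tukey",
    "qpcr_dose_dependence",
    "verdict_table",
]


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str = "ACTB",
    control_concentration: float = 0.0,
) -> pd.DataFrame:
    """Fold-change table from raw Ct values (columns sample_id, concentration,
    gene, ct; optionally time_point, processed independently).

    Samples without a reference-gene Ct are dropped with a warning. The
    control baseline is the mean dCt over control-group samples per gene.
    """
    required = {"sample_id", "concentration", "gene", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    by_time = "time_point" in ct_table.columns
    keys = ["time_point"] if by_time else []
    frames = []
    for _, block in ct_table.groupby(keys, sort=True) if keys else [((), ct_table)]:
        ref = (
            block[block["gene"] == reference_gene]
            .set_index("sample_id")["ct"]
            .to_dict()
        )
        tgt = block[block["gene"] != reference_gene].copy()
        has_ref = tgt["sample_id"].isin(ref)
        if not has_ref.all():
            dropped = sorted(tgt.loc[~has_ref, "sample_id"].unique())
            warnings.warn(
                f"dropped sample(s) without reference Ct: {dropped}", stacklevel=2
            )
            tgt = tgt[has_ref]
        tgt["dct"] = tgt["ct"] - tgt["sample_id"].map(ref)
        baseline = (
            tgt[tgt["concentration"] == control_concentration]
            .groupby("gene")["dct"]
            .mean()
        )
        if baseline.empty:
            raise ValueError("control group is empty")
        tgt["ddct"] = tgt["dct"] - tgt["gene"].map(baseline)
        tgt["log2fc"] = -tgt["ddct"]
        tgt["fc"] = np.exp2(tgt["log2fc"])
        frames.append(tgt)
    return pd.concat(frames, ignore_index=True)


def percentile_filter(
    values: pd.Series | np.ndarray,
    mode: str = "as-printed",
) -> np.ndarray:
    """Outlier filter on one gene x concentration group of log2(FC) values.

    mode="as-printed": retain values within [Q1, Q3] (quartiles by type-7
    linear interpolation). mode="iqr-fence": retain values within
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR]. Groups with fewer than 3 values are
    returned unfiltered with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < 3:
        warnings.warn("fewer than 3 values; percentile filter skipped", stacklevel=2)
        return arr
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    if mode == "as-printed":
        lo, hi = q1, q3
    elif mode == "iqr-fence":
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return arr[(arr >= lo) & (arr <= hi)]


def filter_fold_changes(fc_table: pd.DataFrame, mode: str = "as-printed") -> pd.DataFrame:
    """Apply :func:`percentile_filter` within each gene x concentration group
    (and time point when present)."""
    keys = ["gene", "concentration"] + (
        ["time_point"] if "time_point" in fc_table.columns else []
    )
    kept = []
    for _, grp in fc_table.groupby(keys, sort=True):
        vals = grp["log2fc"].to_numpy(dtype=float)
        if len(vals) < 3:
            kept.append(grp)
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75], method="linear")
        if mode == "iqr-fence":
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        else:
            lo, hi = q1, q3
        kept.append(grp[(grp["log2fc"] >= lo) & (grp["log2fc"] <= hi)])
    return pd.concat(kept, ignore_index=True)


def anova_tukey(
    fc_table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA across concentrations plus Tukey HSD, per gene.

    A gene is testable when >= 2 concentration groups each have >= 2 values;
    untestable genes get p = NaN. Returns (per-gene ANOVA table, pairwise
    Tukey table). "altered" means ANOVA p < alpha.
    """
    keys = ["gene"] + (["time_point"] if "time_point" in fc_table.columns else [])
    anova_rows, tukey_rows = [], []
    for key, grp in fc_table.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        groups = [
            (conc, sub["log2fc"].to_numpy(dtype=float))
            for conc, sub in grp.groupby("concentration", sort=True)
        ]
        usable = [(c, v) for c, v in groups if len(v) >= 2]
        if len(usable) < 2:
            anova_rows.append((*key, np.nan, np.nan, False, False))
            continue
        concs = [c for c, _ in usable]
        samples = [v for _, v in usable]
        f_stat, p = stats.f_oneway(*samples)
        anova_rows.append((*key, float(f_stat), float(p), bool(p < alpha), True))
        hsd = stats.tukey_hsd(*samples)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                tukey_rows.append(
                    (*key, concs[i], concs[j], float(hsd.statistic[i, j]),
                     float(hsd.pvalue[i, j]))
                )
    cols = keys + ["f_stat", "p", "altered", "testable"]
    anova = pd.DataFrame(anova_rows, columns=cols)
    tukey = pd.DataFrame(
        tukey_rows, columns=keys + ["group_a", "group_b", "mean_diff", "p_adj"]
    )
    return anova, tukey


def qpcr_dose_dependence(
    fc_table: pd.DataFrame,
    config: BmdConfig | None = None,
    family: str = "qpcr",
) -> pd.DataFrame:
    """BMD-based dose-dependence verdict per gene (and time point).

    A gene is dose-dependent when the optimal model's lack-of-fit p-value
    exceeds 0.10 and BMD, BMDL and BMDU were all estimable.
    """
    config = config or BmdConfig()
    keys = ["gene"] + (["time_point"] if "time_point" in fc_table.columns else [])
    rows = []
    for key, grp in fc_table.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        dose = grp["concentration"].to_numpy(dtype=float)
        y = grp["log2fc"].to_numpy(dtype=float)
        try:
            res = DoseResponseModel(dose, y, family).fit(config)
        except (ValueError, RuntimeError) as exc:
            logger.info("dose-dependence for %s not testable: %s", key, exc)
            rows.append((*key, None, np.nan, None, None, None, False))
            continue
        lof = res.best.lack_of_fit_p
        relevant = (
            np.isfinite(lof)
            and lof > config.lof_threshold
            and res.bmd is not None
            and res.bmdl is not None
            and res.bmdu is not None
        )
        rows.append(
            (*key, res.best.model, lof, res.bmd, res.bmdl, res.bmdu, bool(relevant))
        )
    return pd.DataFrame(
        rows, columns=keys + ["model", "lack_of_fit_p", "bmd", "bmdl", "bmdu", "dose_dependent"]
    )


def verdict_table(
    ct_table: pd.DataFrame,
    reference_gene: str = "ACTB",
    config: BmdConfig | None = None,
    alpha: float = 0.05,
    filter_mode: str = "as-printed",
) -> pd.DataFrame:
    """Detected / Deregulated / Dose-dependent verdicts per gene and time point.

    Detected: the gene amplified (any finite Ct). Deregulated: ANOVA p <
    alpha on filtered log2(FC). Dose-dependent: BMD verdict from
    :func:`qpcr_dose_dependence`. Mirrors a biomarker validation summary.
    """
    keys = ["gene"] + (["time_point"] if "time_point" in ct_table.columns else [])
    detected = (
        ct_table[ct_table["gene"] != reference_gene]
        .assign(ok=lambda d: np.isfinite(d["ct"].astype(float)))
        .groupby(keys, sort=True)["ok"]
        .any()
        .rename("detected")
        .reset_index()
    )
    present = ct_table[np.isfinite(ct_table["ct"].astype(float))]
    fc = ddct(present, reference_gene=reference_gene)
    filtered = filter_fold_changes(fc, mode=filter_mode)
    anova, _ = anova_tukey(filtered, alpha=alpha)
    dose = qpcr_dose_dependence(filtered, config=config)
    out = detected.merge(anova[keys + ["altered"]], on=keys, how="left")
    out = out.merge(dose[keys + ["dose_dependent"]], on=keys, how="left")
    # verdicts are nested: only detected genes can be deregulated, and
    # dose-dependence is evaluated among the deregulated genes
    out["altered"] = out["altered"].astype("boolean").fillna(False).astype(bool) & out["detected"]
    out["dose_dependent"] = (
        out["dose_dependent"].astype("boolean").fillna(False).astype(bool) & out["altered"]
    )
    return out.rename(columns={"altered": "deregulated"})
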